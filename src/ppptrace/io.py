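"""CSV and YAML I/O with schema validation.

All tabular interchange is plain CSV.  Schema problems are reported with
the offending row numbers so that malformed uploads fail loudly before any
computation runs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .mid import TracerSpec
from .simulate import CellLineSpec, SimulationConfig, TreatmentSpec

INTENSITY_COLUMNS = ["sample_id", "analyte", "fragment_id", "mz", "isotopologue", "intensity"]
CALIBRATION_COLUMNS = ["analyte", "concentration", "response_ratio"]
SAMPLE_COLUMNS = ["sample_id", "analyte", "response_ratio", "protein_ug", "hours"]
SURVIVAL_COLUMNS = ["time", "event", "expression"]
ECAR_COLUMNS = ["time_min", "ecar", "phase"]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} is missing columns: {', '.join(missing)}")


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format isotopologue intensity table."""
    df = pd.read_csv(path)
    _require_columns(df, INTENSITY_COLUMNS, f"intensity table {path}")
    bad = df.index[pd.to_numeric(df["intensity"], errors="coerce").isna()].tolist()
    if bad:
        raise InvalidInputError(
            f"non-numeric intensity at rows {bad[:10]} of {path}"
        )
    neg = df.index[df["intensity"].astype(float) < 0].tolist()
    if neg:
        raise InvalidInputError(f"negative intensity at rows {neg[:10]} of {path}")
    bad_k = df.index[pd.to_numeric(df["isotopologue"], errors="coerce").isna()].tolist()
    if bad_k:
        raise InvalidInputError(f"non-integer isotopologue at rows {bad_k[:10]} of {path}")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, f"survival table {path}")
    if (df["time"] < 0).any():
        raise InvalidInputError(f"negative survival times in {path}")
    if not df["event"].isin([0, 1]).all():
        raise InvalidInputError(f"event column of {path} must be 0/1")
    return df


def load_config(path: str | Path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file.

    Any omitted section falls back to the package defaults, so a config
    may override just the seed or just the noise level.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "lines" in raw:
        kwargs["lines"] = tuple(CellLineSpec(**line) for line in raw["lines"])
    if "treatments" in raw:
        kwargs["treatments"] = tuple(TreatmentSpec(**t) for t in raw["treatments"])
    if "tracer" in raw:
        t = dict(raw["tracer"])
        if "labeled_positions" in t:
            t["labeled_positions"] = frozenset(t["labeled_positions"])
        kwargs["tracer"] = TracerSpec(**t)
    for key in (
        "n_replicates",
        "noise_cv",
        "seed",
        "blank_glucose_mm",
        "blank_lactate_mm",
        "incubation_hours",
        "mean_total_intensity",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    return SimulationConfig(**kwargs)
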