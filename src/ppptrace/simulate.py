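"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the study design: a panel of glioblastoma
brain-tumor-initiating cell (BTIC) lines of proneural or mesenchymal
subtype, with or without metformin, measured by

* GC-MS isotopologue intensities of lactate/pyruvate after
  [1,2-13C2]glucose tracing (:func:`simulate_tracing_dataset`);
* extracellular glucose/lactate isotope-dilution calibration and samples
  (:func:`simulate_exometabolome`);
* glycolysis-stress-test ECAR traces (:func:`simulate_ecar_trace`);
* median-split survival cohorts (:func:`simulate_survival`).

Defaults encode the study's qualitative structure: proneural lines route
more glucose through the oxidative PPP (higher f_ppp) and consume less
glucose; mesenchymal lines are more glycolytic (low f_ppp, high glucose
consumption and lactate output); metformin increases glucose consumption
and lactate production and lowers the PPP share.  Intensity noise is
multiplicative log-normal - GC-MS peak areas are positive and roughly
CV-stable - with a 5% default CV.

Every generator is a pure function of its configuration and seed, and each
tabular output comes with a ground-truth sidecar so recovery tests never
have to re-derive truth from the data themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atomfate import PURE_TRACER, expected_mid
from .assays import EcarTrace
from .correction import build_correction_matrix, convolve_forward
from .exceptions import InvalidInputError
from .mid import DEFAULT_FRAGMENTS, FragmentSpec, TracerSpec

__all__ = [
    "CellLineSpec",
    "TreatmentSpec",
    "SimulationConfig",
    "simulate_tracing_dataset",
    "simulate_exometabolome",
    "simulate_survival",
    "simulate_ecar_trace",
]


@dataclass(frozen=True)
class CellLineSpec:
    """Ground-truth metabolic phenotype of one simulated cell line.

    Rates are in mM per hour of culture supernatant change for a standard
    well; ``protein_ug`` is the per-well protein used for normalization.
    """

    line_id: str
    subtype: str  # "proneural" | "mesenchymal"
    f_ppp: float
    glucose_consumption_rate: float  # mM/h
    lactate_production_rate: float  # mM/h
    protein_ug: float = 100.0

    def __post_init__(self) -> None:
        if self.subtype not in ("proneural", "mesenchymal"):
            raise InvalidInputError(f"unknown subtype {self.subtype!r}")
        if not 0.0 <= self.f_ppp <= 1.0:
            raise InvalidInputError("f_ppp must lie in [0, 1]")


@dataclass(frozen=True)
class TreatmentSpec:
    """A treatment arm: metformin dose plus its effects on the simulated
    phenotype (shift of the PPP fraction, multiplier on glucose/lactate
    rates)."""

    name: str
    metformin_mm: float = 0.0
    f_ppp_shift: float = 0.0
    glucose_rate_multiplier: float = 1.0


#: Default panel mirroring the study's core set: two proneural-like and two
#: mesenchymal-like BTIC lines.  Proneural lines put ~30% of glucose
#: through the oxidative PPP, mesenchymal ~10%; mesenchymal lines consume
#: several-fold more glucose.
DEFAULT_LINES = (
    CellLineSpec("BTIC-8-like", "proneural", 0.30, 0.06, 0.09),
    CellLineSpec("BTIC-18-like", "proneural", 0.30, 0.05, 0.07),
    CellLineSpec("BTIC-11-like", "mesenchymal", 0.10, 0.16, 0.28),
    CellLineSpec("BTIC-13-like", "mesenchymal", 0.10, 0.14, 0.24),
)

#: Default treatment arms: control plus three metformin doses.  Metformin
#: raises glucose consumption and lactate output (glycolytic rescue of
#: inhibited oxidative phosphorylation) and lowers the PPP share.
DEFAULT_TREATMENTS = (
    TreatmentSpec("control"),
    TreatmentSpec("metformin_0.01mM", 0.01, -0.01, 1.05),
    TreatmentSpec("metformin_1mM", 1.0, -0.05, 1.30),
    TreatmentSpec("metformin_10mM", 10.0, -0.08, 1.50),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of the synthetic study."""

    lines: tuple[CellLineSpec, ...] = DEFAULT_LINES
    treatments: tuple[TreatmentSpec, ...] = DEFAULT_TREATMENTS
    n_replicates: int = 3
    noise_cv: float = 0.05
    tracer: TracerSpec = field(default_factory=TracerSpec)
    seed: int = 0
    blank_glucose_mm: float = 17.5  # fresh-medium glucose
    blank_lactate_mm: float = 0.0
    incubation_hours: float = 48.0
    mean_total_intensity: float = 1e6

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")

    def effective_f_ppp(self, line: CellLineSpec, treatment: TreatmentSpec) -> float:
        return float(np.clip(line.f_ppp + treatment.f_ppp_shift, 0.0, 1.0))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise at a given CV."""
    if cv == 0.0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_tracing_dataset(
    config: SimulationConfig | None = None,
    fragments: dict[str, FragmentSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the long-format GC-MS isotopologue intensity table.

    For every line x treatment x replicate x fragment: the model MID at the
    line's effective PPP fraction (nominal-label space) is pushed through
    the measurement operator (tracer impurity + 13C natural abundance),
    scaled to a random total intensity, and perturbed bin-wise by
    multiplicative log-normal noise.

    Returns
    -------
    (data, truth)
        ``data`` with columns sample_id, line_id, treatment, replicate,
        analyte, fragment_id, mz, isotopologue, intensity;
        ``truth`` sidecar with the ground-truth f_ppp per sample.
    """
    config = SimulationConfig() if config is None else config
    fragments = DEFAULT_FRAGMENTS if fragments is None else fragments
    rng = np.random.default_rng(config.seed)
    matrices = {
        fid: build_correction_matrix(frag, config.tracer) for fid, frag in fragments.items()
    }
    rows = []
    truth_rows = []
    for line in config.lines:
        for trt in config.treatments:
            f_eff = config.effective_f_ppp(line, trt)
            for rep in range(1, config.n_replicates + 1):
                sample_id = f"{line.line_id}|{trt.name}|r{rep}"
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "line_id": line.line_id,
                        "subtype": line.subtype,
                        "treatment": trt.name,
                        "replicate": rep,
                        "f_ppp_true": f_eff,
                    }
                )
                for fid, frag in fragments.items():
                    nominal = expected_mid(f_eff, frag, PURE_TRACER)
                    measured = convolve_forward(nominal, matrices[fid])
                    total = config.mean_total_intensity * _lognormal_factors(rng, 0.3, None)
                    noise = _lognormal_factors(rng, config.noise_cv, measured.n_bins)
                    intensities = measured.as_array() * total * noise
                    for k, inten in enumerate(intensities):
                        rows.append(
                            {
                                "sample_id": sample_id,
                                "line_id": line.line_id,
                                "treatment": trt.name,
                                "replicate": rep,
                                "analyte": frag.analyte,
                                "fragment_id": fid,
                                "mz": frag.base_mz + k,
                                "isotopologue": k,
                                "intensity": float(inten),
                            }
                        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_exometabolome(
    config: SimulationConfig | None = None,
    calib_noise_cv: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate isotope-dilution calibration points and supernatant samples.

    Calibration: response ratio = slope * concentration + intercept with
    multiplicative noise at ``calib_noise_cv``.  Samples: medium-blank
    glucose minus 48 h of consumption (floored at zero), lactate as 48 h of
    production, converted to response ratios through the true curve.

    Returns ``(calibration, samples, truth)`` data frames.
    """
    config = SimulationConfig() if config is None else config
    rng = np.random.default_rng(config.seed + 1)
    true_curves = {
        "glucose": (0.10, 0.002),
        "lactate": (0.12, 0.001),
    }
    conc_points = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    calib_rows = []
    for analyte, (slope, intercept) in true_curves.items():
        for conc in conc_points:
            for _ in range(2):
                ratio = (slope * conc + intercept) * _lognormal_factors(rng, calib_noise_cv, None)
                calib_rows.append(
                    {"analyte": analyte, "concentration": conc, "response_ratio": float(ratio)}
                )
    sample_rows = []
    truth_rows = []
    hours = config.incubation_hours
    for line in config.lines:
        for trt in config.treatments:
            mult = trt.glucose_rate_multiplier
            glc = config.blank_glucose_mm - line.glucose_consumption_rate * mult * hours
            glc = max(glc, 0.0)
            lac = config.blank_lactate_mm + line.lactate_production_rate * mult * hours
            truth_rows.append(
                {
                    "line_id": line.line_id,
                    "treatment": trt.name,
                    "glucose_mm": glc,
                    "lactate_mm": lac,
                    "protein_ug": line.protein_ug,
                }
            )
            for rep in range(1, config.n_replicates + 1):
                for analyte, conc in (("glucose", glc), ("lactate", lac)):
                    slope, intercept = true_curves[analyte]
                    ratio = (slope * conc + intercept) * _lognormal_factors(
                        rng, calib_noise_cv, None
                    )
                    sample_rows.append(
                        {
                            "sample_id": f"{line.line_id}|{trt.name}|r{rep}",
                            "line_id": line.line_id,
                            "treatment": trt.name,
                            "replicate": rep,
                            "analyte": analyte,
                            "response_ratio": float(ratio),
                            "protein_ug": line.protein_ug,
                            "hours": hours,
                        }
                    )
    return pd.DataFrame(calib_rows), pd.DataFrame(sample_rows), pd.DataFrame(truth_rows)


def simulate_survival(
    n_per_group: int = 100,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.2,
    seed: int = 0,
    baseline_hazard: float = 0.02,
) -> pd.DataFrame:
    """Simulate a survival cohort with a continuous expression covariate.

    Subjects above the cohort's median expression carry a hazard scaled by
    ``hazard_ratio``; event times are exponential, censoring is independent
    and calibrated so that roughly ``censor_rate`` of subjects are censored.

    Returns columns ``time``, ``event``, ``expression``, ``true_group``.
    """
    if n_per_group < 1:
        raise InvalidInputError("n_per_group must be >= 1")
    if not 0.0 <= censor_rate < 1.0:
        raise InvalidInputError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    expression = rng.lognormal(mean=2.0, sigma=0.5, size=n)
    med = np.median(expression)
    high = expression > med
    hazard = np.where(high, baseline_hazard * hazard_ratio, baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0.0:
        censor_hazard = hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "time": time,
            "event": event,
            "expression": expression,
            "true_group": np.where(high, "high", "low"),
        }
    )


def simulate_ecar_trace(
    basal: float = 10.0,
    post_glucose: float = 40.0,
    post_oligomycin: float = 70.0,
    post_2dg: float = 8.0,
    noise: float = 0.0,
    seed: int = 0,
    n_per_phase: int = 3,
    dt_min: float = 6.0,
) -> EcarTrace:
    """Simulate a glycolysis-stress-test ECAR trace.

    Piecewise-constant phase means (pre-glucose, post-glucose,
    post-oligomycin, post-2-DG) with additive Gaussian noise; injections
    are annotated at the phase boundaries.
    """
    rng = np.random.default_rng(seed)
    levels = [basal, post_glucose, post_oligomycin, post_2dg]
    times = []
    values = []
    t = 0.0
    boundaries = []
    for phase_idx, level in enumerate(levels):
        if phase_idx > 0:
            boundaries.append(t - dt_min / 2.0)
        for _ in range(n_per_phase):
            times.append(t)
            values.append(level + (rng.normal(0.0, noise) if noise > 0 else 0.0))
            t += dt_min
    return EcarTrace(tuple(times), tuple(values), tuple(boundaries))
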