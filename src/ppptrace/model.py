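"""Model/Results interface for PPP-flux estimation, in the style of
statsmodels: a :class:`PPPFluxModel` is built from measured isotopologue
data, its :meth:`~PPPFluxModel.fit` returns a :class:`PPPFluxResults`
carrying the estimate, its uncertainty and diagnostics, and simulation and
plotting hang off the two objects.

Typical use::

    from ppptrace import PPPFluxModel, simulate_tracing_dataset

    data, truth = simulate_tracing_dataset()
    model = PPPFluxModel.from_dataframe(
        data, sample_ids=[s for s in data.sample_id.unique() if "BTIC-18" in s],
        fragment_id="lactate_117",
    )
    res = model.fit(method="least_squares", n_boot=500, seed=1)
    print(res.summary())
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .atomfate import (
    PURE_TRACER,
    FluxPartition,
    bootstrap_ci,
    estimate_fppp_lsq,
    estimate_fppp_ratio,
    expected_mid,
)
from .correction import build_correction_matrix, convolve_forward, correct_mid
from .exceptions import InvalidInputError
from .mid import (
    MID,
    FragmentSpec,
    TracerSpec,
    get_fragment,
    normalize_intensities,
)

__all__ = ["PPPFluxModel", "PPPFluxResults"]


class PPPFluxModel:
    """Partition of glucose catabolism between glycolysis and the oxidative
    PPP, fitted to replicate mass-isotopologue distributions of lactate or
    pyruvate from a [1,2-13C2]glucose tracing experiment.

    Parameters
    ----------
    mids : sequence of MID
        Replicate *measured* MIDs for one fragment (raw fractional
        abundances; correction is applied inside the model unless
        ``apply_correction=False``).
    fragment : FragmentSpec
        The measured ion.
    tracer : TracerSpec, optional
        Tracer lot purity and natural abundance used to build the
        correction operator.  Defaults to 99% purity, natural 13C 1.07%.
    apply_correction : bool
        Set False when the supplied MIDs are already corrected.
    """

    def __init__(
        self,
        mids: Sequence[MID],
        fragment: FragmentSpec,
        tracer: TracerSpec | None = None,
        apply_correction: bool = True,
    ) -> None:
        if len(mids) == 0:
            raise InvalidInputError("need at least one replicate MID")
        self.fragment = fragment
        self.tracer = TracerSpec() if tracer is None else tracer
        self.measured_mids = list(mids)
        if apply_correction:
            cm = build_correction_matrix(fragment, self.tracer)
            self.correction_matrix = cm
            self.corrected_mids = [correct_mid(m, cm) for m in mids]
        else:
            self.correction_matrix = None
            self.corrected_mids = list(mids)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        fragment_id: str = "lactate_117",
        sample_ids: Sequence[str] | None = None,
        tracer: TracerSpec | None = None,
        registry: dict[str, FragmentSpec] | None = None,
        apply_correction: bool = True,
    ) -> "PPPFluxModel":
        """Build a model from a long-format intensity table (columns
        ``sample_id``, ``fragment_id``, ``isotopologue``, ``intensity``);
        each selected sample becomes one replicate MID."""
        frag = get_fragment(fragment_id, registry)
        sub = data[data["fragment_id"] == fragment_id]
        if sample_ids is not None:
            sub = sub[sub["sample_id"].isin(sample_ids)]
        if sub.empty:
            raise InvalidInputError(
                f"no rows for fragment {fragment_id!r} and the requested samples"
            )
        mids = []
        for sid, grp in sub.groupby("sample_id", sort=True):
            vec = (
                grp.sort_values("isotopologue")["intensity"].to_numpy(dtype=float)
            )
            if len(vec) != frag.n_carbons + 1:
                raise InvalidInputError(
                    f"sample {sid!r} has {len(vec)} isotopologue rows, "
                    f"expected {frag.n_carbons + 1}"
                )
            mids.append(normalize_intensities(vec, frag.analyte, fragment_id))
        return cls(mids, frag, tracer, apply_correction=apply_correction)

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        method: str = "least_squares",
        n_boot: int | None = None,
        seed: int = 0,
    ) -> "PPPFluxResults":
        """Estimate the PPP fraction.

        ``method="ratio"`` uses the closed-form m+1/m+2 inversion on the
        mean corrected MID; ``method="least_squares"`` minimizes the
        squared deviation from the model MID.  With ``n_boot`` set (and
        >= 2 replicates) a percentile bootstrap interval is attached.
        """
        mean = np.mean([m.as_array() for m in self.corrected_mids], axis=0)
        mean_mid = MID(tuple(mean / mean.sum()), self.fragment.analyte, self.fragment.fragment_id)
        if method == "ratio":
            part = estimate_fppp_ratio(mean_mid, self.fragment)
        elif method == "least_squares":
            part = estimate_fppp_lsq(self.corrected_mids, self.fragment)
        else:
            raise InvalidInputError(f"unknown method {method!r}")
        if n_boot is not None and len(self.corrected_mids) >= 2:
            ci = bootstrap_ci(
                self.corrected_mids, self.fragment, n_boot=n_boot, seed=seed
            )
            part = FluxPartition(
                part.f_ppp,
                part.estimator,
                ci_low=ci.ci_low,
                ci_high=ci.ci_high,
                clamped=part.clamped,
                degenerate=part.degenerate,
            )
        return PPPFluxResults(self, part, mean_mid)

    # -- simulation -------------------------------------------------------

    def simulate(self, f_ppp: float, measured_space: bool = True) -> MID:
        """Model MID at a given PPP fraction, optionally pushed through the
        measurement operator (natural abundance + impurity)."""
        nominal = expected_mid(f_ppp, self.fragment, PURE_TRACER)
        if measured_space and self.correction_matrix is not None:
            return convolve_forward(nominal, self.correction_matrix)
        return nominal


class PPPFluxResults:
    """Fit results: the flux partition, replicate spread, fitted MID and
    residuals, and a printable summary."""

    def __init__(self, model: PPPFluxModel, partition: FluxPartition, mean_mid: MID) -> None:
        self.model = model
        self.partition = partition
        self.mean_corrected_mid = mean_mid
        self.fitted_mid = expected_mid(partition.f_ppp, model.fragment, PURE_TRACER)

    # -- point estimates ---------------------------------------------------

    @property
    def f_ppp(self) -> float:
        return self.partition.f_ppp

    @property
    def f_glycolysis(self) -> float:
        return self.partition.f_glycolysis

    @property
    def triose_yield_share(self) -> float:
        return self.partition.triose_yield_share

    @property
    def estimator(self) -> str:
        return self.partition.estimator

    @property
    def nobs(self) -> int:
        return len(self.model.corrected_mids)

    def conf_int(self) -> tuple[float, float] | None:
        if self.partition.ci_low is None:
            return None
        return (self.partition.ci_low, self.partition.ci_high)

    @property
    def resid(self) -> np.ndarray:
        """Mean corrected MID minus fitted model MID, per isotopologue bin."""
        return self.mean_corrected_mid.as_array() - self.fitted_mid.as_array()

    @property
    def replicate_f_ppp(self) -> np.ndarray:
        """Per-replicate ratio estimates (diagnostic spread)."""
        return np.array(
            [
                estimate_fppp_ratio(m, self.model.fragment).f_ppp
                for m in self.model.corrected_mids
            ]
        )

    # -- presentation ------------------------------------------------------

    def to_frame(self, sample_id: str = "") -> pd.DataFrame:
        """One tidy row: the export schema used by the pipeline CSVs."""
        p = self.partition
        flags = []
        if p.clamped:
            flags.append("clamped")
        if p.degenerate:
            flags.append("degenerate")
        return pd.DataFrame(
            [
                {
                    "sample_id": sample_id,
                    "analyte": self.model.fragment.analyte,
                    "fragment_id": self.model.fragment.fragment_id,
                    "estimator": p.estimator,
                    "f_ppp": p.f_ppp,
                    "ci_low": p.ci_low,
                    "ci_high": p.ci_high,
                    "flags": ";".join(flags),
                }
            ]
        )

    def summary(self) -> str:
        p = self.partition
        frag = self.model.fragment
        lines = [
            "PPP flux partition ([1,2-13C2]glucose tracing)",
            "=" * 48,
            f"analyte:            {frag.analyte}",
            f"fragment:           {frag.fragment_id} "
            f"(C{'-C'.join(str(c) for c in sorted(frag.retained_carbons))})",
            f"replicates:         {self.nobs}",
            f"estimator:          {p.estimator}",
            f"f_PPP:              {p.f_ppp:.4f}",
            f"f_glycolysis:       {p.f_glycolysis:.4f}",
            f"PPP triose share:   {self.triose_yield_share:.4f}",
        ]
        if p.ci_low is not None:
            lines.append(f"95% bootstrap CI:   [{p.ci_low:.4f}, {p.ci_high:.4f}]")
        if p.clamped:
            lines.append("note: raw inversion outside [0,1]; estimate clamped")
        if p.degenerate:
            lines.append("note: degenerate labeling signal (m+1/m+2 uninformative)")
        mids = self.mean_corrected_mid.fractions
        fit = self.fitted_mid.fractions
        lines.append("")
        lines.append("bin     corrected   fitted")
        for k, (o, f) in enumerate(zip(mids, fit)):
            lines.append(f"m+{k}     {o:.4f}      {f:.4f}")
        return "\n".join(lines)

    def plot_mid(self, ax=None):
        """Bar plot of the mean corrected MID against the fitted model MID."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = np.arange(self.mean_corrected_mid.n_bins)
        width = 0.38
        ax.bar(k - width / 2, self.mean_corrected_mid.fractions, width, label="corrected")
        ax.bar(k + width / 2, self.fitted_mid.fractions, width, label="fitted")
        ax.set_xticks(k)
        ax.set_xticklabels([f"m+{i}" for i in k])
        ax.set_ylabel("fractional abundance")
        ax.set_title(f"f_PPP = {self.f_ppp:.3f} ({self.model.fragment.fragment_id})")
        ax.legend()
        return ax
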