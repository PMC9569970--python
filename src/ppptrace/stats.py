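"""Inferential statistics: balanced two-way ANOVA with Tukey HSD,
median-split group labeling, Kaplan-Meier curves and the log-rank
(Mantel-Cox) test.

The ANOVA is deliberately balanced-only.  With equal replication the
classical fixed-effects sum-of-squares decomposition is unambiguous;
refusing unbalanced input avoids silently choosing among Type I/II/III
sums of squares.  Significance stars follow the usual convention:
* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    InvalidGroupingError,
    InvalidInputError,
    SplitImpossibleError,
    UnbalancedDesignError,
)

__all__ = [
    "AnovaResult",
    "two_way_anova",
    "tukey_hsd",
    "median_split",
    "logrank_test",
    "LogRankResult",
    "km_curve",
    "KaplanMeierCurve",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional asterisk annotation."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    """Fixed-effects two-way ANOVA decomposition for a balanced design.

    ``effects`` maps each source (factor names, ``"interaction"``,
    ``"residual"``) to a dict with ``ss``, ``df``, ``ms``, ``F``, ``p``.
    ``degenerate`` marks a zero residual mean square, in which case F is
    reported as 0 and p as 1 by convention.
    """

    effects: dict[str, dict[str, float]]
    grand_mean: float
    cell_means: pd.DataFrame
    n_per_cell: int
    degenerate: bool = False

    @property
    def mse(self) -> float:
        return self.effects["residual"]["ms"]

    @property
    def df_resid(self) -> int:
        return int(self.effects["residual"]["df"])

    def table(self) -> pd.DataFrame:
        rows = []
        for source, e in self.effects.items():
            rows.append(
                {
                    "source": source,
                    "sum_sq": e["ss"],
                    "df": e["df"],
                    "mean_sq": e["ms"],
                    "F": e.get("F", np.nan),
                    "p": e.get("p", np.nan),
                    "stars": significance_stars(e["p"]) if "p" in e else "",
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Two-way ANOVA (balanced, fixed effects)"]
        lines.append(self.table().to_string(index=False, float_format=lambda x: f"{x:.6g}"))
        if self.degenerate:
            lines.append("note: zero residual variance; F/p reported by convention")
        return "\n".join(lines)


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str = "factor_b",
) -> AnovaResult:
    """Classical balanced two-way ANOVA with interaction.

    Requires >= 2 levels per factor and equal replication (>= 2) in every
    cell; raises :class:`UnbalancedDesignError` otherwise.
    """
    df = data[[factor_a, factor_b, value]].dropna()
    counts = df.groupby([factor_a, factor_b], observed=True)[value].count()
    a_levels = df[factor_a].unique()
    b_levels = df[factor_b].unique()
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise InvalidInputError("need >= 2 levels per factor")
    if len(counts) != a * b or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "two-way ANOVA here supports balanced designs only "
            "(equal replication in every factor-level cell)"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise UnbalancedDesignError("need >= 2 replicates per cell")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    cell = df.groupby([factor_a, factor_b], observed=True)[value].mean()
    mean_a = df.groupby(factor_a, observed=True)[value].mean()
    mean_b = df.groupby(factor_b, observed=True)[value].mean()

    ss_a = b * r * float(((mean_a - grand) ** 2).sum())
    ss_b = a * r * float(((mean_b - grand) ** 2).sum())
    ss_ab = r * float(
        sum(
            (cell[(la, lb)] - mean_a[la] - mean_b[lb] + grand) ** 2
            for la in a_levels
            for lb in b_levels
        )
    )
    fitted = df.set_index([factor_a, factor_b]).index.map(cell)
    ss_e = float(((y - fitted.to_numpy(dtype=float)) ** 2).sum())

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_e = a * b * (r - 1)
    ms_e = ss_e / df_e
    degenerate = ms_e <= 0.0

    def effect(ss: float, dof: int) -> dict[str, float]:
        ms = ss / dof
        if degenerate:
            return {"ss": ss, "df": dof, "ms": ms, "F": 0.0, "p": 1.0}
        F = ms / ms_e
        return {"ss": ss, "df": dof, "ms": ms, "F": F, "p": float(sps.f.sf(F, dof, df_e))}

    effects = {
        factor_a: effect(ss_a, df_a),
        factor_b: effect(ss_b, df_b),
        "interaction": effect(ss_ab, df_ab),
        "residual": {"ss": ss_e, "df": df_e, "ms": ms_e},
    }
    return AnovaResult(
        effects=effects,
        grand_mean=float(grand),
        cell_means=cell.rename("mean").reset_index(),
        n_per_cell=r,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------


def tukey_hsd(
    group_means: dict[str, float],
    mse: float,
    df_resid: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All-pairs Tukey honestly-significant-difference comparisons.

    The studentized-range statistic for a pair is
    ``q = |mean_i - mean_j| / sqrt(mse / n)`` and the adjusted p-value is
    the survival function of the studentized range distribution with ``k``
    groups and ``df_resid`` error degrees of freedom.  A zero ``mse`` is
    reported with the ``degenerate`` flag (p = 1 for tied means).
    """
    if mse < 0:
        raise InvalidInputError("mse must be non-negative")
    names = list(group_means)
    k = len(names)
    if k < 2:
        raise InvalidInputError("need >= 2 groups")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = group_means[names[i]] - group_means[names[j]]
            if mse == 0.0:
                q = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
                degen = True
            else:
                q = abs(diff) / np.sqrt(mse / n_per_group)
                p = float(sps.studentized_range.sf(q, k, df_resid))
                degen = False
            rows.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": p,
                    "significant": p < alpha,
                    "stars": significance_stars(p),
                    "degenerate": degen,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Median split / survival
# ---------------------------------------------------------------------------


def median_split(values) -> np.ndarray:
    """Label each value ``"high"`` (above the median) or ``"low"``.

    Values equal to the median go to ``"low"`` - a deterministic tie rule.
    Raises :class:`SplitImpossibleError` if either group would be empty
    (e.g. all values identical).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise SplitImpossibleError("need >= 2 values to split")
    med = float(np.median(x))
    labels = np.where(x > med, "high", "low")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise SplitImpossibleError("median split would leave an empty group")
    return labels


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: dict[str, float] = field(default_factory=dict)
    expected: dict[str, float] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test.

    At each distinct event time the observed number of events in group 1 is
    compared with its hypergeometric expectation given the risk sets;
    the statistic ``(sum O - sum E)^2 / sum V`` is referred to a chi-square
    distribution with one degree of freedom.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if t.size != e.size or t.size != g.size:
        raise InvalidInputError("times, events, groups must have equal length")
    if np.any(t < 0):
        raise InvalidInputError("survival times must be non-negative")
    labels = np.unique(g)
    if labels.size != 2:
        raise InvalidGroupingError(f"log-rank needs exactly two groups, got {labels.size}")
    in1 = g == labels[0]
    if in1.sum() == 0 or (~in1).sum() == 0:
        raise InvalidGroupingError("one group is empty")
    if e.sum() == 0:
        raise InvalidInputError("no events observed")

    o_minus_e = 0.0
    var = 0.0
    obs1 = 0.0
    exp1 = 0.0
    for tau in np.unique(t[e == 1]):
        at_risk = t >= tau
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = ((t == tau) & (e == 1)).sum()
        d1 = ((t == tau) & (e == 1) & in1).sum()
        expected = d * n1 / n
        o_minus_e += d1 - expected
        obs1 += d1
        exp1 += expected
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return LogRankResult(0.0, 1.0)
    stat = o_minus_e**2 / var
    p = float(sps.chi2.sf(stat, 1))
    total_events = float(e.sum())
    return LogRankResult(
        float(stat),
        p,
        observed={str(labels[0]): obs1, str(labels[1]): total_events - obs1},
        expected={str(labels[0]): exp1, str(labels[1]): total_events - exp1},
    )


@dataclass(frozen=True)
class KaplanMeierCurve:
    """Product-limit survival estimate: a right-continuous step function
    starting at S(0) = 1."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    n_at_risk: tuple[int, ...]

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        return self.survival[idx] if idx >= 0 else 1.0

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.times, self.survival, where="post", label=label)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


def km_curve(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator for one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0 or t.size != e.size:
        raise InvalidInputError("times and events must be equal-length, non-empty")
    if np.any(t < 0):
        raise InvalidInputError("survival times must be non-negative")
    out_t = [0.0]
    out_s = [1.0]
    out_n = [int(t.size)]
    s = 1.0
    for tau in np.unique(t[e == 1]):
        n = int((t >= tau).sum())
        d = int(((t == tau) & (e == 1)).sum())
        s *= 1.0 - d / n
        out_t.append(float(tau))
        out_s.append(s)
        out_n.append(n)
    return KaplanMeierCurve(tuple(out_t), tuple(out_s), tuple(out_n))
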