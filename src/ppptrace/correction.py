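"""Isotopologue correction operators: 13C natural abundance and tracer
impurity.

The measurement operator is a square matrix ``M`` whose column ``j`` is the
measured isotopologue distribution of a molecule carrying exactly ``j``
nominal tracer labels.  Two effects move signal between bins:

* **tracer impurity** - each nominal label is actually 13C only with
  probability ``purity`` (binomial thinning, moves signal *down*);
* **natural abundance** - each unlabeled carbon (and, in full-formula
  mode, every other atom of the ion) is heavy with its natural isotope
  probability (moves signal *up*).

Simulation uses the forward direction (``convolve_forward``); analysis
inverts it.  Correction solves a non-negative least-squares problem rather
than inverting the matrix directly: near-triangular operators amplify noise
into negative bins, and the NNLS solution guarantees non-negative corrected
fractions.  The measured vector only resolves shifts 0..n, so probability
mass beyond m+n is truncated and each column renormalized within the
observed bins - a small bias at high natural abundance, documented rather
than modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.stats import binom

from .exceptions import ConditioningError, ConfigurationError, InvalidInputError
from .mid import MID, FragmentSpec, TracerSpec

__all__ = ["CorrectionMatrix", "build_correction_matrix", "convolve_forward", "correct_mid"]

#: Natural isotopic mass-shift distributions of elements commonly present
#: in GC-MS derivatives (probability of +0/+1/+2 mass units per atom).
ELEMENT_SHIFT_DISTRIBUTIONS: dict[str, dict[int, float]] = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "Si": {0: 0.92223, 1: 0.04685, 2: 0.03092},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425},
}


@dataclass(frozen=True)
class CorrectionMatrix:
    """Measurement operator mapping nominal tracer-label counts to the
    measured isotopologue space."""

    matrix: np.ndarray
    n_carbons: int
    includes_purity: bool
    nat_abund: float
    mode: str = "carbon_only"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != self.n_carbons + 1:
            raise InvalidInputError("correction matrix must be (n+1) x (n+1)")
        if np.any(m < 0):
            raise InvalidInputError("correction matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def size(self) -> int:
        return self.n_carbons + 1


def _shift_pmf(dist: dict[int, float], count: int, n_max: int) -> np.ndarray:
    """PMF of the total mass shift of ``count`` i.i.d. atoms, truncated at
    ``n_max`` (mass collected into a dump bin beyond n_max is dropped)."""
    pmf = np.zeros(n_max + 1)
    pmf[0] = 1.0
    single = np.zeros(max(dist) + 1)
    for shift, prob in dist.items():
        single[shift] = prob
    for _ in range(count):
        pmf = np.convolve(pmf, single)[: n_max + 1]
    return pmf


def build_correction_matrix(
    fragment: FragmentSpec,
    tracer: TracerSpec | None = None,
    mode: str = "carbon_only",
) -> CorrectionMatrix:
    """Build the measurement operator for a fragment ion.

    Parameters
    ----------
    fragment : FragmentSpec
        Determines the number of backbone carbons ``n`` in the ion (matrix
        size ``n+1``) and, in full-formula mode, the elemental composition.
    tracer : TracerSpec
        Supplies the lot purity and the natural 13C abundance.  ``None``
        means a pure tracer at the standard natural abundance.
    mode : str
        ``"carbon_only"`` corrects backbone-carbon 13C natural abundance
        plus tracer impurity (the default scope of MID correction);
        ``"full_formula"`` additionally corrects heavy isotopes of all
        other atoms in ``fragment.formula``.

    Column ``j`` is the distribution of the measured mass shift for a
    molecule with ``j`` nominal labels: the labels are thinned by the
    purity, the remaining unlabeled backbone carbons pick up natural 13C,
    and heteroatoms (full-formula mode) add their own shifts.  Columns are
    renormalized after truncation to bins 0..n.
    """
    tracer = TracerSpec(purity=1.0) if tracer is None else tracer
    n = fragment.n_carbons
    if n < 1:
        raise InvalidInputError("fragment must retain at least one carbon")
    a = tracer.nat_abund_13c
    pi = tracer.purity

    hetero = None
    if mode == "full_formula":
        if fragment.formula is None:
            raise ConfigurationError(
                f"fragment {fragment.fragment_id!r} has no elemental formula; "
                "full_formula correction needs one"
            )
        hetero = np.zeros(n + 1)
        hetero[0] = 1.0
        for element, count in fragment.formula.items():
            if element == "C":
                count = count - n  # backbone carbons handled positionally
                if count < 0:
                    raise ConfigurationError(
                        "formula carbon count below backbone carbon count"
                    )
            if count == 0:
                continue
            if element not in ELEMENT_SHIFT_DISTRIBUTIONS:
                raise ConfigurationError(f"no isotope data for element {element!r}")
            hetero = np.convolve(
                hetero, _shift_pmf(ELEMENT_SHIFT_DISTRIBUTIONS[element], count, n)
            )[: n + 1]
    elif mode != "carbon_only":
        raise ConfigurationError(f"unknown correction mode {mode!r}")

    cols = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        col = np.zeros(n + 1)
        # k of the j nominal labels survive thinning; the n-k unlabeled
        # carbons each carry natural 13C independently.
        for k in range(j + 1):
            w = binom.pmf(k, j, pi)
            if w == 0.0:
                continue
            na = binom.pmf(np.arange(n - k + 1), n - k, a)
            col[k : n + 1] += w * na[: n + 1 - k]
        if hetero is not None:
            col = np.convolve(col, hetero)[: n + 1]
        col_sum = col.sum()
        cols[:, j] = col / col_sum
    return CorrectionMatrix(cols, n, includes_purity=pi < 1.0, nat_abund=a, mode=mode)


def convolve_forward(true_mid: MID, cm: CorrectionMatrix) -> MID:
    """Forward-apply the measurement operator (simulation direction)."""
    x = true_mid.as_array()
    if x.size != cm.size:
        raise InvalidInputError(
            f"MID has {x.size} bins but correction matrix is {cm.size}x{cm.size}"
        )
    y = cm.matrix @ x
    return MID(tuple(y / y.sum()), true_mid.analyte, true_mid.fragment_id)


def correct_mid(measured: MID, cm: CorrectionMatrix) -> MID:
    """Remove natural abundance and tracer impurity from a measured MID.

    Solves ``min ||M x - measured||^2  s.t.  x >= 0`` and renormalizes the
    solution; the round trip ``correct_mid(convolve_forward(x))`` recovers
    ``x`` to 1e-8 on noiseless data.

    Raises
    ------
    ConditioningError
        Operator numerically singular (condition number > 1e12).
    """
    y = measured.as_array()
    if y.size != cm.size:
        raise InvalidInputError(
            f"MID has {y.size} bins but correction matrix is {cm.size}x{cm.size}"
        )
    cond = np.linalg.cond(cm.matrix)
    if not np.isfinite(cond) or cond > 1e12:
        raise ConditioningError(
            f"correction matrix numerically singular (condition number {cond:.3g})"
        )
    x, _ = nnls(cm.matrix, y)
    s = x.sum()
    if s <= 0:
        raise ConditioningError("NNLS returned an all-zero solution")
    return MID(tuple(x / s), measured.analyte, measured.fragment_id)
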