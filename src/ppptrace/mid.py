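"""Core domain types for positional isotopomers, mass-isotopologue
distributions (MIDs) and GC-MS fragment ions.

Conventions
-----------
Carbon positions are 1-based throughout the package: C1 is the carboxyl
carbon of lactate/pyruvate and the aldehyde carbon (C1) of glucose, matching
the bracket notation ``[13C2-1,2]glucose`` used in tracing work.  A
*positional isotopomer* records which backbone carbons carry 13C; a *mass
isotopologue* records only the total number of heavy carbons in a measured
ion.  Projecting positional isotopomers onto a fragment ion (which retains
only a subset of backbone carbons) is what lets the C2-C3 lactate fragment
disambiguate PPP-derived [1,3-13C2]lactate (m+1 on the fragment) from
glycolytic [2,3-13C2]lactate (m+2 on the fragment).

Weights on isotopomers are relative molar amounts; equal ionization
efficiency across isotopologues is assumed.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DegenerateSampleError,
    InvalidFragmentError,
    InvalidInputError,
    InvalidIntensityError,
)

#: Backbone carbon counts of the analytes handled by the tracing model.
BACKBONE_CARBONS: dict[str, int] = {"lactate": 3, "pyruvate": 3, "glucose": 6}

#: Natural abundance of 13C (probability that a carbon is 13C).
NATURAL_13C_ABUNDANCE = 0.0107

#: Tolerance for the sum-to-one invariant of a MID after normalization.
MID_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FragmentSpec:
    """A measured ion: which backbone carbons it retains and its base m/z.

    Parameters
    ----------
    fragment_id : str
        Registry key, e.g. ``"lactate_117"``.
    analyte : str
        One of ``lactate``, ``pyruvate``, ``glucose``.
    retained_carbons : frozenset[int]
        1-based backbone positions present in the ion.
    base_mz : float
        Nominal m/z of the fully unlabeled (m+0) ion.
    formula : dict[str, int], optional
        Elemental composition of the ion, needed only for full-formula
        isotope correction (heteroatoms of the derivative).
    label : str
        Human-readable description.
    """

    fragment_id: str
    analyte: str
    retained_carbons: frozenset[int]
    base_mz: float
    formula: Mapping[str, int] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.analyte not in BACKBONE_CARBONS:
            raise InvalidInputError(f"unknown analyte {self.analyte!r}")
        n_backbone = BACKBONE_CARBONS[self.analyte]
        carbons = frozenset(int(c) for c in self.retained_carbons)
        if not carbons:
            raise InvalidFragmentError("fragment retains no carbons")
        if any(c < 1 or c > n_backbone for c in carbons):
            raise InvalidFragmentError(
                f"retained carbons {sorted(carbons)} outside 1..{n_backbone} "
                f"backbone of {self.analyte}"
            )
        object.__setattr__(self, "retained_carbons", carbons)
        if self.base_mz <= 0:
            raise InvalidInputError("base_mz must be positive")

    @property
    def n_carbons(self) -> int:
        """Number of backbone carbons retained in the ion."""
        return len(self.retained_carbons)

    @property
    def is_full_backbone(self) -> bool:
        return self.n_carbons == BACKBONE_CARBONS[self.analyte]


@dataclass(frozen=True)
class TracerSpec:
    """The labeled substrate: which glucose carbons are nominally 13C and
    with what isotopic purity.

    ``purity`` is the per-position probability that a nominally labeled
    carbon actually carries 13C (lot purity of the tracer);
    ``nat_abund_13c`` is the background probability that any carbon is 13C.
    """

    labeled_positions: frozenset[int] = frozenset({1, 2})
    purity: float = 0.99
    nat_abund_13c: float = NATURAL_13C_ABUNDANCE

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labeled_positions", frozenset(int(p) for p in self.labeled_positions)
        )
        if not 0.0 <= self.purity <= 1.0:
            raise InvalidInputError("purity must lie in [0, 1]")
        if not 0.0 <= self.nat_abund_13c < 0.5:
            raise InvalidInputError("nat_abund_13c must lie in [0, 0.5)")


@dataclass(frozen=True)
class PositionalIsotopomer:
    """A labeling pattern over a metabolite's carbon backbone with a molar
    weight (relative units)."""

    analyte: str
    carbon_labels: tuple[bool, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.analyte not in BACKBONE_CARBONS:
            raise InvalidInputError(f"unknown analyte {self.analyte!r}")
        labels = tuple(bool(x) for x in self.carbon_labels)
        if len(labels) != BACKBONE_CARBONS[self.analyte]:
            raise InvalidInputError(
                f"{self.analyte} has {BACKBONE_CARBONS[self.analyte]} backbone "
                f"carbons, got {len(labels)} label flags"
            )
        object.__setattr__(self, "carbon_labels", labels)
        if self.weight < 0:
            raise InvalidInputError("isotopomer weight must be non-negative")

    @classmethod
    def from_positions(
        cls, analyte: str, labeled: Iterable[int], weight: float = 1.0
    ) -> "PositionalIsotopomer":
        """Build from 1-based labeled positions, e.g. ``{1, 3}`` for
        [1,3-13C2]lactate."""
        n = BACKBONE_CARBONS.get(analyte)
        if n is None:
            raise InvalidInputError(f"unknown analyte {analyte!r}")
        positions = {int(p) for p in labeled}
        if any(p < 1 or p > n for p in positions):
            raise InvalidInputError(f"labeled positions {sorted(positions)} outside 1..{n}")
        return cls(analyte, tuple(i + 1 in positions for i in range(n)), weight)

    @property
    def labeled_positions(self) -> frozenset[int]:
        return frozenset(i + 1 for i, flag in enumerate(self.carbon_labels) if flag)

    @property
    def label_count(self) -> int:
        return sum(self.carbon_labels)


@dataclass(frozen=True)
class MID:
    """A mass-isotopologue distribution: fractional abundances of
    m+0 ... m+n for one analyte/fragment.

    Invariants: all fractions non-negative and summing to one within
    ``MID_SUM_TOL``; length equals retained carbons + 1.
    """

    fractions: tuple[float, ...]
    analyte: str
    fragment_id: str

    def __post_init__(self) -> None:
        fr = tuple(float(x) for x in np.asarray(self.fractions, dtype=float))
        if len(fr) < 1:
            raise InvalidInputError("MID needs at least one bin")
        if any(x < -MID_SUM_TOL for x in fr):
            raise InvalidInputError("MID fractions must be non-negative")
        fr = tuple(max(x, 0.0) for x in fr)
        if abs(sum(fr) - 1.0) > MID_SUM_TOL:
            raise InvalidInputError(
                f"MID fractions must sum to 1 (got {sum(fr):.12f})"
            )
        object.__setattr__(self, "fractions", fr)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.fractions)

    def __getitem__(self, k: int) -> float:
        return self.fractions[k]


# ---------------------------------------------------------------------------
# Fragment registry
# ---------------------------------------------------------------------------

#: Fragments shipped by default.  The lactate C2-C3 ion (m/z 117/118/119) is
#: the diagnostic fragment that separates PPP [1,3-13C2] (m+1 there) from
#: glycolytic [2,3-13C2] (m+2).  The full-backbone ions are the [M-CH3]+ ions
#: of the GC derivatives; their base m/z values are registry configuration.
DEFAULT_FRAGMENTS: dict[str, FragmentSpec] = {
    "lactate_117": FragmentSpec(
        "lactate_117", "lactate", frozenset({2, 3}), 117.0,
        label="lactate derivative fragment retaining C2-C3 (m/z 117)",
    ),
    "lactate_full": FragmentSpec(
        "lactate_full", "lactate", frozenset({1, 2, 3}), 219.0,
        label="lactate derivative [M-CH3]+ (full C1-C3 backbone)",
    ),
    "pyruvate_full": FragmentSpec(
        "pyruvate_full", "pyruvate", frozenset({1, 2, 3}), 174.0,
        label="pyruvate derivative [M-CH3]+ (full C1-C3 backbone)",
    ),
}


def get_fragment(fragment_id: str, registry: Mapping[str, FragmentSpec] | None = None) -> FragmentSpec:
    reg = DEFAULT_FRAGMENTS if registry is None else registry
    try:
        return reg[fragment_id]
    except KeyError as exc:
        raise InvalidFragmentError(f"unknown fragment {fragment_id!r}") from exc


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def positional_to_mid(
    isotopomers: Sequence[PositionalIsotopomer], fragment: FragmentSpec
) -> MID:
    """Project a weighted set of positional isotopomers onto a fragment ion.

    Each isotopomer contributes its weight to the isotopologue bin equal to
    the number of labeled carbons among the fragment's retained carbons; the
    result is normalized to sum to one.

    Raises
    ------
    InvalidInputError
        Empty list or zero total weight.
    InvalidFragmentError
        Fragment analyte does not match the isotopomers.
    """
    if len(isotopomers) == 0:
        raise InvalidInputError("empty isotopomer list")
    for iso in isotopomers:
        if iso.analyte != fragment.analyte:
            raise InvalidFragmentError(
                f"isotopomer analyte {iso.analyte!r} does not match fragment "
                f"analyte {fragment.analyte!r}"
            )
    total = sum(iso.weight for iso in isotopomers)
    if total <= 0:
        raise InvalidInputError("total isotopomer weight must be positive")
    bins = np.zeros(fragment.n_carbons + 1)
    retained = fragment.retained_carbons
    for iso in isotopomers:
        k = len(iso.labeled_positions & retained)
        bins[k] += iso.weight
    return MID(tuple(bins / total), fragment.analyte, fragment.fragment_id)


def normalize_intensities(
    raw: Sequence[float],
    analyte: str = "lactate",
    fragment_id: str = "lactate_full",
) -> MID:
    """Convert raw isotopologue ion intensities to fractional abundances.

    Raises
    ------
    InvalidIntensityError
        Any negative entry.
    DegenerateSampleError
        All-zero vector.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidInputError("intensity input must be a non-empty 1-D vector")
    if np.any(arr < 0):
        raise InvalidIntensityError("negative ion intensity")
    s = arr.sum()
    if s <= 0:
        raise DegenerateSampleError("all-zero intensity vector")
    return MID(tuple(arr / s), analyte, fragment_id)
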