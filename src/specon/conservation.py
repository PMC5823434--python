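"""Equivalency-group positional entropy and specific-conservation (SC) profiling.

Conservation at an alignment column is scored as the *exponential* Shannon
entropy of amino-acid equivalency-group frequencies,

    positional entropy = exp(-sum_i p_i ln p_i),

where ``p_i`` is the fraction of counted residues falling in group ``i``.
The value is the effective number of groups present: 1 for a perfectly
conserved column, up to the number of groups (6 by default) for a column
where every group is equally frequent. Columns with too many gaps (non-gap
fraction below a threshold, 0.64 by default) get no entropy.

The specific conservation (SC) of a canonical position is the ratio of the
entropy in the family's paralog alignment to the entropy in one member's
ortholog alignment. A high SC flags a residue that diverges across family
members but is held fixed among the member's orthologs — a candidate
specificity determinant.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import GAP, Alignment, CanonicalMap, ColumnLabel

__all__ = [
    "DEFAULT_GROUPS",
    "GAP_THRESHOLD",
    "SC_CUTOFF",
    "INSERTION_CUTOFF",
    "EquivalencyScheme",
    "PositionProfile",
    "PositionSC",
    "ConservationProfile",
    "SurfaceDefinition",
    "DEFAULT_SURFACES",
    "LoopRegions",
    "DomainSummary",
    "positional_entropy",
    "profile_alignment",
    "sc_profile",
    "average_region_sc",
    "family_position_average",
    "conserved_insertion_count",
    "summarize_domain",
]

#: The six amino-acid equivalency groups used for all entropy and PSSM work.
DEFAULT_GROUPS = ("AVLIMC", "FWYH", "STNQ", "KR", "DE", "GP")

#: Minimum non-gap fraction for an entropy to be computed (~19 of 29 rows).
GAP_THRESHOLD = 0.64

#: Average SC at or above this marks a region as highly specifically conserved.
SC_CUTOFF = 1.7

#: Ortholog entropy at or below this marks an insertion/flank column conserved.
INSERTION_CUTOFF = 3.3


@dataclass(frozen=True)
class EquivalencyScheme:
    """Disjoint residue-letter groups treated as interchangeable."""

    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("an equivalency scheme needs at least 2 groups")
        seen: set[str] = set()
        for g in self.groups:
            letters = set(g)
            if letters & seen:
                raise ValueError("equivalency groups must be disjoint")
            seen |= letters

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_of(self, residue: str) -> int | None:
        """Index of the group containing ``residue``; None for gaps and
        letters outside the scheme (ambiguity codes)."""
        for i, g in enumerate(self.groups):
            if residue in g:
                return i
        return None


DEFAULT_SCHEME = EquivalencyScheme()


@dataclass
class PositionProfile:
    """Group frequencies and entropy at one alignment column."""

    label: ColumnLabel
    group_fractions: np.ndarray
    nongap_fraction: float
    entropy: float  # nan when undefined (too many gaps)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.entropy)


def _group_counts(column: Iterable[str], scheme: EquivalencyScheme) -> np.ndarray:
    counts = np.zeros(scheme.k, dtype=int)
    for ch in column:
        g = scheme.group_of(ch)
        if g is not None:
            counts[g] += 1
    return counts


def positional_entropy(
    column: Sequence[str],
    scheme: EquivalencyScheme = DEFAULT_SCHEME,
    gap_threshold: float = GAP_THRESHOLD,
) -> float:
    """Exponential Shannon entropy of equivalency-group frequencies.

    ``column`` is the multiset of characters at one alignment column (residue
    letters and gaps). Gaps and letters outside the scheme are excluded from
    both numerator and denominator of the fractions; the 0*ln(0) limit is
    taken as 0. Returns ``nan`` when the non-gap fraction falls below
    ``gap_threshold``.
    """
    if not len(column):
        raise ValueError("empty column")
    counts = _group_counts(column, scheme)
    total = int(counts.sum())
    nongap = total / len(column)
    if nongap < gap_threshold or total == 0:
        return math.nan
    p = counts[counts > 0] / total
    return float(math.exp(-(p * np.log(p)).sum()))


def profile_alignment(
    alignment: Alignment,
    cmap: CanonicalMap | None = None,
    scheme: EquivalencyScheme = DEFAULT_SCHEME,
    gap_threshold: float = GAP_THRESHOLD,
) -> list[PositionProfile]:
    """Profile every column of an alignment: group fractions, non-gap
    fraction and entropy, labelled on the canonical frame when a map is
    given (sequential canonical numbers otherwise)."""
    if cmap is not None:
        if len(cmap.column_labels) != alignment.width:
            raise ValueError("canonical map inconsistent with alignment width")
        labels = cmap.column_labels
    else:
        labels = [ColumnLabel("canonical", number=i + 1) for i in range(alignment.width)]
    profiles: list[PositionProfile] = []
    n_rows = len(alignment)
    for i, label in enumerate(labels):
        column = alignment.column(i)
        counts = _group_counts(column, scheme)
        total = int(counts.sum())
        nongap = total / n_rows
        if total > 0 and nongap >= gap_threshold:
            p = counts[counts > 0] / total
            ent = float(math.exp(-(p * np.log(p)).sum()))
        else:
            ent = math.nan
        fractions = counts / total if total > 0 else counts.astype(float)
        profiles.append(
            PositionProfile(
                label=label,
                group_fractions=fractions,
                nongap_fraction=nongap,
                entropy=ent,
            )
        )
    return profiles


@dataclass
class PositionSC:
    paralog_entropy: float
    ortholog_entropy: float

    @property
    def sc(self) -> float:
        """Paralog/ortholog entropy ratio; nan when either side undefined."""
        if math.isnan(self.paralog_entropy) or math.isnan(self.ortholog_entropy):
            return math.nan
        return self.paralog_entropy / self.ortholog_entropy

    @property
    def sc_rounded(self) -> float:
        return round(self.sc, 1) if not math.isnan(self.sc) else math.nan


@dataclass
class ConservationProfile:
    """Per-canonical-position entropies and SC for one family member."""

    domain_name: str
    positions: dict[int, PositionSC]
    insertion_profiles: list[PositionProfile] = field(default_factory=list)
    gap_threshold: float = GAP_THRESHOLD

    def sc_series(self) -> pd.Series:
        return pd.Series(
            {pos: v.sc for pos, v in sorted(self.positions.items())},
            name=self.domain_name,
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        """Fig-2-style table: one row per canonical or insertion label."""
        rows = []
        for pos, v in sorted(self.positions.items()):
            rows.append(
                {
                    "label": str(pos),
                    "paralog_entropy": v.paralog_entropy,
                    "ortholog_entropy": v.ortholog_entropy,
                    "sc": v.sc,
                    "sc_1dp": v.sc_rounded,
                }
            )
        for prof in self.insertion_profiles:
            rows.append(
                {
                    "label": str(prof.label),
                    "paralog_entropy": math.nan,
                    "ortholog_entropy": prof.entropy,
                    "sc": math.nan,
                    "sc_1dp": math.nan,
                }
            )
        return pd.DataFrame(rows)


def sc_profile(
    paralog_profiles: Sequence[PositionProfile],
    ortholog_profiles: Sequence[PositionProfile],
    domain_name: str,
) -> ConservationProfile:
    """Combine paralog- and ortholog-alignment profiles into SC values.

    Both inputs must be labelled on the canonical frame; the paralog entropy
    of a canonical position is looked up at the matching canonical label.
    Ortholog insertion and flank columns are retained separately with their
    entropies (for conserved-insertion counting); they have no SC since the
    paralog alignment has no matching column.
    """
    paralog_by_pos = {
        p.label.number: p for p in paralog_profiles if p.label.is_canonical
    }
    positions: dict[int, PositionSC] = {}
    insertions: list[PositionProfile] = []
    for prof in ortholog_profiles:
        if prof.label.is_canonical:
            pos = prof.label.number
            par = paralog_by_pos.get(pos)
            positions[pos] = PositionSC(
                paralog_entropy=par.entropy if par is not None else math.nan,
                ortholog_entropy=prof.entropy,
            )
        else:
            insertions.append(prof)
    return ConservationProfile(
        domain_name=domain_name, positions=positions, insertion_profiles=insertions
    )


@dataclass(frozen=True)
class SurfaceDefinition:
    """A named set of canonical positions (a binding surface or region)."""

    name: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"surface {self.name!r} is empty")
        bad = [p for p in self.positions if not 1 <= p <= 60]
        if bad:
            raise ValueError(f"surface {self.name!r} positions outside 1..60: {bad}")


_SI = frozenset({8, 9, 10, 36, 37, 51, 52, 53, 54})
_SII = frozenset({13, 14, 15, 16, 17, 30, 31, 32, 33, 34, 35, 38, 49})

DEFAULT_SURFACES: dict[str, SurfaceDefinition] = {
    "SI": SurfaceDefinition("SI", _SI),
    "SII": SurfaceDefinition("SII", _SII),
    "other": SurfaceDefinition("other", frozenset(range(1, 61)) - _SI - _SII),
}


def average_region_sc(profile: ConservationProfile, surface: SurfaceDefinition) -> float:
    """Mean SC over a surface's positions, skipping undefined SC values.

    Returns nan when no position in the surface has a defined SC.
    """
    values = [
        profile.positions[p].sc
        for p in surface.positions
        if p in profile.positions and not math.isnan(profile.positions[p].sc)
    ]
    if not values:
        return math.nan
    return float(np.mean(values))


def family_position_average(profiles: Sequence[ConservationProfile]) -> pd.Series:
    """Per-position mean SC across family members (the Fig-3 bottom row)."""
    if not profiles:
        raise ValueError("need at least one profile")
    frame = pd.DataFrame({p.domain_name: p.sc_series() for p in profiles})
    return frame.mean(axis=1, skipna=True).rename("mean_sc")


@dataclass(frozen=True)
class LoopRegions:
    """Canonical anchor ranges assigning insertion columns to loops.

    An insertion anchored at canonical position a belongs to the RT-loop,
    N-Src loop or distal loop when a falls in the respective range; flank
    columns belong to the N-/C-terminus. Ranges are inclusive.
    """

    rt_loop: tuple[int, int] = (11, 19)
    n_src_loop: tuple[int, int] = (29, 35)
    distal_loop: tuple[int, int] = (42, 48)

    REGION_NAMES = (
        "N-terminus",
        "RT-loop",
        "N-Src loop",
        "distal loop",
        "C-terminus",
        "other",
    )

    def region_of(self, label: ColumnLabel) -> str:
        if label.kind == "n_flank":
            return "N-terminus"
        if label.kind == "c_flank":
            return "C-terminus"
        if label.is_insertion:
            a = label.number
            if self.rt_loop[0] <= a <= self.rt_loop[1]:
                return "RT-loop"
            if self.n_src_loop[0] <= a <= self.n_src_loop[1]:
                return "N-Src loop"
            if self.distal_loop[0] <= a <= self.distal_loop[1]:
                return "distal loop"
            return "other"
        raise ValueError(f"label {label} is not an insertion or flank column")


def conserved_insertion_count(
    profiles: Sequence[PositionProfile],
    regions: Mapping[str, str] | LoopRegions | None = None,
    cutoff: float = INSERTION_CUTOFF,
) -> dict[str, int]:
    """Count conserved insertion/flank columns per region.

    A column counts when its (ortholog) entropy is defined and <= ``cutoff``.
    ``regions`` maps label strings to region names explicitly, or is a
    :class:`LoopRegions` (default) assigning insertions by their anchor.
    An explicit mapping must cover every insertion/flank label.
    """
    if regions is None:
        regions = LoopRegions()
    counts: Counter[str] = Counter({name: 0 for name in LoopRegions.REGION_NAMES})
    for prof in profiles:
        if prof.label.is_canonical:
            continue
        if isinstance(regions, LoopRegions):
            region = regions.region_of(prof.label)
        else:
            key = str(prof.label)
            if key not in regions:
                raise ValueError(f"label {key!r} missing from region mapping")
            region = regions[key]
            counts.setdefault(region, 0)
        if prof.defined and prof.entropy <= cutoff:
            counts[region] += 1
    return dict(counts)


@dataclass
class DomainSummary:
    """Fig-4-style conservation summary for one family member."""

    domain_name: str
    avg_sc: dict[str, float]
    high_sc: dict[str, bool]
    conserved_insertions: dict[str, int]


def summarize_domain(
    profile: ConservationProfile,
    surfaces: Mapping[str, SurfaceDefinition] | None = None,
    regions: LoopRegions | None = None,
    sc_cutoff: float = SC_CUTOFF,
    insertion_cutoff: float = INSERTION_CUTOFF,
) -> DomainSummary:
    """Average SC per surface with high-SC flags (>= ``sc_cutoff``) plus
    conserved-insertion counts per loop/terminus region."""
    surfaces = dict(surfaces or DEFAULT_SURFACES)
    avg = {name: average_region_sc(profile, surf) for name, surf in surfaces.items()}
    # inclusive threshold, robust to rounding in the mean at machine precision
    high = {
        name: (not math.isnan(v)) and v >= sc_cutoff * (1 - 1e-12)
        for name, v in avg.items()
    }
    counts = conserved_insertion_count(
        profile.insertion_profiles, regions, cutoff=insertion_cutoff
    )
    return DomainSummary(
        domain_name=profile.domain_name,
        avg_sc=avg,
        high_sc=high,
        conserved_insertions=counts,
    )
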