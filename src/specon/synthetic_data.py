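"""Synthetic domain families and SPOT binding matrices with planted truth.

The family generator emulates the statistical structure the conservation
pipeline is designed to detect, with three position classes over a 60-residue
canonical frame:

* housekeeping — one equivalency group family-wide, conserved in both the
  paralog and every ortholog alignment (fold-critical residues);
* specificity — each family member draws its own group, held fixed within
  that member's orthologs (specificity determinants: divergent across
  paralogs, conserved across orthologs, hence high SC);
* variable — drawn near-uniformly over groups everywhere (unconstrained
  surface positions, low SC because both entropies are high).

The binding generator emulates a SPOT array: log-normal background
intensities, planted specific peptide-domain pairs whose intensity share is
set to a target binding fraction, and a handful of low-signal peptides that
must fall to the sum filter.

Both generators are deterministic given their seed (numpy PCG64) and emit
truth tables so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, AlignmentRow, GAP
from .binding_specificity import BindingMatrix
from .conservation import DEFAULT_GROUPS, DEFAULT_SURFACES

__all__ = [
    "InsertionSpec",
    "FamilySpec",
    "BindingSpec",
    "SyntheticFamily",
    "SyntheticBinding",
    "generate_family",
    "generate_binding",
    "default_class_map",
]

HOUSEKEEPING = "housekeeping"
SPECIFICITY = "specificity"
VARIABLE = "variable"


def default_class_map(n_positions: int = 60) -> dict[int, str]:
    """Default planted classes: housekeeping at the SI surface positions,
    specificity at SII, everything else variable."""
    classes = {}
    si = DEFAULT_SURFACES["SI"].positions
    sii = DEFAULT_SURFACES["SII"].positions
    for pos in range(1, n_positions + 1):
        if pos in si:
            classes[pos] = HOUSEKEEPING
        elif pos in sii:
            classes[pos] = SPECIFICITY
        else:
            classes[pos] = VARIABLE
    return classes


@dataclass(frozen=True)
class InsertionSpec:
    """One block of inserted columns in an ortholog alignment.

    ``anchor``: canonical position the insertion follows; ``n_columns``:
    how many columns; ``conserved``: single-group (low entropy) columns when
    True, near-uniform otherwise. The reference row is gapped there.
    """

    anchor: int
    n_columns: int = 1
    conserved: bool = True


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a planted-structure domain family."""

    n_paralogs: int = 28
    n_orthologs: int = 29
    n_positions: int = 60
    position_classes: Mapping[int, str] | None = None  # default_class_map if None
    housekeeping_switch: float = 0.02
    specificity_switch: float = 0.05
    variable_switch: float = 0.65
    gap_probability: float = 0.02
    insertions: Mapping[str, tuple[InsertionSpec, ...]] = field(default_factory=dict)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 equivalency groups")
        for name in ("housekeeping_switch", "specificity_switch", "variable_switch",
                     "gap_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_paralogs < 2 or self.n_orthologs < 2:
            raise ValueError("need at least 2 paralogs and 2 orthologs")

    def classes(self) -> dict[int, str]:
        cm = (
            dict(self.position_classes)
            if self.position_classes is not None
            else default_class_map(self.n_positions)
        )
        missing = [p for p in range(1, self.n_positions + 1) if p not in cm]
        if missing:
            raise ValueError(f"position classes missing positions: {missing}")
        return cm


@dataclass
class SyntheticFamily:
    paralog_alignment: Alignment
    ortholog_alignments: dict[str, Alignment]  # member -> alignment (ref row first)
    truth: pd.DataFrame  # columns: position, position_class
    spec: FamilySpec

    @property
    def members(self) -> list[str]:
        return [r.id for r in self.paralog_alignment.rows]


def _member_name(i: int) -> str:
    return f"Dom{i + 1:02d}"


def _sample_residue(rng: np.random.Generator, group: str) -> str:
    return group[rng.integers(len(group))]


def _mutate_group(rng: np.random.Generator, base: int, k: int, switch: float) -> int:
    """Return ``base`` or, with probability ``switch``, another group."""
    if switch > 0 and rng.random() < switch:
        other = rng.integers(k - 1)
        return other if other < base else other + 1
    return int(base)


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate a paralog alignment, one ortholog alignment per member, and
    the position-class truth table.

    Each member's reference sequence appears both as its paralog-alignment
    row and as the first (reference) row of its ortholog alignment, gapped
    only at that alignment's insertion columns, so canonical mapping is
    exact. Gaps at canonical positions are sprinkled only over non-reference
    ortholog rows.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.groups)
    classes = spec.classes()
    positions = list(range(1, spec.n_positions + 1))

    # family-wide base groups per position; member-specific groups where the
    # class is "specificity"
    base_group = {pos: int(rng.integers(k)) for pos in positions}
    members = [_member_name(i) for i in range(spec.n_paralogs)]
    member_group: dict[str, dict[int, int]] = {
        m: {
            pos: (int(rng.integers(k)) if classes[pos] == SPECIFICITY else base_group[pos])
            for pos in positions
        }
        for m in members
    }

    def draw_groups(member: str) -> list[int]:
        out = []
        for pos in positions:
            cls = classes[pos]
            if cls == HOUSEKEEPING:
                out.append(_mutate_group(rng, base_group[pos], k, spec.housekeeping_switch))
            elif cls == SPECIFICITY:
                out.append(member_group[member][pos])
            else:  # variable: mixture of base group and uniform redraw
                if rng.random() < spec.variable_switch:
                    out.append(int(rng.integers(k)))
                else:
                    out.append(base_group[pos])
        return out

    def groups_to_seq(groups: Sequence[int]) -> str:
        return "".join(_sample_residue(rng, spec.groups[g]) for g in groups)

    # reference sequences (one per member) drive both alignments
    reference_seq = {m: groups_to_seq(draw_groups(m)) for m in members}

    paralog = Alignment(
        rows=[
            AlignmentRow(id=m, sequence=reference_seq[m], species="S_reference",
                         taxon_group=0)
            for m in members
        ],
        kind="paralog",
    )

    ortholog_alignments: dict[str, Alignment] = {}
    for m in members:
        inserts = tuple(spec.insertions.get(m, ()))
        rows = []
        core_rows: list[str] = [reference_seq[m]]
        for o in range(1, spec.n_orthologs):
            seq = []
            for j, pos in enumerate(positions):
                cls = classes[pos]
                if rng.random() < spec.gap_probability:
                    seq.append(GAP)
                    continue
                if cls == HOUSEKEEPING:
                    g = _mutate_group(rng, base_group[pos], k, spec.housekeeping_switch)
                elif cls == SPECIFICITY:
                    g = _mutate_group(rng, member_group[m][pos], k, spec.specificity_switch)
                else:
                    g = int(rng.integers(k)) if rng.random() < spec.variable_switch \
                        else base_group[pos]
                seq.append(_sample_residue(rng, spec.groups[g]))
            core_rows.append("".join(seq))

        # splice insertion columns (reference row gapped, others filled)
        full_rows = [list(s) for s in core_rows]
        offset = 0
        for ins in sorted(inserts, key=lambda x: x.anchor):
            at = ins.anchor + offset
            ins_group = int(rng.integers(k))
            for col in range(ins.n_columns):
                for r, row in enumerate(full_rows):
                    if r == 0:
                        row.insert(at + col, GAP)
                    else:
                        g = ins_group if ins.conserved else int(rng.integers(k))
                        row.insert(at + col, _sample_residue(rng, spec.groups[g]))
            offset += ins.n_columns

        taxa = [0] + [1 + (o - 1) % 7 for o in range(1, spec.n_orthologs)]
        rows = [
            AlignmentRow(
                id=m if o == 0 else f"{m}_sp{o:02d}_{taxa[o]}",
                sequence="".join(full_rows[o]),
                species="S_reference" if o == 0 else f"species_{o:02d}",
                taxon_group=taxa[o],
            )
            for o in range(spec.n_orthologs)
        ]
        ortholog_alignments[m] = Alignment(rows=rows, kind="ortholog")

    truth = pd.DataFrame(
        {"position": positions, "position_class": [classes[p] for p in positions]}
    )
    return SyntheticFamily(
        paralog_alignment=paralog,
        ortholog_alignments=ortholog_alignments,
        truth=truth,
        spec=spec,
    )


@dataclass(frozen=True)
class BindingSpec:
    """Parameters of a planted-specificity SPOT binding dataset."""

    n_species: int = 4
    n_peptides: int = 300
    n_domains: int = 24
    target_bf: float = 0.7
    bf_noise_sigma: float = 0.1
    background_mu: float = math.log(120.0)
    background_sigma: float = 1.0
    max_specific_per_domain: int = 50
    n_below_sum_filter: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_bf <= 0.5:
            import warnings

            warnings.warn(
                f"planted target BF {self.target_bf} <= 0.5 will not be callable",
                stacklevel=2,
            )
        if self.n_domains < 2 or self.n_peptides < 1 or self.n_species < 1:
            raise ValueError("need >= 2 domains, >= 1 peptide and >= 1 species")


@dataclass
class SyntheticBinding:
    matrices: dict[str, BindingMatrix]
    truth: pd.DataFrame  # columns: peptide_id, domain
    low_signal: list[str]
    spec: BindingSpec


def generate_binding(spec: BindingSpec) -> SyntheticBinding:
    """Generate per-species binding matrices plus the planted truth.

    Each domain draws a planted specific-peptide count uniformly from
    0..max_specific_per_domain; peptides are assigned greedily (one domain
    each) until the pool is exhausted. A planted pair's intensity in every
    species is set so its binding fraction sits near ``target_bf`` (log-normal
    jitter of ``bf_noise_sigma`` on the odds). The last ``n_below_sum_filter``
    unplanted peptides are rescaled to row sums below 1000 units.
    """
    rng = np.random.default_rng(spec.seed)
    peptides = [f"pep{i + 1:03d}" for i in range(spec.n_peptides)]
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    seqs = pd.Series(
        ["".join(alphabet[c] for c in rng.integers(20, size=15))
         for _ in peptides],
        index=peptides,
        name="peptide_seq",
    )
    domains = [f"Dom{i + 1:02d}" for i in range(spec.n_domains)]

    # plant specific pairs
    wanted = {d: int(rng.integers(spec.max_specific_per_domain + 1)) for d in domains}
    pool = [p for p in peptides[: spec.n_peptides - spec.n_below_sum_filter]]
    rng.shuffle(pool)
    planted: list[tuple[str, str]] = []
    cursor = 0
    for d in rng.permutation(domains):
        take = min(wanted[str(d)], len(pool) - cursor)
        for _ in range(take):
            planted.append((pool[cursor], str(d)))
            cursor += 1
    planted_domain = dict(planted)
    low_signal = peptides[spec.n_peptides - spec.n_below_sum_filter:]

    matrices: dict[str, BindingMatrix] = {}
    for s in range(spec.n_species):
        name = f"species{s + 1}"
        bg = rng.lognormal(spec.background_mu, spec.background_sigma,
                           size=(spec.n_peptides, spec.n_domains))
        frame = pd.DataFrame(bg, index=peptides, columns=domains)
        for pep, dom in planted:
            others = frame.loc[pep].drop(dom).sum()
            # intensity giving BF = target, with log-normal jitter on the odds
            odds = spec.target_bf / (1 - spec.target_bf)
            odds *= rng.lognormal(0.0, spec.bf_noise_sigma)
            frame.at[pep, dom] = odds * others
        for pep in low_signal:
            row_sum = frame.loc[pep].sum()
            target = rng.uniform(100.0, 950.0)
            frame.loc[pep] *= target / row_sum
        matrices[name] = BindingMatrix(
            species=name, intensities=frame, peptide_seqs=seqs.copy()
        )

    truth = pd.DataFrame(planted, columns=["peptide_id", "domain"]).sort_values(
        ["peptide_id", "domain"], ignore_index=True
    )
    return SyntheticBinding(
        matrices=matrices, truth=truth, low_signal=list(low_signal), spec=spec
    )
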