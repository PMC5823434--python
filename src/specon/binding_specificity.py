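"""SPOT-array binding fractions and peptide-domain specificity calls.

A SPOT experiment yields a normalized binding intensity BI(i, j, d) for each
peptide i against each domain d of one species j. Because raw intensities
confound affinity with promiscuity, specificity is scored as the binding
fraction

    BF(i, j, d) = BI(i, j, d) / sum_k BI(i, j, k),

the share of peptide i's total family signal captured by domain d. Within a
species, paralog domains known to be near-identical are first averaged into
one merged column (for S. cerevisiae 28 domains collapse to 24), low-signal
peptides (summed intensity below 1000 units) are discarded, and a BF
strictly greater than 0.5 calls a specific interaction — necessarily unique
per peptide and species, since fractions sum to one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MIN_SUM",
    "BF_CUTOFF",
    "BindingMatrix",
    "ParalogMergeRule",
    "DEFAULT_MERGE_RULES",
    "BindingFractionTable",
    "DomainBindingSummary",
    "read_binding_matrix",
    "merge_paralogs",
    "sum_filter",
    "binding_fraction",
    "call_specific",
    "summarize_domain_binding",
    "rank_peptides",
]

#: Minimum summed intensity (units) for a peptide row to enter BF calculation.
MIN_SUM = 1000.0

#: Binding fraction strictly above this calls a specific interaction.
BF_CUTOFF = 0.5


@dataclass
class BindingMatrix:
    """Peptide x domain SPOT intensities for one species.

    ``intensities``: DataFrame indexed by peptide id, one column per domain,
    non-negative values. ``peptide_seqs`` maps peptide ids to 15-mer
    sequences (optional).
    """

    species: str
    intensities: pd.DataFrame
    peptide_seqs: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise ValueError(f"{self.species}: duplicate peptide ids")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError(f"{self.species}: negative binding intensities")

    @property
    def domains(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass(frozen=True)
class ParalogMergeRule:
    """Domains of one species whose intensities are averaged into one column."""

    species: str
    merged_name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a merge rule needs at least 2 members")


# The published merge set: near-identical paralog domains averaged per species.
DEFAULT_MERGE_RULES: tuple[ParalogMergeRule, ...] = (
    ParalogMergeRule("S.cerevisiae", "Lsb1/Lsb2", ("Lsb1", "Lsb2")),
    ParalogMergeRule("S.cerevisiae", "Lsb3/Lsb4", ("Lsb3", "Lsb4")),
    ParalogMergeRule("S.cerevisiae", "Myo3/Myo5", ("Myo3", "Myo5")),
    ParalogMergeRule("S.cerevisiae", "Boi1/Boi2", ("Boi1", "Boi2")),
    ParalogMergeRule("C.albicans", "Abp1", ("Abp1_1", "Abp1_2")),
    ParalogMergeRule("C.albicans", "Bem1a", ("Bem1a_1", "Bem1a_2")),
    ParalogMergeRule("C.albicans", "Rvs167", ("Rvs167_1", "Rvs167_2")),
    ParalogMergeRule("A.gossypii", "Bem1a", ("Bem1a_1", "Bem1a_2")),
    ParalogMergeRule("S.pombe", "Hof1", ("Hof1_1", "Hof1_2", "Hof1_3")),
)


def read_binding_matrix(path: str | Path, species: str | None = None) -> BindingMatrix:
    """Read a per-species intensity TSV: peptide id, peptide sequence, then
    one column per domain."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if species is None:
        species = Path(path).stem
    seq_col = frame.columns[0]
    seqs = frame[seq_col].astype(str)
    intens = frame.drop(columns=[seq_col]).astype(float)
    return BindingMatrix(species=species, intensities=intens, peptide_seqs=seqs)


def write_binding_matrix(matrix: BindingMatrix, path: str | Path) -> None:
    out = matrix.intensities.copy()
    seqs = (
        matrix.peptide_seqs
        if matrix.peptide_seqs is not None
        else pd.Series("", index=out.index)
    )
    out.insert(0, "peptide_seq", seqs)
    out.to_csv(path, sep="\t", index_label="peptide_id")


def merge_paralogs(
    matrix: BindingMatrix, rules: Sequence[ParalogMergeRule] = DEFAULT_MERGE_RULES
) -> BindingMatrix:
    """Average near-identical paralog columns into single merged domains.

    Rules for other species are ignored; a rule member missing from this
    species' matrix is an error naming it.
    """
    intens = matrix.intensities.copy()
    seen: set[str] = set()
    for rule in rules:
        if rule.species != matrix.species:
            continue
        missing = [m for m in rule.members if m not in intens.columns]
        if missing:
            raise ValueError(
                f"{matrix.species}: merge rule {rule.merged_name!r} references "
                f"missing domain(s): {', '.join(missing)}"
            )
        overlap = set(rule.members) & seen
        if overlap:
            raise ValueError(
                f"{matrix.species}: domain(s) {sorted(overlap)} appear in more "
                "than one merge rule"
            )
        seen |= set(rule.members)
        merged = intens[list(rule.members)].mean(axis=1)
        position = intens.columns.get_loc(rule.members[0])
        intens = intens.drop(columns=list(rule.members))
        intens.insert(min(position, len(intens.columns)), rule.merged_name, merged)
    return BindingMatrix(
        species=matrix.species, intensities=intens, peptide_seqs=matrix.peptide_seqs
    )


def sum_filter(
    matrix: BindingMatrix, min_sum: float = MIN_SUM
) -> tuple[BindingMatrix, pd.Series]:
    """Split peptides into retained (summed intensity >= ``min_sum``) and
    excluded; the excluded Series carries each dropped peptide's sum."""
    sums = matrix.intensities.sum(axis=1)
    keep = sums >= min_sum
    retained = BindingMatrix(
        species=matrix.species,
        intensities=matrix.intensities[keep],
        peptide_seqs=(
            matrix.peptide_seqs[keep] if matrix.peptide_seqs is not None else None
        ),
    )
    excluded = sums[~keep].rename("intensity_sum")
    return retained, excluded


@dataclass
class BindingFractionTable:
    """Per-species binding fractions after merging and sum filtering."""

    species: str
    bf: pd.DataFrame  # peptide x merged domain, rows summing to 1
    intensities: pd.DataFrame  # matching retained intensities
    excluded_peptides: pd.Series  # peptide id -> intensity sum below threshold
    peptide_seqs: pd.Series | None = None

    @property
    def domains(self) -> list[str]:
        return list(self.bf.columns)


def binding_fraction(
    matrix: BindingMatrix, min_sum: float = MIN_SUM
) -> BindingFractionTable:
    """Compute BF = BI / row sum over all (merged) domains of the species,
    after excluding peptides whose summed intensity is below ``min_sum``."""
    retained, excluded = sum_filter(matrix, min_sum=min_sum)
    sums = retained.intensities.sum(axis=1)
    if (sums <= 0).any():
        bad = sums[sums <= 0].index.tolist()
        raise ValueError(f"{matrix.species}: zero-sum retained rows: {bad}")
    bf = retained.intensities.div(sums, axis=0)
    return BindingFractionTable(
        species=matrix.species,
        bf=bf,
        intensities=retained.intensities,
        excluded_peptides=excluded,
        peptide_seqs=retained.peptide_seqs,
    )


def call_specific(
    table: BindingFractionTable, cutoff: float = BF_CUTOFF
) -> pd.DataFrame:
    """Specific peptide-domain calls: BF strictly greater than ``cutoff``.

    With cutoff >= 0.5 at most one domain can be called per peptide. Returns
    a table with columns peptide_id, domain, bf.
    """
    if cutoff < 0.5:
        warnings.warn(
            "cutoff below 0.5 no longer guarantees one call per peptide",
            stacklevel=2,
        )
    mask = table.bf > cutoff
    calls = []
    for peptide in table.bf.index[mask.any(axis=1)]:
        for domain in table.bf.columns[mask.loc[peptide]]:
            calls.append(
                {
                    "peptide_id": peptide,
                    "domain": domain,
                    "bf": table.bf.at[peptide, domain],
                }
            )
    return pd.DataFrame(calls, columns=["peptide_id", "domain", "bf"])


@dataclass
class DomainBindingSummary:
    """Fig-4-style binding columns for one domain.

    ``n_specific_peptides``: peptides specific to the domain in >= 1 species.
    ``best_peptide`` / ``bf_specific``: the peptide with maximal mean BF
    across species with data, and that mean. ``n_species_specific`` /
    ``n_species_with_data``: the printed "x/y" species pair.
    """

    domain: str
    n_specific_peptides: int
    best_peptide: str | None
    bf_specific: float
    n_species_specific: int
    n_species_with_data: int


def _mean_stat_across_species(
    tables: Sequence[BindingFractionTable], domain: str, stat: str
) -> pd.Series:
    """Mean BF or intensity per peptide over species holding data for both
    the domain and the peptide."""
    per_species = []
    for t in tables:
        if domain in t.domains:
            source = t.bf if stat == "binding_fraction" else t.intensities
            per_species.append(source[domain])
    if not per_species:
        raise ValueError(f"domain {domain!r} absent from every species table")
    return pd.concat(per_species, axis=1).mean(axis=1, skipna=True)


def summarize_domain_binding(
    tables: Sequence[BindingFractionTable],
    domain: str,
    cutoff: float = BF_CUTOFF,
) -> DomainBindingSummary:
    """Summarise a domain's specific binders across species.

    The best peptide maximises mean BF over species with data (ties broken by
    lexicographically smallest peptide id); the species pair counts species
    where the best peptide's BF >= 0.5 over species with data for the domain.
    A species lacking the best peptide (filtered out there) is dropped from
    both counts.
    """
    with_data = [t for t in tables if domain in t.domains]
    if not with_data:
        raise ValueError(f"domain {domain!r} absent from every species table")

    specific_ids: set = set()
    for t in with_data:
        calls = call_specific(t, cutoff=cutoff)
        specific_ids |= set(calls.loc[calls["domain"] == domain, "peptide_id"])

    mean_bf = _mean_stat_across_species(with_data, domain, "binding_fraction")
    if mean_bf.empty:
        best_peptide, bf_specific = None, math.nan
    else:
        best = mean_bf.max()
        best_peptide = sorted(mean_bf.index[mean_bf == best])[0]
        bf_specific = float(best)

    n_species_specific = 0
    n_species_with_data = 0
    for t in with_data:
        if best_peptide is None or best_peptide not in t.bf.index:
            continue  # species lacks the best peptide: dropped from both counts
        n_species_with_data += 1
        if t.bf.at[best_peptide, domain] >= 0.5:
            n_species_specific += 1
    return DomainBindingSummary(
        domain=domain,
        n_specific_peptides=len(specific_ids),
        best_peptide=best_peptide,
        bf_specific=bf_specific,
        n_species_specific=n_species_specific,
        n_species_with_data=n_species_with_data,
    )


def rank_peptides(
    tables: Sequence[BindingFractionTable],
    domain: str,
    by: str = "binding_fraction",
) -> pd.DataFrame:
    """Rank peptides for a domain by mean BF or mean raw intensity across
    species with data, descending; ties broken by peptide id."""
    if by not in ("binding_fraction", "intensity"):
        raise ValueError(f"unknown ranking statistic: {by!r}")
    stat = _mean_stat_across_species(tables, domain, by)
    frame = stat.rename(by).to_frame()
    frame = frame.sort_values(
        by=[by], ascending=False, kind="mergesort"
    )
    # stable sort on id first, then value, gives deterministic tie order
    frame = frame.loc[
        sorted(frame.index, key=lambda p: (-frame.at[p, by], str(p)))
    ]
    frame["rank"] = range(1, len(frame) + 1)
    return frame
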