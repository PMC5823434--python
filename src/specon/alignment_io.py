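"""Alignment reading/writing, canonical domain numbering and species paralog counts.

Alignments come in as aligned FASTA or Clustal files. One row is the
reference-species domain; its ungapped residue coordinates anchor the
canonical 1..60 numbering of the domain fold, so that entropies computed on
different ortholog alignments can be compared position by position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: Letters kept by the reader but excluded from every frequency computation.
AMBIGUOUS = frozenset("XBZUO")

_TAXON_SUFFIX = re.compile(r"_(\d+)$")

__all__ = [
    "GAP",
    "AMBIGUOUS",
    "AlignmentRow",
    "Alignment",
    "ColumnLabel",
    "CanonicalMap",
    "read_alignment",
    "write_alignment",
    "build_canonical_map",
    "slice_to_canonical",
    "species_paralog_count",
    "select_representatives",
]


@dataclass(frozen=True)
class AlignmentRow:
    """One gapped sequence in an alignment.

    ``taxon_group`` is the small integer tag appended to record names
    (``Homo_sapiens_7`` -> 7) marking the taxonomic group of the species;
    0 conventionally marks the reference species. ``None`` when the record
    name carries no suffix.
    """

    id: str
    sequence: str
    species: str = ""
    taxon_group: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"row {self.id!r} has an empty sequence")

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(GAP, "")


@dataclass
class Alignment:
    """An ordered multiple sequence alignment with equal-length rows."""

    rows: list[AlignmentRow]
    kind: str = "ortholog"  # {"paralog", "ortholog"}

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        width = len(self.rows[0].sequence)
        for row in self.rows:
            if len(row.sequence) != width:
                raise ValueError(
                    f"ragged alignment: row {row.id!r} has length "
                    f"{len(row.sequence)}, expected {width}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0].sequence)

    def row(self, row_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise KeyError(f"row {row_id!r} not in alignment")

    def column(self, index: int) -> list[str]:
        """Residues (and gaps) at 0-based column ``index``, row order."""
        return [r.sequence[index] for r in self.rows]


@dataclass(frozen=True, order=True)
class ColumnLabel:
    """Label of one alignment column on the canonical frame.

    ``kind`` is one of ``canonical`` (a core domain position, ``number`` in
    1..60), ``insertion`` (reference gap anchored to the canonical position
    on its left; ``suffix`` counts a, b, ...), ``n_flank`` or ``c_flank``
    (outside the domain span; ``suffix`` counts 1, 2, ... in column order).
    """

    kind: str
    number: int = 0
    suffix: int = 0

    def __str__(self) -> str:
        if self.kind == "canonical":
            return str(self.number)
        if self.kind == "insertion":
            # suffix 1 -> 'a', 2 -> 'b', ...
            letters = ""
            n = self.suffix
            while n > 0:
                n, rem = divmod(n - 1, 26)
                letters = chr(ord("a") + rem) + letters
            return f"{self.number}{letters}"
        if self.kind == "n_flank":
            return f"N{self.suffix}"
        return f"C{self.suffix}"

    @property
    def is_canonical(self) -> bool:
        return self.kind == "canonical"

    @property
    def is_insertion(self) -> bool:
        return self.kind == "insertion"

    @property
    def is_flank(self) -> bool:
        return self.kind in ("n_flank", "c_flank")


@dataclass
class CanonicalMap:
    """Per-column labels mapping an alignment onto canonical numbering."""

    column_labels: list[ColumnLabel]
    reference_id: str

    def __post_init__(self) -> None:
        numbers = [l.number for l in self.column_labels if l.is_canonical]
        if len(set(numbers)) != len(numbers):
            raise ValueError("canonical numbers must be unique")
        if numbers != sorted(numbers):
            raise ValueError("canonical numbers must increase left to right")

    @property
    def canonical_columns(self) -> list[int]:
        """0-based alignment column indices of canonical positions, in order."""
        return [i for i, l in enumerate(self.column_labels) if l.is_canonical]

    def to_frame(self, alignment: Alignment | None = None) -> pd.DataFrame:
        """TSV-ready table: alignment_column (1-based), label, reference residue."""
        data = {
            "alignment_column": list(range(1, len(self.column_labels) + 1)),
            "label": [str(l) for l in self.column_labels],
        }
        if alignment is not None:
            ref = alignment.row(self.reference_id).sequence
            data["reference_residue"] = list(ref)
        return pd.DataFrame(data)


def _row_from_record(record: SeqRecord) -> AlignmentRow:
    name = record.id
    m = _TAXON_SUFFIX.search(name)
    taxon = int(m.group(1)) if m else None
    seq = str(record.seq).upper().replace(".", GAP)
    return AlignmentRow(id=name, sequence=seq, species=name, taxon_group=taxon)


def read_alignment(path: str | Path, format: str = "fasta", kind: str = "ortholog") -> Alignment:
    """Read an aligned FASTA or Clustal file.

    Sequences are upper-cased and '.' gaps normalised to '-'. A trailing
    ``_<integer>`` on a record name is parsed as the taxonomic-group tag.
    Ragged rows and duplicate ids raise ``ValueError``.
    """
    fmt = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}.get(
        format.lower()
    )
    if fmt is None:
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if fmt == "fasta":
        # AlignIO rejects ragged FASTA with a generic message; parse records
        # ourselves so the error can name the offending row.
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no sequences found")
    else:
        records = list(AlignIO.read(str(path), fmt))
    rows = [_row_from_record(r) for r in records]
    return Alignment(rows=rows, kind=kind)


def write_alignment(alignment: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as aligned FASTA or Clustal."""
    fmt = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}.get(
        format.lower()
    )
    if fmt is None:
        raise ValueError(f"unsupported alignment format: {format!r}")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in alignment.rows]
    )
    AlignIO.write(msa, str(path), fmt)


def build_canonical_map(
    alignment: Alignment,
    reference_id: str,
    domain_span: tuple[int, int] | None = None,
) -> CanonicalMap:
    """Assign canonical / insertion / flank labels to every alignment column.

    ``domain_span`` is a pair of 1-based inclusive residue indices in the
    *ungapped* reference sequence delimiting the domain; by default the whole
    reference sequence. Columns where the reference has a residue inside the
    span are numbered 1..60 in order; reference-gap columns between two
    canonical positions become insertions anchored to the left neighbour
    (14a, 14b, ...); everything else is an N- or C-terminal flank column.
    """
    ref = alignment.row(reference_id)  # KeyError if absent
    ungapped_len = len(ref.ungapped)
    if domain_span is None:
        domain_span = (1, ungapped_len)
    start, end = domain_span
    if not (1 <= start <= end):
        raise ValueError(f"invalid domain span {domain_span}")
    if end > ungapped_len:
        raise ValueError(
            f"domain span {domain_span} exceeds reference length {ungapped_len}"
        )
    span_len = end - start + 1
    if span_len > 60:
        raise ValueError(f"domain span covers {span_len} residues, more than 60")

    labels: list[ColumnLabel] = []
    res_index = 0  # 1-based index into the ungapped reference, after increment
    canonical = 0  # last canonical number assigned
    insertion_suffix = 0
    n_flank = 0
    seen_span_end = False
    for ch in ref.sequence:
        if ch != GAP:
            res_index += 1
        inside = ch != GAP and start <= res_index <= end
        if inside:
            canonical += 1
            insertion_suffix = 0
            labels.append(ColumnLabel("canonical", number=canonical))
            if res_index == end:
                seen_span_end = True
        elif ch == GAP and 0 < canonical and not seen_span_end:
            insertion_suffix += 1
            labels.append(ColumnLabel("insertion", number=canonical, suffix=insertion_suffix))
        elif canonical == 0:
            n_flank += 1
            labels.append(ColumnLabel("n_flank", suffix=n_flank))
        else:
            labels.append(ColumnLabel("c_flank", suffix=0))  # renumbered below
    # number C flanks left to right
    c = 0
    for i, l in enumerate(labels):
        if l.kind == "c_flank":
            c += 1
            labels[i] = ColumnLabel("c_flank", suffix=c)
    return CanonicalMap(column_labels=labels, reference_id=reference_id)


def slice_to_canonical(alignment: Alignment, cmap: CanonicalMap) -> Alignment:
    """Restrict an alignment to its canonical 1..60 columns.

    Insertion and flank columns are dropped; row order is preserved.
    """
    if len(cmap.column_labels) != alignment.width:
        raise ValueError("canonical map was not built from this alignment")
    cols = cmap.canonical_columns
    if not cols:
        raise ValueError("no canonical columns to slice (empty span intersection)")
    rows = [
        AlignmentRow(
            id=r.id,
            sequence="".join(r.sequence[i] for i in cols),
            species=r.species,
            taxon_group=r.taxon_group,
        )
        for r in alignment.rows
    ]
    return Alignment(rows=rows, kind=alignment.kind)


def species_paralog_count(presence: pd.DataFrame) -> pd.Series:
    """Species paralog count (SPC): number of family members present per species.

    ``presence`` is a boolean table, species in rows, family members in
    columns. The SPC of a species is its row sum.
    """
    if presence.empty:
        raise ValueError("presence table is empty")
    return presence.astype(bool).sum(axis=1).rename("spc")


def select_representatives(
    presence: pd.DataFrame, taxon_groups: pd.Series
) -> dict[int, str]:
    """Greedy per-taxon-group representative pick: the species with maximal
    SPC, ties broken lexicographically by species name."""
    spc = species_paralog_count(presence)
    reps: dict[int, str] = {}
    for group in sorted(set(taxon_groups)):
        members = [s for s in presence.index if taxon_groups[s] == group]
        members.sort(key=lambda s: (-int(spc[s]), s))
        reps[int(group)] = members[0]
    return reps
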