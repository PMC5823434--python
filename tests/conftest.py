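import pytest

from specon.alignment_io import Alignment, AlignmentRow
from specon.synthetic_data import BindingSpec, FamilySpec, generate_binding, generate_family


def make_alignment(seqs, ids=None, kind="ortholog", taxa=None):
    ids = ids or [f"row{i + 1}" for i in range(len(seqs))]
    taxa = taxa or [None] * len(seqs)
    return Alignment(
        rows=[
            AlignmentRow(id=i, sequence=s, species=i, taxon_group=t)
            for i, s, t in zip(ids, seqs, taxa)
        ],
        kind=kind,
    )


@pytest.fixture(scope="session")
def default_family():
    """One default synthetic family shared by the slower recovery tests."""
    return generate_family(FamilySpec(seed=0))


@pytest.fixture(scope="session")
def default_binding():
    return generate_binding(BindingSpec(seed=0))
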