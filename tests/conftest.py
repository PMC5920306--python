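import pytest

from florphen.curation import CuratedAlignment
from florphen.seqio import LabeledAlignment


def make_alignment(rows: dict[str, str], labels: dict[str, str],
                   clade: str = "FT",
                   clades: dict[str, str] | None = None) -> LabeledAlignment:
    """Build a LabeledAlignment from id->row and id->label dicts."""
    ids = list(rows)
    return LabeledAlignment(
        sequence_ids=ids,
        rows=[rows[i] for i in ids],
        labels=labels,
        clades=clades or {i: clade for i in ids},
        species={i: "toy" for i in ids},
    )


def make_curated(rows: dict[str, str], labels: dict[str, str],
                 clade: str = "FT") -> CuratedAlignment:
    """Identity-curated toy alignment (every column kept)."""
    return CuratedAlignment.identity(make_alignment(rows, labels, clade))


@pytest.fixture
def toy_ft_family() -> CuratedAlignment:
    """Six FT-clade sequences, 8 columns, three functional groups + a query.

    Activators share Y at column 2 and W at column 5; repressors share H at
    column 2; the query matches the activator signal.
    """
    rows = {
        "act1": "MYKAWTRD",
        "act2": "MYKAWSRD",
        "rep1": "MHKACTRD",
        "rep2": "MHKACSRE",
        "neu1": "MAKACTRD",
        "neu2": "MAKACSRD",
        "query": "MYKAWTRD",
    }
    labels = {"act1": "activator", "act2": "activator",
              "rep1": "repressor", "rep2": "repressor",
              "neu1": "neutral", "neu2": "neutral",
              "query": "unknown"}
    return make_curated(rows, labels)
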