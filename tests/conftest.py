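import pytest

from cmaptools.core import Contact, ContactMap, Sequence, SequenceFile
from cmaptools.synthetic import synth_chain


def make_map(pairs_scores, **kwargs):
    """ContactMap from an iterable of (i, j, score) triples."""
    cmap = ContactMap(**kwargs)
    for i, j, score in pairs_scores:
        cmap.add(Contact(i, j, raw_score=score))
    return cmap


@pytest.fixture
def toy_alignment():
    """Four sequences at threshold 0.8: 1 and 2 are mutual neighbours
    (identity 0.9), 3 and 4 are isolated, so Neff = 1/2 + 1/2 + 1 + 1 = 3.
    """
    return SequenceFile(
        id="toy",
        sequences=[
            Sequence("s1", "AAAAAAAAAA"),
            Sequence("s2", "AAAAAAAAAC"),
            Sequence("s3", "CCCCCWWWWW"),
            Sequence("s4", "WWWWWCCCCC"),
        ],
        is_alignment=True,
    )


@pytest.fixture(scope="session")
def folded_chain():
    """A 60-residue compact synthetic chain rich in long-range contacts."""
    return synth_chain(60, seed=11, compactness=0.8)
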