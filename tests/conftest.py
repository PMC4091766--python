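import numpy as np
import pytest

from gapweld.assembly_model import SeqRecord
from gapweld.synthetic_fixtures import FixtureSpec, make_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_reference():
    """A 6 kb deterministic random genome for hand-built drafts."""
    return make_reference(FixtureSpec(genome_length=6000, seed=7))


def splice_gaps(reference: SeqRecord, cuts):
    """Build a gapped draft by hand from (ref_pos, fill_len, n_run) triples.

    Each triple hides ``fill_len`` reference bases behind ``n_run`` Ns at
    ``ref_pos``.  Returns (draft record, list of hidden fill sequences).
    """
    pieces, fills = [], []
    cursor = 0
    for pos, fill_len, n_run in sorted(cuts):
        pieces.append(reference.seq[cursor:pos])
        pieces.append("N" * n_run)
        fills.append(reference.seq[pos : pos + fill_len])
        cursor = pos + fill_len
    pieces.append(reference.seq[cursor:])
    return SeqRecord("draft", "".join(pieces)), fills
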