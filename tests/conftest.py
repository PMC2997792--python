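import numpy as np
import pytest

from pinepop.locus_io import LocusAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(seqs, species, coding_segments=None, locus_id="toy", diversity_class="coding"):
    """Convenience constructor for small hand-written alignments."""
    records = [(f"s{i}", sp, s) for i, (s, sp) in enumerate(zip(seqs, species))]
    return LocusAlignment(
        locus_id=locus_id,
        sequences=records,
        length=len(seqs[0]),
        diversity_class=diversity_class,
        coding_segments=coding_segments or [],
    )


@pytest.fixture
def toy_alignment():
    # 3 taeda + 1 sylvestris, 5 columns; columns 3 and 4 are biallelic
    seqs = ["ATGAA", "ATGAC", "ATGCC", "ATGAA"]
    species = ["taeda", "taeda", "taeda", "sylvestris"]
    return make_alignment(seqs, species)
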