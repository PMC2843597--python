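import pytest

from chipdiv.alignment import AlignmentBlock, PairwiseGenomeAlignment
from chipdiv.simulate import SyntheticConfig, generate


def make_block(mel_text, yak_text, mel_start=0, yak_start=0,
               chrom="chr2L", yak_chrom=None):
    return AlignmentBlock(
        ("mel", "yak"),
        {"mel": chrom, "yak": yak_chrom or chrom},
        {"mel": mel_start, "yak": yak_start},
        {"mel": 1, "yak": 1},
        {"mel": mel_text, "yak": yak_text},
    )


def make_aln(*blocks):
    return PairwiseGenomeAlignment(list(blocks))


def walk_projection(mel_text, yak_text, mel_start, yak_start, q_start, q_end):
    """Column-walk oracle: project [q_start, q_end) of the mel row onto yak
    coordinates one alignment column at a time."""
    m, y = mel_start, yak_start
    hits = []
    for a, b in zip(mel_text, yak_text):
        if a != "-" and q_start <= m < q_end and b != "-":
            hits.append(y)
        if a != "-":
            m += 1
        if b != "-":
            y += 1
    intervals = []
    for p in hits:
        if intervals and intervals[-1][1] == p:
            intervals[-1][1] = p + 1
        else:
            intervals.append([p, p + 1])
    return [tuple(iv) for iv in intervals], len(hits) / (q_end - q_start)


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 300-peak synthetic dataset at default study conditions."""
    return generate(SyntheticConfig(seed=20, n_peaks=300))


@pytest.fixture(scope="session")
def null_dataset():
    """No sequence divergence, shared noise: the two species are identical."""
    cfg = SyntheticConfig(
        seed=21, n_peaks=80, p_sub=0.0, p_indel=0.0,
        sigma_dc=0.0, shared_noise=True,
    )
    return generate(cfg)
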