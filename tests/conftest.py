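import numpy as np
import pytest

import mirtarget as mt

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@pytest.fixture(scope="session")
def mir145():
    """Seed lexicon of mature hsa-miR-145-5p."""
    return mt.derive_seed_words("hsa-miR-145", mt.MIR145)


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    return rng.choice(BASES, size=length, p=p).tobytes().decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_planted_ranked_list(
    lexicon, n=2000, n_top=300, prev_top=0.6, prev_bg=0.1, seed=0, word=None
):
    """Ranked sequence list with a word planted at high prevalence in the
    top (most down-regulated) block, mirroring a strong direct-target
    signal."""
    rng = np.random.default_rng(seed)
    word = word or lexicon.word7m8
    records = []
    for i in range(n):
        length = max(int(rng.lognormal(np.log(1000), 0.6)), 50)
        seq = random_dna(rng, length)
        prob = prev_top if i < n_top else prev_bg
        if rng.random() < prob:
            pos = int(rng.integers(0, length - len(word) + 1))
            seq = seq[:pos] + word + seq[pos + len(word) :]
        records.append(mt.SequenceRecord(f"g{i:04d}", "utr3", seq))
    return records
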