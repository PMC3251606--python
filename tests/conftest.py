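import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gpcrminer import benchmark as bm  # noqa: E402
from gpcrminer import hmm  # noqa: E402


def random_toy_profile(rng: np.random.Generator, n_match: int,
                       n_seqs: int = 4) -> hmm.ProfileHMM:
    """A small profile built from a random gappy alignment."""
    from gpcrminer.seqio import AMINO_ACIDS
    ncol = n_match + int(rng.integers(0, 3))
    rows = []
    for _ in range(n_seqs):
        row = []
        for c in range(ncol):
            if rng.random() < 0.2:
                row.append("-")
            else:
                row.append(AMINO_ACIDS[int(rng.integers(20))])
        rows.append("".join(row))
    # force the first column ungapped so at least one match column exists
    rows = ["A" + r[1:] for r in rows]
    try:
        return hmm.build_profile(rows, name=f"toy{n_match}")
    except hmm.ProfileError:
        return random_toy_profile(rng, n_match, n_seqs)


@pytest.fixture(scope="session")
def toy_profiles():
    rng = np.random.default_rng(20240917)
    profiles = []
    for m in (1, 2, 3, 4):
        for _ in range(3):
            p = random_toy_profile(rng, m)
            if p.n_match <= 4:
                profiles.append(p)
    return profiles


@pytest.fixture(scope="session")
def benchmark_result():
    """The default planted-truth benchmark, mined once per session."""
    return bm.run_default_benchmark(seed=bm.DEFAULT_SEED)
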