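import numpy as np
import pytest

from reeffusion.datamodel import LabelSet, PointAnnotation, RegisteredPair


@pytest.fixture(scope="session")
def labelset() -> LabelSet:
    return LabelSet()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_pair(rng) -> RegisteredPair:
    """A 64x64 registered pair with smooth random content."""
    from scipy.ndimage import gaussian_filter

    ref = np.dstack(
        [gaussian_filter(rng.uniform(0, 1, (64, 64)), 3) for _ in range(3)]
    )
    flr = np.dstack(
        [gaussian_filter(rng.uniform(0, 1, (64, 64)), 3) for _ in range(2)]
    )
    ref = (ref - ref.min()) / (ref.max() - ref.min())
    flr = (flr - flr.min()) / (flr.max() - flr.min())
    return RegisteredPair("pair-0", ref, flr)


def brute_force_signed_rank_p(d: np.ndarray, alternative: str = "greater") -> float:
    """Enumeration oracle: exact one-sided signed-rank p over all 2^m signs."""
    from scipy.stats import rankdata

    d = np.asarray(d, dtype=np.float64)
    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    # all 2^m sign assignments as a bit matrix
    codes = np.arange(2**m)[:, None]
    signs = (codes >> np.arange(m)) & 1
    w_all = signs @ ranks
    if alternative == "greater":
        return float(np.mean(w_all >= w_obs - 1e-12))
    return float(np.mean(w_all <= w_obs + 1e-12))
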