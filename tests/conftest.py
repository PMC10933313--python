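import numpy as np
import pandas as pd
import pytest

from pleiomr import HarmonizedSet, SummaryStats


def make_harm(bx, by, se_x=None, se_y=None, ld=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = len(bx)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(k, 0.01) if se_y is None else np.asarray(se_y, dtype=float)
    return HarmonizedSet([f"v{i}" for i in range(k)], bx, se_x, by, se_y, ld=ld)


def make_stats(snp, a1, a2, freq, b, se, p, n):
    return SummaryStats(pd.DataFrame({
        "SNP": snp, "A1": a1, "A2": a2, "freq": freq,
        "b": b, "se": se, "p": p, "N": n}), validate=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_harm(rng):
    """5-IV random panel with a genuine causal signal."""
    k = 5
    bx = rng.normal(0.1, 0.03, k)
    by = 0.3 * bx + rng.normal(0, 0.005, k)
    return make_harm(bx, by, se_x=np.full(k, 0.008), se_y=np.full(k, 0.009))


@pytest.fixture
def ma_file(tmp_path):
    path = tmp_path / "toy.ma"
    path.write_text(
        "SNP A1 A2 freq b se p N\n"
        "rs1 A G 0.2 0.10 0.02 5.7e-7 10000\n"
        "rs2 C T 0.4 -0.05 0.02 0.0124 10000\n"
        "rs3 G A 0.31 0.02 0.02 0.3173 10000\n")
    return path
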