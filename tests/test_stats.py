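"""KS, Peacock 2D, and Pearson tests against independent oracles."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from apicaltrack.stats import ks_2sample, peacock_2d, pearson


def ks_oracle(a, b):
    """Sup ECDF distance by direct counting at every pooled value."""
    best = 0.0
    for v in np.concatenate([a, b]):
        fa = np.sum(a <= v) / len(a)
        fb = np.sum(b <= v) / len(b)
        best = max(best, abs(fa - fb))
    return best


def peacock_oracle(a, b):
    """Max quadrant-fraction difference by looping origins and orientations."""
    pooled = np.vstack([a, b])
    best = 0.0
    for x0 in np.unique(pooled[:, 0]):
        for y0 in np.unique(pooled[:, 1]):
            for qx in (True, False):
                for qy in (True, False):
                    def frac(s):
                        mx = (s[:, 0] <= x0) if qx else (s[:, 0] > x0)
                        my = (s[:, 1] <= y0) if qy else (s[:, 1] > y0)
                        return np.mean(mx & my)
                    best = max(best, abs(frac(a) - frac(b)))
    return best


def test_ks_identical_and_disjoint_samples():
    r = ks_2sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0 and r.p_value == 1.0
    r = ks_2sample([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert r.statistic == 1.0


def test_ks_rejects_tiny_samples():
    with pytest.raises(ValueError):
        ks_2sample([1.0], [1.0, 2.0])


def test_ks_matches_oracle_and_scipy():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.normal(size=rng.integers(4, 40))
        b = rng.normal(0.4, 1.2, size=rng.integers(4, 40))
        r = ks_2sample(a, b)
        assert r.statistic == pytest.approx(ks_oracle(a, b), abs=0)
        s = ks_2samp(a, b, method="asymp")
        assert r.statistic == pytest.approx(s.statistic, abs=1e-14)
        assert r.p_value == pytest.approx(s.pvalue, abs=1e-12)


def test_ks_invariant_under_monotone_transform_and_symmetry():
    rng = np.random.default_rng(1)
    a = rng.normal(size=30)
    b = rng.normal(0.5, 1, size=25)
    d = ks_2sample(a, b).statistic
    assert ks_2sample(b, a).statistic == d
    assert ks_2sample(np.exp(a), np.exp(b)).statistic == pytest.approx(d)


def test_peacock_identical_and_disjoint():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(10, 2))
    assert peacock_2d(a, a.copy(), p_mode="none").statistic == 0.0
    b = a + 100.0
    assert peacock_2d(a, b, p_mode="none").statistic == 1.0


def test_peacock_degenerate_identical_points():
    a = np.zeros((5, 2))
    r = peacock_2d(a, np.zeros((4, 2)))
    assert r.statistic == 0.0


def test_peacock_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = rng.normal(size=(int(rng.integers(3, 41)), 2))
        b = rng.normal(0.3, 1.1, size=(int(rng.integers(3, 41)), 2))
        d = peacock_2d(a, b, p_mode="none").statistic
        assert d == pytest.approx(peacock_oracle(a, b), abs=1e-12)


def test_peacock_sample_origins_never_exceeds_full_grid():
    rng = np.random.default_rng(4)
    for _ in range(25):
        a = rng.normal(size=(20, 2))
        b = rng.normal(0.5, 1, size=(18, 2))
        full = peacock_2d(a, b, p_mode="none").statistic
        econ = peacock_2d(a, b, mode="sample_origins", p_mode="none").statistic
        assert econ <= full + 1e-12


def test_peacock_monotone_invariance_and_symmetry():
    rng = np.random.default_rng(5)
    a = rng.normal(size=(15, 2))
    b = rng.normal(0.4, 1, size=(17, 2))
    d = peacock_2d(a, b, p_mode="none").statistic
    assert peacock_2d(b, a, p_mode="none").statistic == pytest.approx(d)
    ta = np.column_stack([np.exp(a[:, 0]), a[:, 1] ** 3])
    tb = np.column_stack([np.exp(b[:, 0]), b[:, 1] ** 3])
    assert peacock_2d(ta, tb, p_mode="none").statistic == pytest.approx(d)


def test_peacock_permutation_p_reproducible_and_sensible():
    rng = np.random.default_rng(6)
    a = rng.normal(size=(25, 2))
    b = rng.normal(1.5, 1, size=(25, 2))
    r1 = peacock_2d(a, b, n_perm=199, seed=42)
    r2 = peacock_2d(a, b, n_perm=199, seed=42)
    assert r1.p_value == r2.p_value
    assert r1.p_value < 0.05  # strongly shifted alternative
    null = peacock_2d(a, a + rng.normal(0, 1e-9, a.shape), n_perm=199, seed=1)
    assert null.p_value > 0.5


def test_pearson_exact_lines_and_oracle():
    x = np.arange(10, dtype=float)
    r = pearson(x, 2 * x + 1)
    assert r.statistic == pytest.approx(1.0)
    assert r.extras["slope"] == pytest.approx(2.0)
    assert r.extras["intercept"] == pytest.approx(1.0)
    assert pearson(x, -x).statistic == pytest.approx(-1.0)
    rng = np.random.default_rng(7)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    # hand formula oracle
    num = np.sum((x - x.mean()) * (y - y.mean()))
    den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    assert pearson(x, y).statistic == pytest.approx(num / den, abs=1e-12)


def test_pearson_rejects_degenerate_input():
    with pytest.raises(ValueError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        pearson([1.0, 2.0], [1.0, 2.0])
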