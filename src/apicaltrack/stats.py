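"""Two-sample distribution comparisons for tracked-cell summary statistics.

Implements the two-sample Kolmogorov-Smirnov test, the Peacock test (a
two-dimensional two-sample KS extension maximizing quadrant-probability
differences over candidate origins) with permutation p-values, and Pearson
correlation with the best-fit line.

The Peacock statistic here is

    D = max over origins (x0, y0) and the four quadrant orientations of
        |F_a(Q) - F_b(Q)|

where F(Q) is the empirical fraction of a sample falling in quadrant Q and
quadrants are defined with closed "lower" half-planes (x <= x0, y <= y0).
``full_grid`` mode scans the full pooled-x × pooled-y coordinate grid
(Peacock's original proposal); ``sample_origins`` restricts origins to the
pooled data points themselves (the Fasano-Franceschini economy), so its D is
never larger than the full-grid D.  Because the null distribution of D is
awkward, p-values default to label permutation of the pooled sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "ks_2sample", "peacock_2d", "pearson"]


@dataclass
class TestResult:
    """Outcome of one two-sample test or correlation."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    p_mode: str = "asymptotic"
    extras: dict = field(default_factory=dict)

    def __str__(self):
        return (f"{self.method}: statistic={self.statistic:.6g}, "
                f"p={self.p_value:.4g} (n1={self.n1}, n2={self.n2}, "
                f"{self.p_mode})")


def ks_2sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs, computed by a
    scan over the pooled sorted values (right-continuous ECDFs, so ties are
    handled exactly).  The p-value uses the asymptotic Kolmogorov-Smirnov
    distribution evaluated at the effective sample size
    n_a·n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / na
    cdf_b = np.searchsorted(b, pooled, side="right") / nb
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = na * nb / (na + nb)
    p = float(sps.kstwo.sf(d, round(en)))
    return TestResult(d, min(1.0, p), "ks_2sample", na, nb)


def _cum_counts(ix, iy, gx, gy):
    """H[i, j] = #{points with x-index <= i and y-index <= j}."""
    h = np.zeros((gx, gy))
    np.add.at(h, (ix, iy), 1.0)
    return h.cumsum(axis=0).cumsum(axis=1)


def _quadrant_d(ha, hb, origins_mask=None):
    """Max |F_a - F_b| over the origin grid and 4 quadrant orientations.

    ``ha``/``hb`` are cumulative *fractions* F(x <= X[i], y <= Y[j]) for the
    two samples; the other three quadrant fractions follow from the marginals
    by inclusion-exclusion.  ``origins_mask`` optionally restricts the origin
    grid (sample_origins mode).
    """
    diff = ha - hb
    mx = diff[:, -1][:, None]  # F(x <= x0) difference
    my = diff[-1, :][None, :]  # F(y <= y0) difference
    cand = np.stack([
        np.abs(diff),             # x<=x0, y<=y0
        np.abs(mx - diff),        # x<=x0, y> y0
        np.abs(my - diff),        # x> x0, y<=y0
        np.abs(diff - mx - my),   # x> x0, y> y0  (both totals are 1)
    ])
    if origins_mask is not None:
        cand = np.where(origins_mask[None, :, :], cand, 0.0)
    return float(cand.max())


def peacock_2d(
    a,
    b,
    mode: str = "full_grid",
    n_perm: int = 999,
    seed: int | None = 0,
    p_mode: str = "permutation",
) -> TestResult:
    """Peacock two-sample 2D KS test.

    Parameters
    ----------
    a, b : (n, 2) arrays of points.
    mode : ``full_grid`` scans all pooled-x × pooled-y origins;
        ``sample_origins`` restricts origins to the pooled data points.
    n_perm, seed : label-permutation count and RNG seed for the p-value,
        p = (#{D_perm >= D} + 1) / (n_perm + 1).
    p_mode : ``permutation`` or ``none`` (statistic only, p = NaN).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("each sample needs at least 3 (x, y) points")
    if mode not in ("full_grid", "sample_origins"):
        raise ValueError(f"unknown mode {mode!r}")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    xs, ix = np.unique(pooled[:, 0], return_inverse=True)
    ys, iy = np.unique(pooled[:, 1], return_inverse=True)
    gx, gy = len(xs), len(ys)
    if gx == 1 and gy == 1:  # all points identical in both samples
        return TestResult(0.0, 1.0, f"peacock_2d[{mode}]", na, nb,
                          p_mode="degenerate")
    mask = None
    if mode == "sample_origins":
        mask = np.zeros((gx, gy), dtype=bool)
        mask[ix, iy] = True

    # pooled cumulative counts are permutation-invariant, so each relabeling
    # needs only one fresh histogram: Hb = Htot - Ha
    htot = _cum_counts(ix, iy, gx, gy)

    def stat(labels_a: np.ndarray) -> float:
        ha = _cum_counts(ix[labels_a], iy[labels_a], gx, gy)
        return _quadrant_d(ha / na, (htot - ha) / nb, mask)

    labels = np.zeros(na + nb, dtype=bool)
    labels[:na] = True
    d = stat(labels)
    if p_mode == "none":
        return TestResult(d, float("nan"), f"peacock_2d[{mode}]", na, nb,
                          p_mode="none")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if stat(perm) >= d - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(d, p, f"peacock_2d[{mode}]", na, nb,
                      p_mode=f"permutation(n_perm={n_perm}, seed={seed})")


def pearson(x, y) -> TestResult:
    """Pearson correlation with t-distributed p (n−2 d.o.f.) and best-fit line.

    ``extras`` carries the least-squares slope and intercept of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D samples")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a sample")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return TestResult(float(r), float(p), "pearson", n, n,
                      extras={"slope": float(fit.slope),
                              "intercept": float(fit.intercept)})
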