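"""Two-sample MR estimators operating on a harmonized instrument panel.

Implemented here: inverse-variance-weighted (IVW) regression through the
origin, MR-Egger weighted regression with intercept, the weighted-median
estimator, and the (simple/weighted) mode-based estimator.  Externally
published robust methods (MR-PRESSO, MRMix, RAPS, Con-Mix, Robust,
MR-Lasso) are not reimplemented; a plugin registry lets a caller attach
any function with the same ``HarmonizedSet -> MRResult`` contract.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats

from .results import MRResult, no_instrument_result
from .sumstats import HarmonizedSet, SummaryStats, harmonize, select_instruments

__all__ = [
    "ivw", "egger", "weighted_median", "mode_estimate", "bidirectional_mr",
    "register_method", "get_method", "available_methods",
]


class EstimatorError(ValueError):
    pass


def _two_sided_norm_p(z):
    return 2.0 * stats.norm.sf(np.abs(z))


# ---------------------------------------------------------------------------
# IVW


def ivw(h: HarmonizedSet, variance_model: str = "fixed") -> MRResult:
    """Inverse-variance-weighted estimate: WLS of by on bx through the
    origin with weights 1/se_y^2.

    ``variance_model="multiplicative"`` inflates the fixed-effect se by
    ``max(1, sqrt(Q/(k-1)))`` where Q is the Cochran statistic of the
    per-IV Wald ratios.
    """
    if variance_model not in ("fixed", "multiplicative"):
        raise EstimatorError(f"unknown variance model {variance_model!r}")
    if h.k < 2:
        raise EstimatorError("IVW requires at least 2 instruments")
    w = 1.0 / h.se_y ** 2
    sxx = np.sum(w * h.bx ** 2)
    b = np.sum(w * h.bx * h.by) / sxx
    se = sxx ** -0.5
    # Cochran Q of the ratio estimates around the combined estimate
    ratio = h.by / h.bx
    wr = h.bx ** 2 * w                      # 1/var of each ratio (1st order)
    q = float(np.sum(wr * (ratio - b) ** 2))
    if variance_model == "multiplicative":
        se *= max(1.0, np.sqrt(q / (h.k - 1)))
    p = _two_sided_norm_p(b / se)
    return MRResult("ivw", float(b), float(se), float(p), h.k,
                    het_q=q, het_p=float(stats.chi2.sf(q, h.k - 1)))


# ---------------------------------------------------------------------------
# MR-Egger


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of by on bx with an intercept that
    absorbs average directional pleiotropy.

    Exposure effects are re-oriented so every bx >= 0 before fitting
    (flipping by with them), making the fit invariant to the arbitrary
    effect-allele orientation.  Inference uses a t reference with k-2 df.
    """
    if h.k < 3:
        raise EstimatorError("MR-Egger requires at least 3 instruments")
    flip = np.sign(h.bx)
    flip[flip == 0] = 1.0
    bx = h.bx * flip
    by = h.by * flip
    if np.ptp(bx) == 0:
        raise EstimatorError("degenerate design: no variation in |bx|")
    w = 1.0 / h.se_y ** 2
    # weighted normal equations for [intercept, slope]
    sw = w.sum()
    swx = np.sum(w * bx)
    swxx = np.sum(w * bx * bx)
    swy = np.sum(w * by)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    icept = (swxx * swy - swx * swxy) / det
    resid = by - icept - slope * bx
    df = h.k - 2
    sigma2 = max(np.sum(w * resid ** 2) / df, np.finfo(float).tiny)
    se_slope = np.sqrt(sigma2 * sw / det)
    se_icept = np.sqrt(sigma2 * swxx / det)
    p = 2.0 * stats.t.sf(abs(slope / se_slope), df)
    p_i = 2.0 * stats.t.sf(abs(icept / se_icept), df)
    return MRResult("egger", float(slope), float(se_slope), float(p), h.k,
                    intercept=float(icept), intercept_se=float(se_icept),
                    intercept_p=float(p_i))


# ---------------------------------------------------------------------------
# Weighted median


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by mid-weight interpolation.

    For sorted ratios r_(i) with normalized weights w_(i), the cumulative
    mid-weights are s_i = sum_{j<=i} w_j - w_i/2; the estimate linearly
    interpolates r at s = 1/2.  Vectorized over rows.
    """
    order = np.argsort(ratios, axis=-1)
    r = np.take_along_axis(ratios, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / w.sum(axis=-1, keepdims=True)
    s = np.cumsum(w, axis=-1) - w / 2.0
    below = s < 0.5
    idx_hi = below.sum(axis=-1)            # first s >= 0.5
    k = r.shape[-1]
    idx_hi = np.clip(idx_hi, 0, k - 1)
    idx_lo = np.clip(idx_hi - 1, 0, k - 1)
    take = lambda a, i: np.take_along_axis(a, i[..., None], axis=-1)[..., 0]
    s_lo, s_hi = take(s, idx_lo), take(s, idx_hi)
    r_lo, r_hi = take(r, idx_lo), take(r, idx_hi)
    out = np.where(idx_hi == 0, r_hi,
                   r_lo + (r_hi - r_lo) * (0.5 - s_lo)
                   / np.where(s_hi == s_lo, np.inf, s_hi - s_lo))
    # all mass below 0.5 never happens (s_k = 1 - w_k/2 >= 1/2); clamp anyway
    return out


def _boot_ratio_draws(h: HarmonizedSet, n_boot: int,
                      rng: np.random.Generator, scheme: str):
    """Bootstrap draws of (ratio, weight) rows.

    ``"instruments"`` resamples the k instruments with replacement (the
    nonparametric bootstrap that is consistent for non-smooth statistics
    like the median, and captures between-instrument heterogeneity);
    ``"parametric"`` redraws (bx, by) from their stated normal errors
    around the observed values.
    """
    if scheme == "instruments":
        idx = rng.integers(0, h.k, size=(n_boot, h.k))
        ratios = (h.by / h.bx)[idx]
        weights = (h.bx ** 2 / h.se_y ** 2)[idx]
        return ratios, weights
    if scheme == "parametric":
        bx = rng.normal(h.bx, h.se_x, size=(n_boot, h.k))
        by = rng.normal(h.by, h.se_y, size=(n_boot, h.k))
        return by / bx, bx ** 2 / h.se_y ** 2
    raise EstimatorError(f"unknown bootstrap scheme {scheme!r}")


def _boot_p(b: float, se: float, k: int) -> float:
    """Two-sided p for a bootstrap-se Wald statistic, on a t reference
    with k-1 df (Hartung-Knapp-style small-sample correction)."""
    if se == 0:
        return 0.0 if b != 0 else 1.0
    return float(2.0 * stats.t.sf(abs(b / se), k - 1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None,
                    boot_scheme: str = "instruments") -> MRResult:
    """Weighted-median estimator of b_xy.

    Consistent when instruments carrying at least half the total weight
    are valid.  Weights are inverse first-order Wald-ratio variances; the
    standard error is a bootstrap over instruments (see
    ``_boot_ratio_draws``; ``seed`` required) and inference uses a t
    reference with k-1 df.
    """
    if h.k < 3:
        raise EstimatorError("weighted median requires at least 3 instruments")
    if seed is None:
        raise EstimatorError("weighted_median requires an explicit seed")
    ratios = h.by / h.bx
    w = h.bx ** 2 / h.se_y ** 2           # 1 / first-order ratio variance
    b = float(_weighted_median_rows(ratios[None, :], w[None, :])[0])
    rng = np.random.default_rng(seed)
    rb, wb = _boot_ratio_draws(h, n_boot, rng, boot_scheme)
    boots = _weighted_median_rows(rb, wb)
    se = float(np.std(boots, ddof=1))
    return MRResult("weighted_median", b, se, _boot_p(b, se, h.k), h.k)


# ---------------------------------------------------------------------------
# Mode-based estimate


def _mode_bandwidths(ratios: np.ndarray, factor: float) -> np.ndarray:
    """Modified-Silverman bandwidth per row: 0.9 min(sd, IQR/1.34) k^-1/5."""
    k = ratios.shape[-1]
    sd = np.std(ratios, axis=-1, ddof=1)
    q75, q25 = np.percentile(ratios, [75, 25], axis=-1)
    iqr = (q75 - q25) / 1.349
    spread = np.where(iqr > 0, np.minimum(sd, iqr), sd)
    h = factor * 0.9 * spread * k ** (-0.2)
    return np.maximum(h, 1e-12)


def _kde_argmax_rows(ratios: np.ndarray, weights: np.ndarray,
                     bw: np.ndarray, n_grid: int) -> np.ndarray:
    """Row-wise argmax of the normal-kernel weighted density on a grid."""
    lo = ratios.min(axis=-1) - 2.0 * bw
    hi = ratios.max(axis=-1) + 2.0 * bw
    t = np.linspace(0.0, 1.0, n_grid)
    grid = lo[..., None] + (hi - lo)[..., None] * t          # (B, G)
    z = (grid[..., :, None] - ratios[..., None, :]) / bw[..., None, None]
    dens = np.einsum("...gk,...k->...g", np.exp(-0.5 * z * z), weights)
    best = np.argmax(dens, axis=-1)
    return np.take_along_axis(grid, best[..., None], axis=-1)[..., 0]


def _kde_density(x, ratios, weights, bw):
    z = (x - ratios) / bw
    return float(np.sum(weights * np.exp(-0.5 * z * z)))


def _golden_refine(f, lo, hi, tol=1e-8):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def mode_estimate(h: HarmonizedSet, weighted: bool = False,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None, boot_scheme: str = "instruments",
                  n_grid: int = 512, boot_grid: int = 128) -> MRResult:
    """Mode-based estimate: the argmax of a kernel-smoothed density of the
    per-IV Wald ratios.

    Consistent under the "zero modal pleiotropy" assumption — the largest
    group of instruments sharing a ratio is the valid one, even if valid
    instruments are a minority.  ``weighted`` weights each ratio by its
    inverse first-order Wald variance.  The point estimate refines the
    best grid point by golden-section search; the bootstrap se reuses the
    parametric resampling of :func:`weighted_median` (grid-only argmax for
    speed).
    """
    if h.k < 3:
        raise EstimatorError("mode estimator requires at least 3 instruments")
    if seed is None:
        raise EstimatorError("mode_estimate requires an explicit seed")
    ratios = h.by / h.bx
    if weighted:
        w = h.bx ** 2 / h.se_y ** 2
    else:
        w = np.ones(h.k)
    w = w / w.sum()
    bw = _mode_bandwidths(ratios[None, :], bandwidth_factor)[0]
    grid_best = _kde_argmax_rows(ratios[None, :], w[None, :],
                                 np.array([bw]), n_grid)[0]
    span = (ratios.max() - ratios.min() + 4 * bw) / (n_grid - 1)
    b = _golden_refine(lambda x: _kde_density(x, ratios, w, bw),
                       grid_best - span, grid_best + span)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, int(2e6 // (boot_grid * h.k)))
    rb, wb = _boot_ratio_draws(h, n_boot, rng, boot_scheme)
    if not weighted:
        wb = np.ones_like(rb)
    wb = wb / wb.sum(axis=-1, keepdims=True)
    bwb = _mode_bandwidths(rb, bandwidth_factor)
    for i in range(0, n_boot, chunk):
        sl = slice(i, min(i + chunk, n_boot))
        boots[sl] = _kde_argmax_rows(rb[sl], wb[sl], bwb[sl], boot_grid)
    se = float(np.std(boots, ddof=1))
    name = "weighted_mode" if weighted else "mode"
    return MRResult(name, float(b), se, _boot_p(b, se, h.k), h.k)


# ---------------------------------------------------------------------------
# Method registry (plugin surface for external robust methods)

_REGISTRY: dict[str, Callable[..., MRResult]] = {}


def register_method(name: str, fn: Callable[..., MRResult],
                    overwrite: bool = False) -> None:
    """Register an estimator callable ``fn(h: HarmonizedSet, **opts) ->
    MRResult`` under ``name``.  External published methods (MR-PRESSO,
    MRMix, RAPS, Con-Mix, Robust, MR-Lasso) can be attached here without
    being shipped."""
    if name in _REGISTRY and not overwrite:
        raise EstimatorError(f"method {name!r} already registered")
    _REGISTRY[name] = fn


def get_method(name: str) -> Callable[..., MRResult]:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise EstimatorError(
            f"unknown method {name!r}; available: {sorted(_REGISTRY)}") from None


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def _register_builtins():
    register_method("ivw", ivw, overwrite=True)
    register_method("egger", egger, overwrite=True)
    register_method("weighted_median", weighted_median, overwrite=True)
    register_method("mode", mode_estimate, overwrite=True)
    register_method(
        "weighted_mode",
        lambda h, **kw: mode_estimate(h, weighted=True, **kw),
        overwrite=True)
    # gsmr2 registers itself on import (avoids a circular import here)
    from . import gsmr2 as _gsmr2  # noqa: F401


# ---------------------------------------------------------------------------
# Bidirectional MR


def bidirectional_mr(a: SummaryStats, b: SummaryStats, method: str = "ivw",
                     p_threshold: float = 5e-8,
                     ld: np.ndarray | None = None,
                     ld_ids: list[str] | None = None,
                     r2_threshold: float = 0.01,
                     method_options: dict | None = None
                     ) -> tuple[MRResult, MRResult]:
    """Forward (a -> b) and reverse (b -> a) MR with independently
    selected instruments at the same significance threshold.

    A direction with no genome-wide-significant instruments returns the
    explicit ``"no-instrument"`` marker result rather than raising.
    """
    fn = get_method(method)
    opts = method_options or {}

    def _one_direction(exposure, outcome):
        iv = select_instruments(exposure, p_threshold=p_threshold,
                                ld=ld, ld_ids=ld_ids, r2_threshold=r2_threshold)
        iv = [v for v in iv if v in set(outcome.variant_ids)]
        if not iv:
            return no_instrument_result(method)
        h = harmonize(exposure.subset(iv), outcome.subset(iv))
        return fn(h, **opts)

    return _one_direction(a, b), _one_direction(b, a)


_register_builtins()
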