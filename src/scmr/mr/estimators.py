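"""Two-sample MR estimators.

All estimators operate on harmonized per-variant effects: exposure effects
``bx`` with standard errors ``sx`` and outcome effects ``by`` with standard
errors ``sy``.  Public functions take a :class:`HarmonizedInstrumentSet`;
``_*_core`` functions take plain arrays and are shared with the simulation
studies.

Random-effects behaviour is multiplicative: the fixed-effect standard error
is scaled by ``max(1, residual sd)``, the convention of the common
two-sample MR implementations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import stats as sps

from ..errors import EstimationError
from ..stats import bh_fdr  # noqa: F401  (re-exported: FDR lives with the MR surface)
from .data import HarmonizedInstrumentSet, MREstimate

Z95 = sps.norm.ppf(0.975)


def to_odds_ratio(beta: float, se: float, level: float = 0.95):
    """``(OR, ci_low, ci_high)`` from a log-odds estimate."""
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (float(np.exp(beta)),
            float(np.exp(beta - z * se)),
            float(np.exp(beta + z * se)))


def _finish(method: str, beta: float, se: float, nsnp: int,
            t_df: Optional[int] = None) -> MREstimate:
    beta, se = float(beta), float(se)
    if se > 0:
        if t_df is not None:
            pval = 2.0 * sps.t.sf(abs(beta / se), t_df)
            half = sps.t.ppf(0.975, t_df) * se
        else:
            pval = 2.0 * sps.norm.sf(abs(beta / se))
            half = Z95 * se
    else:
        pval, half = (1.0 if beta == 0 else 0.0), 0.0
    return MREstimate(method=method, beta=beta, se=se,
                      ci_low=beta - half, ci_high=beta + half,
                      pval=float(pval), nsnp=nsnp)


# ---------------------------------------------------------------------------
# Wald ratio / IVW

def _wald_core(bx, sx, by, sy, second_order=False):
    if bx == 0:
        raise EstimationError("Wald ratio undefined for a null exposure effect")
    beta = by / bx
    if second_order:
        se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    else:
        se = sy / abs(bx)
    return beta, se


def wald_ratio(h: HarmonizedInstrumentSet, second_order: bool = False) -> MREstimate:
    """Single-instrument estimate: outcome effect over exposure effect,
    with the first-order delta-method standard error ``se_y / |bx|``."""
    if h.nsnp != 1:
        raise EstimationError("wald_ratio requires exactly one instrument")
    bx, sx, by, sy = (a[0] for a in h.arrays())
    beta, se = _wald_core(bx, sx, by, sy, second_order)
    return _finish("wald_ratio", beta, se, 1)


def _ivw_core(bx, sx, by, sy, random_effects=True):
    """Returns (beta, se, sigma) for the IVW weighted regression through
    the origin with weights 1/sy^2."""
    bx, by, sy = (np.asarray(a, dtype=float) for a in (bx, by, sy))
    denom = np.sum(bx ** 2 / sy ** 2)
    if denom == 0:
        raise EstimationError("all exposure effects are zero")
    beta = np.sum(bx * by / sy ** 2) / denom
    se_fixed = 1.0 / np.sqrt(denom)
    n = bx.size
    sigma = 1.0
    if n >= 2:
        resid = by - beta * bx
        sigma = np.sqrt(np.sum(resid ** 2 / sy ** 2) / (n - 1))
    se = se_fixed * max(1.0, sigma) if random_effects else se_fixed
    return beta, se, sigma


def ivw(h: HarmonizedInstrumentSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    Algebraically the weighted regression of outcome on exposure effects
    through the origin with weights ``1/se_y^2``; with ``random_effects``
    (the default) the standard error is scaled by ``max(1, residual sd)``.
    A single instrument delegates to the Wald ratio.
    """
    if h.nsnp == 1:
        return wald_ratio(h)
    bx, sx, by, sy = h.arrays()
    beta, se, _ = _ivw_core(bx, sx, by, sy, random_effects)
    est = _finish("ivw", beta, se, h.nsnp)
    return est


# ---------------------------------------------------------------------------
# MR-Egger

def _egger_core(bx, by, sy, random_effects=True):
    """Weighted regression with intercept on orientation-corrected effects.

    Returns ``(slope, se_slope, intercept, se_intercept, df)``.
    """
    bx, by, sy = (np.asarray(a, dtype=float) for a in (bx, by, sy))
    n = bx.size
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(n), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ y)
    resid = y - X @ coef
    df = n - 2
    sigma = np.sqrt(np.sum(w * resid ** 2) / df) if df > 0 else 0.0
    scale = max(1.0, sigma) if random_effects else 1.0
    se = np.sqrt(np.diag(cov)) * scale
    return coef[1], se[1], coef[0], se[0], df


def mr_egger(h: HarmonizedInstrumentSet, random_effects: bool = True):
    """MR-Egger regression: ``(slope estimate, intercept estimate)``.

    The intercept estimates average directional pleiotropy; instruments are
    oriented so every exposure effect is non-negative before the weighted
    regression.  Returns ``None`` (method not applicable) below three
    instruments.
    """
    if h.nsnp < 3:
        return None
    bx, sx, by, sy = h.arrays()
    slope, se_s, inter, se_i, df = _egger_core(bx, by, sy, random_effects)
    return (_finish("egger", slope, se_s, h.nsnp, t_df=df),
            _finish("egger_intercept", inter, se_i, h.nsnp, t_df=df))


# ---------------------------------------------------------------------------
# Weighted median / mode

def _weighted_median_point(ratios, weights):
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    p = s - w / 2.0
    return float(np.interp(0.5, p, b))


def _ratio_weights(bx, by, sy):
    ratios = by / bx
    weights = bx ** 2 / sy ** 2
    return ratios, weights


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed):
    rng = np.random.default_rng(seed)
    n = bx.size
    bx_b = rng.normal(bx, sx, (n_boot, n))
    by_b = rng.normal(by, sy, (n_boot, n))
    est = np.empty(n_boot)
    for i in range(n_boot):
        ratios, weights = _ratio_weights(bx_b[i], by_b[i], sy)
        est[i] = point_fn(ratios, weights)
    return float(np.std(est, ddof=1))


def weighted_median(h: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed: Optional[int] = None) -> Optional[MREstimate]:
    """Weighted median of the per-variant ratios.

    Consistent when at least half the total weight comes from valid
    instruments; the standard error is a seeded parametric bootstrap.
    Returns ``None`` below three instruments.
    """
    if h.nsnp < 3:
        return None
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect; ratios undefined")
    ratios, weights = _ratio_weights(bx, by, sy)
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, n_boot, seed)
    return _finish("weighted_median", beta, se, h.nsnp)


def _weighted_mode_point(ratios, weights, bandwidth_mult=1.0):
    n = ratios.size
    w = weights / weights.sum()
    sd = np.std(ratios, ddof=1)
    mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
    s = min(sd, mad) if mad > 0 else sd
    if s == 0:
        return float(ratios[0])
    h = bandwidth_mult * 0.9 * s * n ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def weighted_mode(h: HarmonizedInstrumentSet, bandwidth: float = 1.0,
                  n_boot: int = 1000, seed: Optional[int] = None) -> Optional[MREstimate]:
    """Mode of the weighted Gaussian-kernel density of the ratios.

    Bandwidth is ``bandwidth`` times a normal-reference rule on the ratio
    dispersion; the standard error is a seeded parametric bootstrap.
    Returns ``None`` below three instruments.
    """
    if h.nsnp < 3:
        return None
    bx, sx, by, sy = h.arrays()
    if np.any(bx == 0):
        raise EstimationError("zero exposure effect; ratios undefined")
    ratios, weights = _ratio_weights(bx, by, sy)
    beta = _weighted_mode_point(ratios, weights, bandwidth)
    se = _bootstrap_se(
        lambda r, w: _weighted_mode_point(r, w, bandwidth),
        bx, sx, by, sy, n_boot, seed)
    return _finish("weighted_mode", beta, se, h.nsnp)


# ---------------------------------------------------------------------------
# Heterogeneity

def _cochran_q_core(bx, by, sy, method="ivw"):
    bx, by, sy = (np.asarray(a, dtype=float) for a in (bx, by, sy))
    n = bx.size
    if method == "ivw":
        if n < 2:
            raise EstimationError("Q (IVW) needs at least 2 instruments")
        ratios = by / bx
        w = bx ** 2 / sy ** 2
        pooled = np.sum(w * ratios) / np.sum(w)
        q = float(np.sum(w * (ratios - pooled) ** 2))
        df = n - 1
    elif method == "egger":
        if n < 3:
            raise EstimationError("Q (Egger) needs at least 3 instruments")
        slope, _, inter, _, _ = _egger_core(bx, by, sy)
        sign = np.where(bx < 0, -1.0, 1.0)
        x, y = bx * sign, by * sign
        q = float(np.sum((y - inter - slope * x) ** 2 / sy ** 2))
        df = n - 2
    else:
        raise EstimationError(f"unknown heterogeneity method: {method!r}")
    pval = float(sps.chi2.sf(q, df))
    return q, df, pval


def cochran_q(h: HarmonizedInstrumentSet, method: str = "ivw"):
    """Cochran's Q heterogeneity statistic: ``(Q, df, p)``.

    For ``"ivw"`` the pooled value is the fixed-effect IVW estimate and
    ``df = nsnp - 1``; for ``"egger"`` deviations are taken from the fitted
    Egger line and ``df = nsnp - 2``.
    """
    bx, sx, by, sy = h.arrays()
    return _cochran_q_core(bx, by, sy, method)
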