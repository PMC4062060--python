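"""Two-color array preprocessing: NormExp background correction and
rank-invariant LOESS normalization.

The observed intensity of each probe is modelled as X = B + S with normal
background B ~ N(mu, sigma^2) and exponential specific signal S with mean
alpha. Background correction replaces x by the posterior mean E[S | X = x]
(plus a stabilising offset), which is strictly positive and monotone in x.
Within each co-hybridised pair, the log-ratio M = log2(kd/wt) is then freed of
intensity-dependent dye bias by subtracting a LOESS fit of M on A estimated on
rank-invariant probes and negative controls only, so genuine differential
methylation does not bend the normalization curve.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "NormExpParams",
    "MAMatrix",
    "estimate_normexp_params",
    "normexp_correct",
    "compute_MA",
    "select_rank_invariant",
    "loess_normalize",
    "normalize_pair",
]

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-2
ALPHA_FLOOR = 1e-2
CORRECTED_FLOOR = 0.5


@dataclass(frozen=True)
class NormExpParams:
    """Parameters of the normal-background + exponential-signal model."""

    mu: float
    sigma: float
    alpha: float
    offset: float = 50.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0 or self.offset < 0:
            raise ValueError("need sigma > 0, alpha > 0, offset >= 0")


@dataclass
class MAMatrix:
    """Probes x samples M (log2 kd/wt) and A (mean log2 intensity) matrices."""

    M: pd.DataFrame
    A: pd.DataFrame
    negctrl_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.M.shape != self.A.shape:
            raise ValueError("M and A must share shape")
        if not (np.isfinite(self.M.values).all() and np.isfinite(self.A.values).all()):
            raise ValueError("M and A must be finite")


def estimate_normexp_params(
    intensities: np.ndarray,
    negctrl_mask: np.ndarray | None = None,
    offset: float = 50.0,
    min_negctrl: int = 30,
) -> NormExpParams:
    """Estimate (mu, sigma, alpha) for one channel.

    When >= ``min_negctrl`` negative-control values are available, background
    moments come straight from the controls and alpha from the signal excess
    over background. Otherwise a method-of-moments fit over all intensities is
    used (exponential skewness identifies alpha), with a logged warning.
    """
    x = np.asarray(intensities, dtype=float)
    if negctrl_mask is not None and int(np.sum(negctrl_mask)) >= min_negctrl:
        neg = x[np.asarray(negctrl_mask, dtype=bool)]
        mu = float(np.mean(neg))
        sigma = max(float(np.std(neg, ddof=1)), SIGMA_FLOOR)
        alpha = max(float(np.mean(x) - mu), ALPHA_FLOOR)
        return NormExpParams(mu, sigma, alpha, offset)
    logger.warning(
        "fewer than %d negative controls; falling back to moment fit over all probes",
        min_negctrl,
    )
    m1 = float(np.mean(x))
    var = float(np.var(x, ddof=1)) if x.size > 1 else 0.0
    m3 = float(np.mean((x - m1) ** 3))
    alpha = max((m3 / 2.0) ** (1.0 / 3.0) if m3 > 0 else 0.0, ALPHA_FLOOR)
    sigma = max(np.sqrt(max(var - alpha**2, 0.0)), SIGMA_FLOOR)
    mu = m1 - alpha
    return NormExpParams(mu, sigma, alpha, offset)


def normexp_correct(x, params: NormExpParams):
    """Posterior-mean background correction with floor and offset.

    Returns max(E[S | X = x], 0.5) + offset where, with
    mu_sx = x - mu - sigma^2/alpha,

        E[S | X = x] = mu_sx + sigma * phi(mu_sx/sigma) / Phi(mu_sx/sigma).

    The Mills ratio phi/Phi is evaluated through log-densities so the formula
    stays finite arbitrarily far below background. The 0.5 floor is applied to
    the corrected value before the offset is added.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensities must be finite")
    mu_sx = arr - params.mu - params.sigma**2 / params.alpha
    t = mu_sx / params.sigma
    log_mills = stats.norm.logpdf(t) - log_ndtr(t)
    corrected = mu_sx + params.sigma * np.exp(log_mills)
    out = np.maximum(corrected, CORRECTED_FLOOR) + params.offset
    return out if arr.ndim else float(out)


def compute_MA(r_corrected, g_corrected) -> tuple[np.ndarray, np.ndarray]:
    """M = log2(R/G) and A = (log2 R + log2 G)/2 for the kd (R) and wt (G) channels."""
    r = np.asarray(r_corrected, dtype=float)
    g = np.asarray(g_corrected, dtype=float)
    if r.shape != g.shape:
        raise ValueError("channel shapes differ")
    if np.any(r <= 0) or np.any(g <= 0):
        raise ValueError("corrected intensities must be strictly positive")
    lr, lg = np.log2(r), np.log2(g)
    return lr - lg, (lr + lg) / 2.0


def select_rank_invariant(
    r: np.ndarray,
    g: np.ndarray,
    rank_tol: float = 0.05,
    negctrl_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of probes whose within-channel ranks agree, plus controls.

    A probe is rank-invariant when its rank in the two channels differs by at
    most ``rank_tol * n``; negative controls are always included since they are
    presumed unchanged by construction.
    """
    if not 0 < rank_tol <= 0.5:
        raise ValueError("rank_tol must be in (0, 0.5]")
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    n = r.size
    rr = stats.rankdata(r)
    rg = stats.rankdata(g)
    sel = np.abs(rr - rg) <= rank_tol * n
    if negctrl_mask is not None:
        sel = sel | np.asarray(negctrl_mask, dtype=bool)
    if not sel.any():
        raise ValueError("no rank-invariant probes selected; increase rank_tol")
    return sel


def loess_normalize(
    m: np.ndarray,
    a: np.ndarray,
    subset: np.ndarray,
    span: float = 0.4,
) -> np.ndarray:
    """Subtract a LOESS fit of M on A estimated on ``subset`` probes only.

    Local linear regression with tricube weights (span = fraction of subset
    points per window) and one robustifying iteration, so the occasional
    genuinely differential probe that slips into the subset cannot bend the
    curve. The fit is evaluated at the subset points and linearly interpolated
    to every probe's A value; A values outside the subset's range are clamped
    to the range boundary, so extrapolation reuses the boundary fit. A final
    location step re-centres M on the median residual of the subset (the
    presumed-null probes), so the local-linear smoother's small curvature
    leftover cannot shift the array's null location.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    sub = np.asarray(subset, dtype=bool)
    if int(sub.sum()) < 30:
        raise ValueError("normalization subset must contain at least 30 probes")
    a_sub, m_sub = a[sub], m[sub]
    fit = lowess(m_sub, a_sub, frac=span, it=1, is_sorted=False, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    xvals = np.clip(a, a_sub.min(), a_sub.max())
    fitted = np.interp(xvals, xs, ys)
    resid = m - fitted
    return resid - np.median(resid[sub])


def normalize_pair(
    r_raw: np.ndarray,
    g_raw: np.ndarray,
    negctrl_mask: np.ndarray | None = None,
    offset: float = 50.0,
    span: float = 0.4,
    rank_tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing of one co-hybridised pair: returns (M_normalized, A)."""
    pr = estimate_normexp_params(r_raw, negctrl_mask, offset)
    pg = estimate_normexp_params(g_raw, negctrl_mask, offset)
    rc = normexp_correct(r_raw, pr)
    gc = normexp_correct(g_raw, pg)
    m, a = compute_MA(rc, gc)
    subset = select_rank_invariant(rc, gc, rank_tol, negctrl_mask)
    return loess_normalize(m, a, subset, span), a
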