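"""Summary-data Mendelian randomization estimators and the multi-method
validation logic.

The main analysis dispatches by instrument count: the Wald ratio for a
single instrument and fixed-effect IVW for two or more.  The weak-instrument
suite runs eight estimators — Wald/IVW, weighted median, weighted mode,
MR-Robust (Tukey-bisquare IRLS), debiased IVW, MR-RAPS (profile likelihood
with overdispersion and a Huber-robustified score), MR-PRESSO (resampling
outlier test) and cML-MA (constrained ML with BIC model averaging over the
number of invalid instruments) — each of which trades efficiency for
robustness to weak-instrument bias or horizontal pleiotropy in a different
way.  MR-Egger is deliberately absent: with cis-only instruments the InSIDE
assumption it rests on is not credible.

All causal effects are on the log-odds scale for case-control outcomes, so
``exp(beta)`` is the reported odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .core_io import bh_fdr
from .instruments import InstrumentSet

__all__ = [
    "MRInput",
    "MREstimate",
    "wald_ratio",
    "ivw",
    "weighted_median",
    "weighted_mode",
    "mr_robust",
    "debiased_ivw",
    "mr_raps",
    "mr_presso",
    "cml_ma",
    "run_main_mr",
    "run_weak_suite",
    "cross_method_validation",
    "method_benchmark",
    "WEAK_SUITE_METHODS",
]

_TUKEY_C = 4.685
_HUBER_K = 1.345


@dataclass
class MRInput:
    """Per-instrument exposure/outcome effects for one exposure-outcome pair."""

    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray
    exposure_id: str = ""
    outcome_id: str = ""
    n_outcome: float | None = None  # outcome GWAS sample size (BIC scale)

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.bxse = np.asarray(self.bxse, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.byse = np.asarray(self.byse, dtype=float)
        n = self.bx.size
        if n < 1 or any(a.size != n for a in (self.bxse, self.by, self.byse)):
            raise ValueError("bx/bxse/by/byse must be equal-length, length >= 1")
        if np.any(self.bxse <= 0) or np.any(self.byse <= 0):
            raise ValueError("all standard errors must be > 0")

    @property
    def nsnp(self) -> int:
        return self.bx.size

    @classmethod
    def from_harmonized(cls, inst_set: InstrumentSet, outcome_by_id: dict,
                        outcome_id: str = "") -> "MRInput":
        bx, bxse, by, byse = [], [], [], []
        for rec in inst_set.instruments:
            o = outcome_by_id[rec.variant_id]
            bx.append(rec.stat.beta)
            bxse.append(rec.stat.se)
            by.append(o.beta)
            byse.append(o.se)
        n_out = None
        for rec in inst_set.instruments:
            o = outcome_by_id[rec.variant_id]
            if o.n is not None:
                n_out = float(o.n)
                break
        return cls(np.array(bx), np.array(bxse), np.array(by), np.array(byse),
                   exposure_id=inst_set.exposure_id, outcome_id=outcome_id,
                   n_outcome=n_out)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    p: float
    nsnp: int
    exposure_id: str = ""
    outcome_id: str = ""
    converged: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zc = sps.norm.ppf(0.5 + level / 2)
        return self.beta - zc * self.se, self.beta + zc * self.se


def _normal_p(beta: float, se: float) -> float:
    if se <= 0 or not math.isfinite(se):
        return 1.0
    return max(min(math.erfc(abs(beta / se) / math.sqrt(2.0)), 1.0), 1e-300)


def _est(method: str, mri: MRInput, beta: float, se: float, *,
         converged: bool = True, extras: dict | None = None,
         nsnp: int | None = None) -> MREstimate:
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      p=_normal_p(beta, se), nsnp=nsnp or mri.nsnp,
                      exposure_id=mri.exposure_id, outcome_id=mri.outcome_id,
                      converged=converged, extras=extras or {})


# ---------------------------------------------------------------------------
# Core ratio estimators

def wald_ratio(mri: MRInput, *, second_order: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta = by/bx with delta-method se.

    First-order se = byse/|bx|; the second-order option adds the exposure
    uncertainty term by²·bxse²/bx⁴.
    """
    if mri.nsnp != 1:
        raise ValueError("wald_ratio requires exactly one instrument")
    bx, bxse, by, byse = (float(mri.bx[0]), float(mri.bxse[0]),
                          float(mri.by[0]), float(mri.byse[0]))
    if bx == 0:
        raise ZeroDivisionError("undefined ratio: exposure beta is zero")
    beta = by / bx
    var = byse ** 2 / bx ** 2
    if second_order:
        var += by ** 2 * bxse ** 2 / bx ** 4
    return _est("wald_ratio", mri, beta, math.sqrt(var))


def ivw(mri: MRInput, *, random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted least squares of by on bx through the origin with weights
    1/byse².  The multiplicative random-effects option inflates the se by
    max(1, residual SD) when instruments are heterogeneous.
    """
    if mri.nsnp < 2:
        raise ValueError("ivw requires >= 2 instruments; use wald_ratio")
    w = 1.0 / mri.byse ** 2
    denom = float(np.sum(w * mri.bx ** 2))
    beta = float(np.sum(w * mri.bx * mri.by)) / denom
    se = denom ** -0.5
    resid = (mri.by - beta * mri.bx) / mri.byse
    q = float(np.sum(resid ** 2))
    if random_effects:
        phi = max(1.0, math.sqrt(q / (mri.nsnp - 1)))
        se *= phi
    return _est("ivw", mri, beta, se, extras={"Q": q})


def _ratio_estimates(mri: MRInput) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument ratio estimates and their first-order variances."""
    ratios = mri.by / mri.bx
    var = mri.byse ** 2 / mri.bx ** 2
    return ratios, var


def _weighted_median_rows(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Row-wise weighted median (interpolated weighted empirical CDF at 0.5).

    ``ratios`` and ``weights`` are (B, n) matrices; returns a length-B
    vector.  Used both for the point estimate (B = 1) and for vectorized
    bootstrap / Monte-Carlo draws.
    """
    order = np.argsort(ratios, axis=1)
    r = np.take_along_axis(ratios, order, axis=1)
    w = np.take_along_axis(weights, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) - 0.5 * w
    out = np.empty(r.shape[0])
    for b in range(r.shape[0]):
        out[b] = np.interp(0.5, cum[b], r[b])
    return out


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    return float(_weighted_median_rows(ratios[None, :], weights[None, :])[0])


def _boot_draws(mri: MRInput, n_draws: int, seed: int, null_by: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    bx = rng.normal(mri.bx, mri.bxse, size=(n_draws, mri.nsnp))
    center = 0.0 if null_by else mri.by
    by = rng.normal(center, mri.byse, size=(n_draws, mri.nsnp))
    bx = np.where(bx == 0, 1e-12, bx)
    return bx, by


def _iqr_se(est: np.ndarray) -> float:
    """Bootstrap se as IQR/1.349: the plain SD is inflated when the
    re-estimates jump between ratio clusters (multi-modal draws), which
    makes the normal test badly conservative."""
    q75, q25 = np.percentile(est, [75, 25])
    spread = (q75 - q25) / 1.349
    if spread <= 0:
        spread = est.std(ddof=1)
    return float(max(spread, 1e-300))


def weighted_median(mri: MRInput, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the ratio estimates (50% breakdown point).

    Consistent when instruments carrying >= 50% of the weight are valid.
    Weights are the normalized inverse first-order variances of the ratios;
    the estimate interpolates the weighted empirical CDF at 0.5 and the se
    comes from a seeded parametric bootstrap.
    """
    if mri.nsnp < 3:
        raise ValueError("weighted_median requires >= 3 instruments")
    ratios, var = _ratio_estimates(mri)
    beta = _weighted_median_point(ratios, 1.0 / var)
    bx, by = _boot_draws(mri, n_boot, seed)
    r = by / bx
    w = bx ** 2 / mri.byse[None, :] ** 2
    se = _iqr_se(_weighted_median_rows(r, w))
    return _est("weighted_median", mri, beta, se)


def _mc_null_p(observed: float, null_estimates: np.ndarray) -> float:
    """Parametric Monte-Carlo test of H0: no causal effect (by ~ N(0, byse)).

    With a handful of instruments the analytic standard errors of the
    nonlinear estimators (robust regression, mode) are too unstable for a
    normal reference; resampling the null directly gives a test that is
    calibrated by construction.  Add-one correction keeps p in (0, 1].
    """
    hits = int(np.sum(np.abs(null_estimates) >= abs(observed)))
    return (hits + 1) / (null_estimates.size + 1)


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    s = np.std(ratios, ddof=1)
    mad = sps.median_abs_deviation(ratios, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    if spread == 0:
        spread = max(abs(ratios).max(), 1.0) * 1e-6
    h = factor * 0.9 * spread * ratios.size ** (-1 / 5)
    return max(h, 1e-12)


def _mode_bandwidth_rows(ratios: np.ndarray, factor: float) -> np.ndarray:
    s = np.std(ratios, axis=1, ddof=1)
    mad = sps.median_abs_deviation(ratios, axis=1, scale="normal")
    spread = np.where(mad > 0, np.minimum(s, mad), s)
    fallback = np.maximum(np.abs(ratios).max(axis=1), 1.0) * 1e-6
    spread = np.where(spread > 0, spread, fallback)
    h = factor * 0.9 * spread * ratios.shape[1] ** (-1 / 5)
    return np.maximum(h, 1e-12)


def _weighted_mode_rows(ratios: np.ndarray, weights: np.ndarray,
                        h: np.ndarray, grid_size: int = 512) -> np.ndarray:
    """Row-wise argmax of the weighted Gaussian-kernel ratio density."""
    lo = ratios.min(axis=1) - 3 * h
    hi = ratios.max(axis=1) + 3 * h
    t = np.linspace(0.0, 1.0, grid_size)
    grid = lo[:, None] + (hi - lo)[:, None] * t[None, :]
    z = (grid[:, :, None] - ratios[:, None, :]) / h[:, None, None]
    dens = (weights[:, None, :] * np.exp(-0.5 * z ** 2)).sum(axis=2)
    idx = np.argmax(dens, axis=1)
    return grid[np.arange(grid.shape[0]), idx]


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    return float(_weighted_mode_rows(ratios[None, :], weights[None, :],
                                     np.array([h]))[0])


def weighted_mode(mri: MRInput, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Mode of the kernel-smoothed, inverse-variance-weighted ratio density.

    Consistent when the largest group of instruments sharing a ratio is
    valid (the plurality-valid condition).  Bandwidth is
    ``bandwidth_factor`` × the MAD-based default 0.9·min(sd, mad)·n^(−1/5).
    The se is a seeded parametric bootstrap (IQR-scaled); significance
    comes from a seeded Monte-Carlo null test, because the normal
    approximation with the bootstrap se is badly conservative for the mode.
    """
    if mri.nsnp < 3:
        raise ValueError("weighted_mode requires >= 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    ratios, var = _ratio_estimates(mri)
    weights = (1.0 / var)
    weights = weights / weights.sum()
    h = _mode_bandwidth(ratios, bandwidth_factor)
    beta = _weighted_mode_point(ratios, weights, h)

    def batch(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
        r = by / bx
        w = bx ** 2 / mri.byse[None, :] ** 2
        w = w / w.sum(axis=1, keepdims=True)
        return _weighted_mode_rows(r, w, _mode_bandwidth_rows(r, bandwidth_factor))

    se = _iqr_se(batch(*_boot_draws(mri, n_boot, seed)))
    est = _est("weighted_mode", mri, beta, se)
    est.p = _mc_null_p(beta, batch(*_boot_draws(mri, n_boot, seed + 7,
                                                null_by=True)))
    return est


# ---------------------------------------------------------------------------
# Robust / weak-instrument estimators

def _tukey_w(u: np.ndarray) -> np.ndarray:
    out = np.zeros_like(u)
    inside = np.abs(u) < _TUKEY_C
    out[inside] = (1 - (u[inside] / _TUKEY_C) ** 2) ** 2
    return out


def _huber_w(u: np.ndarray) -> np.ndarray:
    au = np.maximum(np.abs(u), 1e-12)
    return np.minimum(1.0, _HUBER_K / au)


def _robust_fit(mri: MRInput, max_iter: int = 100, tol: float = 1e-10
                ) -> tuple[float, bool, str]:
    """Tukey-bisquare IRLS slope of by on bx through the origin (byse
    weights), median-of-ratios start, Huber fallback on non-convergence."""
    x = mri.bx / mri.byse
    y = mri.by / mri.byse

    def irls(weight_fn) -> tuple[float, bool]:
        beta = float(np.median(mri.by / mri.bx))
        for _ in range(max_iter):
            r = y - beta * x
            scale = sps.median_abs_deviation(r, scale="normal")
            if scale <= 0:
                scale = max(np.abs(r).max(), 1e-12)
            w = weight_fn(r / scale)
            denom = np.sum(w * x ** 2)
            if denom <= 0:
                return beta, False
            new = float(np.sum(w * x * y) / denom)
            if abs(new - beta) < tol * max(1.0, abs(beta)):
                return new, True
            beta = new
        return beta, False

    beta, ok = irls(_tukey_w)
    if ok:
        return beta, True, "tukey"
    beta, ok = irls(_huber_w)
    return beta, ok, "huber"


def _robust_fit_rows(bx: np.ndarray, by: np.ndarray, byse: np.ndarray,
                     n_iter: int = 50) -> np.ndarray:
    """Batched Tukey IRLS across draws: one slope per row of (bx, by)."""
    x = bx / byse[None, :]
    y = by / byse[None, :]
    beta = np.median(by / bx, axis=1)
    for _ in range(n_iter):
        r = y - beta[:, None] * x
        scale = sps.median_abs_deviation(r, axis=1, scale="normal")
        fallback = np.maximum(np.abs(r).max(axis=1), 1e-12)
        scale = np.where(scale > 0, scale, fallback)
        w = _tukey_w(r / scale[:, None])
        denom = (w * x ** 2).sum(axis=1)
        num = (w * x * y).sum(axis=1)
        beta = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), beta)
    return beta


def mr_robust(mri: MRInput, max_iter: int = 100, tol: float = 1e-10,
              n_null: int = 1000, seed: int = 0) -> MREstimate:
    """Robust IVW: Tukey-bisquare IRLS regression of by on bx through the
    origin with base weights 1/byse² (tuning constant 4.685,
    median-of-ratios start), falling back to the Huber loss on
    non-convergence.  The reported se is the robust sandwich floored by the
    model-based weighted-LS variance; significance comes from a seeded
    parametric Monte-Carlo null test, because with a handful of instruments
    the sandwich/normal combination is far too liberal.
    """
    if mri.nsnp < 3:
        raise ValueError("mr_robust requires >= 3 instruments")
    beta, ok, used = _robust_fit(mri, max_iter, tol)
    x = mri.bx / mri.byse
    y = mri.by / mri.byse
    r = y - beta * x
    scale = sps.median_abs_deviation(r, scale="normal")
    if scale <= 0:
        scale = max(np.abs(r).max(), 1e-12)
    u = r / scale
    w = _tukey_w(u) if used == "tukey" else _huber_w(u)
    if used == "tukey":
        inside = np.abs(u) < _TUKEY_C
        dpsi = np.zeros_like(u)
        dpsi[inside] = (1 - (u[inside] / _TUKEY_C) ** 2) * (1 - 5 * (u[inside] / _TUKEY_C) ** 2)
    else:
        dpsi = (np.abs(u) < _HUBER_K).astype(float)
    n = mri.nsnp
    num = scale ** 2 * np.sum((w * u) ** 2 * x ** 2)
    den = np.sum(dpsi * x ** 2)
    var_sand = num / den ** 2 * n / max(n - 1, 1) if den > 0 else 0.0
    denom_w = np.sum(w * x ** 2)
    var_model = (scale ** 2 / denom_w * n / max(n - 1, 1)
                 if denom_w > 0 else math.inf)
    var = max(var_sand, var_model)
    est = _est("mr_robust", mri, beta, math.sqrt(max(var, 1e-300)),
               converged=ok, extras={"loss": used, "weights": w})
    bx0, by0 = _boot_draws(mri, n_null, seed, null_by=True)
    est.p = _mc_null_p(beta, _robust_fit_rows(bx0, by0, mri.byse))
    return est


def debiased_ivw(mri: MRInput) -> MREstimate:
    """Debiased IVW: corrects the weak-instrument attenuation of IVW by
    subtracting the exposure sampling variance from the denominator,
    beta = Σ w·bx·by / Σ w·(bx² − bxse²) with w = 1/byse².
    """
    if mri.nsnp < 2:
        raise ValueError("debiased_ivw requires >= 2 instruments")
    w = 1.0 / mri.byse ** 2
    denom = float(np.sum(w * (mri.bx ** 2 - mri.bxse ** 2)))
    if denom <= 0:
        return MREstimate(method="debiased_ivw", beta=math.nan, se=math.nan,
                          p=1.0, nsnp=mri.nsnp, exposure_id=mri.exposure_id,
                          outcome_id=mri.outcome_id, converged=False,
                          extras={"reason": "instruments too weak: corrected "
                                            "denominator is non-positive"})
    beta = float(np.sum(w * mri.bx * mri.by)) / denom
    # variance with exposure-error correction (sandwich form)
    resid_var = mri.byse ** 2 + beta ** 2 * mri.bxse ** 2
    num = np.sum(w ** 2 * (mri.bx ** 2 * resid_var
                           + beta ** 2 * mri.bxse ** 2 * (mri.bx ** 2 + mri.bxse ** 2)))
    var = float(num) / denom ** 2
    return _est("debiased_ivw", mri, beta, math.sqrt(var))


def _huber_psi(t: np.ndarray) -> np.ndarray:
    return np.clip(t, -_HUBER_K, _HUBER_K)


def mr_raps(mri: MRInput, robust: bool = True, max_iter: int = 200) -> MREstimate:
    """MR-RAPS: profile-likelihood estimate with overdispersion.

    Standardized residual t_j(β, τ²) = (by_j − β·bx_j)/√(byse_j² + β²·bxse_j²
    + τ²); β and the overdispersion τ² ≥ 0 solve the (optionally
    Huber-robustified) estimating equations Σ ψ(t_j)·∂t_j/∂β = 0 and
    Σ [ψ(t_j)·t_j − δ] = 0 with δ = E[ψ(Z)Z] under normality.  The se comes
    from the observed information of the profile score.
    """
    if mri.nsnp < 3:
        raise ValueError("mr_raps requires >= 3 instruments")
    bx, bxse, by, byse = mri.bx, mri.bxse, mri.by, mri.byse

    if robust:
        psi = _huber_psi
        k = _HUBER_K
        # E[psi(Z)Z] = E[Z^2 1{|Z|<k}] + k E[|Z| 1{|Z|>=k}] = 2*Phi(k) - 1
        # (the tail terms cancel exactly for the Huber psi)
        delta = float(2 * sps.norm.cdf(k) - 1)
    else:
        psi = lambda t: t
        delta = 1.0

    def sigma2(beta: float, tau2: float) -> np.ndarray:
        return byse ** 2 + beta ** 2 * bxse ** 2 + tau2

    def score_beta(beta: float, tau2: float) -> float:
        s2 = sigma2(beta, tau2)
        t = (by - beta * bx) / np.sqrt(s2)
        # dt/dbeta = -bx/sqrt(s2) - t * beta*bxse^2/s2
        dt = -bx / np.sqrt(s2) - t * beta * bxse ** 2 / s2
        return float(np.sum(psi(t) * dt))

    def score_tau(beta: float, tau2: float) -> float:
        t = (by - beta * bx) / np.sqrt(sigma2(beta, tau2))
        return float(np.sum(psi(t) * t - delta))

    beta = float(np.sum(bx * by / byse ** 2) / np.sum(bx ** 2 / byse ** 2))
    tau2 = 0.0
    converged = False
    for _ in range(max_iter):
        # update tau2 for current beta (monotone decreasing in tau2)
        if score_tau(beta, 0.0) <= 0:
            new_tau2 = 0.0
        else:
            hi = 1.0
            while score_tau(beta, hi) > 0 and hi < 1e6:
                hi *= 4
            new_tau2 = optimize.brentq(lambda t2: score_tau(beta, t2), 0.0, hi,
                                       xtol=1e-12)
        # update beta by solving the beta-score
        lo, hi = beta - 1.0, beta + 1.0
        expand = 0
        while score_beta(lo, new_tau2) * score_beta(hi, new_tau2) > 0 and expand < 60:
            lo -= 2.0 ** expand * 0.5
            hi += 2.0 ** expand * 0.5
            expand += 1
        try:
            new_beta = optimize.brentq(lambda b: score_beta(b, new_tau2), lo, hi,
                                       xtol=1e-12)
        except ValueError:
            break
        if abs(new_beta - beta) < 1e-10 and abs(new_tau2 - tau2) < 1e-10:
            beta, tau2 = new_beta, new_tau2
            converged = True
            break
        beta, tau2 = new_beta, new_tau2

    # observed information of the beta-score (numerical), sandwich-corrected
    eps = 1e-6 * max(1.0, abs(beta))
    dscore = (score_beta(beta + eps, tau2) - score_beta(beta - eps, tau2)) / (2 * eps)
    s2 = sigma2(beta, tau2)
    t = (by - beta * bx) / np.sqrt(s2)
    dt = -bx / np.sqrt(s2) - t * beta * bxse ** 2 / s2
    bvar = float(np.sum((psi(t) * dt) ** 2))
    if dscore == 0:
        se = math.inf
    else:
        # df correction for the jointly estimated (beta, tau²)
        corr = mri.nsnp / max(mri.nsnp - 2, 1)
        se = math.sqrt(max(bvar / dscore ** 2 * corr, 1e-300))
    est = _est("mr_raps", mri, beta, se, converged=converged,
               extras={"tau2": tau2, "score": score_beta(beta, tau2)})
    # t reference with df = nsnp + 2: the profile-likelihood statistic is
    # noticeably heavy-tailed at a handful of instruments; this df holds the
    # nominal level across instrument counts 4-15 under the null model
    if math.isfinite(se) and se > 0:
        est.p = float(min(max(2 * sps.t.sf(abs(beta / se), df=mri.nsnp + 2),
                              1e-300), 1.0))
    return est


def mr_presso(mri: MRInput, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> MREstimate:
    """MR-PRESSO: parametric-resampling outlier detection plus corrected IVW.

    The global test compares the observed leave-one-out weighted residual
    sum of squares against ``n_sim`` draws simulated under no pleiotropy;
    per-instrument outlier p-values are Bonferroni-adjusted, flagged
    instruments are removed and the IVW estimate recomputed.  Requires four
    or more instruments.
    """
    if mri.nsnp < 4:
        raise ValueError("mr_presso needs four or more instruments")
    rng = np.random.default_rng(seed)
    n = mri.nsnp
    w = 1.0 / mri.byse ** 2

    def loo_beta(bx, by, w):
        num = np.sum(w * bx * by) - w * bx * by
        den = np.sum(w * bx ** 2) - w * bx ** 2
        return num / den

    beta_loo = loo_beta(mri.bx, mri.by, w)
    rss_obs_j = w * (mri.by - beta_loo * mri.bx) ** 2
    rss_obs = float(rss_obs_j.sum())

    # expected-value resampling under the no-pleiotropy model
    rss_sim_j = np.empty((n_sim, n))
    for s in range(n_sim):
        bx_s = rng.normal(mri.bx, mri.bxse)
        by_s = rng.normal(beta_loo * mri.bx, mri.byse)
        bl = loo_beta(bx_s, by_s, w)
        rss_sim_j[s] = w * (by_s - bl * bx_s) ** 2
    rss_sim = rss_sim_j.sum(axis=1)
    global_p = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    outlier_p = (np.sum(rss_sim_j >= rss_obs_j[None, :], axis=0) + 1) / (n_sim + 1)
    outlier_p_adj = np.minimum(outlier_p * n, 1.0)
    # outliers are only acted on when the global test detects pleiotropy
    if global_p < outlier_alpha:
        outliers = np.where(outlier_p_adj < outlier_alpha)[0]
    else:
        outliers = np.array([], dtype=int)

    keep = np.setdiff1d(np.arange(n), outliers)
    extras = {"global_p": global_p, "outlier_indices": outliers.tolist(),
              "outlier_p": outlier_p.tolist()}
    if keep.size < 2:
        ref = ivw(mri)
        return _est("mr_presso", mri, ref.beta, ref.se, converged=False,
                    extras={**extras, "reason": "too few instruments after "
                                                "outlier removal"})
    sub = MRInput(mri.bx[keep], mri.bxse[keep], mri.by[keep], mri.byse[keep],
                  exposure_id=mri.exposure_id, outcome_id=mri.outcome_id)
    corrected = ivw(sub) if sub.nsnp >= 2 else wald_ratio(sub)
    return _est("mr_presso", mri, corrected.beta, corrected.se,
                nsnp=sub.nsnp, extras=extras)


def cml_ma(mri: MRInput, max_iter: int = 200, tol: float = 1e-10,
           sample_size: float | None = None) -> MREstimate:
    """Constrained maximum likelihood with model averaging (cML-MA).

    For each K = 0..nsnp−2, exactly K instruments are allowed a free
    pleiotropy term: iteratively, given β, the K largest weighted residuals
    absorb their own residual and β is re-estimated from the rest.
    BIC(K) = −2·loglik + K·log(N) weights the models, w_K ∝ exp(−ΔBIC/2);
    the averaged β carries the within- plus between-model variance.

    N is the outcome GWAS sample size (``sample_size`` argument, falling
    back to ``mri.n_outcome``, then to 1e5 as a typical GWAS scale): BIC
    selection of the invalid-instrument count is only consistent when the
    penalty grows with the sample size behind the summary statistics, not
    with the instrument count — with K·log(nsnp) the largest of ~10 χ²
    residuals beats the penalty even when every instrument is valid.
    """
    if mri.nsnp < 3:
        raise ValueError("cml_ma requires >= 3 instruments")
    n = mri.nsnp
    big_n = sample_size or mri.n_outcome or 1e5
    w = 1.0 / mri.byse ** 2

    results = []
    for K in range(n - 1):
        beta = float(np.sum(w * mri.bx * mri.by) / np.sum(w * mri.bx ** 2))
        valid = np.ones(n, dtype=bool)
        ok = False
        for _ in range(max_iter):
            resid2 = w * (mri.by - beta * mri.bx) ** 2
            order = np.argsort(-resid2, kind="mergesort")
            invalid = order[:K]
            new_valid = np.ones(n, dtype=bool)
            new_valid[invalid] = False
            denom = np.sum(w[new_valid] * mri.bx[new_valid] ** 2)
            if denom <= 0:
                break
            new_beta = float(np.sum(w[new_valid] * mri.bx[new_valid] * mri.by[new_valid]) / denom)
            if abs(new_beta - beta) < tol * max(1.0, abs(beta)) and np.array_equal(new_valid, valid):
                beta, valid = new_beta, new_valid
                ok = True
                break
            beta, valid = new_beta, new_valid
        if not ok and K > 0:
            continue
        loglik = -0.5 * float(np.sum(w[valid] * (mri.by[valid] - beta * mri.bx[valid]) ** 2))
        bic = -2.0 * loglik + K * math.log(big_n)
        var_k = 1.0 / float(np.sum(w[valid] * mri.bx[valid] ** 2))
        results.append({"K": K, "beta": beta, "var": var_k, "bic": bic,
                        "invalid": np.where(~valid)[0].tolist()})

    if not results:
        raise RuntimeError("cml_ma failed to converge for every K")
    bics = np.array([r["bic"] for r in results])
    wts = np.exp(-(bics - bics.min()) / 2)
    wts /= wts.sum()
    betas = np.array([r["beta"] for r in results])
    vars_ = np.array([r["var"] for r in results])
    beta_ma = float(np.sum(wts * betas))
    var_ma = float(np.sum(wts * (vars_ + (betas - beta_ma) ** 2)))
    k_best = int(results[int(np.argmax(wts))]["K"])
    return _est("cml_ma", mri, beta_ma, math.sqrt(var_ma),
                extras={"model_weights": {r["K"]: float(t) for r, t in zip(results, wts)},
                        "k_best": k_best})


# ---------------------------------------------------------------------------
# Dispatchers and suite

def run_main_mr(mri: MRInput) -> MREstimate | None:
    """Main-analysis dispatcher: Wald ratio for one instrument, fixed-effect
    IVW for two or more, None (skip) for an empty set."""
    if mri is None or mri.nsnp == 0:
        return None
    if mri.nsnp == 1:
        est = wald_ratio(mri)
    else:
        est = ivw(mri)
    return est


WEAK_SUITE_METHODS = (
    "wald_ivw", "weighted_median", "weighted_mode", "mr_robust",
    "cml_ma", "mr_presso", "debiased_ivw", "mr_raps",
)

_METHOD_FLOORS = {"wald_ivw": 1, "weighted_median": 3, "weighted_mode": 3,
                  "mr_robust": 3, "cml_ma": 3, "mr_presso": 4,
                  "debiased_ivw": 2, "mr_raps": 3}


def run_weak_suite(mri: MRInput, n_boot: int = 1000, n_sim: int = 1000,
                   seed: int = 0) -> list[MREstimate]:
    """Run all applicable weak-instrument estimators on one pair.

    Methods whose instrument-count floor exceeds nsnp are skipped (with a
    single-instrument input only the Wald ratio runs).  The same base seed
    drives every resampling method so reruns are bit-identical.
    """
    out: list[MREstimate] = []
    for method in WEAK_SUITE_METHODS:
        if mri.nsnp < _METHOD_FLOORS[method]:
            continue
        try:
            if method == "wald_ivw":
                est = run_main_mr(mri)
                est.method = "wald_ivw"
            elif method == "weighted_median":
                est = weighted_median(mri, n_boot=n_boot, seed=seed)
            elif method == "weighted_mode":
                est = weighted_mode(mri, n_boot=n_boot, seed=seed + 1)
            elif method == "mr_robust":
                est = mr_robust(mri, n_null=n_sim, seed=seed + 3)
            elif method == "cml_ma":
                est = cml_ma(mri)
            elif method == "mr_presso":
                est = mr_presso(mri, n_sim=n_sim, seed=seed + 2)
            elif method == "debiased_ivw":
                est = debiased_ivw(mri)
            else:
                est = mr_raps(mri)
        except (ValueError, ZeroDivisionError, RuntimeError):
            continue
        out.append(est)
    return out


def estimates_to_frame(estimates: Sequence[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        if e is None:
            continue
        rows.append({
            "exposure_id": e.exposure_id, "outcome": e.outcome_id,
            "method": e.method, "nsnp": e.nsnp, "beta": e.beta, "se": e.se,
            "p": e.p, "OR": math.exp(e.beta) if math.isfinite(e.beta) else math.nan,
            "converged": e.converged,
        })
    return pd.DataFrame(rows, columns=["exposure_id", "outcome", "method",
                                       "nsnp", "beta", "se", "p", "OR",
                                       "converged"])


def add_fdr(table: pd.DataFrame, family: str = "method") -> pd.DataFrame:
    """Append BH q-values; the default family is per method across every
    exposure-outcome test of the run."""
    table = table.copy()
    table["q"] = np.nan
    mask = table["p"].notna() & table["converged"]
    if family == "method":
        for _, idx in table[mask].groupby("method").groups.items():
            table.loc[idx, "q"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    elif family == "all":
        table.loc[mask, "q"] = bh_fdr(table.loc[mask, "p"].to_numpy())
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    return table


def cross_method_validation(weak_table: pd.DataFrame,
                            main_table: pd.DataFrame | None = None,
                            q_threshold: float = 0.05) -> pd.DataFrame:
    """Per exposure-outcome pair: count of weak methods significant after
    FDR, validation flags at ≥1/≥2/≥5 methods, and the weak-only discovery
    flag (≥5 weak methods significant but not the main analysis)."""
    need = {"exposure_id", "outcome", "method", "q"}
    if not need <= set(weak_table.columns):
        raise ValueError(f"weak table must have columns {sorted(need)}")
    sig = weak_table.assign(sig=weak_table["q"] < q_threshold)
    counts = (sig.groupby(["exposure_id", "outcome"])
              .agg(n_methods=("method", "nunique"), n_significant=("sig", "sum"))
              .reset_index())
    counts["validated_ge1"] = counts["n_significant"] >= 1
    counts["validated_ge2"] = counts["n_significant"] >= 2
    counts["validated_ge5"] = counts["n_significant"] >= 5

    main_sig: dict[tuple, bool] = {}
    if main_table is not None and len(main_table):
        for row in main_table.itertuples(index=False):
            main_sig[(row.exposure_id, row.outcome)] = bool(row.q < q_threshold)
    counts["main_significant"] = [
        main_sig.get((r.exposure_id, r.outcome), False)
        for r in counts.itertuples(index=False)
    ]
    counts["weak_only_discovery"] = counts["validated_ge5"] & ~counts["main_significant"]
    return counts


def method_benchmark(weak_table: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Power/robustness comparison across methods.

    power_pct: % of a method's estimates passing the FDR cutoff.
    robustness_pct: % of its significant findings validated (q < cutoff) by
    ≥ 2 other methods on the same pair; NaN when the method has no
    significant findings.
    """
    tbl = weak_table.assign(sig=weak_table["q"] < q_threshold)
    sig_by_pair = (tbl[tbl["sig"]]
                   .groupby(["exposure_id", "outcome"])["method"]
                   .apply(set).to_dict())
    rows = []
    for method, grp in tbl.groupby("method"):
        n = len(grp)
        n_sig = int(grp["sig"].sum())
        validated = 0
        for r in grp[grp["sig"]].itertuples(index=False):
            others = sig_by_pair.get((r.exposure_id, r.outcome), set()) - {method}
            if len(others) >= 2:
                validated += 1
        rows.append({
            "method": method, "n_tests": n,
            "power_pct": 100.0 * n_sig / n if n else math.nan,
            "robustness_pct": 100.0 * validated / n_sig if n_sig else math.nan,
        })
    return pd.DataFrame(rows).sort_values("power_pct", ascending=False,
                                          ignore_index=True)
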