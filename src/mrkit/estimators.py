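"""Two-sample summary-data MR estimators.

Given L harmonized instruments with exposure effects gamma_j (se_gamma_j)
and outcome log-odds effects Gamma_j (se_Gamma_j), this module computes:

* per-SNP Wald ratios theta_j = Gamma_j / gamma_j with delta-method SEs,
* the inverse-variance-weighted (IVW) estimate — weighted regression of
  Gamma on gamma through the origin, equivalent to a fixed-effect
  meta-analysis of the ratios,
* MR-Egger regression — the same weighted regression with a free
  intercept, whose slope is robust to directional pleiotropy under the
  InSIDE assumption and whose intercept tests for it,
* the I2_GX statistic quantifying the regression-dilution attenuation of
  MR-Egger under NOME violations, and a SIMEX correction for it,
* the weighted-median estimator, consistent when at least half the weight
  comes from valid instruments.

All estimates are log odds ratios per 1-SD increment of the exposure and
are mirrored on the odds-ratio scale.  Standard errors use a
multiplicative residual-scale convention truncated below at 1 (never
narrower than the fixed-effect SE); ``residual_scale="fixed"`` forces the
fixed-effect scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .summary_io import HarmonizedInstrument

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio: outcome log-odds per SD of exposure."""

    snp_id: str
    theta: float
    se_theta: float
    weight: float  # normalized inverse-variance weight; sums to 1 over a set


@dataclass
class MRResult:
    """A causal-effect estimate on the log-OR scale with its OR mirror."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_ci: Optional[tuple[float, float]] = None
    intercept_p: Optional[float] = None
    i2_gx: Optional[float] = None
    seed: Optional[int] = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def intercept_odds(self) -> Optional[float]:
        return None if self.intercept is None else float(np.exp(self.intercept))

    @property
    def intercept_odds_ci(self) -> Optional[tuple[float, float]]:
        if self.intercept_ci is None:
            return None
        return float(np.exp(self.intercept_ci[0])), float(np.exp(self.intercept_ci[1]))


@dataclass
class SimexConfig:
    """Settings for the SIMEX dilution correction of MR-Egger.

    ``lambdas`` is the grid of added-noise variance multiples; for each, B
    pseudo-datasets perturb gamma with N(0, lambda * se_gamma^2) noise.  A
    quadratic in lambda through the per-lambda mean estimates (including
    the lambda=0 naive fit) is extrapolated to lambda = -1.
    """

    lambdas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    reps_per_lambda: int = 1000
    extrapolant: str = "quadratic"
    seed: Optional[int] = None

    def validate(self) -> None:
        if not self.lambdas or any(l <= 0 for l in self.lambdas):
            raise ValueError("SIMEX lambdas must be positive")
        if list(self.lambdas) != sorted(self.lambdas):
            raise ValueError("SIMEX lambdas must be increasing")
        if self.reps_per_lambda < 1:
            raise ValueError("reps_per_lambda must be >= 1")
        if self.extrapolant != "quadratic":
            raise ValueError(f"unsupported extrapolant {self.extrapolant!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _arrays(instruments: Sequence[HarmonizedInstrument]):
    g = np.array([i.gamma for i in instruments], dtype=float)
    sg = np.array([i.se_gamma for i in instruments], dtype=float)
    G = np.array([i.Gamma for i in instruments], dtype=float)
    sG = np.array([i.se_Gamma for i in instruments], dtype=float)
    ids = [i.snp_id for i in instruments]
    return ids, g, sg, G, sG


def orient_positive(g, sg, G, sG):
    """Jointly flip (gamma, Gamma) signs so that all gamma >= 0.

    MR-Egger is not invariant to the allele coding of individual SNPs; the
    conventional resolution is to express every instrument on its
    exposure-increasing allele before fitting.
    """
    s = np.where(g < 0, -1.0, 1.0)
    return g * s, sg, G * s, sG


def _ci_p(est: float, se: float, quantile: float = Z975, df: Optional[int] = None):
    if df is None:
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else float("nan")
    else:
        p = 2.0 * stats.t.sf(abs(est / se), df) if se > 0 else float("nan")
    return est - quantile * se, est + quantile * se, float(p)


# ---------------------------------------------------------------------------
# Wald ratios
# ---------------------------------------------------------------------------

def ratio_estimates(instruments: Sequence[HarmonizedInstrument],
                    se_order: str = "first") -> list[RatioEstimate]:
    """Per-SNP Wald ratios with delta-method standard errors.

    ``se_order="first"`` gives se = se_Gamma / |gamma| (the convention
    under which IVW is exactly the fixed-effect meta-analysis of the
    ratios); ``"second"`` adds the gamma-uncertainty term
    sqrt(se_Gamma^2/gamma^2 + Gamma^2 se_gamma^2 / gamma^4) and is the
    default input to the heterogeneity and meta-regression stages.
    """
    if se_order not in ("first", "second"):
        raise ValueError(f"se_order must be 'first' or 'second', got {se_order!r}")
    ids, g, sg, G, sG = _arrays(instruments)
    zero = [ids[j] for j in np.flatnonzero(g == 0)]
    if zero:
        raise ValueError(f"gamma = 0 for SNP(s): {', '.join(zero)}; ratio undefined")
    theta = G / g
    if se_order == "first":
        se = sG / np.abs(g)
    else:
        se = np.sqrt(sG ** 2 / g ** 2 + G ** 2 * sg ** 2 / g ** 4)
    w = se ** -2.0
    w = w / w.sum()
    return [RatioEstimate(ids[j], float(theta[j]), float(se[j]), float(w[j]))
            for j in range(len(ids))]


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(instruments: Sequence[HarmonizedInstrument],
        residual_scale: str = "multiplicative") -> MRResult:
    """Inverse-variance-weighted estimate.

    Weighted least squares of Gamma on gamma through the origin with
    weights 1/se_Gamma^2; the slope equals sum(w g G) / sum(w g^2), the
    fixed-effect meta-analysis of first-order-weighted Wald ratios.
    """
    n = len(instruments)
    if n < 1:
        raise ValueError("IVW needs at least one instrument")
    ids, g, sg, G, sG = _arrays(instruments)
    if np.all(g == 0):
        raise ValueError("all gamma are zero; IVW undefined")
    w = sG ** -2.0
    swx2 = float(np.sum(w * g * g))
    est = float(np.sum(w * g * G) / swx2)
    se_unit = swx2 ** -0.5
    if n >= 2:
        sigma2 = float(np.sum(w * (G - est * g) ** 2) / (n - 1))
    else:
        sigma2 = 1.0
    scale = 1.0 if residual_scale == "fixed" else max(1.0, sigma2)
    se = se_unit * np.sqrt(scale)
    lo, hi, p = _ci_p(est, se)
    return MRResult("IVW", est, float(se), lo, hi, p, n_snps=n)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def _egger_fit(g, G, w, residual_scale="multiplicative"):
    """Weighted normal equations for Gamma = a + b*gamma.

    Returns slope, intercept, their SEs and the residual scale used.
    """
    sw = w.sum()
    swx = float(np.sum(w * g))
    swx2 = float(np.sum(w * g * g))
    swy = float(np.sum(w * G))
    swxy = float(np.sum(w * g * G))
    det = sw * swx2 - swx ** 2
    if det <= 0 or not np.isfinite(det):
        raise ValueError("singular design: no spread in gamma")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    n = len(g)
    resid = G - intercept - slope * g
    sigma2 = float(np.sum(w * resid ** 2) / (n - 2)) if n > 2 else 1.0
    scale = 1.0 if residual_scale == "fixed" else max(1.0, sigma2)
    se_slope = np.sqrt(scale * sw / det)
    se_intercept = np.sqrt(scale * swx2 / det)
    return slope, intercept, float(se_slope), float(se_intercept), scale


def mr_egger(instruments: Sequence[HarmonizedInstrument],
             residual_scale: str = "multiplicative",
             ci: str = "gaussian") -> MRResult:
    """MR-Egger regression: weighted regression of Gamma on gamma with a
    free intercept (weights 1/se_Gamma^2), after orienting all instruments
    to gamma >= 0.

    The slope estimates the causal effect under InSIDE; the intercept
    estimates the average directional pleiotropic effect and is also
    reported exponentiated (odds scale).  ``ci="t"`` uses t(n-2) quantiles
    instead of Gaussian ones.
    """
    n = len(instruments)
    if n < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {n}")
    ids, g, sg, G, sG = _arrays(instruments)
    g, sg, G, sG = orient_positive(g, sg, G, sG)
    w = sG ** -2.0
    slope, intercept, se_s, se_i, _ = _egger_fit(g, G, w, residual_scale)
    if ci == "t":
        q = float(stats.t.ppf(0.975, n - 2))
        df = n - 2
    elif ci == "gaussian":
        q, df = Z975, None
    else:
        raise ValueError(f"ci must be 'gaussian' or 't', got {ci!r}")
    lo, hi, p = _ci_p(slope, se_s, q, df)
    ilo, ihi, ip = _ci_p(intercept, se_i, q, df)
    return MRResult(
        "Egger", float(slope), se_s, lo, hi, p, n_snps=n,
        intercept=float(intercept), intercept_se=se_i,
        intercept_ci=(ilo, ihi), intercept_p=ip,
        i2_gx=i2_gx(instruments),
    )


def i2_gx(instruments: Sequence[HarmonizedInstrument]) -> float:
    """I2_GX: expected regression dilution of MR-Egger under NOME violation.

    Q_GX = sum_j (gamma_j - gbar)^2 / se_gamma_j^2 with gbar the
    inverse-variance-weighted mean of the (oriented) gamma; the statistic
    is max(0, (Q_GX - (L-1)) / Q_GX).  Values near 1 mean negligible
    dilution; 1 - I2_GX approximates the proportional attenuation.
    """
    if len(instruments) < 2:
        raise ValueError("I2_GX needs >= 2 instruments")
    _, g, sg, G, sG = _arrays(instruments)
    g, sg, _, _ = orient_positive(g, sg, G, sG)
    if np.all(sg == 0):
        # no measurement error in gamma: the no-dilution limit
        return 1.0 if np.ptp(g) > 0 else 0.0
    wg = sg ** -2.0
    gbar = float(np.sum(wg * g) / wg.sum())
    q_gx = float(np.sum((g - gbar) ** 2 * wg))
    if q_gx == 0.0:
        return 0.0
    return max(0.0, (q_gx - (len(g) - 1)) / q_gx)


# ---------------------------------------------------------------------------
# SIMEX-corrected MR-Egger
# ---------------------------------------------------------------------------

def simex_egger(instruments: Sequence[HarmonizedInstrument],
                config: Optional[SimexConfig] = None,
                residual_scale: str = "multiplicative") -> MRResult:
    """Simulation-extrapolation correction of MR-Egger regression dilution.

    For each lambda in the grid, ``reps_per_lambda`` pseudo-datasets add
    N(0, lambda * se_gamma^2) noise to gamma and MR-Egger is refitted; the
    per-lambda mean slope/intercept (with the lambda=0 naive fit) are
    extrapolated quadratically to lambda = -1, the hypothetical
    error-free state.  Variances follow the standard SIMEX estimate:
    s^2(lambda) = mean model variance - between-rep variance, extrapolated
    the same way and floored at a small positive value.
    """
    cfg = config or SimexConfig()
    cfg.validate()
    n = len(instruments)
    if n < 3:
        raise ValueError(f"SIMEX MR-Egger needs >= 3 instruments, got {n}")
    naive = mr_egger(instruments, residual_scale=residual_scale)
    _, g, sg, G, sG = _arrays(instruments)
    g, sg, G, sG = orient_positive(g, sg, G, sG)
    if np.all(sg == 0):
        # Nothing to simulate: measurement error in gamma is absent and the
        # naive fit is already the error-free fit.
        out = MRResult("EggerSIMEX", naive.estimate, naive.se, naive.ci_low,
                       naive.ci_high, naive.p, n_snps=n,
                       intercept=naive.intercept, intercept_se=naive.intercept_se,
                       intercept_ci=naive.intercept_ci, intercept_p=naive.intercept_p,
                       i2_gx=naive.i2_gx, seed=cfg.seed)
        return out

    rng = np.random.default_rng(cfg.seed)
    w = sG ** -2.0
    B = cfg.reps_per_lambda
    lams = [0.0]
    slopes = [naive.estimate]
    intercepts = [naive.intercept]
    var_slopes = [naive.se ** 2]
    var_intercepts = [naive.intercept_se ** 2]
    for lam in cfg.lambdas:
        noise = rng.standard_normal((B, len(g))) * (np.sqrt(lam) * sg)
        gs = g + noise  # (B, L)
        sw = w.sum()
        swx = gs @ w
        swx2 = (gs * gs) @ w
        swy = float(np.sum(w * G))
        swxy = gs @ (w * G)
        det = sw * swx2 - swx ** 2
        slope_b = (sw * swxy - swx * swy) / det
        int_b = (swx2 * swy - swx * swxy) / det
        resid = G[None, :] - int_b[:, None] - slope_b[:, None] * gs
        sigma2 = (resid ** 2) @ w / (len(g) - 2)
        scale = np.ones(B) if residual_scale == "fixed" else np.maximum(1.0, sigma2)
        vs_b = scale * sw / det
        vi_b = scale * swx2 / det
        bad = ~(np.isfinite(slope_b) & np.isfinite(int_b))
        if bad.mean() > 0.10:
            raise RuntimeError(
                f"SIMEX: {bad.mean():.0%} of pseudo-datasets failed to fit at "
                f"lambda={lam}; increase reps_per_lambda or reduce max lambda")
        ok = ~bad
        lams.append(lam)
        slopes.append(float(slope_b[ok].mean()))
        intercepts.append(float(int_b[ok].mean()))
        if ok.sum() > 1:
            vs = float(vs_b[ok].mean()) - float(np.var(slope_b[ok], ddof=1))
            vi = float(vi_b[ok].mean()) - float(np.var(int_b[ok], ddof=1))
        else:
            vs = float(vs_b[ok].mean())
            vi = float(vi_b[ok].mean())
        var_slopes.append(max(0.0, vs))
        var_intercepts.append(max(0.0, vi))

    lams_a = np.asarray(lams)

    def _extrapolate(values):
        coef = np.polyfit(lams_a, np.asarray(values), 2)
        return float(np.polyval(coef, -1.0))

    est = _extrapolate(slopes)
    icept = _extrapolate(intercepts)
    floor = 1e-3 * var_slopes[0]
    var_est = max(_extrapolate(var_slopes), floor)
    var_icept = max(_extrapolate(var_intercepts), 1e-3 * var_intercepts[0])
    se = float(np.sqrt(var_est))
    se_i = float(np.sqrt(var_icept))
    lo, hi, p = _ci_p(est, se)
    ilo, ihi, ip = _ci_p(icept, se_i)
    return MRResult("EggerSIMEX", est, se, lo, hi, p, n_snps=n,
                    intercept=icept, intercept_se=se_i,
                    intercept_ci=(ilo, ihi), intercept_p=ip,
                    i2_gx=naive.i2_gx, seed=cfg.seed)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_value(theta: np.ndarray, w: np.ndarray,
                           ids: Optional[Sequence[str]] = None) -> float:
    """Weighted median by linear interpolation of the cumulative weights.

    Ratios are ordered (stable tie-break by snp_id when given), weights
    normalized, and the cumulative positions p_j = cumsum(w)_j - w_j/2
    bracket 0.5; the estimate interpolates theta between the bracketing
    order statistics.
    """
    if ids is not None:
        order = np.lexsort((np.asarray(ids, dtype=object), theta))
    else:
        order = np.argsort(theta, kind="stable")
    t = theta[order]
    ww = w[order] / w[order].sum()
    p = np.cumsum(ww) - ww / 2.0
    if 0.5 <= p[0]:
        return float(t[0])
    if 0.5 >= p[-1]:
        return float(t[-1])
    k = int(np.searchsorted(p, 0.5, side="right")) - 1
    frac = (0.5 - p[k]) / (p[k + 1] - p[k])
    return float(t[k] + frac * (t[k + 1] - t[k]))


def weighted_median_point(instruments: Sequence[HarmonizedInstrument]) -> float:
    """Weighted-median point estimate only (no bootstrap SE)."""
    ids, g, sg, G, sG = _arrays(instruments)
    if np.any(g == 0):
        raise ValueError("gamma = 0 present; ratios undefined")
    theta = G / g
    w = (np.abs(g) / sG) ** 2
    return _weighted_median_value(theta, w, ids)


def weighted_median(instruments: Sequence[HarmonizedInstrument],
                    n_boot: int = 1000,
                    seed: Optional[int] = None) -> MRResult:
    """Weighted-median causal estimate with a parametric-bootstrap SE.

    Consistent when instruments carrying at least 50% of the
    inverse-variance weight are valid, regardless of the pleiotropy
    pattern among the rest.  The SE is the standard deviation of the
    estimate over ``n_boot`` resamples drawing gamma* and Gamma* from
    Gaussians centred at the point estimates.
    """
    n = len(instruments)
    if n < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {n}")
    if n_boot < 100:
        import warnings
        warnings.warn(f"n_boot={n_boot} < 100 gives an unstable bootstrap SE")
    ids, g, sg, G, sG = _arrays(instruments)
    if np.any(g == 0):
        raise ValueError("gamma = 0 present; ratios undefined")
    theta = G / g
    w = (np.abs(g) / sG) ** 2  # 1 / first-order ratio variance
    est = _weighted_median_value(theta, w, ids)

    rng = np.random.default_rng(seed)
    gb = g + rng.standard_normal((n_boot, n)) * sg
    Gb = G + rng.standard_normal((n_boot, n)) * sG
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = Gb[b] / gb[b]
        wb = (gb[b] / sG) ** 2
        boots[b] = _weighted_median_value(tb, wb)
    se = float(np.std(boots, ddof=1))
    lo, hi, p = _ci_p(est, se)
    return MRResult("WeightedMedian", est, se, lo, hi, p, n_snps=n, seed=seed)
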