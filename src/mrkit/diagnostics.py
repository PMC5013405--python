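"""Influence, heterogeneity and sample-overlap diagnostics.

Three sensitivity checks around the core estimators:

* :func:`influence_tests` — per-SNP externally studentized residuals and
  Cook's distances under both the IVW (through-origin) and MR-Egger
  (with-intercept) weighted fits; a SNP is flagged influential if any of
  the four tests has p < 0.05.
* :func:`heterogeneity` — Cochran's Q, Higgins' I2 and tau^2 over the
  per-SNP Wald ratios; between-instrument heterogeneity corresponds to
  horizontal pleiotropy in the MR context.
* :func:`overlap_tetrachoric` — indirect sample-overlap check: per-SNP
  association Z-statistics from the two GWAS are truncated at zero and
  the tetrachoric correlation of the resulting 2x2 table estimated by
  bivariate-normal maximum likelihood.  Near-zero values argue against
  material overlap between the exposure and outcome samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimators import RatioEstimate, _arrays, orient_positive
from .meta_regression import tau2_dl, tau2_reml

INFLUENCE_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Influence
# ---------------------------------------------------------------------------

@dataclass
class InfluenceReport:
    """Per-SNP influence statistics under the IVW and Egger weighted fits.

    ``table`` columns: snp_id, stud_resid_{ivw,egger}, cooks_{ivw,egger},
    the four p-values, and the ``influential`` union flag.  ``df`` records
    the reference-distribution degrees of freedom actually used.
    """

    table: pd.DataFrame
    df: dict[str, object]

    @property
    def influential_snps(self) -> set[str]:
        return set(self.table.loc[self.table["influential"], "snp_id"])


def _weighted_influence(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Externally studentized residuals and Cook's distances of a WLS fit.

    Computed on the sqrt(w)-transformed design, where the weighted fit is
    ordinary least squares.
    """
    sw = np.sqrt(w)
    Xs = X * sw[:, None]
    ys = y * sw
    n, p = Xs.shape
    XtX_inv = np.linalg.inv(Xs.T @ Xs)
    H = Xs @ XtX_inv @ Xs.T
    h = np.clip(np.diag(H), 0.0, 1.0 - 1e-12)
    e = ys - Xs @ (XtX_inv @ (Xs.T @ ys))
    s2 = float(np.sum(e * e) / (n - p))
    # leave-one-out residual variance
    s2_i = ((n - p) * s2 - e * e / (1.0 - h)) / (n - p - 1)
    s2_i = np.maximum(s2_i, 1e-300)
    t_ext = e / np.sqrt(s2_i * (1.0 - h))
    cooks = e * e * h / (p * s2 * (1.0 - h) ** 2)
    return t_ext, cooks


def influence_tests(instruments: Sequence, df_convention: str = "stated") -> InfluenceReport:
    """Classify instruments as influential under IVW and MR-Egger fits.

    P-values come from Student's t with n-2 df for studentized residuals
    (two-sided) and from the upper tail of F(1, n-1) for IVW / F(1, n-2)
    for Egger for Cook's distance.  ``df_convention="conventional"``
    switches the Egger studentized-residual df to the textbook n-3
    (= n - parameters - 1); the default follows the stated n-2 for both
    models.  A SNP is influential iff any of the four p-values < 0.05.
    """
    n = len(instruments)
    if n < 4:
        raise ValueError(f"influence tests need >= 4 instruments, got {n}")
    if df_convention not in ("stated", "conventional"):
        raise ValueError("df_convention must be 'stated' or 'conventional'")
    ids, g, sg, G, sG = _arrays(instruments)
    g, sg, G, sG = orient_positive(g, sg, G, sG)
    w = sG ** -2.0

    t_ivw, d_ivw = _weighted_influence(G, g[:, None], w)
    X_egger = np.column_stack([np.ones(n), g])
    t_egg, d_egg = _weighted_influence(G, X_egger, w)

    df_t_ivw = n - 2
    df_t_egg = n - 2 if df_convention == "stated" else n - 3
    p_t_ivw = 2.0 * stats.t.sf(np.abs(t_ivw), df_t_ivw)
    p_t_egg = 2.0 * stats.t.sf(np.abs(t_egg), df_t_egg)
    p_d_ivw = stats.f.sf(d_ivw, 1, n - 1)
    p_d_egg = stats.f.sf(d_egg, 1, n - 2)

    influential = ((p_t_ivw < INFLUENCE_ALPHA) | (p_t_egg < INFLUENCE_ALPHA)
                   | (p_d_ivw < INFLUENCE_ALPHA) | (p_d_egg < INFLUENCE_ALPHA))
    table = pd.DataFrame({
        "snp_id": ids,
        "stud_resid_ivw": t_ivw, "p_stud_resid_ivw": p_t_ivw,
        "stud_resid_egger": t_egg, "p_stud_resid_egger": p_t_egg,
        "cooks_d_ivw": d_ivw, "p_cooks_d_ivw": p_d_ivw,
        "cooks_d_egger": d_egg, "p_cooks_d_egger": p_d_egg,
        "influential": influential,
    })
    return InfluenceReport(table=table, df={
        "stud_resid_ivw": df_t_ivw, "stud_resid_egger": df_t_egg,
        "cooks_d_ivw": (1, n - 1), "cooks_d_egger": (1, n - 2),
        "convention": df_convention,
    })


# ---------------------------------------------------------------------------
# Heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityReport:
    Q: float
    df: int
    q_p: float
    i2_higgins: float       # max(0, (Q - df)/Q)
    tau2: float
    tau2_estimator: str
    i2_model: float         # tau2 / (tau2 + typical sampling variance)


def heterogeneity(ratios: Sequence[RatioEstimate],
                  tau2_estimator: str = "REML") -> HeterogeneityReport:
    """Between-instrument heterogeneity of the Wald ratios.

    Q uses fixed-effect inverse-variance weights; I2 is reported both as
    Higgins' Q-based statistic and as the tau^2-based model summary
    tau^2/(tau^2 + s~^2) with s~^2 the typical sampling variance — random
    -effects software commonly prints the latter.
    """
    if len(ratios) < 2:
        raise ValueError("heterogeneity needs >= 2 ratios")
    theta = np.array([r.theta for r in ratios], dtype=float)
    se = np.array([r.se_theta for r in ratios], dtype=float)
    if np.any(se <= 0):
        raise ValueError("ratio standard errors must be positive")
    w = se ** -2.0
    mean_w = float(np.sum(w * theta) / w.sum())
    Q = float(np.sum(w * (theta - mean_w) ** 2))
    df = len(ratios) - 1
    q_p = float(stats.chi2.sf(Q, df))
    i2_h = max(0.0, (Q - df) / Q) if Q > 0 else 0.0

    X = np.ones((len(ratios), 1))
    v = se ** 2
    tau2 = tau2_reml(theta, v, X) if tau2_estimator == "REML" else tau2_dl(theta, v, X)
    s_typ = (df) / (w.sum() - float(np.sum(w ** 2)) / w.sum())
    i2_m = tau2 / (tau2 + s_typ) if (tau2 + s_typ) > 0 else 0.0
    return HeterogeneityReport(Q=Q, df=df, q_p=q_p, i2_higgins=i2_h,
                               tau2=tau2, tau2_estimator=tau2_estimator,
                               i2_model=i2_m)


# ---------------------------------------------------------------------------
# Sample-overlap diagnostic
# ---------------------------------------------------------------------------

@dataclass
class OverlapDiagnostic:
    n_snps_compared: int
    n11: int   # Z_a > 0 and Z_b > 0
    n10: int   # Z_a > 0, Z_b <= 0
    n01: int
    n00: int
    tetrachoric_r: float
    method: str = "ml"

    def write(self, path) -> None:
        """Key-value text block with the table counts and the correlation."""
        with open(path, "w") as fh:
            fh.write(f"n_snps_compared\t{self.n_snps_compared}\n")
            fh.write(f"n11\t{self.n11}\nn10\t{self.n10}\n")
            fh.write(f"n01\t{self.n01}\nn00\t{self.n00}\n")
            fh.write(f"tetrachoric_r\t{self.tetrachoric_r:.6g}\n")
            fh.write(f"method\t{self.method}\n")


def _tetrachoric_ml(n11, n10, n01, n00) -> float:
    counts = np.array([n00, n01, n10, n11], dtype=float)
    if 0.0 in counts:
        counts = counts + 0.5
    n = counts.sum()
    # thresholds from the margins (their ML estimates)
    p_a0 = (counts[0] + counts[1]) / n   # P(Z_a <= 0)
    p_b0 = (counts[0] + counts[2]) / n
    t1 = stats.norm.ppf(p_a0)
    t2 = stats.norm.ppf(p_b0)

    def nll(rho):
        p00 = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        p00 = min(max(p00, 1e-12), 1 - 1e-12)
        p01 = max(stats.norm.cdf(t1) - p00, 1e-12)
        p10 = max(stats.norm.cdf(t2) - p00, 1e-12)
        p11 = max(1.0 - p00 - p01 - p10, 1e-12)
        probs = np.array([p00, p01, p10, p11])
        return -float(counts @ np.log(probs))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                                   options={"xatol": 1e-6})
    return float(res.x)


def _tetrachoric_cosine(n11, n10, n01, n00) -> float:
    a, b, c, d = float(n11), float(n10), float(n01), float(n00)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.cos(np.pi / (1.0 + np.sqrt(a * d / (b * c)))))


def overlap_tetrachoric(z_a: np.ndarray, z_b: np.ndarray,
                        method: str = "ml") -> OverlapDiagnostic:
    """Tetrachoric correlation of sign-truncated Z-statistics.

    Each Z is truncated to 1 if Z > 0 else 0; the 2x2 table of the two
    truncated vectors is fitted with a latent bivariate normal by maximum
    likelihood (``method="ml"``) or the cosine approximation
    ``cos(pi / (1 + sqrt(OR)))`` (``method="cosine"``).  A 0.5 continuity
    correction is applied when any cell is empty.  Under no sample
    overlap and a mostly-null genome, r is expected to be near zero.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if z_a.shape != z_b.shape or z_a.ndim != 1:
        raise ValueError("z_a and z_b must be equal-length 1-D vectors")
    a = (z_a > 0).astype(int)
    b = (z_b > 0).astype(int)
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError("all Z-statistics fall in one category for one "
                         "vector; tetrachoric correlation undefined")
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    if method == "ml":
        r = _tetrachoric_ml(n11, n10, n01, n00)
    elif method == "cosine":
        r = _tetrachoric_cosine(n11, n10, n01, n00)
    else:
        raise ValueError("method must be 'ml' or 'cosine'")
    return OverlapDiagnostic(n_snps_compared=len(a), n11=n11, n10=n10,
                             n01=n01, n00=n00, tetrachoric_r=r, method=method)
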