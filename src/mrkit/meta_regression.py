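"""Random-effects meta-regression of per-SNP Wald ratios on moderators.

Between-instrument heterogeneity of the Wald ratios corresponds to
horizontal pleiotropy in the MR context.  This module quantifies how much
of it is explained by binary moderators (influence status, biological
category membership) using the additive random-effects model

    theta_j ~ N(x_j' beta, se_j^2 + tau^2),

with tau^2 estimated by REML (default) or the DerSimonian-Laird moment
estimator, and a forward-selection procedure that adds category
indicators one at a time by largest residual-tau^2 reduction until no
candidate's moderator test reaches p < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimators import RatioEstimate


class CollinearModeratorsError(ValueError):
    pass


@dataclass
class MetaRegressionResult:
    moderators: list[str]
    tau2_null: float
    tau2_residual: float
    adjusted_r2: float          # max(0, (tau2_null - tau2_residual) / tau2_null)
    residual_i2: float          # tau2_res / (tau2_res + typical sampling variance)
    qm: float
    qm_df: int
    qm_p: float
    qe: float
    qe_df: int
    qe_p: float
    tau2_estimator: str = "REML"
    coef: Optional[pd.Series] = None
    coef_se: Optional[pd.Series] = None


@dataclass
class ForwardSelectionResult:
    selected: list[str]
    trace: pd.DataFrame     # step, candidate, tau2_residual, adjusted_r2, qm_p, retained
    steps: list[MetaRegressionResult] = field(default_factory=list)


# ---------------------------------------------------------------------------
# tau^2 estimation
# ---------------------------------------------------------------------------

def _wls(y, X, weights):
    W = weights
    XtW = X.T * W
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ y)
    return beta, cov


def _reml_nll(tau2, y, v, X):
    V = v + tau2
    W = 1.0 / V
    XtWX = (X.T * W) @ X
    beta = np.linalg.solve(XtWX, (X.T * W) @ y)
    r = y - X @ beta
    _, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * (np.sum(np.log(V)) + logdet + np.sum(W * r * r))


def tau2_reml(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """REML estimate of the between-instrument variance, by bounded
    scalar minimization of the restricted negative log-likelihood."""
    upper = max(10.0 * float(np.var(y)), 10.0 * float(np.max(v)), 1e-6)
    res = optimize.minimize_scalar(
        _reml_nll, bounds=(0.0, upper), args=(y, v, X),
        method="bounded", options={"xatol": 1e-10})
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on 0; snap when the
    # boundary is at least as good
    if _reml_nll(0.0, y, v, X) <= res.fun + 1e-12:
        tau2 = 0.0
    return max(0.0, tau2)


def tau2_dl(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """DerSimonian-Laird moment estimator, generalized to moderators:
    tau2 = max(0, (QE - (k - p)) / tr(P)) with P the fixed-weights
    residual-projection matrix."""
    w = 1.0 / v
    beta, _ = _wls(y, X, w)
    r = y - X @ beta
    qe = float(np.sum(w * r * r))
    k, p = X.shape
    Wm = np.diag(w)
    XtWX_inv = np.linalg.inv(X.T @ Wm @ X)
    P = Wm - Wm @ X @ XtWX_inv @ X.T @ Wm
    denom = float(np.trace(P))
    return max(0.0, (qe - (k - p)) / denom) if denom > 0 else 0.0


_TAU2 = {"REML": tau2_reml, "DL": tau2_dl}


def _typical_sampling_variance(v: np.ndarray, X: np.ndarray) -> float:
    """Higgins-Thompson 'typical' within-study variance, (k - p) / tr(P)."""
    w = 1.0 / v
    k, p = X.shape
    Wm = np.diag(w)
    XtWX_inv = np.linalg.inv(X.T @ Wm @ X)
    P = Wm - Wm @ X @ XtWX_inv @ X.T @ Wm
    tr = float(np.trace(P))
    return (k - p) / tr if tr > 0 else float("nan")


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _check_moderators(M: pd.DataFrame, n: int) -> None:
    vals = M.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        bad = [c for c in M.columns
               if not np.isin(M[c].to_numpy(dtype=float), (0.0, 1.0)).all()]
        raise ValueError(f"moderator column(s) not binary 0/1: {', '.join(bad)}")
    X = np.column_stack([np.ones(n), vals])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns implicated: those whose removal restores full rank
        guilty = []
        for j, c in enumerate(M.columns):
            Xr = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(Xr) == Xr.shape[1]:
                guilty.append(c)
        raise CollinearModeratorsError(
            f"collinear moderator column(s): {', '.join(guilty) or 'unidentified'}")


def re_meta_regression(ratios: Sequence[RatioEstimate],
                       moderators: Optional[pd.DataFrame] = None,
                       tau2_estimator: str = "REML") -> MetaRegressionResult:
    """Fit the additive random-effects meta-regression.

    ``moderators`` is an indicator DataFrame (rows aligned with
    ``ratios``, columns labelled); with no moderators the model reduces
    to a plain random-effects meta-analysis and adjusted R^2 is 0 by
    definition.  Reported quantities mirror standard meta-regression
    output: tau^2 with and without moderators, adjusted R^2 (proportion
    of tau^2 explained, floored at 0), residual I^2, the omnibus
    moderator Wald test QM and the fixed-weights residual-heterogeneity
    test QE.
    """
    if tau2_estimator not in _TAU2:
        raise ValueError(f"tau2_estimator must be one of {sorted(_TAU2)}")
    est_tau2 = _TAU2[tau2_estimator]
    y = np.array([r.theta for r in ratios], dtype=float)
    v = np.array([r.se_theta for r in ratios], dtype=float) ** 2
    n = len(y)
    labels: list[str] = []
    if moderators is not None and len(moderators.columns) > 0:
        if len(moderators) != n:
            raise ValueError("moderator rows must align with ratios")
        _check_moderators(moderators, n)
        labels = [str(c) for c in moderators.columns]
        X = np.column_stack([np.ones(n), moderators.to_numpy(dtype=float)])
    else:
        X = np.ones((n, 1))
    k_mod = X.shape[1] - 1
    if n < k_mod + 2:
        raise ValueError(f"need >= {k_mod + 2} ratios for {k_mod} moderators, got {n}")

    X0 = np.ones((n, 1))
    tau2_null = est_tau2(y, v, X0)
    tau2_res = est_tau2(y, v, X)

    # random-effects coefficients and Wald moderator test
    W = 1.0 / (v + tau2_res)
    beta, cov = _wls(y, X, W)
    if k_mod > 0:
        b = beta[1:]
        C = cov[1:, 1:]
        qm = float(b @ np.linalg.solve(C, b))
        qm_p = float(stats.chi2.sf(qm, k_mod))
    else:
        qm, qm_p = 0.0, float("nan")

    # fixed-weights residual heterogeneity test
    w_fe = 1.0 / v
    beta_fe, _ = _wls(y, X, w_fe)
    r_fe = y - X @ beta_fe
    qe = float(np.sum(w_fe * r_fe * r_fe))
    qe_df = n - X.shape[1]
    qe_p = float(stats.chi2.sf(qe, qe_df)) if qe_df > 0 else float("nan")

    s2 = _typical_sampling_variance(v, X)
    residual_i2 = tau2_res / (tau2_res + s2) if np.isfinite(s2) and (tau2_res + s2) > 0 else 0.0
    adj_r2 = 0.0
    if k_mod > 0 and tau2_null > 0:
        adj_r2 = max(0.0, (tau2_null - tau2_res) / tau2_null)

    names = ["intercept"] + labels
    return MetaRegressionResult(
        moderators=labels,
        tau2_null=tau2_null, tau2_residual=tau2_res,
        adjusted_r2=adj_r2, residual_i2=residual_i2,
        qm=qm, qm_df=k_mod, qm_p=qm_p,
        qe=qe, qe_df=qe_df, qe_p=qe_p,
        tau2_estimator=tau2_estimator,
        coef=pd.Series(beta, index=names),
        coef_se=pd.Series(np.sqrt(np.diag(cov)), index=names),
    )


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def _added_term_p(fit: MetaRegressionResult, label: str) -> float:
    """Wald test (chi-square, 1 df) on one coefficient of a fitted model."""
    b = float(fit.coef[label])
    se = float(fit.coef_se[label])
    if se <= 0:
        return float("nan")
    return float(stats.chi2.sf((b / se) ** 2, 1))


def forward_select(ratios: Sequence[RatioEstimate],
                   category_indicators: pd.DataFrame,
                   alpha: float = 0.05,
                   tau2_estimator: str = "REML") -> ForwardSelectionResult:
    """Forward selection of category moderators by tau^2 reduction.

    At each step the candidate whose inclusion yields the largest drop in
    residual tau^2 is provisionally added and retained iff the Wald test
    on its coefficient in the incremental model has p < ``alpha``;
    selection stops at the first non-retained candidate.  Ties in tau^2
    are broken lexicographically by label; candidates identical to an
    already-selected column are skipped with a warning.
    """
    if len(category_indicators.columns) < 2:
        raise ValueError("forward selection needs >= 2 candidate categories")
    selected: list[str] = []
    steps: list[MetaRegressionResult] = []
    rows = []
    remaining = sorted(str(c) for c in category_indicators.columns)
    step = 0
    while remaining:
        step += 1
        best = None  # (tau2_res, label, fit)
        for label in list(remaining):
            cols = selected + [label]
            M = category_indicators[cols]
            dup = any((M[label].to_numpy() == M[s].to_numpy()).all() for s in selected)
            if dup:
                warnings.warn(f"forward_select: candidate {label!r} duplicates a "
                              "selected column; skipped")
                remaining.remove(label)
                continue
            try:
                fit = re_meta_regression(ratios, M, tau2_estimator=tau2_estimator)
            except CollinearModeratorsError:
                continue
            if best is None or fit.tau2_residual < best[0] - 1e-15:
                best = (fit.tau2_residual, label, fit)
        if best is None:
            break
        tau2_res, label, fit = best
        p_add = _added_term_p(fit, label)
        retained = bool(np.isfinite(p_add) and p_add < alpha)
        rows.append({"step": step, "candidate": label,
                     "tau2_residual": tau2_res,
                     "adjusted_r2": fit.adjusted_r2,
                     "qm_p": p_add, "retained": retained})
        steps.append(fit)
        if not retained:
            break
        selected.append(label)
        remaining.remove(label)
    trace = pd.DataFrame(rows, columns=["step", "candidate", "tau2_residual",
                                        "adjusted_r2", "qm_p", "retained"])
    return ForwardSelectionResult(selected=selected, trace=trace, steps=steps)
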