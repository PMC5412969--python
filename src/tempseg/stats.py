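"""Cohort-level statistics: PCA reading composite and gated semipartials.

The analysis chain mirrors a continuous individual-differences design:

1. z-transform the three reading raw scores (NART, TOWRE Sight Word
   Efficiency, TOWRE Phonemic Decoding Efficiency);
2. principal component analysis on their 3x3 Pearson correlation matrix;
   the first component is the composite reading score (all loadings
   oriented positive, higher = better reading);
3. per outcome variable, a Shapiro-Wilk normality gate chooses Pearson
   (parametric) or Spearman (rank) statistics;
4. semipartial correlations of the composite with each visual outcome
   controlling gender and nonverbal IQ: the *predictor* is residualized on
   the covariates by OLS (with intercept) and the residual is correlated
   with the raw outcome, so the coefficient is the predictor's unique
   contribution.  The Spearman variant rank-transforms every variable
   first.  p-values use the t approximation with n - 2 - n_covariates
   degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PcaComposite",
    "z_transform",
    "pca_composite",
    "variance_explained",
    "normality_gate",
    "semipartial",
    "analyze_cohort",
    "READING_COLUMNS",
    "OUTCOME_COLUMNS",
]

READING_COLUMNS = ("nart_raw", "towre_swe_raw", "towre_pde_raw")

#: the eight visual outcomes analyzed against the reading composite
OUTCOME_COLUMNS = tuple(
    f"{task}_{param}"
    for task in ("motion", "form")
    for param in ("acuity_limit_s", "knee_k_s", "asymptote_t_pct", "slope_s")
)


def z_transform(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class PcaComposite:
    loadings: np.ndarray  # PC1 loadings on the correlation scale
    eigenvalues: np.ndarray  # descending; sum to n_vars
    pct_variance_pc1: float
    scores: np.ndarray  # zero-mean composite, one per participant


def pca_composite(reading: pd.DataFrame | np.ndarray) -> PcaComposite:
    """PC1 of the correlation matrix of three reading scores.

    Loadings are reported on the correlation scale (eigenvector *
    sqrt(eigenvalue)), oriented so all are positive; scores project the
    z-scored variables on the unit-norm PC1 eigenvector.
    """
    x = np.asarray(reading, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected a 3-column table")
    n = x.shape[0]
    if n <= 3:
        raise ValueError("need n > 3")
    sds = x.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant column")
    z = (x - x.mean(axis=0)) / sds
    corr = np.corrcoef(z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("singular correlation matrix")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    v1 = evecs[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    loadings = v1 * np.sqrt(max(evals[0], 0.0))
    scores = z @ v1
    return PcaComposite(
        loadings=loadings,
        eigenvalues=evals,
        pct_variance_pc1=variance_explained(evals[0], 3),
        scores=scores,
    )


def variance_explained(eigenvalue: float, n_vars: int) -> float:
    """Percent of total variance: eigenvalue / n_vars * 100."""
    if not (0.0 <= eigenvalue <= n_vars):
        raise ValueError("eigenvalue out of range")
    return eigenvalue / n_vars * 100.0


def normality_gate(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[Literal["parametric", "rank"], float]:
    """Shapiro-Wilk gate: p < alpha -> rank statistics, else parametric."""
    v = np.asarray(values, dtype=float)
    if not (3 <= v.size <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0:
        warnings.warn("constant input; falling back to rank statistics")
        return "rank", 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(sps.shapiro(v).pvalue)
    return ("rank" if p < alpha else "parametric"), p


def _ols_residuals(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), covariates])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def semipartial(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] | np.ndarray | None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Semipartial correlation of predictor x with outcome y.

    x is residualized on the covariates (OLS with intercept); the residual
    is correlated with raw y.  ``method="spearman"`` rank-transforms x, y
    and the covariates before residualization and correlation.  Returns
    (coefficient, p-value); a predictor fully explained by the covariates
    yields (0.0, 1.0).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = xv.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate length mismatch")
    k = cov.shape[1]

    if method == "spearman":
        xv = sps.rankdata(xv)
        yv = sps.rankdata(yv)
        cov = np.column_stack([sps.rankdata(c) for c in cov.T]) if k else cov

    resid = _ols_residuals(xv, cov)
    if np.allclose(resid, 0.0, atol=1e-12 * max(1.0, np.abs(xv).max())):
        return 0.0, 1.0
    r = float(np.corrcoef(resid, yv)[0, 1])
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    r_clip = min(max(r, -0.999999999999), 0.999999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


def analyze_cohort(
    table: pd.DataFrame, gate_alpha: float = 0.05
) -> tuple[pd.DataFrame, PcaComposite]:
    """Full cohort analysis: composite + gated semipartial correlations.

    Produces one row per visual outcome (8 rows: acuity, knee, asymptote
    and slope for the motion and form tasks) for the reading composite
    controlling gender and nonverbal IQ, plus two rows correlating
    nonverbal IQ with the asymptotic thresholds controlling reading and
    gender.  Each row records the gate's Shapiro-Wilk p, the method chosen,
    the coefficient and its p-value.
    """
    missing = [
        c
        for c in (*READING_COLUMNS, "gender", "nonverbal_iq", *OUTCOME_COLUMNS)
        if c not in table.columns
    ]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(table) < 4:
        raise ValueError("need n >= 4")

    pca = pca_composite(table[list(READING_COLUMNS)].to_numpy())
    comp = pca.scores
    gender = table["gender"].to_numpy(dtype=float)
    iq = table["nonverbal_iq"].to_numpy(dtype=float)

    rows = []
    for col in OUTCOME_COLUMNS:
        y = table[col].to_numpy(dtype=float)
        method, sw_p = normality_gate(y, gate_alpha)
        kind = "pearson" if method == "parametric" else "spearman"
        r, p = semipartial(comp, y, np.column_stack([gender, iq]), kind)
        rows.append(
            {
                "predictor": "reading_composite",
                "outcome": col,
                "method": kind,
                "coefficient": r,
                "p_value": p,
                "normality_p": sw_p,
            }
        )
    for col in ("motion_asymptote_t_pct", "form_asymptote_t_pct"):
        y = table[col].to_numpy(dtype=float)
        method, sw_p = normality_gate(y, gate_alpha)
        kind = "pearson" if method == "parametric" else "spearman"
        r, p = semipartial(iq, y, np.column_stack([comp, gender]), kind)
        rows.append(
            {
                "predictor": "nonverbal_iq",
                "outcome": col,
                "method": kind,
                "coefficient": r,
                "p_value": p,
                "normality_p": sw_p,
            }
        )
    return pd.DataFrame(rows), pca
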