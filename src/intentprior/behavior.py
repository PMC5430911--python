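"""Behavioural analyses: choice model, prior-effect scores, RM-ANOVA.

The choice model is a Bernoulli logistic regression of correct responses on
the observer's trial-by-trial prior, the ordinal amount of visuomotor
evidence (1 = low .. 4 = very high), and their interaction:

    logit P(CR=1) = b0 + b_prior*z(prior) + b_evidence*z(evidence)
                       + b_interaction*z(prior)*z(evidence)

Predictors are z-scored before fitting so the coefficients are standardized
slopes; a negative interaction means reliance on the prior grows as evidence
shrinks.  The "prior effect" score is the percent-correct difference between
likely- and unlikely-intention trials at each evidence level (positive when
the induced prior helps), and cohort-level summaries use classical two-way
within-subject ANOVA with partial eta squared effect sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehavioralFit",
    "EffectResult",
    "AnovaResult",
    "CorrelationResult",
    "fit_choice_model",
    "prior_effect",
    "rm_anova_2x",
    "paired_posthoc",
    "correlate",
]


@dataclass(frozen=True)
class BehavioralFit:
    """Standardized logistic coefficients and their standard errors."""

    beta0: float
    beta_prior: float
    beta_evidence: float
    beta_interaction: float
    se: tuple[float, float, float, float]
    converged: bool
    separation: bool
    n: int
    fitted_probs: np.ndarray

    @property
    def coefs(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta_prior, self.beta_evidence, self.beta_interaction]
        )


def _zscore(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"constant predictor: {name} has zero variance")
    return (x - x.mean()) / sd


def _irls(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic IRLS with optional ridge penalty (intercept unpenalized)."""
    n, k = X.shape
    beta = np.zeros(k)
    pen = ridge * np.eye(k)
    pen[0, 0] = 0.0
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1.0 - p), 1e-10, None)
        z = eta + (y - p) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X + pen, XtW @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X + pen)
    se = np.sqrt(np.diag(cov))
    return beta, se, converged


def fit_choice_model(
    prior: Sequence[float],
    evidence: Sequence[float],
    correct: Sequence[int],
    ridge_fallback: float = 1e-4,
) -> BehavioralFit:
    """Fit the standardized prior-by-evidence logistic choice model.

    Predictors are z-scored and the interaction is the product of the
    standardized terms.  The fit is plain maximum likelihood (IRLS); under
    (quasi-)separation — including constant responses — a small ridge
    penalty (``ridge_fallback``) stabilises the solve and the fit is flagged.
    """
    prior = np.asarray(prior, dtype=float)
    evidence = np.asarray(evidence, dtype=float)
    y = np.asarray(correct, dtype=float)
    if not (len(prior) == len(evidence) == len(y)):
        raise ValueError("prior, evidence and correct must have equal length")
    if len(y) < 10:
        raise ValueError(f"need at least 10 trials, got {len(y)}")
    if len(np.unique(evidence)) < 2:
        raise ValueError("constant predictor: evidence has fewer than 2 levels")
    zp = _zscore(prior, "prior")
    ze = _zscore(evidence, "evidence")
    X = np.column_stack([np.ones_like(zp), zp, ze, zp * ze])

    separation = bool(y.min() == y.max())
    beta = se = None
    converged = False
    if not separation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, se, converged = _irls(X, y)
        # diverging coefficients signal (quasi-)separation
        if not converged or not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 15:
            separation = True
    if separation:
        warnings.warn(
            "separation detected; refitting with ridge penalty "
            f"lambda={ridge_fallback:g} (coefficients unreliable)",
            stacklevel=2,
        )
        beta, se, converged = _irls(X, y, ridge=ridge_fallback)
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return BehavioralFit(
        beta0=float(beta[0]),
        beta_prior=float(beta[1]),
        beta_evidence=float(beta[2]),
        beta_interaction=float(beta[3]),
        se=tuple(float(s) for s in se),
        converged=bool(converged),
        separation=separation,
        n=len(y),
        fitted_probs=p,
    )


def prior_effect(
    trials: pd.DataFrame,
    condition_col: Optional[str] = None,
) -> pd.DataFrame:
    """Percent-correct difference between likely and unlikely trials.

    ``trials`` needs columns ``evidence_level``, ``is_likely`` and
    ``correct`` (and optionally a condition column).  Returns one row per
    (condition,) evidence level with ``pc_likely``, ``pc_unlikely``,
    ``prior_effect = pc_likely - pc_unlikely`` (percent scale, positive when
    the biased intention is recognised more accurately), trial counts, and a
    ``missing`` flag for cells with no trials on one side.
    """
    df = trials.copy()
    df = df[df["is_likely"].notna()]
    group_cols = ([condition_col] if condition_col else []) + ["evidence_level"]
    rows = []
    for key, g in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        lik = g[g["is_likely"].astype(bool)]
        unl = g[~g["is_likely"].astype(bool)]
        pc_l = 100.0 * lik["correct"].mean() if len(lik) else np.nan
        pc_u = 100.0 * unl["correct"].mean() if len(unl) else np.nan
        rows.append(
            dict(
                zip(group_cols, key),
                pc_likely=pc_l,
                pc_unlikely=pc_u,
                prior_effect=pc_l - pc_u,
                n_likely=len(lik),
                n_unlikely=len(unl),
                missing=bool(len(lik) == 0 or len(unl) == 0),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass(frozen=True)
class AnovaResult:
    """Two-way within-subject ANOVA: one :class:`EffectResult` per effect."""

    factor_a: str
    factor_b: str
    effects: dict[str, EffectResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": k, "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p, "eta_p2": e.eta_p2}
                for k, e in self.effects.items()
            ]
        )


def _ratio(
    ss_eff: float, df1: int, ss_err: float, df2: int, eps: float = 0.0
) -> tuple[float, float, float]:
    # sums of squares below the cancellation floor are exact zeros
    ss_eff = 0.0 if ss_eff <= eps else ss_eff
    ss_err = 0.0 if ss_err <= eps else ss_err
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        # no error variance: define F = 0 when the effect is also null
        f = 0.0 if ms_eff == 0 else np.inf
    else:
        f = ms_eff / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    denom = ss_eff + ss_err
    eta = ss_eff / denom if denom > 0 else 0.0
    return float(f), p, float(eta)


def rm_anova_2x(
    scores: np.ndarray,
    factor_a: str = "A",
    factor_b: str = "B",
) -> AnovaResult:
    """Classical two-factor repeated-measures ANOVA.

    ``scores`` has shape (subjects, levels_a, levels_b) and must be complete
    (no NaN).  Each effect is tested against its own effect-by-subject
    interaction, the standard univariate within-subject decomposition;
    partial eta squared is SS_effect / (SS_effect + SS_error).
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 3:
        raise ValueError("scores must be subjects x levels_a x levels_b")
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(Y).any():
        raise ValueError("missing cells are not allowed (no imputation)")

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))  # subject means
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)  # (n, a)
    m_sb = Y.mean(axis=1)  # (n, b)
    m_ab = Y.mean(axis=0)  # (a, b)

    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + m) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + m) ** 2)
    resid = (
        Y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - m
    )
    ss_abs = np.sum(resid**2)
    eps = 1e-12 * max(1.0, float(np.sum((Y - m) ** 2)))

    effects = {}
    for name, ss_eff, df1, ss_err, df2 in [
        (factor_a, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        (factor_b, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        (f"{factor_a} x {factor_b}", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    ]:
        f, p, eta = _ratio(ss_eff, df1, ss_err, df2, eps)
        effects[name] = EffectResult(F=f, df1=df1, df2=df2, p=p, eta_p2=eta)
    return AnovaResult(factor_a=factor_a, factor_b=factor_b, effects=effects)


def paired_posthoc(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Uncorrected paired comparison (Fisher-LSD-style paired t-test)."""
    t, p = stats.ttest_rel(scores_a, scores_b)
    return float(t), float(p)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    ok: bool  # False when a variable has zero variance


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the two-sided t-test p value.

    Used for inter-individual brain-behaviour comparisons (e.g. the
    behavioural vs. neural prior-by-evidence interaction estimates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=np.nan, p=np.nan, n=len(x), ok=False)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x), ok=True)
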