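"""Diagnostic accuracy, 2x2 effects, logistic modelling, and the DeLong test.

Conventions: Wilson score intervals for the four proportion metrics; Cohen's
kappa with the Fleiss-Cohen-Everitt asymptotic standard error; Woolf
(log-scale normal) intervals for 2x2 odds ratios; AUROC as the Mann-Whitney
estimator with ties counted one half; the paired-AUROC comparison uses the
DeLong placement-value covariance estimator and is reported as a chi-square
statistic with one degree of freedom (the squared z score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# 2x2 agreement and accuracy

@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total < 1:
            raise ValueError("need at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(index_flags, reference_flags) -> ConfusionMatrix:
    """2x2 cross-tabulation of a boolean index test against a reference."""
    idx = np.asarray(index_flags, dtype=bool)
    ref = np.asarray(reference_flags, dtype=bool)
    if idx.shape != ref.shape:
        raise ValueError("index and reference vectors differ in length")
    return ConfusionMatrix(
        tp=int((idx & ref).sum()), fp=int((idx & ~ref).sum()),
        fn=int((~idx & ref).sum()), tn=int((~idx & ~ref).sum()))


@dataclass
class MetricCI:
    estimate: float | None
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class AccuracyReport:
    sensitivity: MetricCI
    specificity: MetricCI
    ppv: MetricCI
    npv: MetricCI
    kappa: MetricCI


def _wilson(k: int, n: int) -> MetricCI:
    if n == 0:
        return MetricCI(None)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return MetricCI(k / n, float(lo), float(hi))


def _kappa_ci(cm: ConfusionMatrix) -> MetricCI:
    n = cm.total
    p = np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]], dtype=float) / n
    po = p[0, 0] + p[1, 1]
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if pe == 1.0:
        return MetricCI(None)
    kappa = (po - pe) / (1 - pe)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
    t1 = sum(p[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2
             for i in range(2))
    t2 = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j)
    t3 = (po * pe - 2 * pe + po) ** 2
    var = (t1 + t2 - t3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    return MetricCI(kappa, max(kappa - Z95 * se, -1.0),
                    min(kappa + Z95 * se, 1.0))


def accuracy(cm: ConfusionMatrix) -> AccuracyReport:
    """Sensitivity/specificity/PPV/NPV with Wilson 95% CIs, plus kappa.

    A metric whose margin is zero is reported as undefined (None estimate).
    """
    return AccuracyReport(
        sensitivity=_wilson(cm.tp, cm.tp + cm.fn),
        specificity=_wilson(cm.tn, cm.tn + cm.fp),
        ppv=_wilson(cm.tp, cm.tp + cm.fp),
        npv=_wilson(cm.tn, cm.tn + cm.fn),
        kappa=_kappa_ci(cm),
    )


# ---------------------------------------------------------------------------
# Odds ratios

@dataclass
class EffectEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    scale: str  # unadjusted_2x2 | adjusted_model
    corrected: bool = False  # Haldane-Anscombe 0.5 applied

    def __post_init__(self):
        if not self.ci_low <= self.or_point <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def odds_ratio_2x2(exposed_events: int, exposed_total: int,
                   unexposed_events: int, unexposed_total: int
                   ) -> EffectEstimate:
    """Cross-product odds ratio with the Woolf log-scale 95% CI.

    If any implied cell is zero, the Haldane-Anscombe 0.5 correction is
    applied to all four cells and flagged on the result.
    """
    if exposed_total <= 0 or unexposed_total <= 0:
        raise ValueError("group totals must be positive")
    a = exposed_events
    b = exposed_total - exposed_events
    c = unexposed_events
    d = unexposed_total - unexposed_events
    if min(a, b, c, d) < 0:
        raise ValueError("events exceed totals")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        or_point=or_point,
        ci_low=math.exp(math.log(or_point) - Z95 * se),
        ci_high=math.exp(math.log(or_point) + Z95 * se),
        scale="unadjusted_2x2", corrected=corrected)


# ---------------------------------------------------------------------------
# Collinearity screening

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j from its R^2 against the remaining columns plus an
    intercept."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError(f"constant column at position {j}")
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_screen(design: pd.DataFrame, exposure: str, threshold: float = 2.5
               ) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the worst covariate with VIF > threshold.

    The exposure column participates in the auxiliary regressions but is
    never dropped.  Returns (kept column names incl. exposure, dropped list
    of (name, VIF at removal)).
    """
    if exposure not in design.columns:
        raise ValueError(f"exposure {exposure!r} not in design")
    cols = list(design.columns)
    dropped: list[tuple[str, float]] = []
    while True:
        X = design[cols].to_numpy(float)
        vifs = {c: _vif_one(X, i) for i, c in enumerate(cols)}
        candidates = {c: v for c, v in vifs.items()
                      if c != exposure and v > threshold}
        if not candidates:
            return cols, dropped
        worst = max(candidates, key=candidates.get)
        dropped.append((worst, candidates[worst]))
        cols.remove(worst)


# ---------------------------------------------------------------------------
# Logistic model

class FitError(RuntimeError):
    """Non-convergence or separation in a logistic fit."""


@dataclass
class ModelFit:
    exposure: str
    coefficients: pd.Series
    std_errors: pd.Series
    effect: EffectEstimate
    probs: np.ndarray
    auroc_value: float
    dropped_covariates: list[tuple[str, float]] = field(default_factory=list)


def fit_logistic(outcome, design: pd.DataFrame, exposure: str,
                 dropped: list[tuple[str, float]] | None = None) -> ModelFit:
    """Maximum-likelihood logistic fit; an intercept is added.

    The exposure's OR and Wald 95% CI are read off exp(coefficient); the
    per-subject predicted probabilities are retained for AUROC work.
    Raises :class:`FitError` on non-convergence or apparent separation.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) < 10 * X.shape[1]:
        import warnings
        warnings.warn("fewer than 10 observations per parameter",
                      stacklevel=2)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    beta = fit.params[exposure]
    se = fit.bse[exposure]
    if not np.isfinite(se) or abs(beta) > 15:
        raise FitError(
            f"separation suspected: beta({exposure}) = {beta:.3g}, "
            f"se = {se:.3g}")
    probs = np.asarray(fit.predict(X))
    effect = EffectEstimate(
        or_point=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se),
        ci_high=math.exp(beta + Z95 * se),
        scale="adjusted_model" if design.shape[1] > 1 else "unadjusted_2x2")
    return ModelFit(
        exposure=exposure, coefficients=fit.params, std_errors=fit.bse,
        effect=effect, probs=probs, auroc_value=auroc(probs, y),
        dropped_covariates=list(dropped or []))


# ---------------------------------------------------------------------------
# AUROC and the DeLong paired comparison

def auroc(scores, outcomes) -> float:
    """Mann-Whitney AUROC; ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores: np.ndarray, y: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Midrank placement values (V10 for positives, V01 for negatives)."""
    x, w = scores[y], scores[~y]
    m, n = x.size, w.size
    tx = rankdata(np.concatenate([x, w]))
    rx = rankdata(x)
    rw = rankdata(w)
    v10 = (tx[:m] - rx) / n
    v01 = 1.0 - (tx[m:] - rw) / m
    return v10, v01


@dataclass
class DeLongResult:
    auroc_a: float
    auroc_b: float
    delta: float  # auroc_b - auroc_a
    variance_delta: float
    chi2: float
    p_value: float


def delong_compare(probs_a, probs_b, outcomes) -> DeLongResult:
    """Paired AUROC comparison on the same subjects.

    Returns the signed delta (model b minus model a), its placement-value
    variance, chi2 = delta^2 / var (df 1) and the p-value.  If the two score
    vectors give identical placements (zero variance), delta is 0 and p is 1.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("probability and outcome vectors must align")
    v10a, v01a = _placements(a, y)
    v10b, v01b = _placements(b, y)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    delta = auc_b - auc_a
    if var <= 0 or math.isclose(var, 0.0, abs_tol=1e-300):
        return DeLongResult(auc_a, auc_b, 0.0 if abs(delta) < 1e-12 else delta,
                            0.0, 0.0 if abs(delta) < 1e-12 else math.inf,
                            1.0 if abs(delta) < 1e-12 else 0.0)
    chi2 = delta * delta / var
    return DeLongResult(auc_a, auc_b, delta, float(var), float(chi2),
                        float(sps.chi2.sf(chi2, df=1)))
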