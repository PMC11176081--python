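"""Cross-dataset diagnosis probabilities and diagnostic-performance metrics.

To score a target cohort, a logistic regression of diagnosis on the per-gene
standardized residuals (sWSR for relative expression, HC-standardized
covariate residuals for absolute expression) is fitted on the *pooled samples
of the other cohorts* and applied to the target cohort -- the target never
contributes to its own model.  Performance is summarised threshold-free:
rank-sum p, AUC, and Nagelkerke pseudo-R2 converted to the liability scale at
an assumed population prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from stoichsi.io_formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PerformanceReport:
    """Threshold-free discrimination metrics of one score against diagnosis."""

    metric: str
    wilcoxon_p: float
    auc: float
    nagelkerke_r2_observed: float
    r2_liability: float
    prevalence: float
    n_cases: int
    n_controls: int


# ---------------------------------------------------------------------------
# logistic models


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Unpenalised ML logistic fit with a weak-ridge fallback on separation."""
    from sklearn.linear_model import LogisticRegression
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
        model.fit(X, y)
        converged = model.n_iter_[0] < 2000 and np.all(np.isfinite(model.coef_))
    if not converged or np.max(np.abs(model.coef_)) > 1e4:
        logger.warning("logistic fit unstable (separation?); refitting with weak ridge")
        model = LogisticRegression(penalty="l2", C=1e4, solver="lbfgs", max_iter=2000)
        model.fit(X, y)
    return model


def cross_dataset_probabilities(matrices: dict[str, pd.DataFrame],
                                diagnoses: dict[str, np.ndarray],
                                target: str) -> pd.Series:
    """Predicted diagnosis probabilities for ``target`` from the other cohorts.

    ``matrices`` maps dataset name to an individuals x genes matrix of
    standardized residuals; genes are intersected across all datasets (order
    taken from the target), training samples are pooled over the non-target
    datasets.
    """
    if target not in matrices:
        raise ValidationError(f"unknown target dataset {target!r}")
    others = [d for d in matrices if d != target]
    if len(others) < 2:
        raise ValidationError("need >= 2 training datasets")
    common = [g for g in matrices[target].columns
              if all(g in matrices[d].columns for d in others)]
    dropped = matrices[target].shape[1] - len(common)
    if dropped:
        logger.info("dropping %d genes absent from some training dataset", dropped)
    if not common:
        raise ValidationError("no genes shared across datasets")
    X_train = np.vstack([matrices[d][common].to_numpy() for d in others])
    y_train = np.concatenate([(np.asarray(diagnoses[d]) == "BD").astype(int)
                              for d in others])
    if y_train.min() == y_train.max():
        raise ValidationError("training pool contains a single class")
    # audit: target samples must not appear in the training pool
    target_ids = set(matrices[target].index)
    train_ids = set().union(*(set(matrices[d].index) for d in others))
    if target_ids & train_ids:
        raise ValidationError("target samples leaked into the training pool")
    model = _fit_logistic(X_train, y_train)
    probs = model.predict_proba(matrices[target][common].to_numpy())[:, 1]
    return pd.Series(probs, index=matrices[target].index, name=f"p_BD[{target}]")


# ---------------------------------------------------------------------------
# metrics


def auc(scores, labels, case: str = "BD") -> float:
    """AUC via the Mann-Whitney U statistic with tie correction (0.5 per tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == case]
    neg = scores[labels != case]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def nagelkerke_r2(labels, predictor, case: str = "BD") -> float:
    """Nagelkerke pseudo-R2 of a univariate logistic regression on ``predictor``.

    R2_CS = 1 - (L0/L1)^(2/N) rescaled by its maximum 1 - L0^(2/N).
    """
    import statsmodels.api as sm

    y = (np.asarray(labels) == case).astype(int)
    x = np.asarray(predictor, dtype=float)
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    X = sm.add_constant(x)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    n = y.size
    r2_cs = 1.0 - np.exp(2.0 / n * (fit.llnull - fit.llf))
    max_cs = 1.0 - np.exp(2.0 / n * fit.llnull)
    return float(np.clip(r2_cs / max_cs, 0.0, 1.0))


def liability_adjust(r2_observed: float, K: float = 0.02, P: float = 0.5) -> float:
    """Convert an observed-scale R2 to the liability scale (Lee et al. 2012).

    K is the population prevalence of the disorder; P the case fraction of the
    sample.  Accounts for case oversampling in case-control designs.
    """
    if not (0 < K < 1 and 0 < P < 1):
        raise ValidationError("K and P must lie in (0, 1)")
    if not 0 <= r2_observed <= 1:
        raise ValidationError("r2 must lie in [0, 1]")
    t = stats.norm.ppf(1 - K)  # liability threshold
    z = stats.norm.pdf(t)  # density at threshold
    mbar = z / K  # mean liability of cases
    C = (K * (1 - K) / z ** 2) * (K * (1 - K) / (P * (1 - P)))
    theta = mbar * (P - K) / (1 - K) * (mbar * (P - K) / (1 - K) - t)
    return float(C * r2_observed / (1 + C * theta * r2_observed))


def performance_report(scores, labels, metric: str = "SI",
                       prevalence: float = 0.02) -> PerformanceReport:
    """All three diagnostic-performance tests for one score."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    cases = scores[labels == "BD"]
    controls = scores[labels == "HC"]
    res = stats.mannwhitneyu(cases, controls, alternative="two-sided")
    r2_obs = nagelkerke_r2(labels, scores)
    P = cases.size / labels.size
    return PerformanceReport(
        metric=metric, wilcoxon_p=float(res.pvalue), auc=auc(scores, labels),
        nagelkerke_r2_observed=r2_obs,
        r2_liability=liability_adjust(r2_obs, K=prevalence, P=P),
        prevalence=prevalence, n_cases=int(cases.size), n_controls=int(controls.size))


def report_table(reports: list[PerformanceReport], dataset: str) -> pd.DataFrame:
    return pd.DataFrame([{
        "dataset": dataset, "metric": r.metric, "p": r.wilcoxon_p, "auc": r.auc,
        "r2_observed": r.nagelkerke_r2_observed, "r2_liability": r.r2_liability,
        "n_cases": r.n_cases, "n_controls": r.n_controls,
    } for r in reports])
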