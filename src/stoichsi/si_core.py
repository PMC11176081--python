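"""Resampled gene-expression models and the stoichiometric-imbalance score.

For each resampling iteration a random subset of the healthy controls (the
*modelling set* M^k) is used to fit, per gene j, a LASSO model of that gene's
log2 RPKM from all other analysis genes plus the five unpenalised covariates.
Residuals are computed only for individuals outside M^k, weighted by the
model's R^2 and scaled by the gene's mean observed expression over all
individuals:

    wsr[i,j,k] = R2[j,k] * (y[i,j] - yhat[i,j,k]) / mean_i(y[i,j])

These are averaged over the iterations in which individual i was not used for
modelling (WSR[i,j]), standardised against the healthy controls (sWSR[i,j]),
and aggregated into the per-individual score

    SI[i] = mean_j |sWSR[i,j]|.

Strict train/test separation -- no individual is ever scored by a model it
helped fit -- is asserted on every run (:func:`verify_no_leakage`).

The penalty is chosen per model by 10-fold cross-validation with the one
standard-error rule (the most regularised model within one SE of the minimum
CV error), as in glmnet.  Covariates are kept unpenalised via the
Frisch-Waugh-Lovell projection: the LASSO is solved on gene predictors and
response orthogonalised against the covariate block, which yields exactly the
solution of the joint problem with a penalty-free covariate block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from stoichsi.io_formats import SampleTable, ValidationError
from stoichsi.preprocess import covariate_design, standardize_by_hc

logger = logging.getLogger(__name__)

MODES = ("model_on_controls", "model_on_cases", "hc_split_null")


class PlanCoverageError(ValidationError):
    """An individual never appears in any test set of the plan."""


class LeakageError(AssertionError):
    """A test individual contributed to a model it was scored against."""


@dataclass
class ResamplingPlan:
    """Modelling/test split schedule over the modelling pool.

    ``modelling_sets[k]`` holds the sample ids fitted on in iteration k; the
    implied test set is every other individual in the dataset.
    """

    modelling_sets: list[np.ndarray]
    pool: list[str]
    model_size: int
    seed: int

    @property
    def iterations(self) -> int:
        return len(self.modelling_sets)

    def to_json(self) -> dict:
        return {
            "model_size": self.model_size,
            "iterations": self.iterations,
            "seed": self.seed,
            "pool": list(self.pool),
            "modelling_sets": [list(m) for m in self.modelling_sets],
        }


def make_plan(controls: list[str], model_size: int, iterations: int, seed: int,
              ensure_coverage: bool = True, max_tries: int = 20) -> ResamplingPlan:
    """Draw ``iterations`` uniform modelling subsets of the control pool.

    With ``ensure_coverage`` the uniform draw is retried (deterministically)
    until every control is left out of at least one modelling set, so that
    every control acquires a test-set residual.  When uniform resampling
    cannot plausibly achieve that (few iterations relative to the pool), the
    first ceil(pool/test) iterations instead cycle a seeded permutation of the
    pool through the test slots -- coverage by construction -- and any
    remaining iterations are uniform.
    """
    controls = list(controls)
    n_pool = len(controls)
    if model_size >= n_pool:
        raise ValidationError(
            f"model_size {model_size} must be < number of controls {n_pool}")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    test_size = n_pool - model_size
    rounds = -(-n_pool // test_size)  # ceil
    if iterations < rounds and ensure_coverage:
        logger.warning(
            "%d iterations cannot test all %d controls (%d test slots each); "
            "some controls will have no residuals", iterations, n_pool, test_size)
        ensure_coverage = False
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))

    def covered(sets) -> bool:
        tested: set[str] = set()
        for m in sets:
            tested |= set(controls) - set(m)
        return tested == set(controls)

    sets = None
    for _ in range(max_tries):
        cand = [np.array(sorted(rng.choice(controls, size=model_size, replace=False)))
                for _ in range(iterations)]
        if not ensure_coverage or covered(cand):
            sets = cand
            break
    if sets is None:  # force coverage: cycle a permutation through the test slots
        perm = [controls[i] for i in rng.permutation(n_pool)]
        sets = []
        for k in range(iterations):
            if k < rounds:
                block = set(perm[k * test_size:(k + 1) * test_size])
                candidates = [c for c in controls if c not in block]
                m = rng.choice(candidates, size=model_size, replace=False)
            else:
                m = rng.choice(controls, size=model_size, replace=False)
            sets.append(np.array(sorted(m)))
    return ResamplingPlan(modelling_sets=sets, pool=controls,
                          model_size=model_size, seed=seed)


@dataclass
class GeneModel:
    """One fitted gene model (target gene j, iteration k)."""

    target: str
    iteration: int
    predictor_genes: list[str]
    coef_genes: np.ndarray  # on standardized predictor columns
    coef_covariates: np.ndarray
    covariate_names: list[str]
    lambda_: float
    r2: float
    _mu: np.ndarray = field(repr=False, default=None)
    _sd: np.ndarray = field(repr=False, default=None)

    def predict(self, gene_expr: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        """Predicted log2 RPKM for new samples (rows)."""
        Xs = (gene_expr - self._mu) / self._sd
        return Xs @ self.coef_genes + covariates @ self.coef_covariates


def _lambda_grid(lam_max: float, n_lambda: int, min_ratio: float) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _quiet_lasso_path(X, y, *, alphas, precompute, Xy, tol, max_iter):
    """lasso_path without per-call validation or near-convergence warnings.

    The penalty path stops at a modest duality-gap tolerance; warnings about
    the last fraction of a percent of the gap are noise at these problem
    sizes.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        return lasso_path(X, y, alphas=alphas, precompute=precompute, Xy=Xy,
                          tol=tol, max_iter=max_iter, check_input=False)


def _gram_path_direct(G, Xy, y, alphas, n_samples, tol, max_iter):
    """Warm-started LASSO path from sufficient statistics (Gram, X^T y).

    Calls scikit-learn's Gram-matrix coordinate-descent solver directly,
    skipping the per-call validation of :func:`lasso_path`, which dominates
    runtime when tens of thousands of small models are fitted.  The solver's
    objective is (1/2) w'Qw - q'w + l1 |w|, i.e. the LASSO with
    l1 = alpha * n_samples.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import _cd_fast as cd_fast
    from sklearn.utils import check_random_state

    p = G.shape[0]
    rng = check_random_state(0)
    coef = np.zeros(p)
    coefs = np.empty((p, len(alphas)))
    Gc = np.ascontiguousarray(G)
    q = np.ascontiguousarray(Xy)
    yc = np.ascontiguousarray(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i, alpha in enumerate(alphas):
            coef, *_ = cd_fast.enet_coordinate_descent_gram(
                coef, alpha * n_samples, 0.0, Gc, q, yc, max_iter, tol,
                rng, False, False, False)
            coefs[:, i] = coef
    return coefs


def _gram_path(Z, y, *, alphas, G, Xy, tol, max_iter):
    """Dispatch to the direct Gram path, falling back to public lasso_path."""
    global _DIRECT_OK
    if _DIRECT_OK:
        try:
            return _gram_path_direct(G, Xy, y, alphas, Z.shape[0], tol, max_iter)
        except (TypeError, ImportError):  # solver signature changed
            _DIRECT_OK = False
            logger.warning("direct Gram solver unavailable; using lasso_path")
    _, coefs, _ = _quiet_lasso_path(Z, y, alphas=alphas, precompute=G, Xy=Xy,
                                    tol=tol, max_iter=max_iter)
    return coefs


_DIRECT_OK = True


def _kfold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[f::n_folds] for f in range(n_folds)]


def _fit_1se(Xg: np.ndarray, C: np.ndarray, y: np.ndarray, rng: np.random.Generator,
             n_lambda: int, lambda_min_ratio: float, n_folds: int,
             tol: float = 3e-3, max_iter: int = 300):
    """LASSO with unpenalised covariate block and 1-SE penalty selection.

    Xg: modelling samples x gene predictors (raw log2 RPKM);
    C: modelling samples x covariate design (with intercept); y: target.
    Returns (coef_genes_on_standardized_cols, coef_covariates, lambda, r2, mu, sd).
    """
    m = y.size
    mu = Xg.mean(axis=0)
    sd = Xg.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (Xg - mu) / sd

    Q, _ = np.linalg.qr(C)
    Zr = Xs - Q @ (Q.T @ Xs)
    yr = y - Q @ (Q.T @ y)
    Xy = Zr.T @ yr
    lam_max = np.max(np.abs(Xy)) / m
    if lam_max <= 0 or not np.isfinite(lam_max):
        coef_g = np.zeros(Xs.shape[1])
        coef_c, *_ = np.linalg.lstsq(C, y, rcond=None)
        return coef_g, coef_c, 0.0, 0.0, mu, sd
    alphas = _lambda_grid(lam_max, n_lambda, lambda_min_ratio)

    n_folds = max(2, min(n_folds, m // 2))
    folds = [f for f in _kfold_indices(m, n_folds, rng) if f.size]
    mse = np.empty((len(folds), n_lambda))
    all_rows = np.arange(m)
    for f, val in enumerate(folds):
        tr = np.setdiff1d(all_rows, val, assume_unique=True)
        Ctr, Cval = C[tr], C[val]
        Qtr, _ = np.linalg.qr(Ctr)
        Ztr = Xs[tr] - Qtr @ (Qtr.T @ Xs[tr])
        ytr = y[tr] - Qtr @ (Qtr.T @ y[tr])
        G = Ztr.T @ Ztr
        coefs = _gram_path(Ztr, ytr, alphas=alphas, G=G, Xy=Ztr.T @ ytr,
                           tol=tol, max_iter=max_iter)
        # covariate coefficients per lambda from OLS of the lasso remainder
        # (pinv tolerates fold-level rank deficiency, e.g. a constant one-hot)
        remainder = y[tr][:, None] - Xs[tr] @ coefs
        bc = np.linalg.pinv(Ctr) @ remainder
        pred = Xs[val] @ coefs + Cval @ bc
        mse[f] = np.mean((y[val][:, None] - pred) ** 2, axis=0)

    mean_mse = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(len(folds))
    mean_mse = np.where(np.isfinite(mean_mse), mean_mse, np.inf)
    i_min = int(np.argmin(mean_mse))
    threshold = mean_mse[i_min] + (se[i_min] if np.isfinite(se[i_min]) else 0.0)
    within = np.flatnonzero(mean_mse <= threshold)
    i_1se = int(within[0]) if within.size else i_min  # alphas descend

    Gf = Zr.T @ Zr
    coefs_full = _gram_path(Zr, yr, alphas=alphas, G=Gf, Xy=Xy,
                            tol=tol, max_iter=max_iter)
    coef_g = coefs_full[:, i_1se]
    coef_c, *_ = np.linalg.lstsq(C, y - Xs @ coef_g, rcond=None)
    yhat = Xs @ coef_g + C @ coef_c
    denom = np.std(yhat) * np.std(y)
    r2 = 0.0 if denom == 0 else float(np.corrcoef(y, yhat)[0, 1] ** 2)
    if not np.isfinite(r2):
        r2 = 0.0
    return coef_g, coef_c, float(alphas[i_1se]), r2, mu, sd


def fit_gene_model(log2_rpkm: pd.DataFrame, samples: SampleTable, target: str,
                   modelling_ids: list[str], iteration: int = 0, seed: int = 0,
                   n_lambda: int = 50, lambda_min_ratio: float = 0.01,
                   n_folds: int = 10, min_model_size: int = 20) -> GeneModel:
    """Fit one gene's LASSO model on a modelling sample set.

    ``log2_rpkm`` is genes x samples; predictors are all other rows plus the
    covariate design of ``samples``.
    """
    if len(modelling_ids) < min_model_size:
        raise ValidationError(f"modelling set smaller than {min_model_size}")
    genes = list(log2_rpkm.index)
    j = genes.index(target)
    pred_genes = [g for g in genes if g != target]
    design = covariate_design(samples).loc[list(log2_rpkm.columns)]
    sub = list(modelling_ids)
    Y = log2_rpkm[sub].to_numpy().T
    C = design.loc[sub].to_numpy()
    y = Y[:, j]
    if np.std(y) == 0:
        raise ValidationError(f"target gene {target} constant on modelling set")
    Xg = np.delete(Y, j, axis=1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, iteration, j]))
    coef_g, coef_c, lam, r2, mu, sd = _fit_1se(
        Xg, C, y, rng, n_lambda, lambda_min_ratio, n_folds)
    return GeneModel(
        target=target, iteration=iteration, predictor_genes=pred_genes,
        coef_genes=coef_g, coef_covariates=coef_c,
        covariate_names=list(design.columns), lambda_=lam, r2=r2, _mu=mu, _sd=sd)


# ---------------------------------------------------------------------------
# Eq. 1-3 primitives


def compute_wsr(y_obs, y_pred, r2, gene_mean_over_all_m):
    """Weighted scaled residual: r2 * (y - yhat) / mean(y over all individuals)."""
    gene_mean_over_all_m = np.asarray(gene_mean_over_all_m, dtype=float)
    if np.any(gene_mean_over_all_m == 0):
        raise ValidationError("zero mean expression; gene must be excluded")
    return np.asarray(r2) * (np.asarray(y_obs) - np.asarray(y_pred)) / gene_mean_over_all_m


def aggregate_WSR(wsr: np.ndarray, plan: ResamplingPlan, sample_ids: list[str]) -> np.ndarray:
    """Average the per-iteration wsr tensor over qualifying iterations.

    ``wsr`` has shape (iterations, individuals, genes) with entries defined
    (non-NaN) only where the individual is outside that iteration's modelling
    set.  Each (i, j) cell of the result averages over exactly the iterations
    with i not in M^k; an individual with no qualifying iteration raises
    :class:`PlanCoverageError`.
    """
    wsr = np.asarray(wsr, dtype=float)
    p, m, n = wsr.shape
    mask = np.ones((p, m), dtype=bool)
    id_pos = {s: i for i, s in enumerate(sample_ids)}
    for k, mset in enumerate(plan.modelling_sets):
        for s in mset:
            if s in id_pos:
                mask[k, id_pos[s]] = False
    counts = mask.sum(axis=0)
    if np.any(counts == 0):
        bad = [sample_ids[i] for i in np.flatnonzero(counts == 0)]
        raise PlanCoverageError(f"individuals never in a test set: {bad[:5]}")
    total = np.where(mask[:, :, None], wsr, 0.0).sum(axis=0)
    return total / counts[:, None]


def standardize_sWSR(WSR: pd.DataFrame, diagnosis: np.ndarray,
                     reference: str = "HC") -> pd.DataFrame:
    """HC-standardise a WSR matrix (individuals x genes) column-wise."""
    return standardize_by_hc(WSR.T, np.asarray(diagnosis), reference=reference).T


def si_score(sWSR: pd.DataFrame | np.ndarray) -> pd.Series | float:
    """Mean absolute standardized residual per individual (row)."""
    if isinstance(sWSR, pd.DataFrame):
        return sWSR.abs().mean(axis=1)
    arr = np.abs(np.asarray(sWSR, dtype=float))
    return arr.mean(axis=-1)


def _default_model_size(n_pool: int, iterations: int) -> int:
    """2/3 of the pool, shrunk if needed so all controls can be tested."""
    two_thirds = int(round(n_pool * 2 / 3))
    max_for_coverage = n_pool - (-(-n_pool // max(iterations, 1)))
    return max(2, min(two_thirds, max_for_coverage))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class IterationRecord:
    """Audit record of one resampling iteration (small runs only)."""

    modelling_ids: list[str]
    test_ids: list[str]
    y_pred: np.ndarray  # test x genes
    r2: np.ndarray  # genes


@dataclass
class SIProfile:
    """Full output of a stoichiometric-imbalance run on one dataset."""

    WSR: pd.DataFrame  # individuals x genes
    sWSR: pd.DataFrame  # individuals x genes (zero-variance genes dropped)
    si: pd.Series  # per individual, >= 0
    r2: pd.DataFrame  # iterations x genes, model fit quality
    diagnosis: pd.Series
    mode: str
    plan: ResamplingPlan
    n_test_iterations: pd.Series  # per individual
    gene_mean: pd.Series
    iteration_records: list[IterationRecord] | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.WSR.columns)


def run_si(expr: pd.DataFrame, samples: SampleTable, plan: ResamplingPlan | None = None,
           mode: str = "model_on_controls", model_size: int | None = None,
           iterations: int | None = None, seed: int = 0, n_lambda: int = 50,
           lambda_min_ratio: float = 0.01, n_folds: int = 10,
           keep_iteration_records: bool = False) -> SIProfile:
    """Run the full resampling pipeline on one dataset.

    Parameters
    ----------
    expr : DataFrame, genes x samples
        log2 RPKM of the analysis genes (already filtered/normalised).
    plan : ResamplingPlan, optional
        Built automatically from ``model_size``/``iterations``/``seed`` when
        omitted (model_size defaults to 2/3 of the modelling pool).
    mode : str
        ``model_on_controls`` (primary analysis), ``model_on_cases`` (control
        experiment: fit on case subsets, scale by case statistics) or
        ``hc_split_null`` (control experiment: controls split in two, group 1
        models, group 2 plays the role of cases).
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; choose from {MODES}")
    if mode == "hc_split_null":
        return _run_hc_split_null(expr, samples, plan=plan, model_size=model_size,
                                  iterations=iterations, seed=seed, n_lambda=n_lambda,
                                  lambda_min_ratio=lambda_min_ratio, n_folds=n_folds,
                                  keep_iteration_records=keep_iteration_records)

    reference = "HC" if mode == "model_on_controls" else "BD"
    sample_ids = list(expr.columns)
    table = samples.reindex(sample_ids)
    dx = table.diagnosis
    pool = sorted(s for s, d in zip(sample_ids, dx) if d == reference)
    if len(pool) < 3:
        raise ValidationError(f"too few {reference} samples to model on")

    if plan is None:
        if iterations is None:
            iterations = 100
        if model_size is None:
            model_size = _default_model_size(len(pool), iterations)
        plan = make_plan(pool, model_size, iterations, seed)
    else:
        if not set(map(str, np.concatenate(plan.modelling_sets))) <= set(pool):
            raise LeakageError("plan modelling sets include non-pool samples")

    # drop unusable genes: zero variance or zero overall mean (Eq. 1 denominator)
    Yfull = expr.to_numpy().T  # samples x genes
    gene_sd = Yfull.std(axis=0)
    gene_mean = Yfull.mean(axis=0)
    usable = (gene_sd > 0) & (np.abs(gene_mean) > 1e-12)
    if not usable.all():
        dropped = [g for g, u in zip(expr.index, usable) if not u]
        logger.warning("dropping %d unusable genes (constant or zero mean): %s",
                       len(dropped), dropped[:5])
    genes = [g for g, u in zip(expr.index, usable) if u]
    Y = Yfull[:, usable]
    gene_mean = gene_mean[usable]
    # canonical gene order: results are invariant to the input row order
    order = np.argsort(genes)
    genes = [genes[i] for i in order]
    Y = Y[:, order]
    gene_mean = gene_mean[order]
    m, n = Y.shape

    design = covariate_design(table)
    design = design.loc[sample_ids]
    C = design.to_numpy()

    id_pos = {s: i for i, s in enumerate(sample_ids)}
    wsr_sum = np.zeros((m, n))
    test_count = np.zeros(m, dtype=int)
    r2_store = np.zeros((plan.iterations, n))
    records: list[IterationRecord] | None = [] if keep_iteration_records else None

    for k, mset in enumerate(plan.modelling_sets):
        model_idx = np.array([id_pos[s] for s in mset])
        test_mask = np.ones(m, dtype=bool)
        test_mask[model_idx] = False
        test_idx = np.flatnonzero(test_mask)
        if np.intersect1d(model_idx, test_idx).size:
            raise LeakageError("modelling and test sets overlap")
        Ym, Cm = Y[model_idx], C[model_idx]
        Yt, Ct = Y[test_idx], C[test_idx]
        y_pred_iter = np.empty((test_idx.size, n)) if records is not None else None
        for j in range(n):
            y = Ym[:, j]
            Xg = np.delete(Ym, j, axis=1)
            rng = np.random.default_rng(np.random.SeedSequence([plan.seed, k, j]))
            coef_g, coef_c, _, r2, mu, sd = _fit_1se(
                Xg, Cm, y, rng, n_lambda, lambda_min_ratio, n_folds)
            r2_store[k, j] = r2
            Xt = (np.delete(Yt, j, axis=1) - mu) / sd
            yhat = Xt @ coef_g + Ct @ coef_c
            wsr_sum[test_idx, j] += r2 * (Yt[:, j] - yhat) / gene_mean[j]
            if y_pred_iter is not None:
                y_pred_iter[:, j] = yhat
        test_count[test_idx] += 1
        if records is not None:
            records.append(IterationRecord(
                modelling_ids=[sample_ids[i] for i in model_idx],
                test_ids=[sample_ids[i] for i in test_idx],
                y_pred=y_pred_iter, r2=r2_store[k].copy()))

    if np.any(test_count == 0):
        bad = [sample_ids[i] for i in np.flatnonzero(test_count == 0)]
        raise PlanCoverageError(f"individuals never tested: {bad[:5]}")

    WSR = pd.DataFrame(wsr_sum / test_count[:, None], index=sample_ids, columns=genes)
    dx_series = pd.Series(dx, index=sample_ids)
    sWSR = standardize_sWSR(WSR, dx, reference=reference)
    si = si_score(sWSR)
    profile = SIProfile(
        WSR=WSR, sWSR=sWSR, si=si, r2=pd.DataFrame(r2_store, columns=genes),
        diagnosis=dx_series, mode=mode, plan=plan,
        n_test_iterations=pd.Series(test_count, index=sample_ids),
        gene_mean=pd.Series(gene_mean, index=genes),
        iteration_records=records)
    verify_no_leakage(profile)
    return profile


def _run_hc_split_null(expr: pd.DataFrame, samples: SampleTable, plan=None,
                       model_size=None, iterations=None, seed: int = 0, **kwargs):
    """Null control experiment: controls split in two, no cases involved.

    Group 1 supplies the (resampled) modelling sets and its held-out members
    are tested alongside all of group 2; group 2 takes the case role in the
    output's diagnosis labelling ("BD") so downstream comparisons read the
    same way as the primary analysis.  On data without disease signal the two
    groups should be statistically indistinguishable.
    """
    sample_ids = list(expr.columns)
    table = samples.reindex(sample_ids)
    hc_ids = sorted(s for s, d in zip(sample_ids, table.diagnosis) if d == "HC")
    if len(hc_ids) < 6:
        raise ValidationError("hc_split_null needs >= 6 controls")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 424242]))
    perm = rng.permutation(len(hc_ids))
    half = len(hc_ids) // 2
    group1 = [hc_ids[i] for i in sorted(perm[:half])]
    group2 = [hc_ids[i] for i in sorted(perm[half:])]

    pseudo = table.table[table.table["sample_id"].isin(hc_ids)].copy()
    pseudo["diagnosis"] = np.where(pseudo["sample_id"].isin(group1), "HC", "BD")
    pseudo_samples = SampleTable(pseudo.reset_index(drop=True))
    sub_expr = expr[pseudo_samples.sample_ids]

    if plan is None:
        if iterations is None:
            iterations = 100
        if model_size is None:
            model_size = _default_model_size(len(group1), iterations)
        plan = make_plan(group1, model_size, iterations, seed)
    profile = run_si(sub_expr, pseudo_samples, plan=plan, mode="model_on_controls",
                     **kwargs)
    profile.mode = "hc_split_null"
    return profile


def verify_no_leakage(profile: SIProfile) -> bool:
    """Assert that no individual was scored by a model it helped fit.

    Recomputes, from the plan alone, the number of qualifying (test)
    iterations of every individual and checks it equals the count actually
    used in the WSR average; also checks every recorded modelling set is
    drawn from the declared pool and disjoint from its test set.
    """
    plan = profile.plan
    ids = list(profile.WSR.index)
    pool = set(plan.pool)
    expected = np.zeros(len(ids), dtype=int)
    for k, mset in enumerate(plan.modelling_sets):
        mset_set = set(mset)
        if not mset_set <= pool:
            raise LeakageError(f"iteration {k} models on samples outside the pool")
        for i, s in enumerate(ids):
            if s not in mset_set:
                expected[i] += 1
    actual = profile.n_test_iterations.loc[ids].to_numpy()
    if not np.array_equal(expected, actual):
        raise LeakageError("test-iteration counts disagree with the plan")
    if profile.iteration_records is not None:
        for k, rec in enumerate(profile.iteration_records):
            if set(rec.modelling_ids) & set(rec.test_ids):
                raise LeakageError(f"iteration {k} test set overlaps modelling set")
    return True
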