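import numpy as np
import pandas as pd
import pytest

from stoichsi import preprocess, si_core
from stoichsi.io_formats import SampleTable, ValidationError
from stoichsi.si_core import (
    LeakageError,
    PlanCoverageError,
    ResamplingPlan,
    aggregate_WSR,
    compute_wsr,
    fit_gene_model,
    make_plan,
    run_si,
    si_score,
    standardize_sWSR,
    verify_no_leakage,
)


def _sample_table(n, rng, n_cases=0):
    dx = ["BD"] * n_cases + ["HC"] * (n - n_cases)
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{j:03d}" for j in range(n)],
        "diagnosis": dx,
        "age": rng.uniform(20, 80, size=n),
        "sex": rng.choice(["M", "F"], size=n),
        "ethnicity": rng.choice(["E1", "E2"], size=n),
        "RIN": rng.uniform(5, 9, size=n),
        "PMI": rng.uniform(5, 50, size=n),
    }))


# ---------------------------------------------------------------------------
# resampling plan


def test_plan_split_sizes_match_cohort_layout():
    controls = [f"c{i}" for i in range(165)]
    plan = make_plan(controls, model_size=94, iterations=100, seed=0)
    assert plan.iterations == 100
    for mset in plan.modelling_sets:
        assert len(mset) == 94
        assert len(set(mset)) == 94
        assert set(mset) <= set(controls)
    # every control tested at least once
    tested = set()
    for mset in plan.modelling_sets:
        tested |= set(controls) - set(mset)
    assert tested == set(controls)


def test_plan_deterministic_under_seed():
    controls = [f"c{i}" for i in range(40)]
    p1 = make_plan(controls, 25, 20, seed=9)
    p2 = make_plan(controls, 25, 20, seed=9)
    for a, b in zip(p1.modelling_sets, p2.modelling_sets):
        np.testing.assert_array_equal(a, b)
    p3 = make_plan(controls, 25, 20, seed=10)
    assert any(not np.array_equal(a, b)
               for a, b in zip(p1.modelling_sets, p3.modelling_sets))


def test_plan_single_iteration_and_invalid_sizes():
    controls = [f"c{i}" for i in range(10)]
    plan = make_plan(controls, 6, 1, seed=1, ensure_coverage=False)
    assert plan.iterations == 1 and len(plan.modelling_sets[0]) == 6
    with pytest.raises(ValidationError):
        make_plan(controls, 10, 5, seed=1)


# ---------------------------------------------------------------------------
# gene models


def test_lasso_recovers_exact_linear_combination(rng):
    n, m = 6, 80
    samples = _sample_table(m, rng)
    X = rng.normal(5, 1, size=(m, n))
    X[:, 0] = 1.5 * X[:, 1] - 0.8 * X[:, 2] + 4.0  # exact, noise-free
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(n)],
                        columns=samples.sample_ids)
    model = fit_gene_model(expr, samples, target="g0",
                           modelling_ids=samples.sample_ids[:60], seed=0)
    assert model.r2 > 0.999
    support = {g for g, c in zip(model.predictor_genes, model.coef_genes)
               if abs(c) > 1e-3}
    assert {"g1", "g2"} <= support


def test_lasso_null_target_shrinks_all_gene_coefficients(rng):
    n, m = 8, 100
    samples = _sample_table(m, rng)
    X = rng.normal(5, 1, size=(m, n))  # target independent of the rest
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(n)],
                        columns=samples.sample_ids)
    model = fit_gene_model(expr, samples, target="g0",
                           modelling_ids=samples.sample_ids[:80], seed=0)
    assert model.r2 < 0.25
    assert np.all(np.abs(model.coef_genes) < 0.05)


def test_unpenalised_covariate_retained(rng):
    m = 80
    samples = _sample_table(m, rng)
    age = samples.table["age"].to_numpy()
    X = rng.normal(5, 1, size=(m, 4))
    X[:, 0] = 0.2 * age + rng.normal(0, 0.3, size=m)
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(4)],
                        columns=samples.sample_ids)
    model = fit_gene_model(expr, samples, target="g0",
                           modelling_ids=samples.sample_ids[:60], seed=0)
    age_idx = model.covariate_names.index("age")
    assert abs(model.coef_covariates[age_idx]) > 0.1  # never penalised away
    # and the model predicts well purely through the covariate
    assert model.r2 > 0.8


def test_gene_model_prediction_matches_training_fit(rng):
    samples = _sample_table(50, rng)
    X = rng.normal(5, 1, size=(50, 5))
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(5)],
                        columns=samples.sample_ids)
    ids = samples.sample_ids[:40]
    model = fit_gene_model(expr, samples, target="g2", modelling_ids=ids, seed=3)
    design = preprocess.covariate_design(samples).loc[ids].to_numpy()
    Xg = expr.drop(index="g2")[ids].to_numpy().T
    yhat = model.predict(Xg, design)
    r2 = np.corrcoef(yhat, expr.loc["g2", ids])[0, 1] ** 2
    assert r2 == pytest.approx(model.r2, abs=1e-10)


def test_constant_target_raises(rng):
    samples = _sample_table(30, rng)
    X = rng.normal(5, 1, size=(30, 3))
    X[:, 1] = 7.0
    expr = pd.DataFrame(X.T, index=["g0", "g1", "g2"], columns=samples.sample_ids)
    with pytest.raises(ValidationError):
        fit_gene_model(expr, samples, "g1", samples.sample_ids[:25], seed=0)


# ---------------------------------------------------------------------------
# Eq. 1-3 primitives


def test_wsr_arithmetic():
    assert compute_wsr(10.0, 9.0, 0.8, 10.0) == pytest.approx(0.08)
    assert compute_wsr(7.3, 7.3, 0.9, 5.0) == 0.0  # perfect prediction
    assert compute_wsr(10.0, 3.0, 0.0, 5.0) == 0.0  # uninformative model
    with pytest.raises(ValidationError):
        compute_wsr(1.0, 0.5, 0.5, 0.0)


def test_aggregate_wsr_hand_computed_plan():
    """Control in the modelling set for iterations 0,1 of 4: its WSR averages
    iterations 2,3 only; a case averages all four."""
    ids = ["case", "ctrl"]
    plan = ResamplingPlan(
        modelling_sets=[np.array(["ctrl"]), np.array(["ctrl"]),
                        np.array(["x"]), np.array(["x"])],
        pool=["ctrl", "x"], model_size=1, seed=0)
    wsr = np.full((4, 2, 1), np.nan)
    wsr[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]  # case: tested every iteration
    wsr[2:, 1, 0] = [10.0, 20.0]  # control: tested only in iterations 2,3
    WSR = aggregate_WSR(wsr, plan, ids)
    assert WSR[0, 0] == pytest.approx(2.5)
    assert WSR[1, 0] == pytest.approx(15.0)


def test_aggregate_wsr_single_iteration_and_coverage_error():
    ids = ["a", "b"]
    plan = ResamplingPlan([np.array(["b"])], pool=["a", "b"], model_size=1, seed=0)
    wsr = np.full((1, 2, 1), np.nan)
    wsr[0, 0, 0] = 0.7
    with pytest.raises(PlanCoverageError):
        aggregate_WSR(wsr, plan, ids)  # b never tested
    plan2 = ResamplingPlan([np.array(["b"]), np.array(["a"])],
                           pool=["a", "b"], model_size=1, seed=0)
    wsr2 = np.full((2, 2, 1), np.nan)
    wsr2[0, 0, 0] = 0.7
    wsr2[1, 1, 0] = -0.2
    WSR = aggregate_WSR(wsr2, plan2, ids)
    np.testing.assert_allclose(WSR[:, 0], [0.7, -0.2])


def test_swsr_affine_invariance(rng):
    WSR = pd.DataFrame(rng.normal(size=(30, 4)),
                       index=[f"s{i}" for i in range(30)],
                       columns=[f"g{i}" for i in range(4)])
    dx = np.array(["HC"] * 20 + ["BD"] * 10)
    s1 = standardize_sWSR(WSR, dx)
    s2 = standardize_sWSR(3.0 * WSR + 1.7, dx)
    np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-10)


def test_si_score_arithmetic():
    assert si_score(np.array([0.0, 0.0, 0.0])) == 0.0
    assert si_score(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0
    assert si_score(np.array([2.0, 0.0, 0.0, 0.0])) == 0.5


# ---------------------------------------------------------------------------
# full pipeline properties


def test_full_pipeline_matches_brute_force_recomputation(rng):
    """4 genes, 20 samples, 2 iterations: the pipeline's WSR/sWSR/SI equal an
    independent loop-based recomputation of the three defining equations from
    the per-iteration model outputs, to 1e-10."""
    samples = _sample_table(20, rng, n_cases=6)
    X = rng.normal(6, 1, size=(20, 4))
    X[:, 0] += 0.8 * X[:, 1]
    expr = pd.DataFrame(X.T, index=[f"g{i}" for i in range(4)],
                        columns=samples.sample_ids)
    controls = [s for s, d in zip(samples.sample_ids, samples.diagnosis) if d == "HC"]
    plan = make_plan(controls, model_size=7, iterations=2, seed=7)
    profile = run_si(expr, samples, plan=plan, n_lambda=10,
                     keep_iteration_records=True)

    ids = list(profile.WSR.index)
    genes = profile.genes
    dx = profile.diagnosis
    y_obs = expr.loc[genes, ids].to_numpy().T
    gene_mean = y_obs.mean(axis=0)  # over all individuals

    # brute force: explicit loops over (k, i, j)
    p = profile.plan.iterations
    wsr = np.full((p, len(ids), len(genes)), np.nan)
    for k, rec in enumerate(profile.iteration_records):
        for ti, sid in enumerate(rec.test_ids):
            i = ids.index(sid)
            for j in range(len(genes)):
                wsr[k, i, j] = (rec.r2[j] * (y_obs[i, j] - rec.y_pred[ti, j])
                                / gene_mean[j])
    counts = np.zeros(len(ids))
    WSR_bf = np.zeros((len(ids), len(genes)))
    for i, sid in enumerate(ids):
        ks = [k for k in range(p)
              if sid not in set(profile.plan.modelling_sets[k])]
        assert ks, "every individual must be tested at least once"
        WSR_bf[i] = wsr[ks, i, :].mean(axis=0)
        counts[i] = len(ks)
    hc = WSR_bf[(dx == "HC").to_numpy()]
    sWSR_bf = (WSR_bf - hc.mean(axis=0)) / hc.std(axis=0, ddof=1)
    si_bf = np.abs(sWSR_bf).mean(axis=1)

    np.testing.assert_allclose(profile.WSR.to_numpy(), WSR_bf, atol=1e-10)
    np.testing.assert_allclose(profile.sWSR.to_numpy(), sWSR_bf, atol=1e-10)
    np.testing.assert_allclose(profile.si.to_numpy(), si_bf, atol=1e-10)
    np.testing.assert_array_equal(profile.n_test_iterations.to_numpy(), counts)


def test_leakage_audit_passes_and_detects_violation(null_expr):
    expr, samples = null_expr
    profile = run_si(expr, samples, iterations=5, seed=2, n_lambda=8)
    assert verify_no_leakage(profile)
    # corrupt the audit trail: claim one fewer test iteration
    profile.n_test_iterations.iloc[0] += 1
    with pytest.raises(LeakageError):
        verify_no_leakage(profile)


def test_si_invariant_to_gene_and_sample_order(null_expr):
    expr, samples = null_expr
    base = run_si(expr, samples, iterations=4, seed=5, n_lambda=8)
    rng = np.random.default_rng(0)
    gperm = rng.permutation(expr.shape[0])
    sperm = rng.permutation(expr.shape[1])
    shuffled = expr.iloc[gperm, sperm]
    other = run_si(shuffled, samples, iterations=4, seed=5, n_lambda=8)
    np.testing.assert_allclose(base.si.loc[base.si.index].to_numpy(),
                               other.si.loc[base.si.index].to_numpy(), atol=1e-9)


def test_case_si_monotone_in_delta():
    """Mean case SI is non-decreasing in the perturbation size delta."""
    from stoichsi.synthetic_data import SimConfig, generate_cohort, panel_gene_ids

    means = []
    for delta in (0.0, 2.0, 4.0):
        cfg = SimConfig(n_genes=16, module_spec=[(6, 0.7), (4, -0.5)],
                        cohorts=[(12, 30)], delta=delta,
                        imbalance_rate_lambda=3.0, seed=11)
        dataset, samples, _ = generate_cohort(cfg, 0)
        expr = preprocess.to_log2_rpkm(dataset).log2_rpkm
        expr = expr.loc[panel_gene_ids(expr.index)]
        profile = run_si(expr, samples, iterations=6, seed=3, n_lambda=10)
        means.append(float(profile.si[profile.diagnosis == "BD"].mean()))
    assert means[0] <= means[1] <= means[2]


def test_perturbed_genes_have_largest_case_swsr(imbalanced_cohort):
    """Injected genes are enriched among the genes with the largest mean
    absolute case sWSR (rank enrichment)."""
    from stoichsi.synthetic_data import panel_gene_ids

    dataset, samples, truth = imbalanced_cohort
    expr = preprocess.to_log2_rpkm(dataset).log2_rpkm
    expr = expr.loc[panel_gene_ids(expr.index)]
    profile = run_si(expr, samples, iterations=8, seed=4, n_lambda=10)
    case_ids = [s for s, d in zip(profile.sWSR.index, profile.diagnosis) if d == "BD"]
    perturbed_ranks, other_ranks = [], []
    gene_rank = {}
    for sid in case_ids:
        row = profile.sWSR.loc[sid].abs().rank(ascending=False)
        hit = truth.genes_for(sid) & set(row.index)
        for g in row.index:
            (perturbed_ranks if g in hit else other_ranks).append(row[g])
    assert np.mean(perturbed_ranks) < np.mean(other_ranks) - 1.0


def test_model_on_cases_mode_standardizes_by_cases(imbalanced_cohort):
    from stoichsi.synthetic_data import panel_gene_ids

    dataset, samples, _ = imbalanced_cohort
    expr = preprocess.to_log2_rpkm(dataset).log2_rpkm
    expr = expr.loc[panel_gene_ids(expr.index)]
    profile = run_si(expr, samples, mode="model_on_cases", iterations=6,
                     model_size=9, seed=6, n_lambda=8)
    bd = profile.sWSR[profile.diagnosis == "BD"]
    np.testing.assert_allclose(bd.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(bd.std(axis=0, ddof=1), 1, atol=1e-10)


def test_hc_split_null_balanced_groups(null_expr):
    expr, samples = null_expr
    profile = run_si(expr, samples, mode="hc_split_null", iterations=6,
                     seed=8, n_lambda=8)
    # only controls involved, split into pseudo-groups
    assert set(profile.diagnosis) == {"HC", "BD"}
    assert len(profile.si) == int((samples.diagnosis == "HC").sum())
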