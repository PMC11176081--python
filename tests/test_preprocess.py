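import numpy as np
import pandas as pd
import pytest

from stoichsi import preprocess as pp
from stoichsi.io_formats import CountDataset, SampleTable, ValidationError


def _dataset(counts, lengths=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    lengths = np.full(n_genes, 1000) if lengths is None else np.asarray(lengths)
    return CountDataset([f"g{i}" for i in range(n_genes)],
                        [f"s{j}" for j in range(n_samples)], counts, lengths)


# ---------------------------------------------------------------------------
# TMM


def _tmm_fixture():
    """Seeded 100-gene, 6-sample matrix with a composition-biased last sample."""
    rng = np.random.default_rng(20240917)
    base = rng.gamma(2.0, 50.0, size=100)
    depth = rng.uniform(0.5, 2.0, size=6)
    counts = rng.poisson(base[:, None] * depth[None, :]).astype(int)
    counts[:50, 5] *= 3
    return counts

# edgeR::calcNormFactors(method="TMM") on the exact fixture above
EDGER_FACTORS = np.array([1.0178218428, 1.0210436733, 1.0230469089,
                          1.0091426200, 1.0183047318, 0.9152886074])


def test_tmm_matches_edger_reference():
    np.testing.assert_allclose(pp.tmm_factors(_tmm_fixture()), EDGER_FACTORS,
                               atol=1e-8)


def test_tmm_identical_and_depth_scaled_libraries():
    rng = np.random.default_rng(0)
    col = rng.poisson(100, size=200)
    col[col == 0] = 1
    same = np.column_stack([col, col])
    np.testing.assert_allclose(pp.tmm_factors(same), [1.0, 1.0], atol=1e-12)
    # depth differs, composition identical -> still (1, 1)
    doubled = np.column_stack([col, 2 * col])
    np.testing.assert_allclose(pp.tmm_factors(doubled), [1.0, 1.0], atol=1e-12)


def test_tmm_brute_force_oracle_on_composition_shift():
    """Factor matches a directly coded trimmed weighted mean of M values."""
    rng = np.random.default_rng(7)
    a = rng.poisson(200, size=200) + 1
    b = a.copy()
    b[:100] *= 2  # half of B's genes doubled
    counts = np.column_stack([a, b])
    factors = pp.tmm_factors(counts)

    # independent brute force, reference = sample A (f75 ties resolved equally)
    lib_a, lib_b = a.sum(), b.sum()
    f75 = [np.quantile(a, 0.75) / lib_a, np.quantile(b, 0.75) / lib_b]
    ref = int(np.argmin(np.abs(np.array(f75) - np.mean(f75))))
    obs, lo = (b, lib_b) if ref == 0 else (a, lib_a)
    refc, lr = (a, lib_a) if ref == 0 else (b, lib_b)
    m = np.log2((obs / lo) / (refc / lr))
    av = 0.5 * np.log2((obs / lo) * (refc / lr))
    w = (lo - obs) / (lo * obs) + (lr - refc) / (lr * refc)
    n = m.size
    from scipy.stats import rankdata
    rm, ra = rankdata(m), rankdata(av)
    keep = ((rm >= np.floor(n * 0.3) + 1) & (rm <= n - np.floor(n * 0.3))
            & (ra >= np.floor(n * 0.05) + 1) & (ra <= n - np.floor(n * 0.05)))
    f_other = 2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    expected = np.array([1.0, f_other] if ref == 0 else [f_other, 1.0])
    expected /= np.exp(np.mean(np.log(expected)))
    np.testing.assert_allclose(factors, expected, rtol=1e-10)


def test_tmm_scaling_one_library_preserves_other_ratios():
    """Depth-scaling a (non-reference) library leaves the others' factor
    ratios unchanged: TMM responds to composition, not depth."""
    counts = _tmm_fixture()
    lib = counts.sum(axis=0)
    f75 = np.array([np.quantile(counts[:, s], 0.75) / lib[s] for s in range(6)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    scale_me = (ref + 1) % 6
    f0 = pp.tmm_factors(counts)
    scaled = counts.copy()
    scaled[:, scale_me] *= 4
    f1 = pp.tmm_factors(scaled)
    others = [i for i in range(6) if i != scale_me]
    for i in others:
        for j in others:
            np.testing.assert_allclose(f1[i] / f1[j], f0[i] / f0[j], rtol=1e-9)


def test_tmm_rejects_all_zero_sample():
    counts = np.array([[1, 0], [2, 0]])
    with pytest.raises(ValidationError):
        pp.tmm_factors(counts)


# ---------------------------------------------------------------------------
# RPKM


def test_log2_rpkm_arithmetic():
    # column sums to 1e7; gene 0: count 1000, length 2000 -> RPKM 50
    counts = np.array([[1000, 1000], [9999000, 9999000]])
    ds = _dataset(counts, lengths=[2000, 1000])
    norm = pp.to_log2_rpkm(ds, tmm_factor=np.array([1.0, 1.0]), pseudocount=0.0)
    assert norm.log2_rpkm.iloc[0, 0] == pytest.approx(np.log2(50), abs=1e-9)
    assert np.log2(50) == pytest.approx(5.6438, abs=1e-3)


def test_log2_rpkm_zero_count_with_unit_pseudocount():
    counts = np.array([[0, 0], [100, 100]])
    ds = _dataset(counts)
    norm = pp.to_log2_rpkm(ds, tmm_factor=np.array([1.0, 1.0]), pseudocount=1.0)
    assert (norm.log2_rpkm.iloc[0] == 0).all()


def test_rpkm_depth_invariance():
    counts = np.array([[50, 100], [950, 1900]])  # second column = 2x first
    ds = _dataset(counts)
    norm = pp.to_log2_rpkm(ds, tmm_factor=np.array([1.0, 1.0]), pseudocount=0.0)
    np.testing.assert_allclose(norm.log2_rpkm["s0"], norm.log2_rpkm["s1"], rtol=1e-12)


# ---------------------------------------------------------------------------
# low-expression filter


def test_filter_boundary_of_30_percent_rule():
    """Gene above threshold in 7/10 samples kept; in 6/10 removed."""
    lib_target = 1_000_000
    n = 10
    counts = np.zeros((3, n), dtype=int)
    counts[0] = [10] * 7 + [0] * 3  # low in exactly 30% -> kept
    counts[1] = [10] * 6 + [0] * 4  # low in 40% -> removed
    counts[2] = lib_target - counts[0] - counts[1]  # filler fixes library size
    ds = _dataset(counts)
    keep = pp.filter_low_expression(ds)
    assert keep[0] and not keep[1] and keep[2]


def test_filter_all_zero_gene_removed_high_gene_kept():
    counts = np.vstack([np.zeros(5, int), np.full(5, 1000)])
    keep = pp.filter_low_expression(_dataset(counts))
    assert list(keep) == [False, True]


def test_filter_monotone_in_counts():
    rng = np.random.default_rng(3)
    counts = rng.poisson(8, size=(30, 12))
    ds = _dataset(counts)
    keep = pp.filter_low_expression(ds)
    bumped = pp.filter_low_expression(_dataset(counts + 5))
    assert np.all(bumped[keep])  # adding counts never removes a kept gene


# ---------------------------------------------------------------------------
# residualization


def _samples(n, rng, ethnicity_levels=("E1", "E2")):
    return SampleTable(pd.DataFrame({
        "sample_id": [f"s{j}" for j in range(n)],
        "diagnosis": rng.choice(["BD", "HC"], size=n),
        "age": rng.uniform(20, 80, size=n),
        "sex": rng.choice(["M", "F"], size=n),
        "ethnicity": rng.choice(list(ethnicity_levels), size=n),
        "RIN": rng.uniform(5, 9, size=n),
        "PMI": rng.uniform(5, 50, size=n),
    }))


def test_residualize_removes_age_effect_and_is_orthogonal(rng):
    n = 120
    samples = _samples(n, rng)
    age = samples.table["age"].to_numpy()
    expr = 2.0 * age + rng.normal(0, 1.0, size=n)
    mat = pd.DataFrame([expr], index=["g0"], columns=samples.sample_ids)
    res = pp.residualize_absolute(mat, samples)
    resid = res.residual.iloc[0].to_numpy()
    assert np.var(resid) < 0.05 * np.var(expr)
    assert abs(np.dot(resid, age - age.mean())) < 1e-6 * n


def test_residualize_without_covariate_effects_centers(rng):
    samples = _samples(40, rng)
    expr = rng.normal(5, 1, size=40)
    mat = pd.DataFrame([expr], index=["g0"], columns=samples.sample_ids)
    resid = pp.residualize_absolute(mat, samples).residual.iloc[0]
    assert abs(resid.mean()) < 1e-10  # intercept removed


def test_single_ethnicity_cohort_drops_constant_column(rng):
    samples = _samples(40, rng, ethnicity_levels=("E1",))
    expr = rng.normal(5, 1, size=(3, 40))
    mat = pd.DataFrame(expr, index=["g0", "g1", "g2"], columns=samples.sample_ids)
    res = pp.residualize_absolute(mat, samples)
    assert not any("ethnicity" in c for c in res.covariates_used)


# ---------------------------------------------------------------------------
# PCA screen


def test_pca_screen_flags_displaced_sample(rng):
    X = rng.normal(0, 1, size=(30, 50))
    X[:, 7] += 20.0  # displaced on the dominant axis
    mat = pd.DataFrame(X, columns=[f"s{j}" for j in range(50)])
    _, flagged = pp.pca_screen(mat)
    assert flagged["s7"]
    assert flagged.sum() == 1


def test_pca_screen_order_invariant(rng):
    X = rng.normal(0, 1, size=(20, 40))
    X[:, 3] += 15.0
    mat = pd.DataFrame(X, columns=[f"s{j}" for j in range(40)])
    _, f1 = pp.pca_screen(mat)
    perm = rng.permutation(40)
    _, f2 = pp.pca_screen(mat.iloc[:, perm])
    assert set(f1[f1].index) == set(f2[f2].index)


def test_pca_screen_false_positive_rate_below_1pct():
    flags = total = 0
    for seed in range(25):
        r = np.random.default_rng(seed)
        mat = pd.DataFrame(r.normal(0, 1, size=(25, 60)))
        _, flagged = pp.pca_screen(mat)
        flags += int(flagged.sum())
        total += 60
    assert flags / total < 0.01


# ---------------------------------------------------------------------------
# HC standardization


def test_standardize_by_hc_moments_and_cases():
    rng = np.random.default_rng(5)
    mat = pd.DataFrame(rng.normal(3, 2, size=(4, 40)),
                       columns=[f"s{j}" for j in range(40)])
    dx = np.array(["HC"] * 30 + ["BD"] * 10)
    out = pp.standardize_by_hc(mat, dx)
    hc = out.loc[:, dx == "HC"]
    np.testing.assert_allclose(hc.mean(axis=1), 0, atol=1e-12)
    np.testing.assert_allclose(hc.std(axis=1, ddof=1), 1, atol=1e-12)
    # a case exactly at the HC mean maps to 0; at mean + 2 sd maps to 2
    mu = mat.loc[0, dx == "HC"].mean()
    sd = mat.loc[0, dx == "HC"].std(ddof=1)
    mat2 = mat.copy()
    mat2.iloc[0, 30] = mu
    mat2.iloc[0, 31] = mu + 2 * sd
    out2 = pp.standardize_by_hc(mat2, dx)
    assert out2.iloc[0, 30] == pytest.approx(0, abs=1e-12)
    assert out2.iloc[0, 31] == pytest.approx(2, abs=1e-12)


def test_standardize_idempotent_on_hc():
    rng = np.random.default_rng(6)
    mat = pd.DataFrame(rng.normal(size=(3, 25)))
    dx = np.array(["HC"] * 25)
    once = pp.standardize_by_hc(mat, dx)
    twice = pp.standardize_by_hc(once, dx)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_standardize_drops_zero_variance_gene():
    mat = pd.DataFrame([[1.0] * 10, list(range(10))])
    dx = np.array(["HC"] * 6 + ["BD"] * 4)
    out = pp.standardize_by_hc(mat, dx)
    assert 0 not in out.index and 1 in out.index
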