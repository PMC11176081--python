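import numpy as np
import pytest

from stoichsi import preprocess
from stoichsi.synthetic_data import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with co-expression structure but no injected imbalance."""
    cfg = SimConfig(n_genes=16, module_spec=[(6, 0.7), (4, -0.5)],
                    cohorts=[(12, 30)], delta=0.0, seed=11)
    return generate_cohort(cfg, 0)


@pytest.fixture(scope="session")
def imbalanced_cohort():
    """Small cohort with strong injected imbalance (delta=3, lambda=3)."""
    cfg = SimConfig(n_genes=16, module_spec=[(6, 0.7), (4, -0.5)],
                    cohorts=[(14, 32)], delta=3.0, imbalance_rate_lambda=3.0, seed=12)
    return generate_cohort(cfg, 0)


@pytest.fixture(scope="session")
def null_expr(null_cohort):
    """log2 RPKM of the analysis panel (background filler dropped)."""
    dataset, samples, _ = null_cohort
    from stoichsi.synthetic_data import panel_gene_ids

    expr = preprocess.to_log2_rpkm(dataset).log2_rpkm
    return expr.loc[panel_gene_ids(expr.index)], samples


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: results never depend on the
    order in which tests consume random draws."""
    return np.random.default_rng(42)
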