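"""Synthetic multi-cohort RNA-seq generator with stoichiometric structure.

Emulates the features of case-control brain cohorts that the downstream
analysis relies on: several cohorts with realistic case/control sizes, a large
positively co-expressed gene module plus smaller modules anti-correlated with
it, covariate effects on expression (age, sex, ethnicity, RIN, PMI), negative
binomial counts, and -- in cases only -- sparse perturbation of a few genes'
latent expression *conditional on the shared module factor*, so that a
perturbed gene leaves its stoichiometric relation with its partners while the
module as a whole is unchanged.

Every generated case carries a ground-truth record of which genes were
perturbed and by how much (:class:`TruthTable`), which the generator's
consumers use to validate signal recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stoichsi.io_formats import (
    CountDataset,
    LocusGeneTable,
    SampleTable,
    write_counts,
    write_gene_lengths,
    write_samples,
)

#: cohort (n_cases, n_controls) defaults: four cortical case-control datasets
DEFAULT_COHORTS = [(71, 165), (35, 93), (73, 75), (125, 142)]

#: (module size, signed within-module correlation target); a negative sign
#: makes the module load negatively on the shared factor, i.e. anti-correlated
#: with the positive modules.  Strengths chosen so that gene models reach the
#: fit quality reported for real cortical cohorts (many R^2 above 0.75).
DEFAULT_MODULES = [(24, 0.8), (10, -0.65), (7, -0.6), (5, 0.65)]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    delta is the perturbation magnitude in units of the gene's healthy-control
    residual SD (residual = latent log2 expression conditional on the module
    factor and covariates); imbalance_rate_lambda is the Poisson mean of the
    number of perturbed genes per case.

    ``n_background_genes`` adds independently expressed genes (ids prefixed
    ``BG``) that carry most of the library mass, as in real bulk RNA-seq where
    the analysis panel is a tiny fraction of the transcriptome.  Without them,
    per-sample normalisation (library size, RPKM) would absorb the shared
    module factor and destroy the very co-expression the panel is built to
    show.  Background genes are never perturbed and are excluded from the
    analysis gene set.
    """

    n_genes: int = 54
    n_background_genes: int = 300
    module_spec: list[tuple[int, float]] = field(default_factory=lambda: list(DEFAULT_MODULES))
    cohorts: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_COHORTS))
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"age": 0.10, "sex": 0.10, "ethnicity": 0.05,
                                 "RIN": 0.15, "PMI": 0.05})
    imbalance_rate_lambda: float = 3.0
    delta: float = 2.0
    #: "per_gene": each gene has a fixed disease direction shared by all cases
    #: perturbed in it (matching the consistent per-gene over/under-expression
    #: seen in real cohorts); "per_pair": direction drawn independently per
    #: gene-case pair (no gene-level directional signal).
    sign_mode: str = "per_gene"
    #: perturb only genes that belong to a co-expression module (imbalance is
    #: a property of a gene's relation to its partners; a gene without
    #: partners has no stoichiometric relation to break)
    perturb_module_genes_only: bool = True
    #: SD of a per-cohort coherent shift of the case group's module-factor
    #: mean.  Emulates disease-linked global expression differences in
    #: post-mortem brain (medication, agonal state, cell composition) that
    #: move whole modules coherently: they confound absolute expression
    #: within a cohort but leave each gene's relation to its partners -- and
    #: hence the residuals -- unchanged, and they do not replicate across
    #: cohorts.
    case_factor_shift: float = 0.25
    #: per-cohort probability that a module gene decouples from its module
    #: (loading set to 0, variance reverting to idiosyncratic).  Emulates the
    #: partial replication of co-expression across cohorts from different
    #: brain regions and preps.
    module_dropout: float = 0.15
    #: Zipf exponent concentrating which genes get perturbed: selection
    #: probability of the g-th most-often-hit gene is proportional to
    #: (g+1)^-perturb_concentration.  0 gives uniform selection; the default
    #: reproduces the observed pattern of a modest set of frequently
    #: imbalanced driver genes (top gene imbalanced in ~20% of cases) with a
    #: long tail.
    perturb_concentration: float = 0.9
    nb_dispersion: float = 0.01
    lib_size_range: tuple[int, int] = (200_000, 600_000)
    gene_length_range: tuple[int, int] = (500, 8000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if sum(size for size, _ in self.module_spec) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for _, r in self.module_spec:
            if not -1.0 <= r <= 1.0:
                raise ValueError("module correlations must lie in [-1, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.imbalance_rate_lambda < 0:
            raise ValueError("imbalance_rate_lambda must be >= 0")
        for n_cases, n_controls in self.cohorts:
            if n_cases < 0 or n_controls < 1:
                raise ValueError("cohorts need n_cases >= 0 and n_controls >= 1")
        if self.sign_mode not in ("per_gene", "per_pair"):
            raise ValueError("sign_mode must be 'per_gene' or 'per_pair'")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohorts)


@dataclass
class TruthTable:
    """Ground truth of the injected imbalance: per case, the perturbed genes.

    ``perturbations`` maps case sample id to a list of ``(gene_id, signed
    shift)`` pairs where the shift is in HC-residual-SD units (sign x delta).
    Controls never appear.
    """

    perturbations: dict[str, list[tuple[str, float]]]

    def genes_for(self, sample_id: str) -> set[str]:
        return {g for g, _ in self.perturbations.get(sample_id, [])}

    @property
    def n_perturbed(self) -> dict[str, int]:
        return {s: len(v) for s, v in self.perturbations.items()}


def _cohort_rng(config: SimConfig, cohort_index: int) -> np.random.Generator:
    """Per-cohort generator derived deterministically from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, cohort_index]))


def _gene_params(config: SimConfig):
    """Gene-level parameters shared across cohorts (drawn from the master seed).

    Returns baseline log2 expression, factor loadings, residual SDs and gene
    lengths.  Within a module with target correlation r and total latent SD s,
    the loading is sign(r) * s * sqrt(|r|) and the residual SD s * sqrt(1-|r|),
    which gives pairwise latent correlation r inside the module.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_000]))
    n = config.n_genes
    baseline = rng.uniform(2.0, 8.0, size=n)  # log2 RPKM-like scale
    total_sd = rng.uniform(0.4, 1.0, size=n)
    loading = np.zeros(n)
    resid_sd = total_sd.copy()
    pos = 0
    for size, r in config.module_spec:
        sl = slice(pos, pos + size)
        loading[sl] = np.sign(r) * total_sd[sl] * np.sqrt(abs(r))
        resid_sd[sl] = total_sd[sl] * np.sqrt(1.0 - abs(r))
        pos += size
    lengths = rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                           size=n)
    slopes = {}
    for cov, scale in config.covariate_effect_sizes.items():
        slopes[cov] = rng.normal(0.0, scale, size=n)
    # disease direction per gene, shared across cohorts and cases
    disease_sign = rng.choice([-1.0, 1.0], size=n)
    # propensity ordering for concentrated perturbation (shared across cohorts)
    perturb_order = rng.permutation(n)
    # independent background transcriptome (no module factor, no perturbation)
    nb = config.n_background_genes
    bg = {
        "baseline": rng.uniform(2.0, 8.0, size=nb),
        "sd": rng.uniform(0.2, 0.6, size=nb),
        "lengths": rng.integers(config.gene_length_range[0],
                                config.gene_length_range[1] + 1, size=nb),
        "slopes": {cov: rng.normal(0.0, scale, size=nb)
                   for cov, scale in config.covariate_effect_sizes.items()},
    }
    return baseline, loading, resid_sd, lengths, slopes, disease_sign, perturb_order, bg


def generate_cohort(config: SimConfig, cohort_index: int, return_debug: bool = False):
    """Generate one cohort: counts, metadata and the perturbation truth table.

    Latent log2 expression of gene g in sample i is

        baseline_g + loading_g * F_i + sum_c slope_cg * z_ic + eps_ig
        (+ sign * delta * resid_sd_g for perturbed genes of cases)

    with F_i a standard-normal per-sample module factor, z_ic standardized
    covariates and eps_ig ~ N(0, resid_sd_g^2).  Expected counts allocate the
    sample's library size across genes proportionally to
    2^latent x gene length, and observed counts are negative binomial
    (gamma-Poisson) with dispersion ``nb_dispersion``.
    """
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} out of range")
    n_cases, n_controls = config.cohorts[cohort_index]
    m = n_cases + n_controls
    n = config.n_genes
    nb = config.n_background_genes
    rng = _cohort_rng(config, cohort_index)
    (baseline, loading, resid_sd, lengths, slopes, disease_sign,
     perturb_order, bg) = _gene_params(config)

    sample_ids = [f"C{cohort_index}S{i:04d}" for i in range(m)]
    diagnosis = np.array(["BD"] * n_cases + ["HC"] * n_controls)
    gene_ids = [f"G{j:03d}" for j in range(n)] + [f"BG{j:04d}" for j in range(nb)]

    covs = pd.DataFrame({
        "sample_id": sample_ids,
        "diagnosis": diagnosis,
        "age": np.round(rng.uniform(18.0, 90.0, size=m), 1),
        "sex": rng.choice(["M", "F"], size=m),
        "ethnicity": rng.choice(["CAUC", "OTHER"], size=m, p=[0.8, 0.2]),
        "RIN": np.round(rng.uniform(5.0, 9.0, size=m), 2),
        "PMI": np.round(rng.uniform(5.0, 50.0, size=m), 1),
    })

    # co-expression varies between cohorts (different regions and preps in
    # real data): loadings are jittered per cohort and a fraction of module
    # genes decouple entirely, reverting to idiosyncratic variance.  The
    # within-cohort module structure is preserved but the absolute covariance
    # no longer transfers exactly across cohorts.
    total_sd = np.sqrt(loading ** 2 + resid_sd ** 2)
    loading = loading * rng.uniform(0.7, 1.3, size=n)
    decoupled = (loading != 0) & (rng.random(n) < config.module_dropout)
    loading = np.where(decoupled, 0.0, loading)
    resid_sd = np.where(decoupled, total_sd, resid_sd)
    factor = rng.standard_normal(m)
    # coherent, cohort-specific case-group shift along the module factor
    factor[:n_cases] += rng.normal(0.0, config.case_factor_shift)
    latent = baseline[None, :] + factor[:, None] * loading[None, :]
    for cov, slope in slopes.items():
        raw = covs[cov]
        if raw.dtype.kind in "ifu":
            z = (raw - raw.mean()) / (raw.std(ddof=0) or 1.0)
        else:
            x = (raw == sorted(raw.unique())[-1]).astype(float)
            z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        latent += np.outer(z.to_numpy(), slope)
    eps = rng.standard_normal((m, n)) * resid_sd[None, :]
    latent += eps

    n_module = sum(size for size, _ in config.module_spec)
    perturbable = np.arange(n_module if (config.perturb_module_genes_only
                                         and n_module > 0) else n)
    # concentrated propensities: a stable subset of driver genes is hit often
    ranks = np.empty(n, dtype=float)
    ranks[perturb_order] = np.arange(1, n + 1)
    weights = ranks[perturbable] ** -config.perturb_concentration
    weights /= weights.sum()
    perturbations: dict[str, list[tuple[str, float]]] = {}
    for i in range(n_cases):
        k = min(int(rng.poisson(config.imbalance_rate_lambda)), perturbable.size)
        genes = rng.choice(perturbable, size=k, replace=False, p=weights)
        if config.sign_mode == "per_gene":
            signs = disease_sign[genes]
        else:
            signs = rng.choice([-1.0, 1.0], size=k)
        entries = []
        for g, s in zip(genes, signs):
            if config.delta > 0:
                latent[i, g] += s * config.delta * resid_sd[g]
                eps[i, g] += s * config.delta * resid_sd[g]
                entries.append((gene_ids[g], float(s * config.delta)))
        perturbations[sample_ids[i]] = entries

    # background latent expression: covariate effects + noise, no module factor
    bg_latent = bg["baseline"][None, :] + np.zeros((m, nb))
    for cov, slope in bg["slopes"].items():
        raw = covs[cov]
        if raw.dtype.kind in "ifu":
            z = (raw - raw.mean()) / (raw.std(ddof=0) or 1.0)
        else:
            x = (raw == sorted(raw.unique())[-1]).astype(float)
            z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        bg_latent += np.outer(z.to_numpy(), slope)
    bg_latent += rng.standard_normal((m, nb)) * bg["sd"][None, :]

    latent = np.hstack([latent, bg_latent])
    lengths = np.concatenate([lengths, bg["lengths"]])
    lib = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, size=m)
    weights = (2.0 ** latent) * lengths[None, :]
    expected = weights / weights.sum(axis=1, keepdims=True) * lib[:, None]
    phi = config.nb_dispersion
    if phi > 0:
        mean_nb = rng.gamma(shape=1.0 / phi, scale=expected * phi)
    else:
        mean_nb = expected
    counts = rng.poisson(mean_nb).T.astype(np.int64)  # genes x samples

    dataset = CountDataset(gene_ids=gene_ids, sample_ids=sample_ids,
                           counts=counts, gene_length_bp=lengths)
    samples = SampleTable(covs)
    truth = TruthTable(perturbations=perturbations)
    if return_debug:
        # ground-truth internals for validation: the latent conditional
        # residuals (the quantity the SI pipeline estimates), factor, loadings
        debug = {"residual": eps, "factor": factor,
                 "loading": loading, "resid_sd": resid_sd}
        return dataset, samples, truth, debug
    return dataset, samples, truth


def write_fixture(dataset: CountDataset, samples: SampleTable, truth: TruthTable,
                  dir_path) -> dict[str, Path]:
    """Write a cohort as TSV + JSON files; round-trips through the io readers."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": dir_path / "counts.tsv",
        "samples": dir_path / "samples.tsv",
        "gene_lengths": dir_path / "gene_lengths.tsv",
        "truth": dir_path / "truth.json",
    }
    write_counts(dataset, paths["counts"])
    write_samples(samples, paths["samples"])
    write_gene_lengths(dataset, paths["gene_lengths"])
    with open(paths["truth"], "w") as fh:
        json.dump({s: [[g, d] for g, d in v] for s, v in truth.perturbations.items()},
                  fh, indent=0, sort_keys=True)
        fh.write("\n")
    return paths


def panel_gene_ids(gene_ids) -> list[str]:
    """Analysis-panel genes: everything except the ``BG`` background filler."""
    return [g for g in gene_ids if not str(g).startswith("BG")]


def read_truth(path) -> TruthTable:
    with open(path) as fh:
        raw = json.load(fh)
    return TruthTable({s: [(g, float(d)) for g, d in v] for s, v in raw.items()})


# ---------------------------------------------------------------------------
# synthetic locus-to-gene table


def synthetic_locus_table(seed: int = 0) -> LocusGeneTable:
    """Synthetic stand-in for a published GWAS locus-to-gene table.

    Reproduces the documented structure of the bipolar-disorder GWAS gene-set
    construction: 64 loci of which 39 have a protein-coding gene with
    L2G > 0.5 (two of them with a second gene at nearly identical L2G, both
    kept), 21 fall back to the nearest protein-coding gene, 4 contain no
    protein-coding gene, and one gene is shared between two loci -- yielding
    61 unique genes.  The gene identities are synthetic; only the selection
    structure is meaningful.
    """
    rng = np.random.default_rng(seed)
    rows = []
    gene_counter = 0

    def new_gene():
        nonlocal gene_counter
        gene_counter += 1
        return f"LG{gene_counter:04d}"

    shared_gene = None
    # 39 loci resolved by L2G; loci 0 and 1 carry a near-tie second gene
    for locus in range(39):
        top = new_gene()
        top_l2g = rng.uniform(0.55, 0.95)
        rows.append((f"locus{locus:02d}", top, 1, top_l2g, int(rng.integers(0, 5e5))))
        if locus < 2:
            rows.append((f"locus{locus:02d}", new_gene(), 1,
                         top_l2g - rng.uniform(0.005, 0.02), int(rng.integers(0, 5e5))))
        # distractors: lower L2G coding gene + a non-coding candidate
        rows.append((f"locus{locus:02d}", new_gene(), 1,
                     rng.uniform(0.0, 0.4), int(rng.integers(0, 5e5))))
        rows.append((f"locus{locus:02d}", new_gene(), 0,
                     rng.uniform(0.0, 0.9), int(rng.integers(0, 5e5))))
        if locus == 5:
            shared_gene = top
    # 21 loci resolved by distance (no gene above threshold); the first one
    # shares its nearest gene with locus05 (overlapping loci)
    for locus in range(39, 60):
        nearest = shared_gene if locus == 39 else new_gene()
        rows.append((f"locus{locus:02d}", nearest, 1,
                     rng.uniform(0.0, 0.45), int(rng.integers(0, 1e4))))
        rows.append((f"locus{locus:02d}", new_gene(), 1,
                     rng.uniform(0.0, 0.45), int(rng.integers(2e4, 5e5))))
    # 4 loci without protein-coding candidates
    for locus in range(60, 64):
        rows.append((f"locus{locus:02d}", new_gene(), 0,
                     rng.uniform(0.0, 0.9), int(rng.integers(0, 5e5))))

    df = pd.DataFrame(rows, columns=["locus_id", "gene_id", "protein_coding",
                                     "l2g", "distance_bp"])
    df["l2g"] = df["l2g"].round(4)
    return LocusGeneTable(df)
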