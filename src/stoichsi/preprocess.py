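"""Normalization, filtering, residualization and outlier screening.

The normalization chain follows standard bulk RNA-seq practice: between-sample
scaling by the weighted trimmed mean of M-values (TMM, Robinson & Oshlack
2010), then within-sample conversion to reads per kilobase per million mapped
reads (RPKM) on the TMM-adjusted library size, analysed on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from stoichsi.io_formats import COVARIATES, CountDataset, SampleTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """log2 RPKM expression with its TMM scaling factors."""

    log2_rpkm: pd.DataFrame  # genes x samples
    tmm_factor: pd.Series  # per sample, geometric mean 1
    kept_genes: list[str]


@dataclass
class ResidualMatrix:
    """Per-gene OLS residuals of expression on the sample covariates."""

    residual: pd.DataFrame  # genes x samples
    covariates_used: list[str]


# ---------------------------------------------------------------------------
# TMM


def tmm_factors(counts: CountDataset | np.ndarray, trim_m: float = 0.30,
                trim_a: float = 0.05) -> np.ndarray:
    """Weighted trimmed mean of M-values scaling factors.

    Implements the Robinson-Oshlack estimator with the edgeR defaults:
    the reference sample is the one whose upper-quartile count fraction is
    closest to the mean; per sample, M (log2 ratio) and A (mean log2
    abundance) are computed pairwise against the reference over genes with
    non-zero counts in both, doubly trimmed (``trim_m`` of each M tail,
    ``trim_a`` of each A tail), and averaged with inverse asymptotic-variance
    weights.  Factors are rescaled to geometric mean 1.
    """
    mat = counts.counts if isinstance(counts, CountDataset) else np.asarray(counts)
    mat = mat.astype(float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValidationError("TMM needs a genes x samples matrix with >= 2 samples")
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValidationError("all-zero sample in count matrix")

    f75 = np.array([np.quantile(mat[:, s], 0.75) / lib[s] for s in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.array([
        _tmm_pair(mat[:, s], lib[s], mat[:, ref], lib[ref], trim_m, trim_a)
        for s in range(mat.shape[1])
    ])
    # rescale so the factors multiply to 1 (comparisons are relative anyway)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, lib_obs, ref, lib_ref, trim_m, trim_a) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    keep = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, v = m[keep], a[keep], v[keep]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = _rank(m)
    rank_a = _rank(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (matches R's rank())."""
    from scipy.stats import rankdata

    return rankdata(x)


# ---------------------------------------------------------------------------
# RPKM


def to_log2_rpkm(counts: CountDataset, tmm_factor: np.ndarray | None = None,
                 pseudocount: float = 1.0) -> NormalizedMatrix:
    """Convert counts to log2(RPKM + pseudocount).

    RPKM = 1e9 * count / (length_bp * effective library size), where the
    effective library size is the raw column sum scaled by the sample's TMM
    factor.
    """
    if tmm_factor is None:
        tmm_factor = tmm_factors(counts)
    tmm_factor = np.asarray(tmm_factor, dtype=float)
    eff_lib = counts.library_size * tmm_factor
    if np.any(eff_lib <= 0):
        raise ValidationError("zero effective library size")
    rpkm = 1e9 * counts.counts / (counts.gene_length_bp[:, None] * eff_lib[None, :])
    log2_rpkm = np.log2(rpkm + pseudocount)
    return NormalizedMatrix(
        log2_rpkm=pd.DataFrame(log2_rpkm, index=counts.gene_ids, columns=counts.sample_ids),
        tmm_factor=pd.Series(tmm_factor, index=counts.sample_ids),
        kept_genes=list(counts.gene_ids),
    )


# ---------------------------------------------------------------------------
# low-expression filter


def filter_low_expression(counts: CountDataset, min_count: float = 10.0,
                          max_low_fraction: float = 0.30) -> np.ndarray:
    """Boolean keep-mask for genes with adequate expression.

    The count threshold is expressed in CPM at the median library depth
    (``min_count`` reads at the median depth); a gene is removed when the
    fraction of samples below that CPM exceeds ``max_low_fraction``.
    """
    lib = counts.library_size.astype(float)
    if lib.size < 1:
        raise ValidationError("need at least one sample")
    cpm_threshold = min_count / (np.median(lib) / 1e6)
    cpm = 1e6 * counts.counts / lib[None, :]
    low_fraction = (cpm < cpm_threshold).mean(axis=1)
    return low_fraction <= max_low_fraction


# ---------------------------------------------------------------------------
# covariate design & residualization


def covariate_design(samples: SampleTable, add_intercept: bool = True) -> pd.DataFrame:
    """Numeric design matrix for the five covariates.

    Binary categoricals (sex, ethnicity) are coded 0/1 against a reference
    level; multi-level categoricals are one-hot encoded with the first level
    (sorted) as reference.  Constant columns (e.g. a single-ethnicity cohort)
    are dropped with a warning.
    """
    t = samples.table
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(t))
    for cov in COVARIATES:
        vals = t[cov]
        if vals.dtype.kind in "ifu":
            cols[cov] = vals.to_numpy(dtype=float)
        else:
            levels = sorted(vals.astype(str).unique())
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (vals.astype(str) == level).to_numpy(dtype=float)
            if len(levels) == 1:
                logger.warning("covariate %r is constant; dropped from design", cov)
    design = pd.DataFrame(cols, index=t["sample_id"])
    constant = [c for c in design.columns if c != "intercept" and design[c].nunique() == 1]
    if constant:
        logger.warning("dropping constant design columns: %s", constant)
        design = design.drop(columns=constant)
    return design


def residualize_absolute(log2_rpkm: pd.DataFrame, samples: SampleTable) -> ResidualMatrix:
    """OLS residuals of each gene's log2 RPKM on the five covariates.

    The regression pools all samples (cases and controls), so case-control
    mean differences survive residualization while covariate effects are
    removed.
    """
    design = covariate_design(samples)
    design = design.loc[log2_rpkm.columns]
    X = design.to_numpy()
    Y = log2_rpkm.to_numpy().T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return ResidualMatrix(
        residual=pd.DataFrame(resid.T, index=log2_rpkm.index, columns=log2_rpkm.columns),
        covariates_used=[c for c in design.columns if c != "intercept"],
    )


# ---------------------------------------------------------------------------
# PCA outlier screen


def pca_screen(matrix: pd.DataFrame, n_components: int = 2, k: float = 6.0):
    """Flag samples far from the bulk on the leading principal components.

    Scores on PC1..PCn are computed from the gene-centered matrix; a sample is
    flagged when any score lies more than ``k`` median-absolute-deviations
    from the median score of that component.  This is an automated stand-in
    for visual inspection of PCA plots.

    Returns
    -------
    scores : DataFrame (samples x components)
    flagged : boolean Series per sample
    """
    if matrix.shape[1] < 3:
        raise ValidationError("PCA screen needs >= 3 samples")
    X = matrix.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0)
    # SVD on samples x genes; columns of U scaled by singular values = scores
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    ncomp = min(n_components, s.size)
    scores = u[:, :ncomp] * s[:ncomp]
    flagged = np.zeros(X.shape[0], dtype=bool)
    for c in range(ncomp):
        med = np.median(scores[:, c])
        mad = np.median(np.abs(scores[:, c] - med))
        if mad == 0:
            continue
        flagged |= np.abs(scores[:, c] - med) > k * mad
    scores_df = pd.DataFrame(scores, index=matrix.columns,
                             columns=[f"PC{i + 1}" for i in range(ncomp)])
    return scores_df, pd.Series(flagged, index=matrix.columns)


# ---------------------------------------------------------------------------
# HC standardization


def standardize_by_hc(matrix: pd.DataFrame, diagnosis: np.ndarray,
                      reference: str = "HC") -> pd.DataFrame:
    """Standardize every sample by the healthy-control mean and SD, per gene.

    Genes whose reference-group SD is zero are dropped with a warning (their
    standardized values would be undefined).  SD uses the n-1 denominator.
    """
    diagnosis = np.asarray(diagnosis)
    hc = matrix.loc[:, diagnosis == reference]
    if hc.shape[1] < 2:
        raise ValidationError(f"need >= 2 {reference!r} samples to standardize")
    mean = hc.mean(axis=1)
    sd = hc.std(axis=1, ddof=1)
    bad = sd == 0
    if bad.any():
        logger.warning("excluding %d genes with zero %s variance", int(bad.sum()), reference)
    out = matrix.loc[~bad].sub(mean[~bad], axis=0).div(sd[~bad], axis=0)
    return out
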