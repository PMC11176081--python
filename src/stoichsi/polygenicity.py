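"""Architecture of the imbalance: how many genes per individual, how many
individuals per gene.

A gene-individual pair is called *imbalanced* when |sWSR| strictly exceeds a
threshold (default 2 healthy-control standard deviations).  Summaries along
the individual axis (counts of imbalanced genes) and the gene axis (fractions
of imbalanced individuals per diagnosis group) describe whether the disorder
reflects many genes mildly off in everyone or a few genes strongly off in
each patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stoichsi.io_formats import ValidationError


@dataclass
class ImbalanceSummary:
    threshold: float
    per_individual_counts: pd.Series  # index: sample ids
    per_gene_fractions: pd.DataFrame  # index: genes; columns: HC, BD
    median_count: dict[str, float]  # per diagnosis group (lower median)
    mean_fraction: dict[str, float]  # per group, mean over genes
    max_bd_fraction: float


def imbalance_counts(sWSR: pd.DataFrame, threshold: float = 2.0) -> pd.Series:
    """Number of genes with |sWSR| > threshold, per individual (row)."""
    return (sWSR.abs() > threshold).sum(axis=1)


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower-of-the-two convention for even counts."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        return float("nan")
    return float(v[(v.size - 1) // 2])


def gene_imbalance_fractions(sWSR: pd.DataFrame, diagnosis: np.ndarray,
                             threshold: float = 2.0) -> pd.DataFrame:
    """Per-gene fraction of imbalanced individuals, split by diagnosis group."""
    diagnosis = np.asarray(diagnosis)
    out = {}
    for group in ("HC", "BD"):
        mask = diagnosis == group
        if mask.sum() == 0:
            raise ValidationError(f"no {group} individuals")
        out[group] = (sWSR.loc[mask].abs() > threshold).mean(axis=0)
    return pd.DataFrame(out)


def summarize_imbalance(sWSR: pd.DataFrame, diagnosis: np.ndarray,
                        threshold: float = 2.0) -> ImbalanceSummary:
    """Full polygenicity summary of one dataset's sWSR matrix."""
    diagnosis = np.asarray(diagnosis)
    counts = imbalance_counts(sWSR, threshold)
    fractions = gene_imbalance_fractions(sWSR, diagnosis, threshold)
    medians = {g: _lower_median(counts[diagnosis == g].to_numpy())
               for g in ("HC", "BD")}
    means = {g: float(fractions[g].mean()) for g in ("HC", "BD")}
    return ImbalanceSummary(
        threshold=threshold, per_individual_counts=counts,
        per_gene_fractions=fractions, median_count=medians, mean_fraction=means,
        max_bd_fraction=float(fractions["BD"].max()))


def gene_logistic_ranking(pooled_sWSR: pd.DataFrame, diagnosis: np.ndarray) -> pd.DataFrame:
    """Per-gene coefficients of a multivariate logistic fit on pooled datasets.

    The same regression as the cross-dataset classifier, but fitted on all
    samples at once; genes are ranked by coefficient p-value to identify those
    carrying the classification signal.
    """
    import statsmodels.api as sm

    y = (np.asarray(diagnosis) == "BD").astype(int)
    X = sm.add_constant(pooled_sWSR.to_numpy())
    fit = sm.Logit(y, X).fit(disp=0, maxiter=500)
    genes = list(pooled_sWSR.columns)
    out = pd.DataFrame({
        "gene": genes,
        "coef": fit.params[1:],
        "p": fit.pvalues[1:],
    }).sort_values("p").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def summary_table(summary: ImbalanceSummary, dataset: str) -> pd.DataFrame:
    rows = [{
        "dataset": dataset, "threshold": summary.threshold,
        "median_count_HC": summary.median_count["HC"],
        "median_count_BD": summary.median_count["BD"],
        "mean_fraction_HC": summary.mean_fraction["HC"],
        "mean_fraction_BD": summary.mean_fraction["BD"],
        "max_bd_fraction": summary.max_bd_fraction,
    }]
    return pd.DataFrame(rows)
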