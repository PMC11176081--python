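"""Gene-level case-control tests on residualized absolute and relative expression.

Each gene is tested with a two-sided Mann-Whitney-Wilcoxon rank-sum test
(exact null for small samples without ties, normal approximation with tie
correction otherwise) and p-values are pooled across *all* genes and datasets
before a single Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from stoichsi.io_formats import ValidationError

EXACT_MAX_N = 30


def wilcoxon_de(values: np.ndarray, diagnosis: np.ndarray,
                case: str = "BD", control: str = "HC") -> tuple[float, str]:
    """Two-sided rank-sum test of one gene's values between cases and controls.

    Returns (p, direction) with direction the sign of the case-control median
    difference ("up-in-BD", "down-in-BD" or "none").
    """
    values = np.asarray(values, dtype=float)
    diagnosis = np.asarray(diagnosis)
    x = values[diagnosis == case]
    y = values[diagnosis == control]
    if x.size < 2 or y.size < 2:
        raise ValidationError("need >= 2 samples per group")
    if np.all(values == values[0]):
        return 1.0, "none"
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    diff = np.median(x) - np.median(y)
    direction = "up-in-BD" if diff > 0 else ("down-in-BD" if diff < 0 else "none")
    return float(min(res.pvalue, 1.0)), direction


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (with monotonicity enforcement)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_table(matrices: dict[str, pd.DataFrame], diagnoses: dict[str, np.ndarray],
             level: str = "relative", alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene tests in every dataset, BH-adjusted across all genes and datasets.

    Parameters
    ----------
    matrices : dict dataset -> DataFrame (individuals x genes)
        Residualized absolute expression or WSR matrices.
    diagnoses : dict dataset -> array of "BD"/"HC" per individual.

    Returns a table with columns
    ``gene, dataset, level, p, q, direction, nominal, fdr_significant``.
    """
    rows = []
    for name, mat in matrices.items():
        dx = np.asarray(diagnoses[name])
        for gene in mat.columns:
            p, direction = wilcoxon_de(mat[gene].to_numpy(), dx)
            rows.append((gene, name, level, p, direction))
    out = pd.DataFrame(rows, columns=["gene", "dataset", "level", "p", "direction"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["nominal"] = out["p"] < alpha
    out["fdr_significant"] = out["q"] < alpha
    return out
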