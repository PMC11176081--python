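"""Locus-to-gene prioritisation of the analysis gene set.

Each GWAS locus contributes at most a couple of genes: the top protein-coding
gene by OpenTargets L2G score when any exceeds the threshold (plus a second
gene whose L2G is within a small tolerance of the top — a near-tie), otherwise
the protein-coding gene nearest the index SNP.  Loci without protein-coding
candidates contribute nothing and the final list is deduplicated across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from stoichsi.io_formats import LocusGeneTable, ValueParseError


@dataclass
class GeneSet:
    """Ordered, unique analysis genes with per-gene selection provenance."""

    gene_ids: list[str]
    provenance: dict[str, str]  # gene -> {"L2G-top", "L2G-tie", "nearest"}

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_genes(table: LocusGeneTable, l2g_threshold: float = 0.5,
                 tie_tolerance: float = 0.05) -> GeneSet:
    """Apply the per-locus prioritisation rules and deduplicate across loci.

    Parameters
    ----------
    l2g_threshold : float
        A locus is resolved by L2G when any protein-coding candidate scores
        strictly above this.
    tie_tolerance : float
        Second genes within this absolute L2G distance of the locus top gene
        are also selected ("very similar" scores).
    """
    t = table.table
    if (t["distance_bp"] < 0).any():
        raise ValueParseError("negative distance_bp")
    selected: list[str] = []
    provenance: dict[str, str] = {}
    for locus in table.locus_ids:
        cand = t[(t["locus_id"] == locus) & (t["protein_coding"] == 1)]
        if cand.empty:
            continue
        if (cand["l2g"] > l2g_threshold).any():
            cand = cand.sort_values(["l2g", "gene_id"], ascending=[False, True])
            top = cand.iloc[0]
            picks = [(top["gene_id"], "L2G-top")]
            for _, row in cand.iloc[1:].iterrows():
                if top["l2g"] - row["l2g"] <= tie_tolerance:
                    picks.append((row["gene_id"], "L2G-tie"))
        else:
            cand = cand.sort_values(["distance_bp", "gene_id"])
            picks = [(cand.iloc[0]["gene_id"], "nearest")]
        for gene, prov in picks:
            if gene not in provenance:
                selected.append(gene)
                provenance[gene] = prov
    return GeneSet(gene_ids=selected, provenance=provenance)


def gene_set_table(gene_set: GeneSet) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": gene_set.gene_ids,
        "provenance": [gene_set.provenance[g] for g in gene_set.gene_ids],
    })
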