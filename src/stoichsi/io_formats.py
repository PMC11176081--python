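"""Readers, writers and validated containers for counts, metadata and locus tables.

All tabular interchange is plain TSV:

* count matrix -- first column ``gene_id``, remaining columns one per sample;
* sample metadata -- columns ``sample_id, diagnosis, age, sex, ethnicity, RIN, PMI``;
* gene lengths -- columns ``gene_id, length_bp``;
* locus-to-gene table -- columns ``locus_id, gene_id, protein_coding, l2g, distance_bp``.

Gene lengths may alternatively be derived from a GTF annotation
(:func:`gene_lengths_from_gtf`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DIAGNOSIS_LEVELS = ("HC", "BD")
COVARIATES = ("age", "sex", "ethnicity", "RIN", "PMI")
ADULT_AGE = 18.0


class ValidationError(ValueError):
    """Base class for malformed-input failures."""


class DimensionMismatchError(ValidationError):
    """Row/column counts of related tables disagree."""


class DuplicateIDError(ValidationError):
    """A gene or sample identifier occurs more than once."""


class MissingSampleError(ValidationError):
    """A sample present in one table is absent from a companion table."""


class ValueParseError(ValidationError):
    """A field could not be parsed as its declared type."""


@dataclass
class CountDataset:
    """Raw gene-level read counts for one cohort.

    ``counts`` is genes x samples, non-negative integers.  ``library_size``
    is always the per-sample column sum.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_length_bp: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_length_bp = np.asarray(self.gene_length_bp)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.sample_ids) != n_samples:
            raise DimensionMismatchError(
                f"counts is {self.counts.shape} but there are "
                f"{len(self.gene_ids)} gene ids and {len(self.sample_ids)} sample ids"
            )
        if len(self.gene_length_bp) != n_genes:
            raise DimensionMismatchError(
                f"{len(self.gene_length_bp)} gene lengths for {n_genes} genes"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise DuplicateIDError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != n_samples:
            raise DuplicateIDError("duplicate sample ids in count matrix")
        if np.any(self.counts < 0):
            raise ValueParseError("negative counts")
        if np.any(self.gene_length_bp <= 0):
            raise ValueParseError("non-positive gene length")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: np.ndarray | list) -> "CountDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountDataset(
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep],
            gene_length_bp=self.gene_length_bp[keep],
        )

    def subset_samples(self, keep: np.ndarray | list) -> "CountDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountDataset(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            counts=self.counts[:, keep],
            gene_length_bp=self.gene_length_bp,
        )


@dataclass
class SampleTable:
    """Per-sample diagnosis and covariates.

    Samples younger than :data:`ADULT_AGE` are flagged in ``excluded`` rather
    than silently dropped; :meth:`adults` returns the filtered table.
    """

    table: pd.DataFrame
    excluded: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = self.table
        required = ("sample_id",) + ("diagnosis",) + COVARIATES
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise DuplicateIDError("duplicate sample ids in metadata")
        bad_dx = set(t["diagnosis"]) - set(DIAGNOSIS_LEVELS)
        if bad_dx:
            raise ValueParseError(f"unknown diagnosis levels: {sorted(bad_dx)}")
        for col in ("age", "RIN", "PMI"):
            vals = pd.to_numeric(t[col], errors="coerce")
            if vals.isna().any():
                raise ValueParseError(f"non-numeric or missing values in {col!r}")
            self.table[col] = vals.astype(float)
        if t[list(required)].isna().any().any():
            raise ValidationError("missing covariate values")
        rin = self.table["RIN"]
        if ((rin < 0) | (rin > 10)).any():
            raise ValueParseError("RIN outside [0, 10]")
        self.table = self.table.reset_index(drop=True)
        self.excluded = (self.table["age"] < ADULT_AGE).to_numpy()
        if self.excluded.any():
            logger.info("flagged %d samples under age %d", self.excluded.sum(), ADULT_AGE)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def diagnosis(self) -> np.ndarray:
        return self.table["diagnosis"].to_numpy()

    def adults(self) -> "SampleTable":
        return SampleTable(self.table.loc[~self.excluded].reset_index(drop=True).copy())

    def reindex(self, sample_ids: list[str]) -> "SampleTable":
        sub = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(sub)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class LocusGeneTable:
    """GWAS loci with candidate genes and OpenTargets locus-to-gene (L2G) scores."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["locus_id", "gene_id", "protein_coding", "l2g", "distance_bp"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValidationError(f"locus table missing columns: {missing}")
        if ((t["l2g"] < 0) | (t["l2g"] > 1)).any():
            raise ValueParseError("L2G scores outside [0, 1]")
        if (t["distance_bp"] < 0).any():
            raise ValueParseError("negative distance to index SNP")
        if t.duplicated(["locus_id", "gene_id"]).any():
            raise DuplicateIDError("duplicate (locus, gene) rows")

    @property
    def locus_ids(self) -> list:
        return list(dict.fromkeys(self.table["locus_id"]))


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path, gene_lengths=None) -> CountDataset:
    """Read a genes x samples TSV count matrix.

    Parameters
    ----------
    path : str or Path
        TSV whose first column is the gene id and whose header row holds
        sample ids.
    gene_lengths : str, Path, or mapping, optional
        Gene-length TSV (or an explicit ``{gene_id: length_bp}`` mapping).
        If omitted, all lengths default to 1000 bp (length-blind use).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueParseError(f"non-integer count values in {path}: {exc}") from None
    gene_ids = [str(g) for g in df.index]
    if gene_lengths is None:
        lengths = np.full(len(gene_ids), 1000, dtype=np.int64)
    else:
        if isinstance(gene_lengths, (str, Path)):
            gene_lengths = read_gene_lengths(gene_lengths)
        try:
            lengths = np.array([gene_lengths[g] for g in gene_ids], dtype=np.int64)
        except KeyError as exc:
            raise MissingSampleError(f"gene {exc} has no length entry") from None
    return CountDataset(
        gene_ids=gene_ids,
        sample_ids=[str(s) for s in df.columns],
        counts=counts,
        gene_length_bp=lengths,
    )


def read_gene_lengths(path) -> dict[str, int]:
    """Read a two-column ``gene_id\tlength_bp`` TSV into a dict."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise ValidationError("gene-length table needs columns gene_id, length_bp")
    if df["gene_id"].duplicated().any():
        raise DuplicateIDError("duplicate gene ids in length table")
    lengths = pd.to_numeric(df["length_bp"], errors="coerce")
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueParseError("gene lengths must be positive numbers")
    return dict(zip(df["gene_id"].astype(str), lengths.astype(int)))


def read_samples(path) -> SampleTable:
    """Read and validate the sample-metadata TSV."""
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_locus_table(path) -> LocusGeneTable:
    """Read and validate a locus-to-gene TSV."""
    df = pd.read_csv(path, sep="\t")
    return LocusGeneTable(df)


def validate_cohort(dataset: CountDataset, samples: SampleTable) -> None:
    """Cross-check a count matrix against its metadata table."""
    extra = set(dataset.sample_ids) - set(samples.sample_ids)
    if extra:
        raise MissingSampleError(f"samples in counts but not metadata: {sorted(extra)[:5]}")
    missing = set(samples.sample_ids) - set(dataset.sample_ids)
    if missing:
        raise MissingSampleError(f"samples in metadata but not counts: {sorted(missing)[:5]}")


def write_counts(dataset: CountDataset, path) -> None:
    df = pd.DataFrame(dataset.counts, index=pd.Index(dataset.gene_ids, name="gene_id"),
                      columns=dataset.sample_ids)
    df.to_csv(path, sep="\t")


def write_gene_lengths(dataset: CountDataset, path) -> None:
    pd.DataFrame({"gene_id": dataset.gene_ids,
                  "length_bp": dataset.gene_length_bp}).to_csv(path, sep="\t", index=False)


def write_samples(samples: SampleTable, path) -> None:
    out = samples.table.copy()
    for col in ("age", "RIN", "PMI"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF gene lengths


def gene_lengths_from_gtf(gtf_path, canonical_tag: str = "Ensembl_canonical") -> dict[str, int]:
    """Per-gene transcript length from a GTF annotation.

    For each transcript the length is the size of the union of its exon
    intervals (1-based inclusive coordinates).  A gene's length is its
    canonical transcript's length when a transcript carries ``canonical_tag``
    in its ``tag`` attribute, otherwise the median of its transcript lengths
    (midpoint for an even number of transcripts).
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    lengths: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        tx_lengths = []
        canonical = None
        for tx in db.children(gene, featuretype="transcript"):
            exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
            if not exons:
                continue
            length = _union_length(exons)
            tx_lengths.append(length)
            tags = tx.attributes.get("tag", [])
            if canonical_tag in tags:
                canonical = length
        if not tx_lengths:
            raise ValidationError(f"gene {gene.id} has no transcripts with exons")
        if canonical is not None:
            lengths[gene.id] = canonical
        else:
            lengths[gene.id] = int(np.median(tx_lengths))
    return lengths


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals."""
    merged_len = 0
    cur_start, cur_end = None, None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            merged_len += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        merged_len += cur_end - cur_start + 1
    return merged_len


# ---------------------------------------------------------------------------
# config


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    return cfg


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
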