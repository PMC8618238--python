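"""Count-matrix container, normalized expression (RPKM/CPM), QC, and qPCR math.

The central container is :class:`CountMatrix`: an integer gene x sample read-count
table together with per-gene exonic lengths and a per-sample metadata sheet
(condition group, replicate, heat-shock flag, RNAi target).  Everything downstream
— differential expression, overlap statistics, classification — operates on this
object or on DataFrames derived from it, always keyed by gene identifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .errors import ValidationError

SAMPLE_META_COLUMNS = ["group", "replicate", "heat_shock", "rnai_target"]


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with gene lengths and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id; values are
        non-negative integers.
    lengths
        Series of exonic lengths in base pairs, indexed by gene id (same order
        and set as ``counts.index``).
    sample_meta
        DataFrame indexed by sample id with columns ``group``, ``replicate``,
        ``heat_shock`` (0/1) and ``rnai_target`` (empty string for none).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = c.columns[np.argmax((arr != np.round(arr)).any(axis=0))]
                raise ValidationError(f"non-integer counts (e.g. sample {bad!r})")
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        missing = c.index.difference(self.lengths.index)
        if len(missing):
            raise ValidationError(f"genes missing from length table: {list(missing[:5])}")
        self.lengths = self.lengths.reindex(c.index)
        if (self.lengths < 1).any():
            bad = self.lengths.index[self.lengths < 1][0]
            raise ValidationError(f"length < 1 bp for gene {bad!r}")
        missing = c.columns.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(f"samples missing from sample sheet: {list(missing)}")
        self.sample_meta = self.sample_meta.reindex(c.columns)
        for col in SAMPLE_META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    def library_sizes(self) -> pd.Series:
        """Per-sample total read count (the RPKM/CPM denominator)."""
        return self.counts.sum(axis=0)

    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["group"]))

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.sample_meta["group"]):
            raise ValidationError(f"unknown group {group!r}")
        mask = self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])


@dataclass
class ExpressionMatrix:
    """Normalized expression values on the same gene x sample axes as the counts."""

    values: pd.DataFrame
    unit: str  # "RPKM" or "CPM"
    log_transformed: bool = False
    pseudocount: float = 0.0


# ---------------------------------------------------------------------------
# TSV I/O


def load_dataset(counts_path, samples_path, lengths_path) -> CountMatrix:
    """Load a dataset from three TSV files into a validated :class:`CountMatrix`.

    ``counts_path``: first column gene id, remaining columns one per sample.
    ``samples_path``: columns sample_id, group, replicate, heat_shock, rnai_target.
    ``lengths_path``: columns gene_id, length_bp.
    """
    for p in (counts_path, samples_path, lengths_path):
        if not Path(p).exists():
            raise ValidationError(f"file not found: {p}")
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(
        samples_path, sep="\t", index_col=0, dtype={"rnai_target": str}
    )
    meta["rnai_target"] = meta.get("rnai_target", "").fillna("")
    lengths_df = pd.read_csv(lengths_path, sep="\t", index_col=0)
    if "length_bp" not in lengths_df.columns:
        raise ValidationError("length table must have a 'length_bp' column")
    return CountMatrix(counts=counts, lengths=lengths_df["length_bp"], sample_meta=meta)


def write_dataset(cm: CountMatrix, outdir) -> dict[str, Path]:
    """Write counts/samples/lengths TSVs; round-trips through :func:`load_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "lengths": outdir / "lengths.tsv",
    }
    counts = cm.counts.copy()
    counts.index.name = "gene_id"
    counts.to_csv(paths["counts"], sep="\t")
    meta = cm.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(paths["samples"], sep="\t")
    lengths = cm.lengths.to_frame("length_bp")
    lengths.index.name = "gene_id"
    lengths.to_csv(paths["lengths"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# Normalization


def cpm(cm: CountMatrix, log2_transform: bool = False, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Counts per million.  Column sums equal 1e6 exactly (before any log)."""
    lib = cm.library_sizes()
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValidationError(f"zero library size for sample {bad!r}")
    values = cm.counts * 1e6 / lib
    if log2_transform:
        values = np.log2(values + pseudocount)
    return ExpressionMatrix(values=values, unit="CPM",
                            log_transformed=log2_transform,
                            pseudocount=pseudocount if log2_transform else 0.0)


def rpkm(cm: CountMatrix, log10_transform: bool = False, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Reads per kilobase of exon per million reads.

    value(g, s) = counts(g, s) * 1e9 / (library_size(s) * length_bp(g))
    """
    lib = cm.library_sizes()
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValidationError(f"zero library size for sample {bad!r}")
    values = cm.counts.mul(1e9).div(lib, axis=1).div(cm.lengths, axis=0)
    if log10_transform:
        values = np.log10(values + pseudocount)
    return ExpressionMatrix(values=values, unit="RPKM",
                            log_transformed=log10_transform,
                            pseudocount=pseudocount if log10_transform else 0.0)


def mean_rpkm_by_group(cm: CountMatrix, group: str) -> pd.Series:
    """Per-gene mean RPKM over the replicates of one sample group."""
    samples = cm.samples_in_group(group)
    return rpkm(cm).values[samples].mean(axis=1)


# ---------------------------------------------------------------------------
# QC: PCA + hierarchical clustering of samples


@dataclass
class QCReport:
    """Sample-level QC: PCA scores and a complete-linkage dendrogram.

    ``merge_order`` lists, for every agglomeration step, the sample-id sets of
    the two clusters joined (replicate pairs with identical profiles merge at
    distance 0, hence first).
    """

    pca_scores: pd.DataFrame
    explained_variance: np.ndarray
    linkage: np.ndarray
    merge_order: list[tuple[frozenset, frozenset, float]]
    n_genes_used: int = 0

    def to_dict(self) -> dict:
        return {
            "explained_variance": [float(v) for v in self.explained_variance],
            "pca_scores": {
                s: [float(v) for v in row]
                for s, row in self.pca_scores.iterrows()
            },
            "merge_order": [
                [sorted(a), sorted(b), float(d)] for a, b, d in self.merge_order
            ],
            "n_genes_used": self.n_genes_used,
        }


def qc_summary(cm: CountMatrix, pseudocount: float = 1.0,
               linkage_method: str = "complete") -> tuple[QCReport, pd.DataFrame]:
    """PCA and hierarchical clustering of samples for replicate QC.

    Pipeline: log2(CPM + pseudocount) -> per-gene z-score across samples
    (zero-variance genes dropped) -> PCA over samples via SVD -> complete-linkage
    clustering of pairwise Euclidean distances.

    Returns the report and the symmetric sample-distance DataFrame.
    """
    if cm.counts.shape[1] < 2:
        raise ValidationError("QC requires at least 2 samples")
    logc = cpm(cm, log2_transform=True, pseudocount=pseudocount).values
    mu = logc.mean(axis=1)
    sd = logc.std(axis=1, ddof=0)
    keep = sd > 0
    z = logc.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    # samples are observations, z-scored genes are features; gene means are 0
    x = z.to_numpy().T
    x = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else var
    scores = x @ vt.T
    n_pc = min(x.shape)
    score_df = pd.DataFrame(
        scores[:, :n_pc], index=cm.sample_ids,
        columns=[f"PC{i+1}" for i in range(n_pc)],
    )
    dist_condensed = ssd.pdist(z.to_numpy().T, metric="euclidean")
    link = sch.linkage(dist_condensed, method=linkage_method)
    dist_df = pd.DataFrame(
        ssd.squareform(dist_condensed), index=cm.sample_ids, columns=cm.sample_ids
    )
    merge_order = _merge_order(link, list(cm.sample_ids))
    report = QCReport(
        pca_scores=score_df,
        explained_variance=explained,
        linkage=link,
        merge_order=merge_order,
        n_genes_used=int(keep.sum()),
    )
    return report, dist_df


def _merge_order(link: np.ndarray, labels: list[str]) -> list[tuple[frozenset, frozenset, float]]:
    clusters: dict[int, frozenset] = {i: frozenset([lab]) for i, lab in enumerate(labels)}
    order = []
    n = len(labels)
    for step, (a, b, dist, _size) in enumerate(link):
        ca, cb = clusters[int(a)], clusters[int(b)]
        order.append((ca, cb, float(dist)))
        clusters[n + step] = ca | cb
    return order


# ---------------------------------------------------------------------------
# qPCR validation math


def ddct_relative_expression(ct_target_test: float, ct_ref_test: float,
                             ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the delta-delta-Ct method: 2**(-ddCt).

    ddCt = (Ct_target - Ct_reference)_test - (Ct_target - Ct_reference)_control,
    with the reference gene (actin) Ct normalizing each condition.
    """
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError(f"non-finite Ct value in {cts}")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)
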