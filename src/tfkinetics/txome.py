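"""Transcriptomic classification of transcription-factor variants.

Downstream of differential-expression calling, a variant is classified by how
it activates the factor's direct target genes relative to the wild type:

* :func:`promoter_peak_intersect` — restrict differentially expressed genes to
  those with a ChIP peak in the strand-extended promoter window (2 kb upstream
  of the gene start through the gene end, strand-aware).
* :func:`log2fc_vs_reference` — per-gene log2 fold changes of each condition
  against the non-transfected (NT) reference, on CPM with a pseudocount.
* :func:`classify_mutant` — the logFC-ratio estimator: the per-gene difference
  of mutant and wild-type log2FCs; its median over the target genes calls the
  variant gain (median > 0) or loss of function, alongside the Pearson
  correlation of the two log2FC vectors.
* :func:`zscore_rows` / :func:`cluster_rows_cols` — per-gene standardization
  and hierarchical clustering for heat-map style summaries.
* :func:`nrq_from_ct` — qPCR Ct values to normalized relative quantities
  against the geometric mean of multiple reference genes, assuming perfect
  (2-fold per cycle) amplification efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ClassificationResult",
    "promoter_peak_intersect",
    "log2fc_vs_reference",
    "classify_mutant",
    "zscore_rows",
    "cluster_rows_cols",
    "nrq_from_ct",
    "read_bed",
]


@dataclass(frozen=True)
class ClassificationResult:
    """Gain/loss call of a variant from the logFC-ratio estimator."""

    condition: str
    median_log2fc_ratio: float
    pearson_r: float
    call: str                    # "gain" or "loss"
    n_genes: int
    per_gene: pd.DataFrame       # gene_id, log2fc_mut, log2fc_wt, ratio, direction

    def summary(self) -> str:
        return (
            f"{self.condition}: median logFC ratio = {self.median_log2fc_ratio:+.3f} "
            f"({self.call} of function), r = {self.pearson_r:.3f}, "
            f"n = {self.n_genes} target genes"
        )


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    """Read a BED3/BED6 file (0-based half-open) into a DataFrame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    if n_cols is not None and df.shape[1] < n_cols:
        raise ValueError(f"expected at least {n_cols} BED columns")
    return df


def promoter_peak_intersect(
    genes: pd.DataFrame, peaks: pd.DataFrame, pad: int = 2000
) -> pd.DataFrame:
    """Genes whose strand-extended promoter window overlaps at least one peak.

    The window runs from ``start - pad`` to ``end`` on the + strand and from
    ``start`` to ``end + pad`` on the - strand (0-based half-open coordinates;
    negative window starts are clipped to 0). Overlap is >= 1 bp.

    Parameters
    ----------
    genes : DataFrame with columns ``chrom, start, end, gene_id, strand``
        (BED6 column order with the name column holding the gene id works).
    peaks : DataFrame with columns ``chrom, start, end`` (BED3).

    Returns the retained subset of ``genes`` in input order.
    """
    g = genes.rename(columns={"name": "gene_id"}).copy()
    bad = ~g["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand symbol(s): {sorted(g.loc[bad, 'strand'].unique())}")
    win_start = np.where(g["strand"] == "+", g["start"] - pad, g["start"])
    win_end = np.where(g["strand"] == "+", g["end"], g["end"] + pad)
    win_start = np.clip(win_start, 0, None)

    keep = np.zeros(len(g), dtype=bool)
    for chrom, p in peaks.groupby("chrom"):
        on = (g["chrom"] == chrom).to_numpy()
        if not on.any():
            continue
        ps = p["start"].to_numpy()
        pe = p["end"].to_numpy()
        ws = win_start[on][:, None]
        we = win_end[on][:, None]
        hit = ((ws < pe[None, :]) & (we > ps[None, :])).any(axis=1)
        keep[np.flatnonzero(on)] = hit
    return genes.loc[keep]


def log2fc_vs_reference(
    counts: pd.DataFrame, reference: str = "NT", pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-gene log2 fold changes of every condition against the reference.

    Counts are scaled to counts-per-million per column; each condition's value
    is log2((cpm + pseudocount) / (cpm_ref + pseudocount)). Replicate columns
    named ``<condition>_r<j>`` are averaged on the log scale. The reference
    column of the result is identically 0.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero library size in counts")
    cpm = counts / lib * 1e6
    conditions = {}
    for col in counts.columns:
        cond = col.rsplit("_r", 1)[0] if "_r" in col and col.rsplit("_r", 1)[1].isdigit() else col
        conditions.setdefault(cond, []).append(col)
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    logcpm = {
        cond: np.log2(cpm[cols] + pseudocount).mean(axis=1)
        for cond, cols in conditions.items()
    }
    ref = logcpm[reference]
    out = pd.DataFrame({cond: lc - ref for cond, lc in logcpm.items()}, index=counts.index)
    return out


def classify_mutant(
    fc_mut: pd.Series, fc_wt: pd.Series, gene_subset=None, condition: str = "mutant"
) -> ClassificationResult:
    """Classify a variant against the wild type via the logFC-ratio estimator.

    For each target gene g, ratio_g = log2FC_mut(g) - log2FC_wt(g) (the log2 of
    the mutant/wild-type fold-change ratio). The variant is called gain of
    function iff the median ratio over the gene subset is positive; genes are
    individually labelled up- or downregulated by the sign of ratio_g. The
    Pearson correlation between the two log2FC vectors quantifies target
    specificity.
    """
    if gene_subset is None:
        gene_subset = fc_mut.index.intersection(fc_wt.index)
    gene_subset = pd.Index(gene_subset)
    if len(gene_subset) == 0:
        raise ValueError("gene subset is empty")
    m = fc_mut.loc[gene_subset].astype(float)
    w = fc_wt.loc[gene_subset].astype(float)
    ratio = m - w
    median = float(ratio.median())
    r = float(np.corrcoef(m, w)[0, 1]) if len(gene_subset) > 1 else np.nan
    per_gene = pd.DataFrame({
        "gene_id": gene_subset,
        "log2fc_mut": m.to_numpy(),
        "log2fc_wt": w.to_numpy(),
        "log2fc_ratio": ratio.to_numpy(),
        "direction": np.where(ratio.to_numpy() > 0, "up", "down"),
    })
    return ClassificationResult(
        condition=condition,
        median_log2fc_ratio=median,
        pearson_r=r,
        call="gain" if median > 0 else "loss",
        n_genes=int(len(gene_subset)),
        per_gene=per_gene,
    )


def zscore_rows(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize each row to mean 0, SD 1 (z = (x - mu) / sigma)."""
    m = matrix.astype(float)
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=ddof)
    zero = sd <= 0
    if zero.any():
        raise ValueError(f"zero-SD row(s): {list(m.index[zero])}")
    return m.sub(mu, axis=0).div(sd, axis=0)


def cluster_rows_cols(zmatrix: pd.DataFrame):
    """Hierarchical clustering of rows and columns of a standardized matrix.

    Agglomerative, Euclidean distance, average linkage; leaf order is the
    deterministic scipy dendrogram order (ties resolved by input order).

    Returns ``(row_order, col_order, row_linkage, col_linkage)`` where the
    orders are integer index arrays; with fewer than 2 rows (columns) the
    identity order and ``None`` linkage are returned.
    """
    m = zmatrix.to_numpy(dtype=float)

    def _one(data):
        if data.shape[0] < 2:
            return np.arange(data.shape[0]), None
        z = hierarchy.linkage(pdist(data, metric="euclidean"), method="average")
        return np.asarray(hierarchy.leaves_list(z)), z

    row_order, row_z = _one(m)
    col_order, col_z = _one(m.T)
    return row_order, col_order, row_z, col_z


def nrq_from_ct(
    ct: pd.DataFrame, reference_genes, calibrator_sample: str
) -> pd.DataFrame:
    """qPCR Ct values to normalized relative quantities (NRQ).

    Assuming 2-fold amplification per cycle, the relative quantity of gene g in
    sample s against the calibrator sample is RQ(s, g) = 2**(Ct(cal, g) -
    Ct(s, g)); the NRQ divides by the geometric mean of the RQs of the
    reference (housekeeping) genes of that sample.

    Parameters
    ----------
    ct : DataFrame, samples x genes (index = sample, columns = gene).
    reference_genes : iterable of column names used as the normalization set.
    calibrator_sample : index label of the calibrator.

    Samples with any missing Ct are dropped with a warning.
    """
    refs = list(reference_genes)
    missing = [r for r in refs if r not in ct.columns]
    if missing:
        raise ValueError(f"reference gene(s) absent from Ct table: {missing}")
    if calibrator_sample not in ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not in Ct table")
    table = ct.astype(float)
    incomplete = table.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"excluding sample(s) with missing Ct: {list(table.index[incomplete])}",
            stacklevel=2,
        )
        table = table.loc[~incomplete]
    rq = 2.0 ** (table.loc[calibrator_sample] - table)
    norm = np.exp(np.log(rq[refs]).mean(axis=1))
    return rq.div(norm, axis=0)
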