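"""Library-size and target-density normalization of strand count matrices.

Counts are normalized in two steps: a per-sample library size factor
(median-of-ratios against a geometric-mean pseudo-reference, the DESeq
convention) and a per-(gene, strand) divisor — the number of GG dinucleotides
on the matched strand, the actual target density of a Pt-d(GpG) assay —
or gene length in kb for comparison. RPKM serves RNA-seq, and the
TS/(TS+NTS) ratio cancels every multiplicative bias shared by both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "size_factors",
    "normalize",
    "NormalizedMatrix",
    "qc_filter",
    "rpkm",
    "ts_ratio",
    "log2p1",
]

QC_CRITERIA = ["no-expression", "unmatched-id", "gg<10", "length>=100Kb", "reads<20"]
MAX_GENE_LENGTH = 100_000  # genes must be strictly shorter
MIN_GG = 10
MIN_READS_TOTAL = 20


def size_factors(raw: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios library size factors for a gene x sample count table.

    The pseudo-reference is the per-gene geometric mean across samples over
    genes with all-positive counts; factor_s = median_g(count_gs / ref_g).
    """
    if raw.shape[1] < 1:
        raise ValueError("need at least one sample")
    mat = raw.to_numpy(dtype=float) + pseudocount
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a pseudocount"
        )
    logmat = np.log(mat[allpos])
    ref = logmat.mean(axis=1)
    factors = np.exp(np.median(logmat - ref[:, None], axis=0))
    return pd.Series(factors, index=raw.columns, name="size_factor")


@dataclass
class NormalizedMatrix:
    """Normalized values with full provenance: value x denominator == raw."""

    assay: str
    mode: str  # "gg" or "length"
    values: pd.DataFrame  # gene_id, strand_class, sample, raw, denominator, value
    size_factors: pd.Series
    dropped: pd.DataFrame  # cells excluded for a zero denominator

    def reconstruct_raw(self) -> pd.Series:
        return self.values["value"] * self.values["denominator"]

    def wide(self, strand_class: str, column: str = "value") -> pd.DataFrame:
        sub = self.values[self.values["strand_class"] == strand_class]
        return sub.pivot_table(index="gene_id", columns="sample", values=column, aggfunc="sum")


def normalize(
    counts: pd.DataFrame,
    factors: pd.Series,
    gene_model: pd.DataFrame,
    mode: str = "gg",
    assay: str = "",
) -> NormalizedMatrix:
    """Normalize a long (gene_id, strand_class, sample, count) table.

    value = raw / (size_factor x gg_count) in "gg" mode (strand-matched GG
    count) or raw / (size_factor x length_kb) in "length" mode. Cells whose
    denominator is zero are dropped and reported.
    """
    if mode not in {"gg", "length"}:
        raise ValueError(f"unknown mode {mode!r}")
    gm = gene_model.set_index("gene_id")
    df = counts.copy()
    if mode == "gg":
        gg = np.where(
            df["strand_class"].to_numpy() == "TS",
            gm["gg_ts"].reindex(df["gene_id"]).to_numpy(dtype=float),
            gm["gg_nts"].reindex(df["gene_id"]).to_numpy(dtype=float),
        )
        per_gene = gg
    else:
        per_gene = gm["length"].reindex(df["gene_id"]).to_numpy(dtype=float) / 1e3
    sf = factors.reindex(df["sample"]).to_numpy(dtype=float)
    if np.isnan(sf).any():
        raise ValueError("size factors missing for some samples")
    denom = sf * per_gene
    df = df.rename(columns={"count": "raw"})
    df["denominator"] = denom
    keep = denom > 0
    dropped = df.loc[~keep].copy()
    df = df.loc[keep].copy()
    df["value"] = df["raw"] / df["denominator"]
    return NormalizedMatrix(
        assay=assay, mode=mode, values=df.reset_index(drop=True),
        size_factors=factors, dropped=dropped.reset_index(drop=True),
    )


def qc_filter(
    gene_model: pd.DataFrame,
    expression_counts: pd.DataFrame,
    raw_matrices: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Evaluate the five gene-level QC criteria.

    (i) at least one sample with expression > 0; (ii) gene id present in
    every assay table; (iii) >= 10 GG dinucleotides on the TS or the NTS;
    (iv) length strictly < 100,000 bp; (v) >= 20 reads in total across
    samples, per assay (RNA-seq and each matrix in ``raw_matrices``).

    ``raw_matrices`` maps assay name -> either a gene x sample table or a
    long (gene_id, strand_class, sample, count) table. Returns one row per
    gene with one boolean column per criterion (True = failed) and ``pass_qc``.
    """
    gm = gene_model.set_index("gene_id")
    genes = gm.index

    def gene_totals(tab: pd.DataFrame) -> pd.Series:
        if {"gene_id", "count"}.issubset(tab.columns):
            return tab.groupby("gene_id")["count"].sum()
        return tab.sum(axis=1)

    expr_tot = expression_counts.sum(axis=1)
    expr_any = (expression_counts > 0).any(axis=1)

    report = pd.DataFrame(index=genes)
    report["no-expression"] = ~expr_any.reindex(genes, fill_value=False)
    in_all = pd.Series(True, index=genes)
    in_all &= genes.isin(expression_counts.index)
    for tab in raw_matrices.values():
        ids = tab["gene_id"].unique() if "gene_id" in tab.columns else tab.index
        in_all &= genes.isin(ids)
    report["unmatched-id"] = ~in_all
    report["gg<10"] = ~((gm["gg_ts"] >= MIN_GG) | (gm["gg_nts"] >= MIN_GG))
    report["length>=100Kb"] = gm["length"] >= MAX_GENE_LENGTH
    low_reads = expr_tot.reindex(genes, fill_value=0) < MIN_READS_TOTAL
    for tab in raw_matrices.values():
        low_reads |= gene_totals(tab).reindex(genes, fill_value=0) < MIN_READS_TOTAL
    report["reads<20"] = low_reads
    report["pass_qc"] = ~report[QC_CRITERIA].any(axis=1)
    return report


def rpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and sample."""
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    if (lens <= 0).any() or np.isnan(lens).any():
        raise ValueError("gene lengths must be positive for all genes")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("zero total counts in at least one sample")
    return counts / (lens[:, None] / 1e3) / (totals[None, :] / 1e6)


def ts_ratio(ts, nts):
    """TS/(TS+NTS); NaN where both are zero. Accepts scalars or arrays."""
    ts_a = np.asarray(ts, dtype=float)
    nts_a = np.asarray(nts, dtype=float)
    if (ts_a < 0).any() or (nts_a < 0).any():
        raise ValueError("strand values must be non-negative")
    denom = ts_a + nts_a
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, ts_a / np.where(denom > 0, denom, 1.0), np.nan)
    if np.isscalar(ts) and np.isscalar(nts):
        return float(out)
    return out


def log2p1(x):
    """log2(x + 1); the pseudocount used for all downstream log scales."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)
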