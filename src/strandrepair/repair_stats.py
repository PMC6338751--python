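"""Headline strand-asymmetry statistics.

The accounting behind them: Damage-seq measures total induced damage minus
the repair accumulated over [0, T] (transcription-coupled repair acts only on
the transcribed strand; global repair on both), while XR-seq is a snapshot of
the repair ongoing at T. Because global repair removes a negligible share of
the total damage, the fraction of TS damage removed by TCR by time T is
estimated as

    tcr_fraction = 1 - Damage_TS / Damage_NTS

with both sides library-size and GG-normalized. The remaining routines
stratify damage/repair by expression quantile, infer per-sample relative
damage against a pseudo-reference, contrast the GG-signature fraction between
mitochondrial and nuclear reads, and correlate gene-level epigenomic signals
with damage and repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeRef
from .normalize import log2p1, ts_ratio, NormalizedMatrix
from .reads import read_gg_signature_fraction

__all__ = [
    "tcr_fraction",
    "repair_estimates",
    "quantile_stratify",
    "QuantileProfile",
    "relative_damage",
    "mito_background_contrast",
    "gene_track_signal",
    "marker_correlations",
]


def tcr_fraction(damage_ts, damage_nts):
    """1 - damage_ts/damage_nts; NaN where damage_nts == 0.

    May be negative from sampling noise; reported unclipped (a clipped
    companion is added by :func:`repair_estimates`).
    """
    ts = np.asarray(damage_ts, dtype=float)
    nts = np.asarray(damage_nts, dtype=float)
    if (ts < 0).any() or (nts < 0).any():
        raise ValueError("normalized damage must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nts > 0, 1.0 - ts / np.where(nts > 0, nts, 1.0), np.nan)
    if np.isscalar(damage_ts) and np.isscalar(damage_nts):
        return float(out)
    return out


def repair_estimates(
    damage: NormalizedMatrix, xr: NormalizedMatrix
) -> pd.DataFrame:
    """Per-gene normalized damage/repair, TCR fraction and strand ratios.

    Values are averaged across samples (replicates) per strand class first.
    """
    def mean_by_gene(nm: NormalizedMatrix, cls: str) -> pd.Series:
        sub = nm.values[nm.values["strand_class"] == cls]
        return sub.groupby("gene_id")["value"].mean()

    d_ts, d_nts = mean_by_gene(damage, "TS"), mean_by_gene(damage, "NTS")
    x_ts, x_nts = mean_by_gene(xr, "TS"), mean_by_gene(xr, "NTS")
    genes = sorted(set(d_ts.index) | set(d_nts.index) | set(x_ts.index) | set(x_nts.index))
    df = pd.DataFrame(
        {
            "damage_ts": d_ts.reindex(genes),
            "damage_nts": d_nts.reindex(genes),
            "xr_ts": x_ts.reindex(genes),
            "xr_nts": x_nts.reindex(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    df["tcr_fraction"] = tcr_fraction(df["damage_ts"].fillna(0), df["damage_nts"].fillna(0))
    df["tcr_fraction_clipped"] = df["tcr_fraction"].clip(lower=0.0, upper=1.0)
    df["damage_ratio"] = ts_ratio(df["damage_ts"].fillna(0), df["damage_nts"].fillna(0))
    df["xr_ratio"] = ts_ratio(df["xr_ts"].fillna(0), df["xr_nts"].fillna(0))
    return df


@dataclass
class QuantileProfile:
    """Expression-quantile means and gene-wise Spearman correlations."""

    n_bins: int
    bins: pd.DataFrame  # bin, assay, strand_class, expr_lo, expr_hi, n_genes, mean_log
    correlations: pd.DataFrame  # assay, strand_class, spearman_rho, p_value
    degenerate_expression: bool = False


def quantile_stratify(
    expression: pd.Series,
    matrices: dict[str, NormalizedMatrix],
    n_bins: int = 10,
) -> QuantileProfile:
    """Group genes into expression-quantile bins and profile damage/repair.

    Per gene the log2(value + 1) is averaged across replicates; bins are
    equal-count in expression rank order. Spearman rho is computed gene-wise
    between expression and each (assay, strand class) profile. Constant
    expression cannot be ranked meaningfully: bins fall back to stable input
    order and the profile is flagged ``degenerate_expression``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    expression = expression.dropna()
    if len(expression) < n_bins:
        raise ValueError("need at least n_bins genes")
    degenerate = expression.nunique() == 1
    order = expression.sort_values(kind="stable").index.to_numpy()
    bin_of = {}
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        for g in chunk:
            bin_of[g] = b

    bin_rows, cor_rows = [], []
    for assay, nm in matrices.items():
        for cls in ("TS", "NTS"):
            sub = nm.values[nm.values["strand_class"] == cls]
            per_gene = (
                sub.assign(log_value=log2p1(sub["value"]))
                .groupby("gene_id")["log_value"]
                .mean()
                .reindex(expression.index)
            )
            common = per_gene.dropna().index
            if degenerate or len(common) < 3 or per_gene[common].nunique() == 1:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(expression[common], per_gene[common])
            cor_rows.append((assay, cls, rho, p))
            grp = pd.DataFrame(
                {"gene_id": common, "bin": [bin_of[g] for g in common], "v": per_gene[common]}
            )
            for b, bsub in grp.groupby("bin"):
                e = expression[bsub["gene_id"]]
                bin_rows.append(
                    (b, assay, cls, float(e.min()), float(e.max()), len(bsub), float(bsub["v"].mean()))
                )
    bins = pd.DataFrame(
        bin_rows,
        columns=["bin", "assay", "strand_class", "expr_lo", "expr_hi", "n_genes", "mean_log"],
    ).sort_values(["assay", "strand_class", "bin"]).reset_index(drop=True)
    cors = pd.DataFrame(cor_rows, columns=["assay", "strand_class", "spearman_rho", "p_value"])
    return QuantileProfile(n_bins=n_bins, bins=bins, correlations=cors,
                           degenerate_expression=degenerate)


def relative_damage(raw_nts: pd.DataFrame, gg_nts: pd.Series) -> pd.Series:
    """Per-sample relative damage against a geometric-mean pseudo-reference.

    ``raw_nts`` is a gene x sample table of NTS Damage-seq counts (site
    occupancy, i.e. deduplicated, when absolute comparability across depths
    is wanted); counts are GG-normalized per gene, compared to the per-gene
    geometric mean across samples, and the per-sample median ratio is scaled
    to mean 1. Only the ordering and spacing across samples is meaningful.
    """
    if raw_nts.shape[1] < 2:
        raise ValueError("need at least two samples")
    gg = gg_nts.reindex(raw_nts.index).to_numpy(dtype=float)
    if (gg <= 0).any() or np.isnan(gg).any():
        raise ValueError("gg_nts must be positive for all genes")
    v = raw_nts.to_numpy(dtype=float) / gg[:, None]
    allpos = (v > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in every sample")
    logv = np.log(v[allpos])
    ref = logv.mean(axis=1)
    med = np.exp(np.median(logv - ref[:, None], axis=0))
    med = med / med.mean()
    return pd.Series(med, index=raw_nts.columns, name="relative_damage")


def mito_background_contrast(
    reads: pd.DataFrame,
    genome: GenomeRef,
    assay: str,
    mito_chroms: set[str] | None = None,
) -> dict[str, dict[str, float]]:
    """GG-signature fraction in mitochondria-like vs nuclear reads."""
    mito = set(mito_chroms) if mito_chroms is not None else set(genome.mito_chroms)
    nuclear = set(genome.sequences) - mito
    return {
        "mito": read_gg_signature_fraction(reads, genome, assay, chroms=mito & set(genome.sequences)),
        "nuclear": read_gg_signature_fraction(reads, genome, assay, chroms=nuclear),
    }


def gene_track_signal(
    track: pd.DataFrame,
    genes: pd.DataFrame,
    region_mode: str = "body",
    promoter_window: int = 1_000,
) -> pd.Series:
    """Coverage-weighted mean track intensity per gene.

    ``track`` has columns (chrom, start, end, intensity). In "body" mode the
    region is the gene interval; in "promoter" mode it is TSS +/- window,
    strand-aware (TSS = start for + genes, end for - genes). Uncovered bases
    contribute intensity 0, so a track covering half a gene at intensity 2
    yields 1.0. Genes with no overlap get 0.
    """
    if region_mode not in {"body", "promoter"}:
        raise ValueError(f"unknown region_mode {region_mode!r}")
    if (track["end"] <= track["start"]).any():
        raise ValueError("malformed track intervals (end <= start)")
    if not np.isfinite(track["intensity"].to_numpy(dtype=float)).all():
        raise ValueError("track intensities must be finite")
    by_chrom = {c: sub.sort_values("start") for c, sub in track.groupby("chrom")}
    out = {}
    for row in genes.itertuples(index=False):
        if region_mode == "body":
            lo, hi = int(row.start), int(row.end)
        else:
            tss = int(row.start) if row.strand == "+" else int(row.end)
            lo, hi = tss - promoter_window, tss + promoter_window
        sub = by_chrom.get(row.chrom)
        total = 0.0
        if sub is not None:
            s = sub["start"].to_numpy(np.int64)
            e = sub["end"].to_numpy(np.int64)
            x = sub["intensity"].to_numpy(dtype=float)
            ov = np.minimum(e, hi) - np.maximum(s, lo)
            pos = ov > 0
            total = float((ov[pos] * x[pos]).sum())
        out[row.gene_id] = total / (hi - lo) if hi > lo else 0.0
    return pd.Series(out, name="track_signal")


def marker_correlations(
    signals: pd.DataFrame,
    targets: pd.DataFrame,
    gene_subset: list[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho and BH-adjusted p for every (marker, quantity) pair.

    ``signals``: gene x marker; ``targets``: gene x quantity (e.g. the
    columns of :func:`repair_estimates` plus expression). ``gene_subset`` is
    typically the non-induced genes. Pairs with < 3 complete genes get NaN.
    """
    if gene_subset is not None:
        signals = signals.loc[signals.index.intersection(gene_subset)]
        targets = targets.loc[targets.index.intersection(gene_subset)]
    common = signals.index.intersection(targets.index)
    if len(common) == 0:
        raise ValueError("no genes shared between signals and targets")
    signals = signals.loc[common]
    targets = targets.loc[common]
    rows = []
    for marker in signals.columns:
        for quantity in targets.columns:
            pair = pd.concat([signals[marker], targets[quantity]], axis=1).dropna()
            if len(pair) < 3:
                rows.append((marker, quantity, np.nan, np.nan, len(pair)))
                continue
            rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append((marker, quantity, rho, p, len(pair)))
    df = pd.DataFrame(rows, columns=["marker", "quantity", "spearman_rho", "p_value", "n_genes"])
    ok = df["p_value"].notna()
    df["p_adj"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj"] = stats.false_discovery_control(df.loc[ok, "p_value"], method="bh")
    df["significant"] = df["p_adj"] < fdr
    return df
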