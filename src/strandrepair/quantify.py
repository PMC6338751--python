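"""Gene-level, strand-resolved quantification of lesion calls.

TS/NTS convention: the transcribed strand (TS) is the template strand,
antisense to the mRNA, so a lesion on the strand OPPOSITE a gene's annotated
strand is on the TS; a lesion on the same strand is on the NTS. Counts are
per (gene, strand class, sample); intergenic calls are tallied separately so
per-sample totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeRef

__all__ = [
    "GENE_COLUMNS",
    "count_gg",
    "gg_positions",
    "assign_strand_class",
    "annotate_genes",
    "build_count_matrix",
    "StrandCountMatrix",
    "genes_from_bed",
    "genes_to_bed",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "length", "gg_ts", "gg_nts", "is_mito"]


def count_gg(sequence: str, strand: str) -> int:
    """Overlapping GG occurrences on the given strand of a + strand sequence.

    '-' counts GG on the reverse complement, i.e. overlapping CC on the given
    sequence. N never matches. "GGG" on '+' counts 2.
    """
    return len(gg_positions(sequence, strand))


def gg_positions(sequence: str, strand: str) -> np.ndarray:
    """0-based + strand coordinates of the 5' G of each GG on ``strand``.

    On '+' the 5' G is the lower coordinate; on '-' (GG = CC on the + strand)
    the 5' G of the damaged-strand dinucleotide is the HIGHER coordinate.
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(sequence) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    base = ord("G") if strand == "+" else ord("C")
    hit = (arr[:-1] == base) & (arr[1:] == base)
    pos = np.flatnonzero(hit).astype(np.int64)
    return pos if strand == "+" else pos + 1


def assign_strand_class(lesion_strand: str, gene_strand: str) -> str:
    """TS if the lesion strand is opposite the gene's sense strand, else NTS."""
    return "TS" if lesion_strand != gene_strand else "NTS"


def annotate_genes(genes: pd.DataFrame, genome: GenomeRef) -> pd.DataFrame:
    """Fill length, per-strand GG counts and mitochondrial flags.

    ``genes`` needs columns gene_id, chrom, start, end, strand. gg_nts counts
    GG on the gene's own (coding) strand; gg_ts on the template strand.
    """
    genes = genes.copy()
    rows_ts, rows_nts, mito = [], [], []
    for row in genes.itertuples(index=False):
        seq = genome.fetch(row.chrom, int(row.start), int(row.end))
        opposite = "-" if row.strand == "+" else "+"
        rows_nts.append(count_gg(seq, row.strand))
        rows_ts.append(count_gg(seq, opposite))
        mito.append(genome.is_mito(row.chrom))
    genes["length"] = genes["end"] - genes["start"]
    genes["gg_ts"] = rows_ts
    genes["gg_nts"] = rows_nts
    genes["is_mito"] = mito
    return genes[GENE_COLUMNS]


def _check_non_overlapping(genes: pd.DataFrame) -> None:
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping genes on {chrom}; resolve the annotation first")


@dataclass
class StrandCountMatrix:
    """Per-assay strand-resolved counts in long form.

    ``counts`` has columns (gene_id, strand_class, sample, count) and a row
    for every (gene, TS/NTS, sample) cell; ``intergenic`` and ``totals`` keep
    the conservation ledger: totals[s] = sum of gene cells + intergenic[s].
    """

    assay: str
    counts: pd.DataFrame
    intergenic: dict[str, int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def wide(self, strand_class: str) -> pd.DataFrame:
        """gene x sample matrix for one strand class."""
        sub = self.counts[self.counts["strand_class"] == strand_class]
        return sub.pivot_table(
            index="gene_id", columns="sample", values="count", aggfunc="sum", fill_value=0
        )


def build_count_matrix(
    calls_by_sample: dict[str, pd.DataFrame],
    genes: pd.DataFrame,
    assay: str = "damage",
    dedup: bool = False,
) -> StrandCountMatrix:
    """Assign lesion calls to genes and tabulate TS/NTS counts per sample.

    A lesion belongs to a gene iff its 5' G coordinate lies in the half-open
    gene interval. Genes must be non-overlapping. With ``dedup=True``
    identical (chrom, strand, lesion_start) calls within a sample collapse to
    one (site-occupancy counting, the tabular analogue of upstream read
    deduplication).
    """
    _check_non_overlapping(genes)
    gene_ids = genes["gene_id"].tolist()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        by_chrom[chrom] = (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["gene_id"].to_numpy(),
            sub["strand"].to_numpy(),
        )

    frames = []
    intergenic: dict[str, int] = {}
    totals: dict[str, int] = {}
    index = pd.MultiIndex.from_product(
        [gene_ids, ["TS", "NTS"]], names=["gene_id", "strand_class"]
    )
    for sample, calls in calls_by_sample.items():
        if dedup and len(calls):
            calls = calls.drop_duplicates(subset=["chrom", "strand", "lesion_start"])
        totals[sample] = len(calls)
        cell = pd.Series(0, index=index, dtype=np.int64)
        n_inter = 0
        for chrom, sub in calls.groupby("chrom"):
            if chrom not in by_chrom:
                n_inter += len(sub)
                continue
            starts, ends, ids, gstrands = by_chrom[chrom]
            pos = sub["lesion_start"].to_numpy(np.int64)
            gi = np.searchsorted(starts, pos, side="right") - 1
            inside = (gi >= 0) & (pos < ends[np.clip(gi, 0, None)])
            n_inter += int((~inside).sum())
            if inside.any():
                lst = sub["strand"].to_numpy()[inside]
                gst = gstrands[gi[inside]]
                cls = np.where(lst != gst, "TS", "NTS")
                grouped = pd.DataFrame({"gene_id": ids[gi[inside]], "strand_class": cls})
                vc = grouped.value_counts()
                cell = cell.add(vc.reindex(index, fill_value=0), fill_value=0)
        intergenic[sample] = n_inter
        df = cell.astype(np.int64).rename("count").reset_index()
        df["sample"] = sample
        frames.append(df[["gene_id", "strand_class", "sample", "count"]])

    counts = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene_id", "strand_class", "sample", "count"])
    )
    return StrandCountMatrix(assay=assay, counts=counts, intergenic=intergenic, totals=totals)


# ------------------------------------------------------------------ file I/O


def genes_from_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def genes_to_bed(genes: pd.DataFrame, path: str) -> None:
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)
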