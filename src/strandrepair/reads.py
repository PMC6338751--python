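"""Positional Pt-d(GpG) signature filtering of aligned Damage-seq / XR-seq reads.

Both assays leave the damaged GG dinucleotide at a fixed position relative to
one read end:

* Damage-seq — the primer-extension product starts immediately 3' of the
  lesion, so the GG sits 1-2 bp upstream of the read's 5' end (in read
  orientation).
* XR-seq — the excised oligomer (21-31 nt) carries the lesion near its 3'
  end; the GG lies 5-8 nt upstream of the 3'-terminal base (terminal base =
  position 1), i.e. inside a 4-nt window with three possible placements.

Reads are tabular (one row per alignment, 0-based half-open reference
coordinates); filters are pure functions of (reads, genome) and return the
accepted lesion calls plus a rejection tally with documented precedence
mapq -> length -> out-of-bounds -> non-GG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeRef

__all__ = [
    "MAPQ_MIN_EXCLUSIVE",
    "XR_LEN_RANGE",
    "filter_damage_reads",
    "filter_xr_reads",
    "read_gg_signature_fraction",
    "reads_from_sam",
    "reads_from_bed",
    "write_sam",
    "write_bed6",
]

#: reads must have mapping quality strictly greater than this
MAPQ_MIN_EXCLUSIVE = 20
#: accepted XR-seq oligomer lengths, inclusive
XR_LEN_RANGE = (21, 31)
#: GG window relative to the XR-seq 3' end: positions 5..8, 3'-terminal base = 1
_XR_NEAR, _XR_FAR = 5, 8

READ_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "mapq"]

_G = ord("G")
_C = ord("C")


@dataclass
class FilterTally:
    """Mutually exclusive rejection causes; accepted + rejections = input."""

    accepted: int = 0
    mapq: int = 0
    length: int = 0
    out_of_bounds: int = 0
    non_gg: int = 0

    @property
    def total(self) -> int:
        return self.accepted + self.mapq + self.length + self.out_of_bounds + self.non_gg

    def as_dict(self) -> dict[str, int]:
        return {
            "accepted": self.accepted,
            "mapq": self.mapq,
            "length": self.length,
            "out_of_bounds": self.out_of_bounds,
            "non_gg": self.non_gg,
        }


def _validate_reads(reads: pd.DataFrame, genome: GenomeRef) -> None:
    missing = set(reads["chrom"]) - set(genome.sequences)
    if missing:
        raise KeyError(f"read chromosomes absent from genome: {sorted(missing)}")
    if len(reads) and not (reads["start"] < reads["end"]).all():
        raise ValueError("reads must satisfy start < end")
    bad = set(reads["strand"]) - {"+", "-"}
    if bad:
        raise ValueError(f"invalid strand values: {sorted(bad)}")


def _chrom_arrays(genome: GenomeRef) -> dict[str, np.ndarray]:
    return {c: np.frombuffer(s.encode("ascii"), dtype=np.uint8) for c, s in genome.sequences.items()}


def _pair_at(arr: np.ndarray, pos: np.ndarray, base: int) -> np.ndarray:
    """True where arr[pos] == base == arr[pos+1]; pos assumed in bounds."""
    safe = np.clip(pos, 0, len(arr) - 2)
    return (arr[safe] == base) & (arr[safe + 1] == base)


def _damage_signature(
    arrays: dict[str, np.ndarray], reads: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-read (in_bounds, has_GG, lesion_start) for the Damage-seq rule.

    + read: GG must occupy genome [start-2, start); lesion 5' G = start-2.
    - read: the 2 bases just past the alignment end must be CC on the + strand
      (GG on the read strand); lesion 5' G (on the damaged strand) = end+1.
    """
    n = len(reads)
    in_bounds = np.zeros(n, dtype=bool)
    has_gg = np.zeros(n, dtype=bool)
    lesion = np.full(n, -1, dtype=np.int64)
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        arr = arrays[chrom]
        idx = sub.index.to_numpy()
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        if strand == "+":
            ok = (start >= 2) & (end <= len(arr))
            gg = _pair_at(arr, start - 2, _G) & ok
            les = start - 2
        else:
            ok = (start >= 0) & (end + 2 <= len(arr))
            gg = _pair_at(arr, end, _C) & ok
            les = end + 1
        in_bounds[idx] = ok
        has_gg[idx] = gg
        lesion[idx] = les
    return in_bounds, has_gg, lesion


def _xr_signature(
    arrays: dict[str, np.ndarray], reads: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-read (in_bounds, has_GG, lesion_start) for the XR-seq window rule.

    The window holds positions 5-8 from the 3' end; a GG may start at window
    offsets j = 0, 1, 2 (read orientation, 5'->3'). The lesion is assigned to
    the 3'-most GG occurrence (largest j).
    """
    n = len(reads)
    in_bounds = np.zeros(n, dtype=bool)
    has_gg = np.zeros(n, dtype=bool)
    lesion = np.full(n, -1, dtype=np.int64)
    for (chrom, strand), sub in reads.groupby(["chrom", "strand"], sort=False):
        arr = arrays[chrom]
        idx = sub.index.to_numpy()
        start = sub["start"].to_numpy(np.int64)
        end = sub["end"].to_numpy(np.int64)
        if strand == "+":
            # window genome coords [end-8, end-4); GG at offset j -> 5' G at end-8+j
            ok = (end - _XR_FAR >= 0) & (start >= 0) & (end <= len(arr))
            pair = [_pair_at(arr, end - _XR_FAR + j, _G) & ok for j in range(3)]
            les_of_j = [end - _XR_FAR + j for j in range(3)]
        else:
            # read-oriented window = revcomp of genome [start+4, start+8);
            # GG at offset j -> CC on + strand at (start+6-j, start+7-j);
            # lesion 5' G on the damaged (-) strand = start+7-j
            ok = (start + _XR_FAR <= len(arr)) & (start >= 0) & (end <= len(arr))
            pair = [_pair_at(arr, start + 6 - j, _C) & ok for j in range(3)]
            les_of_j = [start + 7 - j for j in range(3)]
        best = np.where(pair[2], 2, np.where(pair[1], 1, np.where(pair[0], 0, -1)))
        found = best >= 0
        les = np.full(len(sub), -1, dtype=np.int64)
        for j in range(3):
            sel = best == j
            les[sel] = les_of_j[j][sel]
        in_bounds[idx] = ok
        has_gg[idx] = found
        lesion[idx] = les
    return in_bounds, has_gg, lesion


def _assemble(
    reads: pd.DataFrame,
    pass_mapq: np.ndarray,
    pass_len: np.ndarray,
    in_bounds: np.ndarray,
    has_gg: np.ndarray,
    lesion: np.ndarray,
) -> tuple[pd.DataFrame, FilterTally]:
    tally = FilterTally()
    # precedence: mapq -> length -> out-of-bounds -> non-GG
    rej_mapq = ~pass_mapq
    rej_len = pass_mapq & ~pass_len
    rej_oob = pass_mapq & pass_len & ~in_bounds
    rej_gg = pass_mapq & pass_len & in_bounds & ~has_gg
    accepted = pass_mapq & pass_len & in_bounds & has_gg
    tally.mapq = int(rej_mapq.sum())
    tally.length = int(rej_len.sum())
    tally.out_of_bounds = int(rej_oob.sum())
    tally.non_gg = int(rej_gg.sum())
    tally.accepted = int(accepted.sum())
    calls = pd.DataFrame(
        {
            "read_id": reads.loc[accepted, "read_id"].to_numpy(),
            "chrom": reads.loc[accepted, "chrom"].to_numpy(),
            "strand": reads.loc[accepted, "strand"].to_numpy(),
            "lesion_start": lesion[accepted],
            "dinucleotide": "GG",
        }
    )
    return calls, tally


def filter_damage_reads(
    reads: pd.DataFrame, genome: GenomeRef
) -> tuple[pd.DataFrame, FilterTally]:
    """Apply the Damage-seq acceptance rule: mapq > 20 and GG 1-2 bp upstream
    of the 5' end; returns lesion calls and a rejection tally."""
    reads = reads.reset_index(drop=True)
    _validate_reads(reads, genome)
    if reads.empty:
        return (
            pd.DataFrame(columns=["read_id", "chrom", "strand", "lesion_start", "dinucleotide"]),
            FilterTally(),
        )
    arrays = _chrom_arrays(genome)
    pass_mapq = reads["mapq"].to_numpy() > MAPQ_MIN_EXCLUSIVE
    pass_len = np.ones(len(reads), dtype=bool)  # no length rule for Damage-seq
    in_bounds, has_gg, lesion = _damage_signature(arrays, reads)
    return _assemble(reads, pass_mapq, pass_len, in_bounds, has_gg, lesion)


def filter_xr_reads(reads: pd.DataFrame, genome: GenomeRef) -> tuple[pd.DataFrame, FilterTally]:
    """Apply the XR-seq acceptance rule: mapq > 20, length 21-31 nt, and a GG
    wholly inside positions 5-8 from the 3' end; returns calls and tally."""
    reads = reads.reset_index(drop=True)
    _validate_reads(reads, genome)
    if reads.empty:
        return (
            pd.DataFrame(columns=["read_id", "chrom", "strand", "lesion_start", "dinucleotide"]),
            FilterTally(),
        )
    arrays = _chrom_arrays(genome)
    length = (reads["end"] - reads["start"]).to_numpy(np.int64)
    pass_mapq = reads["mapq"].to_numpy() > MAPQ_MIN_EXCLUSIVE
    pass_len = (length >= XR_LEN_RANGE[0]) & (length <= XR_LEN_RANGE[1])
    in_bounds, has_gg, lesion = _xr_signature(arrays, reads)
    return _assemble(reads, pass_mapq, pass_len, in_bounds, has_gg, lesion)


def read_gg_signature_fraction(
    reads: pd.DataFrame,
    genome: GenomeRef,
    assay: str,
    chroms: set[str] | None = None,
) -> dict[str, float]:
    """Fraction of reads carrying the assay's positional GG signature.

    Composition only: mapping quality and length are NOT tested, matching how
    background contamination is assessed. Reads whose signature window falls
    off the chromosome count in the denominator but not the numerator.
    Returns {numerator, denominator, fraction}; fraction is NaN when no read
    overlaps the requested chromosome set.
    """
    if assay not in {"damage", "xr"}:
        raise ValueError(f"unknown assay {assay!r}")
    reads = reads.reset_index(drop=True)
    _validate_reads(reads, genome)
    if chroms is not None:
        reads = reads[reads["chrom"].isin(chroms)].reset_index(drop=True)
    if reads.empty:
        return {"numerator": 0, "denominator": 0, "fraction": float("nan")}
    arrays = _chrom_arrays(genome)
    sig = _damage_signature if assay == "damage" else _xr_signature
    _, has_gg, _ = sig(arrays, reads)
    num = int(has_gg.sum())
    den = int(len(reads))
    return {"numerator": num, "denominator": den, "fraction": num / den}


# ------------------------------------------------------------------ file I/O


def reads_from_sam(path: str) -> pd.DataFrame:
    """Load single-end alignments from SAM/BAM into the tabular read form.

    Coordinates come from the CIGAR-aware reference span (pysam's
    reference_start/reference_end), so soft clips and indels are handled by
    the aligner's accounting; unmapped reads are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_end is None:
                continue
            rows.append(
                (
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    aln.mapping_quality,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def reads_from_bed(path: str) -> pd.DataFrame:
    """Load reads from a BED6 mirror (name = read id, score = MAPQ)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "read_id", "mapq", "strand"],
        dtype={"chrom": str},
    )
    return df[READ_COLUMNS]


def write_bed6(reads: pd.DataFrame, path: str) -> None:
    reads[["chrom", "start", "end", "read_id", "mapq", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def write_sam(reads: pd.DataFrame, genome: GenomeRef, path: str) -> None:
    """Write reads as a text SAM with @SQ headers; sequence taken from the
    reference (the simulator does not model sequencing errors)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": n} for c, n in genome.lengths.items()],
    }
    tid = {c: i for i, c in enumerate(genome.lengths)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = str(row.read_id)
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = int(row.mapq)
            a.flag = 16 if row.strand == "-" else 0
            # SAM stores SEQ in forward-reference orientation for both strands
            seq = genome.fetch(row.chrom, int(row.start), int(row.end))
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            out.write(a)
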