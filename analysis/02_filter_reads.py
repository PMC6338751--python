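#!/usr/bin/env python
"""Filter the simulated alignments by the positional Pt-d(GpG) signature
(Damage-seq: GG 1-2 bp upstream of the 5' end; XR-seq: mapq > 20, 21-31 nt,
GG 5-8 nt upstream of the 3' end) and localize each putative lesion."""

from pathlib import Path

import pandas as pd

from strandrepair import GenomeRef, filter_damage_reads, filter_xr_reads
from strandrepair.reads import reads_from_sam

ROOT = Path(__file__).resolve().parents[1]
RAW = ROOT / "scratch" / "simdata"
OUT = ROOT / "scratch" / "filter"  # per-read tables are bulky
TABLES = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = GenomeRef.from_fasta(RAW / "genome.fa")
    tally_rows = []
    for assay, fn in (("damage", filter_damage_reads), ("xr", filter_xr_reads)):
        for sam in sorted(RAW.glob(f"{assay}_*.sam")):
            sample = sam.stem.split("_", 1)[1]
            reads = reads_from_sam(str(sam))
            calls, tally = fn(reads, genome)
            calls.to_csv(OUT / f"lesions_{assay}_{sample}.tsv", sep="\t", index=False)
            tally_rows.append({"assay": assay, "sample": sample, **tally.as_dict()})
            print(
                f"{assay}/{sample}: {tally.accepted}/{tally.total} accepted "
                f"({100 * tally.accepted / tally.total:.1f}%); "
                f"non-GG {tally.non_gg}, low mapq {tally.mapq}"
            )
    TABLES.mkdir(exist_ok=True)
    pd.DataFrame(tally_rows).to_csv(TABLES / "rejections.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
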