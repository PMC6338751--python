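#!/usr/bin/env python
"""Assign lesion calls to genes, split them into transcribed (TS) vs
non-transcribed (NTS) strand, and tabulate per-sample counts."""

from pathlib import Path

import pandas as pd

from strandrepair import build_count_matrix

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"



def main() -> None:
    genes = pd.read_csv(RESULTS / "gene_model.tsv", sep="\t")
    for assay in ("damage", "xr"):
        calls = {}
        for path in sorted((ROOT / "scratch" / "filter").glob(f"lesions_{assay}_*.tsv")):
            sample = path.stem.rsplit("_", 1)[1]
            calls[sample] = pd.read_csv(path, sep="\t")
        mat = build_count_matrix(calls, genes, assay=assay)
        mat.counts.to_csv(RESULTS / f"counts_{assay}.tsv", sep="\t", index=False)
        by_cls = mat.counts.groupby("strand_class")["count"].sum()
        print(
            f"{assay}: genic TS {by_cls['TS']}, NTS {by_cls['NTS']}, "
            f"intergenic {sum(mat.intergenic.values())} (totals conserved: "
            f"{by_cls.sum() + sum(mat.intergenic.values()) == sum(mat.totals.values())})"
        )


if __name__ == "__main__":
    main()
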