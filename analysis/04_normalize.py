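#!/usr/bin/env python
"""Normalize the strand count matrices (median-of-ratios library size factor,
then the per-strand GG-dinucleotide target count), compute RNA-seq RPKM, and
apply the five-criterion gene QC."""

from pathlib import Path

import pandas as pd

from strandrepair import normalize, qc_filter, rpkm, size_factors

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RAW = ROOT / "scratch" / "simdata"


def main() -> None:
    genes = pd.read_csv(RESULTS / "gene_model.tsv", sep="\t")
    rnaseq = pd.read_csv(RAW / "rnaseq_counts.tsv", sep="\t", index_col=0)

    counts = {a: pd.read_csv(RESULTS / f"counts_{a}.tsv", sep="\t") for a in ("damage", "xr")}
    sf_rows = []
    for assay, long in counts.items():
        per_gene = long.groupby(["gene_id", "sample"])["count"].sum().unstack(fill_value=0)
        sf = size_factors(per_gene)
        nm = normalize(long, sf, genes, mode="gg", assay=assay)
        nm.values.to_csv(RESULTS / f"normalized_{assay}.tsv", sep="\t", index=False)
        for sample, f in sf.items():
            sf_rows.append((assay, sample, f))
        print(f"{assay}: size factors " + ", ".join(f"{s}={f:.3f}" for _, s, f in sf_rows if _ == assay))
    pd.DataFrame(sf_rows, columns=["assay", "sample", "size_factor"]).to_csv(
        RESULTS / "size_factors.tsv", sep="\t", index=False
    )

    expr = rpkm(rnaseq, genes.set_index("gene_id")["length"])
    expr.to_csv(RESULTS / "rpkm.tsv", sep="\t")

    qc = qc_filter(genes, rnaseq, {a: c for a, c in counts.items()})
    qc.to_csv(RESULTS / "qc_report.tsv", sep="\t")
    fails = qc.loc[~qc["pass_qc"]].drop(columns="pass_qc")
    print(f"QC: {int(qc['pass_qc'].sum())}/{len(qc)} genes pass")
    for gene, row in fails.iterrows():
        print(f"  {gene} fails: {', '.join(c for c, v in row.items() if v)}")


if __name__ == "__main__":
    main()
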