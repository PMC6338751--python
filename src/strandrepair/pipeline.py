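"""End-to-end orchestration: simulate -> filter -> count -> normalize -> analyze.

A run is driven by a YAML config (or a RunConfig built in code), executes the
stages in dependency order, writes every stage's tables under the output
directory, and records a manifest (input checksums, parameters, per-stage
tallies) sufficient to reproduce every number from the inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .genome import GenomeRef, DEFAULT_MITO_NAMES
from . import reads as rd
from .quantify import annotate_genes, build_count_matrix, genes_from_bed
from .normalize import normalize, qc_filter, rpkm, size_factors
from .repair_stats import (
    mito_background_contrast,
    quantile_stratify,
    relative_damage,
    repair_estimates,
)
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either ``simulate`` is set (the run generates its own inputs) or the
    explicit input paths are. Filter thresholds are fixed to the published
    values and are not configurable here by design.
    """

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    genome_fasta: str | None = None
    genes_bed: str | None = None
    damage_reads: dict[str, str] = field(default_factory=dict)  # sample -> SAM/BED path
    xr_reads: dict[str, str] = field(default_factory=dict)
    rnaseq_counts: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)  # marker -> BED path
    normalization_mode: str = "gg"
    n_bins: int = 10
    promoter_window: int = 1_000
    mito_chroms: tuple[str, ...] = tuple(sorted(DEFAULT_MITO_NAMES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            if "gene_length_range" in sim:
                sim["gene_length_range"] = tuple(sim["gene_length_range"])
            if "xr_len_range" in sim:
                sim["xr_len_range"] = tuple(sim["xr_len_range"])
            cfg.simulate = SimConfig(**sim)
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated precondition; empty list means runnable."""
    problems: list[str] = []
    if config.simulate is not None:
        problems += config.simulate.validate()
    else:
        for name in ("genome_fasta", "genes_bed"):
            path = getattr(config, name)
            if path is None:
                problems.append(f"{name} is required when not simulating")
            elif not Path(path).exists():
                problems.append(f"{name} path does not exist: {path}")
        for pool_name, pool in (("damage_reads", config.damage_reads), ("xr_reads", config.xr_reads)):
            for sample, path in pool.items():
                if not Path(path).exists():
                    problems.append(f"{pool_name}[{sample}] path does not exist: {path}")
        if config.rnaseq_counts is not None and not Path(config.rnaseq_counts).exists():
            problems.append(f"rnaseq_counts path does not exist: {config.rnaseq_counts}")
    for marker, path in config.tracks.items():
        if not Path(path).exists():
            problems.append(f"tracks[{marker}] path does not exist: {path}")
    if config.normalization_mode not in {"gg", "length"}:
        problems.append("normalization_mode must be 'gg' or 'length'")
    if config.n_bins < 2:
        problems.append("n_bins must be >= 2")
    if config.promoter_window <= 0:
        problems.append("promoter_window must be > 0")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reads(path: str) -> pd.DataFrame:
    if path.endswith((".sam", ".bam")):
        return rd.reads_from_sam(path)
    return rd.reads_from_bed(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid run config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "parameters": {
            "normalization_mode": config.normalization_mode,
            "n_bins": config.n_bins,
            "promoter_window": config.promoter_window,
            "mito_chroms": list(config.mito_chroms),
        },
        "stages": {},
        "inputs": {},
    }

    # ---- stage: inputs (simulate or load)
    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim = SimConfig(**{**asdict(sim), "seed": config.seed})
            sim.gene_length_range = tuple(sim.gene_length_range)  # type: ignore[assignment]
            sim.xr_len_range = tuple(sim.xr_len_range)  # type: ignore[assignment]
        bundle = simulate_dataset(sim)
        simdir = outdir / "sim"
        bundle.write(simdir)
        genome, genes = bundle.genome, bundle.genes
        damage_pools = bundle.damage_reads
        xr_pools = bundle.xr_reads
        rnaseq = bundle.rnaseq
        manifest["stages"]["simulate"] = {
            "config": {**asdict(sim)},
            "n_genes": len(genes),
            "lesions_per_sample": {s: len(t) for s, t in bundle.truth.items()},
        }
        manifest["inputs"]["genome_fasta"] = _sha256(simdir / "genome.fa")
        manifest["inputs"]["genes_bed"] = _sha256(simdir / "genes.bed")
    else:
        genome = GenomeRef.from_fasta(config.genome_fasta, mito_chroms=set(config.mito_chroms))
        genes = annotate_genes(genes_from_bed(config.genes_bed), genome)
        damage_pools = {s: _load_reads(p) for s, p in config.damage_reads.items()}
        xr_pools = {s: _load_reads(p) for s, p in config.xr_reads.items()}
        rnaseq = (
            pd.read_csv(config.rnaseq_counts, sep="\t", index_col=0)
            if config.rnaseq_counts
            else None
        )
        manifest["inputs"]["genome_fasta"] = _sha256(Path(config.genome_fasta))
        manifest["inputs"]["genes_bed"] = _sha256(Path(config.genes_bed))
    genes.to_csv(outdir / "gene_model.tsv", sep="\t", index=False)

    # ---- stage: filter
    calls = {"damage": {}, "xr": {}}
    tallies = {"damage": {}, "xr": {}}
    for assay, pools, fn in (
        ("damage", damage_pools, rd.filter_damage_reads),
        ("xr", xr_pools, rd.filter_xr_reads),
    ):
        for sample, reads in pools.items():
            got, tally = fn(reads[rd.READ_COLUMNS], genome)
            calls[assay][sample] = got
            tallies[assay][sample] = tally.as_dict()
            got.to_csv(outdir / f"lesions_{assay}_{sample}.tsv", sep="\t", index=False)
    manifest["stages"]["filter"] = tallies

    # ---- stage: count
    matrices = {}
    for assay in ("damage", "xr"):
        mat = build_count_matrix(calls[assay], genes, assay=assay)
        matrices[assay] = mat
        mat.counts.to_csv(outdir / f"counts_{assay}.tsv", sep="\t", index=False)
    manifest["stages"]["count"] = {
        assay: {"intergenic": m.intergenic, "totals": m.totals} for assay, m in matrices.items()
    }

    # ---- stage: normalize
    normalized = {}
    sf_rows = []
    for assay, mat in matrices.items():
        per_gene = mat.counts.groupby(["gene_id", "sample"])["count"].sum().unstack(fill_value=0)
        sf = size_factors(per_gene) if per_gene.shape[1] > 1 else pd.Series(
            1.0, index=per_gene.columns, name="size_factor"
        )
        nm = normalize(mat.counts, sf, genes, mode=config.normalization_mode, assay=assay)
        normalized[assay] = nm
        nm.values.to_csv(outdir / f"normalized_{assay}.tsv", sep="\t", index=False)
        for sample, f in sf.items():
            sf_rows.append((assay, sample, f))
    pd.DataFrame(sf_rows, columns=["assay", "sample", "size_factor"]).to_csv(
        outdir / "size_factors.tsv", sep="\t", index=False
    )

    qc = None
    expr = None
    if rnaseq is not None:
        expr_rpkm = rpkm(rnaseq, genes.set_index("gene_id")["length"])
        expr_rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
        expr = expr_rpkm.mean(axis=1)
        qc = qc_filter(genes, rnaseq, {a: m.counts for a, m in matrices.items()})
        qc.to_csv(outdir / "qc_report.tsv", sep="\t")
        manifest["stages"]["qc"] = {
            "genes_total": int(len(qc)),
            "genes_passing": int(qc["pass_qc"].sum()),
        }

    # ---- stage: analyze
    est = repair_estimates(normalized["damage"], normalized["xr"])
    est.to_csv(outdir / "repair_estimates.tsv", sep="\t")
    if expr is not None and qc is not None:
        keep = qc.index[qc["pass_qc"]]
        sub_expr = expr.reindex(keep).dropna()
        if len(sub_expr) >= config.n_bins:
            profile = quantile_stratify(sub_expr, normalized, n_bins=config.n_bins)
            profile.bins.to_csv(outdir / "quantile_profile.tsv", sep="\t", index=False)
            profile.correlations.to_csv(
                outdir / "quantile_correlations.tsv", sep="\t", index=False
            )
    nts_counts = matrices["damage"].wide("NTS")
    if nts_counts.shape[1] >= 2 and (nts_counts.to_numpy() > 0).all(axis=1).any():
        rel = relative_damage(nts_counts, genes.set_index("gene_id")["gg_nts"])
        rel.rename_axis("sample").to_csv(outdir / "relative_damage.tsv", sep="\t")
    mito_rows = []
    for assay, pools in (("damage", damage_pools), ("xr", xr_pools)):
        for sample, reads in pools.items():
            contrast = mito_background_contrast(reads, genome, assay)
            for comp, vals in contrast.items():
                mito_rows.append((assay, sample, comp, vals["numerator"], vals["denominator"], vals["fraction"]))
    pd.DataFrame(
        mito_rows,
        columns=["assay", "sample", "compartment", "numerator", "denominator", "fraction"],
    ).to_csv(outdir / "mito_contrast.tsv", sep="\t", index=False)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
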