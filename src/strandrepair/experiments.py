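"""In-silico study designs: the simulation experiments the package's claims
rest on, each returning the measured quantities as a flat dict.

Every experiment builds its inputs with the forward simulator, runs the real
pipeline operations (filter -> count -> normalize -> estimate) and measures
recovery of the known truth. The problem sizes are chosen so the Monte Carlo
error of each measured quantity is comfortably below the effect it probes;
docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import substream
from .genome import GenomeRef, revcomp
from .normalize import normalize, qc_filter, size_factors, ts_ratio
from .quantify import annotate_genes, build_count_matrix, count_gg
from .reads import READ_COLUMNS, filter_damage_reads, filter_xr_reads
from .repair_stats import (
    mito_background_contrast,
    quantile_stratify,
    relative_damage,
    tcr_fraction,
)
from .simulate import (
    SimConfig,
    emit_damage_reads,
    emit_xr_reads,
    simulate_genome,
    simulate_lesions,
)

__all__ = [
    "roundtrip_recovery",
    "filter_oracle_agreement",
    "tcr_recovery",
    "expression_sign_structure",
    "relative_damage_recovery",
    "normalization_invariants",
    "qc_fidelity",
    "mito_contrast_demo",
]


def _truth_positions(truth: pd.DataFrame, calls: pd.DataFrame) -> np.ndarray:
    """Look up each accepted call's true lesion position via the read id."""
    lid = calls["read_id"].str.rsplit(":", n=1).str[-1]
    return truth.set_index("lesion_id")["position"].reindex(lid).to_numpy()


# ------------------------------------------------------------ round trip


def roundtrip_recovery(seed: int, n_reads: int = 20_000) -> dict:
    """Zero background, all MAPQ passing: both filters must accept every
    emitted read and localize every lesion exactly."""
    cfg = SimConfig(seed=seed, background_read_fraction=0.0, low_mapq_fraction=0.0,
                    n_reads_per_assay=n_reads)
    genome, genes = simulate_genome(cfg)
    rng = substream(seed, "roundtrip-expression")
    expr = pd.Series(rng.gamma(0.5, 2.0, len(genes)), index=genes["gene_id"].to_numpy())
    truth, _ = simulate_lesions(genome, genes, expr, cfg)
    out: dict = {}
    for assay, emit, filt in (
        ("damage", emit_damage_reads, filter_damage_reads),
        ("xr", emit_xr_reads, filter_xr_reads),
    ):
        reads = emit(truth, genome, cfg, sample="rt")
        calls, tally = filt(reads[READ_COLUMNS], genome)
        exact = (_truth_positions(truth, calls) == calls["lesion_start"].to_numpy()).mean()
        out[f"{assay}_pass_pct"] = 100.0 * tally.accepted / tally.total
        out[f"{assay}_position_exact_pct"] = 100.0 * float(exact)
    out["n"] = n_reads
    return out


# ------------------------------------------------------------ brute-force oracle


def _oracle_damage(chrom_seq: str, start: int, end: int, strand: str, mapq: int):
    """Reference re-scan of the Damage-seq rule using plain string slicing."""
    if mapq <= 20:
        return "mapq", None
    L = len(chrom_seq)
    if strand == "+":
        if start < 2 or end > L:
            return "out_of_bounds", None
        return ("accepted", start - 2) if chrom_seq[start - 2 : start] == "GG" else ("non_gg", None)
    if start < 0 or end + 2 > L:
        return "out_of_bounds", None
    window = revcomp(chrom_seq[end : end + 2])
    return ("accepted", end + 1) if window == "GG" else ("non_gg", None)


def _oracle_xr(chrom_seq: str, start: int, end: int, strand: str, mapq: int):
    """Reference re-scan of the XR-seq rule using plain string slicing."""
    if mapq <= 20:
        return "mapq", None
    if not 21 <= end - start <= 31:
        return "length", None
    L = len(chrom_seq)
    if strand == "+":
        if end - 8 < 0 or end > L or start < 0:
            return "out_of_bounds", None
        window = chrom_seq[end - 8 : end - 4]
    else:
        if start + 8 > L or start < 0 or end > L:
            return "out_of_bounds", None
        window = revcomp(chrom_seq[start + 4 : start + 8])
    hits = [j for j in range(3) if window[j : j + 2] == "GG"]
    if not hits:
        return "non_gg", None
    j = max(hits)  # 3'-most placement
    lesion = end - 8 + j if strand == "+" else start + 7 - j
    return "accepted", lesion


def random_reads(genome: GenomeRef, n: int, seed: int) -> pd.DataFrame:
    """Random alignments exercising every rejection branch: edge positions,
    out-of-range lengths and sub-threshold MAPQ included on purpose."""
    rng = substream(seed, "random-reads")
    chroms = np.array(genome.chroms)
    sizes = np.array([genome.lengths[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    length = rng.integers(10, 61, size=n)
    clen = sizes[pick].astype(np.int64)
    start = rng.integers(0, np.maximum(clen - 10, 1))
    end = np.minimum(start + length, clen + rng.integers(0, 3, size=n))  # some overhang
    end = np.maximum(end, start + 1)
    return pd.DataFrame(
        {
            "read_id": [f"rnd{i}" for i in range(n)],
            "chrom": chroms[pick],
            "start": start,
            "end": end,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "mapq": rng.integers(0, 61, size=n),
        }
    )


def filter_oracle_agreement(seed: int, n_reads: int = 10_000) -> dict:
    """Compare both filters against an independent per-read string re-scan,
    and per-gene/strand GG counts against a brute-force overlapping scan."""
    cfg = SimConfig(seed=seed, n_genes=20, chrom_length=50_000)
    genome, genes = simulate_genome(cfg)
    reads = random_reads(genome, n_reads, seed)
    out: dict = {"n": n_reads}
    for assay, filt, oracle in (
        ("damage", filter_damage_reads, _oracle_damage),
        ("xr", filter_xr_reads, _oracle_xr),
    ):
        calls, tally = filt(reads, genome)
        got = dict(zip(calls["read_id"], calls["lesion_start"]))
        mism = 0
        tally_oracle: dict[str, int] = {}
        for row in reads.itertuples(index=False):
            verdict, lesion = oracle(
                genome.sequences[row.chrom], int(row.start), int(row.end), row.strand, int(row.mapq)
            )
            tally_oracle[verdict] = tally_oracle.get(verdict, 0) + 1
            if verdict == "accepted":
                if got.get(row.read_id) != lesion:
                    mism += 1
            elif row.read_id in got:
                mism += 1
        for cause, n in tally_oracle.items():
            if tally.as_dict().get(cause, 0) != n:
                mism += abs(tally.as_dict().get(cause, 0) - n)
        out[f"{assay}_mismatches"] = mism

    gg_mism = 0
    for row in genes.itertuples(index=False):
        seq = genome.fetch(row.chrom, int(row.start), int(row.end))
        plus = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "GG")
        minus = sum(1 for i in range(len(seq) - 1) if revcomp(seq[i : i + 2]) == "GG")
        want_nts, want_ts = (plus, minus) if row.strand == "+" else (minus, plus)
        if count_gg(seq, "+") != plus or count_gg(seq, "-") != minus:
            gg_mism += 1
        if row.gg_nts != want_nts or row.gg_ts != want_ts:
            gg_mism += 1
    out["gg_count_mismatches"] = gg_mism
    return out


# ------------------------------------------------------------ TCR-fraction recovery


def tcr_recovery(seed: int, n_genes: int = 200) -> dict:
    """Recover known transcribed-strand repaired fractions spanning [0, 0.9]
    with negligible global repair and ~500 expected NTS lesions per gene.

    The estimator runs on the real pipeline path: one Damage-seq read per
    unrepaired lesion -> filter -> strand-resolved counting -> GG
    normalization -> 1 - Damage_TS/Damage_NTS.
    """
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=700_000,
        n_genes=n_genes,
        gene_length_range=(6_000, 6_000),
        gc_content=0.42,
        damage_rate=1.9,  # ~500 expected lesions over ~264 GG sites/strand
        tcr_rate_coef=0.5,
        gr_rate_ts=0.0,
        gr_rate_nts=0.0,
        background_read_fraction=0.0,
    )
    genome, genes = simulate_genome(cfg)
    f_true = np.linspace(0.0, 0.9, n_genes)
    # choose expression so 1 - exp(-k_TCR e T) hits each target fraction
    e = -np.log(1.0 - f_true) / (cfg.tcr_rate_coef * cfg.T)
    expr = pd.Series(e, index=genes["gene_id"].to_numpy())
    truth, _ = simulate_lesions(genome, genes, expr, cfg)
    reads = emit_damage_reads(truth, genome, cfg, sample="tcr", n_reads=None)
    calls, _ = filter_damage_reads(reads[READ_COLUMNS], genome)
    mat = build_count_matrix({"s": calls}, genes, assay="damage")
    sf = pd.Series(1.0, index=["s"])
    nm = normalize(mat.counts, sf, genes, mode="gg", assay="damage")
    wide_ts = nm.wide("TS")["s"].reindex(genes["gene_id"])
    wide_nts = nm.wide("NTS")["s"].reindex(genes["gene_id"])
    est = tcr_fraction(wide_ts.to_numpy(), wide_nts.to_numpy())
    err = np.abs(est - f_true)
    rho = sps.spearmanr(est, f_true).statistic
    return {
        "mean_abs_error": float(err.mean()),
        "max_abs_error": float(err.max()),
        "spearman_estimate_vs_truth": float(rho),
        "n": n_genes,
    }


# ------------------------------------------------------------ expression coupling


def _sign_structure_config(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=600_000,
        n_genes=500,
        gene_length_range=(1_500, 3_000),
        gc_content=0.42,
        damage_rate=1.0,
        tcr_rate_coef=0.12,
        gr_rate_ts=0.001,
        gr_rate_nts=0.001,
        background_read_fraction=0.02,
        n_reads_per_assay=200_000,
        n_samples=2,
    )


def expression_sign_structure(seed: int) -> dict:
    """Reproduce the reported correlation directions: repair on the
    transcribed strand rises with expression, remaining TS damage falls, and
    NTS damage is expression-independent."""
    cfg = _sign_structure_config(seed)
    genome, genes = simulate_genome(cfg)
    rng = substream(seed, "sign-expression")
    expr = pd.Series(
        rng.gamma(cfg.expression_shape, 1.0 / cfg.expression_shape, len(genes)),
        index=genes["gene_id"].to_numpy(),
    )
    calls = {"damage": {}, "xr": {}}
    for rep in ("r1", "r2"):
        truth, _ = simulate_lesions(genome, genes, expr, cfg, label=f"lesions:{rep}")
        dmg = emit_damage_reads(truth, genome, cfg, sample=f"d{rep}")
        xr = emit_xr_reads(truth, genome, cfg, sample=f"x{rep}")
        calls["damage"][rep], _ = filter_damage_reads(dmg[READ_COLUMNS], genome)
        calls["xr"][rep], _ = filter_xr_reads(xr[READ_COLUMNS], genome)
    normalized = {}
    for assay in ("damage", "xr"):
        mat = build_count_matrix(calls[assay], genes, assay=assay)
        per_gene = mat.counts.groupby(["gene_id", "sample"])["count"].sum().unstack(fill_value=0)
        sf = size_factors(per_gene, pseudocount=0.5)
        normalized[assay] = normalize(mat.counts, sf, genes, mode="gg", assay=assay)
    profile = quantile_stratify(expr, normalized, n_bins=10)
    cors = profile.correlations.set_index(["assay", "strand_class"])["spearman_rho"]
    return {
        "rho_expression_xr_ts": float(cors[("xr", "TS")]),
        "rho_expression_damage_ts": float(cors[("damage", "TS")]),
        "rho_expression_damage_nts": float(cors[("damage", "NTS")]),
        "n": len(genes),
    }


# ------------------------------------------------------------ relative damage


def relative_damage_recovery(
    seed: int, multipliers: tuple[float, ...] = (2.0, 1.5, 1.2, 0.8)
) -> dict:
    """Recover per-sample genome-wide damage-rate multipliers from NTS
    Damage-seq site-occupancy counts against the pseudo-reference.

    One read per unrepaired lesion (library yield tracks adduct load) and
    deduplicated site counts keep the measurement depth-robust: the depth
    check duplicates one sample's reads wholesale and expects no shift.
    """
    base = SimConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length=1_400_000,
        n_genes=250,
        gene_length_range=(8_000, 12_000),
        gc_content=0.55,
        damage_rate=0.04,
        tcr_rate_coef=0.3,
        gr_rate_ts=0.01,
        gr_rate_nts=0.01,
        background_read_fraction=0.0,
    )
    genome, genes = simulate_genome(base)
    rng = substream(seed, "reldmg-expression")
    expr = pd.Series(rng.gamma(0.5, 2.0, len(genes)), index=genes["gene_id"].to_numpy())
    calls = {}
    for i, m in enumerate(multipliers):
        cfg = SimConfig(**{**base.__dict__, "damage_rate": base.damage_rate * m})
        truth, _ = simulate_lesions(genome, genes, expr, cfg, label=f"lesions:s{i}")
        reads = emit_damage_reads(truth, genome, cfg, sample=f"s{i}", n_reads=None)
        calls[f"s{i}"], _ = filter_damage_reads(reads[READ_COLUMNS], genome)
    mat = build_count_matrix(calls, genes, assay="damage", dedup=True)
    nts = mat.wide("NTS")
    gg = genes.set_index("gene_id")["gg_nts"]
    rel = relative_damage(nts, gg)
    target = np.array(multipliers) / np.mean(multipliers)
    got = rel.reindex([f"s{i}" for i in range(len(multipliers))]).to_numpy()
    rel_err = np.abs(got - target) / target

    # depth change: sequence sample 0's library twice over
    deeper = dict(calls)
    dup = calls["s0"].copy()
    dup["read_id"] = dup["read_id"] + ":dup"
    deeper["s0"] = pd.concat([calls["s0"], dup], ignore_index=True)
    mat2 = build_count_matrix(deeper, genes, assay="damage", dedup=True)
    rel2 = relative_damage(mat2.wide("NTS"), gg)
    shift = np.abs(rel2.reindex(rel.index).to_numpy() - rel.to_numpy())
    return {
        "max_rel_error_pct": 100.0 * float(rel_err.max()),
        "depth_invariance_max_shift_pct": 100.0 * float(shift.max()),
        "recovered": got.tolist(),
        "target": target.tolist(),
        "n": len(genes),
    }


# ------------------------------------------------------------ normalization invariants


def normalization_invariants(seed: int, n_genes: int = 300, n_samples: int = 4) -> dict:
    """Exercise the algebraic guarantees on random count tables: exact
    reconstruction, depth invariance of median-of-ratios normalization (up to
    one global scalar), and TS/(TS+NTS) bias cancellation."""
    rng = substream(seed, "norm-invariants")
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    gm = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": "chr1",
            "start": np.arange(n_genes) * 2_000,
            "end": np.arange(n_genes) * 2_000 + 1_500,
            "strand": "+",
            "length": 1_500,
            "gg_ts": rng.integers(10, 120, n_genes),
            "gg_nts": rng.integers(10, 120, n_genes),
            "is_mito": False,
        }
    )
    rows = []
    for g in gene_ids:
        for cls in ("TS", "NTS"):
            for s in samples:
                rows.append((g, cls, s, int(rng.poisson(60) + 1)))
    counts = pd.DataFrame(rows, columns=["gene_id", "strand_class", "sample", "count"])

    per_gene = counts.groupby(["gene_id", "sample"])["count"].sum().unstack()
    sf = size_factors(per_gene)
    nm = normalize(counts, sf, gm, mode="gg")
    recon = (nm.reconstruct_raw() - nm.values["raw"]).abs().max()

    # double every count in one sample: normalized matrix unchanged up to a
    # single global scalar (median-of-ratios factors absorb pure depth)
    scaled = counts.copy()
    mask = scaled["sample"] == samples[0]
    scaled.loc[mask, "count"] *= 2
    sf2 = size_factors(scaled.groupby(["gene_id", "sample"])["count"].sum().unstack())
    nm2 = normalize(scaled, sf2, gm, mode="gg")
    v1 = nm.values.set_index(["gene_id", "strand_class", "sample"])["value"]
    v2 = nm2.values.set_index(["gene_id", "strand_class", "sample"])["value"]
    ratio = (v2 / v1).to_numpy()
    depth_dev = float(np.abs(ratio / ratio.mean() - 1.0).max())

    # factor ratios scale with depth: factor_s0/factor_s1 doubles exactly
    factor_ratio_shift = abs((sf2[samples[0]] / sf2[samples[1]]) / (sf[samples[0]] / sf[samples[1]]) - 2.0)

    ts = rng.integers(0, 50, n_genes).astype(float)
    nts = rng.integers(1, 50, n_genes).astype(float)
    shared = rng.uniform(0.1, 10.0, n_genes)
    r1 = ts_ratio(ts, nts)
    r2 = ts_ratio(ts * shared, nts * shared)
    ratio_invariance = float(np.nanmax(np.abs(r1 - r2)))
    in_range = bool(np.nanmin(r1) >= 0.0 and np.nanmax(r1) <= 1.0)
    return {
        "reconstruction_max_abs_error": float(recon),
        "depth_invariance_max_rel_dev": depth_dev,
        "factor_ratio_depth_shift": float(factor_ratio_shift),
        "ts_ratio_shared_factor_max_dev": ratio_invariance,
        "ts_ratio_in_unit_interval": in_range,
        "n": n_genes,
    }


# ------------------------------------------------------------ QC fidelity


def qc_toy_tables() -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], dict[str, set]]:
    """A 10-gene table where each gene exercises one QC criterion or its
    boundary; returns (gene_model, rnaseq, raw matrices, expected failures)."""
    design = {
        # gene_id: (gg_ts, gg_nts, length, expr, rna, damage, xr, in_xr)
        "g01": (50, 50, 5_000, 30, 30, 40, 40, True),   # passes everything
        "g02": (50, 50, 5_000, 0, 0, 40, 40, True),     # no expression (+ <20 RNA reads)
        "g03": (50, 50, 5_000, 30, 30, 40, 40, False),  # absent from XR table
        "g04": (9, 9, 5_000, 30, 30, 40, 40, True),     # both strands under the GG floor
        "g05": (9, 10, 5_000, 30, 30, 40, 40, True),    # boundary: 10 on one strand passes
        "g06": (50, 50, 100_000, 30, 30, 40, 40, True), # exactly 100 kb fails (strict <)
        "g07": (50, 50, 99_999, 30, 30, 40, 40, True),  # just under 100 kb passes
        "g08": (50, 50, 5_000, 30, 30, 40, 19, True),   # 19 XR reads in total
        "g09": (50, 50, 5_000, 30, 30, 40, 20, True),   # boundary: 20 reads passes
        "g10": (50, 50, 5_000, 5, 19, 40, 40, True),    # expressed but <20 RNA reads
    }
    expected = {
        "g02": {"no-expression", "reads<20"},
        "g03": {"unmatched-id", "reads<20"},  # zero XR reads also trips (v)
        "g04": {"gg<10"},
        "g06": {"length>=100Kb"},
        "g08": {"reads<20"},
        "g10": {"reads<20"},
    }
    rows, rna_rows, dmg_rows, xr_rows = [], [], [], []
    pos = 0
    for g, (gg_ts, gg_nts, length, expr, rna, dmg, xr, in_xr) in design.items():
        rows.append((g, "chr1", pos, pos + length, "+", length, gg_ts, gg_nts, False))
        pos += length + 100
        rna_rows.append((g, expr, rna - expr))
        for cls, val in (("TS", dmg // 2), ("NTS", dmg - dmg // 2)):
            dmg_rows.append((g, cls, "s1", val))
        if in_xr:
            for cls, val in (("TS", xr // 2), ("NTS", xr - xr // 2)):
                xr_rows.append((g, cls, "s1", val))
    gm = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "length", "gg_ts", "gg_nts", "is_mito"]
    )
    rna = pd.DataFrame(rna_rows, columns=["gene_id", "rna_r1", "rna_r2"]).set_index("gene_id")
    mats = {
        "damage": pd.DataFrame(dmg_rows, columns=["gene_id", "strand_class", "sample", "count"]),
        "xr": pd.DataFrame(xr_rows, columns=["gene_id", "strand_class", "sample", "count"]),
    }
    return gm, rna, mats, expected


def qc_fidelity() -> dict:
    """Exactly the intended toy genes must fail, for exactly the intended
    reasons, honoring the strict boundaries."""
    gm, rna, mats, expected = qc_toy_tables()
    report = qc_filter(gm, rna, mats)
    from .normalize import QC_CRITERIA

    mis = 0
    for g in gm["gene_id"]:
        failed = {c for c in QC_CRITERIA if report.loc[g, c]}
        if failed != expected.get(g, set()):
            mis += 1
    return {"misclassified_genes": mis, "n": len(gm)}


# ------------------------------------------------------------ mito contrast


def mito_contrast_demo(seed: int, n_reads: int = 50_000) -> dict:
    """Default-conditions XR-seq: mitochondria-like reads are pure background
    (no excision repair there), so their GG-signature fraction sits at the
    genomic chance level while nuclear reads are signature-rich."""
    cfg = SimConfig(seed=seed, n_reads_per_assay=n_reads, background_read_fraction=0.05)
    genome, genes = simulate_genome(cfg)
    rng = substream(seed, "mito-expression")
    expr = pd.Series(rng.gamma(0.5, 2.0, len(genes)), index=genes["gene_id"].to_numpy())
    truth, _ = simulate_lesions(genome, genes, expr, cfg)
    reads = emit_xr_reads(truth, genome, cfg, sample="mito")
    contrast = mito_background_contrast(reads[READ_COLUMNS], genome, "xr")
    return {
        "mito_gg_signature_pct": 100.0 * contrast["mito"]["fraction"],
        "nuclear_gg_signature_pct": 100.0 * contrast["nuclear"]["fraction"],
        "n": n_reads,
    }
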