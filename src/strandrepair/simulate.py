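"""Forward simulator for cisplatin damage and excision repair sequencing data.

The generative model, per GG dinucleotide site:

* damage — lesions deposited uniformly across the genome, count per site
  ~ Poisson(d), independent of strand, position and transcription;
* repair — each lesion acquires an exponential waiting time with a
  strand-class rate: k_TCR * e_g + k_GR_TS on the transcribed strand of gene
  g with expression e_g; k_GR_NTS on the non-transcribed strand and in
  intergenic sequence; 0 on the mitochondria-like chromosome (no excision
  repair in mitochondria). A lesion is repaired by collection time T iff its
  waiting time is <= T.

Damage-seq then samples UNREPAIRED lesions (fixed-length reads starting
immediately 3' of the lesion) and XR-seq samples lesions excised in the
snapshot window (T - delta, T] as 21-31 nt oligomers carrying the lesion
5-8 nt from their 3' end. Both assays admit a configurable background read
fraction placed uniformly at random (mitochondria-like noise), and RNA-seq
counts are negative binomial with mean proportional to expression x length.

All randomness flows from ``SimConfig.seed`` through labelled substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .genome import GenomeRef
from .quantify import annotate_genes, gg_positions, GENE_COLUMNS
from . import reads as _reads

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_genome",
    "simulate_expression",
    "simulate_lesions",
    "emit_damage_reads",
    "emit_xr_reads",
    "emit_rnaseq_counts",
    "simulate_dataset",
]

MITO_CHROM = "chrM"


@dataclass
class SimConfig:
    """Study conditions for the forward model; defaults give a desk-scale
    genome with mouse-like GC content and a 4 h cisplatin treatment."""

    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (800, 3_000)
    gc_content: float = 0.42
    expression_shape: float = 0.5  # gamma shape; scale chosen so mean e_g = 1
    damage_rate: float = 0.2  # expected lesions per GG site (d)
    tcr_rate_coef: float = 0.5  # per hour per unit expression (k_TCR)
    gr_rate_ts: float = 0.02  # per hour (k_GR,TS)
    gr_rate_nts: float = 0.02  # per hour (k_GR,NTS)
    T: float = 4.0  # hours of repair before collection
    xr_len_range: tuple[int, int] = (21, 31)
    background_read_fraction: float = 0.05
    n_reads_per_assay: int = 100_000
    rnaseq_dispersion: float = 10.0
    seed: int = 0
    # extensions beyond the core parameter set
    n_samples: int = 2
    damage_read_length: int = 50
    xr_snapshot_window: float = 0.25  # hours; XR-seq samples (T - delta, T]
    low_mapq_fraction: float = 0.0  # fraction of emitted reads given MAPQ <= 20
    mito_fraction: float = 0.125  # mito chromosome length / chrom_length

    def validate(self) -> list[str]:
        """Return a list of precondition violations (empty when valid)."""
        v = []
        if self.n_chromosomes < 1:
            v.append("n_chromosomes must be >= 1")
        if self.chrom_length < 100:
            v.append("chrom_length must be >= 100")
        if self.n_genes < 0:
            v.append("n_genes must be >= 0")
        lo, hi = self.gene_length_range
        if not (2 <= lo <= hi):
            v.append("gene_length_range must satisfy 2 <= lo <= hi")
        if not 0.0 < self.gc_content <= 1.0:
            v.append("gc_content must be in (0, 1]")
        for name in ("damage_rate", "tcr_rate_coef", "gr_rate_ts", "gr_rate_nts"):
            if getattr(self, name) < 0:
                v.append(f"{name} must be >= 0")
        if self.T <= 0:
            v.append("T must be > 0")
        xlo, xhi = self.xr_len_range
        if not (1 <= xlo <= xhi <= self.chrom_length):
            v.append("xr_len_range must be ordered and within [1, chrom_length]")
        if not 0.0 <= self.background_read_fraction < 1.0:
            v.append("background_read_fraction must be in [0, 1)")
        if self.n_reads_per_assay < 0:
            v.append("n_reads_per_assay must be >= 0")
        if self.rnaseq_dispersion <= 0:
            v.append("rnaseq_dispersion must be > 0")
        if self.n_samples < 1:
            v.append("n_samples must be >= 1")
        if self.damage_read_length < 3:
            v.append("damage_read_length must be >= 3")
        if not 0 < self.xr_snapshot_window <= self.T:
            v.append("xr_snapshot_window must be in (0, T]")
        if not 0.0 <= self.low_mapq_fraction <= 1.0:
            v.append("low_mapq_fraction must be in [0, 1]")
        return v

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


# ------------------------------------------------------------------ genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


MIN_GG_PER_STRAND = 10


def _inject_gg(seq: np.ndarray, lo: int, hi: int, strand: str, rng: np.random.Generator) -> None:
    """Overwrite a random interior dinucleotide with GG ('+') or CC ('-')."""
    pos = int(rng.integers(lo, hi - 1))
    pair = b"GG" if strand == "+" else b"CC"
    seq[pos] = pair[0]
    seq[pos + 1] = pair[1]


def simulate_genome(config: SimConfig) -> tuple[GenomeRef, pd.DataFrame]:
    """Generate chromosomes and a non-overlapping, strand-balanced annotation.

    Genes are packed with random intergenic gaps; each gene is guaranteed at
    least ``MIN_GG_PER_STRAND`` GG dinucleotides per strand (deficient genes
    get GG/CC dinucleotides written in at random interior positions). One
    extra small chromosome (chrM) is mitochondria-like and carries no genes.
    """
    config.require_valid()
    rng = substream(config.seed, "genome")

    seqs: dict[str, np.ndarray] = {}
    nuclear = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for chrom in nuclear:
        seqs[chrom] = _random_sequence(rng, config.chrom_length, config.gc_content)
    mito_len = max(200, int(config.chrom_length * config.mito_fraction))
    seqs[MITO_CHROM] = _random_sequence(rng, mito_len, config.gc_content)

    # distribute genes round-robin over nuclear chromosomes
    per_chrom = [config.n_genes // len(nuclear)] * len(nuclear)
    for i in range(config.n_genes % len(nuclear)):
        per_chrom[i] += 1
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = np.array(["+", "-"] * ((config.n_genes + 1) // 2))[: config.n_genes]
    strands = rng.permutation(strands)

    rows = []
    gi = 0
    for chrom, k in zip(nuclear, per_chrom):
        if k == 0:
            continue
        lens = lengths[gi : gi + k]
        free = config.chrom_length - int(lens.sum())
        if free < k + 1:
            raise ValueError(
                f"infeasible packing: {k} genes of total length {int(lens.sum())} "
                f"do not fit on {chrom} (length {config.chrom_length})"
            )
        # random gap sizes summing to `free`, each >= 1
        cuts = np.sort(rng.choice(np.arange(1, free), size=k, replace=False))
        gaps = np.diff(np.concatenate([[0], cuts, [free]]))
        pos = 0
        for j in range(k):
            pos += int(gaps[j])
            start, end = pos, pos + int(lens[j])
            rows.append((f"g{gi + j + 1:04d}", chrom, start, end, strands[gi + j]))
            pos = end
        gi += k

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    # guarantee the per-strand GG floor inside every gene
    for row in genes.itertuples(index=False):
        seq = seqs[row.chrom]
        for strand in "+-":
            for _ in range(10_000):
                sub = seq[row.start : row.end].tobytes().decode("ascii")
                if len(gg_positions(sub, strand)) >= MIN_GG_PER_STRAND:
                    break
                _inject_gg(seq, row.start, row.end, strand, rng)
            else:
                raise RuntimeError("could not satisfy GG floor; gene too short?")

    genome = GenomeRef(
        {c: a.tobytes().decode("ascii") for c, a in seqs.items()},
        mito_chroms=frozenset({MITO_CHROM, "MT"}),
    )
    return genome, annotate_genes(genes, genome)


def simulate_expression(config: SimConfig, genes: pd.DataFrame) -> pd.Series:
    """Per-gene expression e_g ~ Gamma(shape, scale) with mean 1."""
    rng = substream(config.seed, "expression")
    shape = config.expression_shape
    vals = rng.gamma(shape, 1.0 / shape, size=len(genes))
    return pd.Series(vals, index=genes["gene_id"].to_numpy(), name="expression")


# ------------------------------------------------------------------ lesions


def _site_table(genome: GenomeRef, genes: pd.DataFrame) -> pd.DataFrame:
    """All GG sites genome-wide with gene assignment and repair strand class."""
    frames = []
    gene_by_chrom = {c: sub.sort_values("start") for c, sub in genes.groupby("chrom")}
    for chrom, seq in genome.sequences.items():
        for strand in "+-":
            pos = gg_positions(seq, strand)
            if len(pos) == 0:
                continue
            gene_id = np.full(len(pos), "", dtype=object)
            cls = np.full(len(pos), "intergenic", dtype=object)
            sub = gene_by_chrom.get(chrom)
            if sub is not None:
                starts = sub["start"].to_numpy(np.int64)
                ends = sub["end"].to_numpy(np.int64)
                ids = sub["gene_id"].to_numpy()
                gstr = sub["strand"].to_numpy()
                gi = np.searchsorted(starts, pos, side="right") - 1
                inside = (gi >= 0) & (pos < ends[np.clip(gi, 0, None)])
                gene_id[inside] = ids[gi[inside]]
                cls[inside] = np.where(gstr[gi[inside]] != strand, "TS", "NTS")
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "strand": strand,
                        "position": pos,
                        "gene_id": gene_id,
                        "strand_class": cls,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _site_rates(sites: pd.DataFrame, expression: pd.Series, config: SimConfig,
                mito: set[str]) -> np.ndarray:
    """Per-site exponential repair rate under the strand-class model."""
    rate = np.full(len(sites), config.gr_rate_nts, dtype=float)
    is_ts = (sites["strand_class"] == "TS").to_numpy()
    if is_ts.any():
        e = expression.reindex(sites.loc[is_ts, "gene_id"]).to_numpy()
        rate[is_ts] = config.tcr_rate_coef * e + config.gr_rate_ts
    rate[sites["chrom"].isin(mito).to_numpy()] = 0.0  # no excision repair in mito
    return rate


def simulate_lesions(
    genome: GenomeRef,
    genes: pd.DataFrame,
    expression: pd.Series,
    config: SimConfig,
    label: str = "lesions",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the lesion history and its per-gene/strand kinetic summary.

    Returns (truth, kinetics). ``truth`` has one row per lesion with its
    repair time; ``kinetics`` holds the analytic expectations per gene and
    strand class: total_damage = d x #GG sites, repaired_fraction_by_T =
    1 - exp(-rate T), instantaneous_repair_at_T = total_damage x rate x
    exp(-rate T).
    """
    config.require_valid()
    if (expression.reindex(genes["gene_id"]).fillna(0) < 0).any():
        raise ValueError("expression must be >= 0")
    rng = substream(config.seed, label)
    sites = _site_table(genome, genes)
    rate = _site_rates(sites, expression, config, set(genome.mito_chroms))

    n_per_site = rng.poisson(config.damage_rate, size=len(sites))
    reps = np.repeat(np.arange(len(sites)), n_per_site)
    truth = sites.iloc[reps].reset_index(drop=True)
    site_rate = rate[reps]
    with np.errstate(divide="ignore"):
        scale = np.where(site_rate > 0, 1.0 / np.where(site_rate > 0, site_rate, 1.0), np.inf)
    repair_time = np.where(np.isinf(scale), np.inf, rng.exponential(np.where(np.isinf(scale), 1.0, scale)))
    truth["repair_time"] = repair_time
    truth["repaired_by_T"] = repair_time <= config.T
    truth.insert(0, "lesion_id", [f"L{i:08d}" for i in range(len(truth))])

    # analytic per-gene/strand kinetics
    rows = []
    e = expression.reindex(genes["gene_id"]).fillna(0.0)
    for row in genes.itertuples(index=False):
        for cls, n_sites in (("TS", row.gg_ts), ("NTS", row.gg_nts)):
            if cls == "TS":
                r = config.tcr_rate_coef * float(e[row.gene_id]) + config.gr_rate_ts
            else:
                r = config.gr_rate_nts
            if row.is_mito:
                r = 0.0
            total = config.damage_rate * n_sites
            frac = 1.0 - np.exp(-r * config.T)
            inst = total * r * np.exp(-r * config.T)
            rows.append((row.gene_id, cls, total, frac, inst, r))
    kinetics = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "strand_class",
            "total_damage",
            "repaired_fraction_by_T",
            "instantaneous_repair_at_T",
            "repair_rate",
        ],
    )
    return truth, kinetics


# ------------------------------------------------------------------ reads


def _background_reads(
    rng: np.random.Generator, genome: GenomeRef, n: int, lengths: np.ndarray
) -> pd.DataFrame:
    chroms = np.array(genome.chroms)
    sizes = np.array([genome.lengths[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    maxlen = sizes[pick].astype(np.int64)
    lengths = np.minimum(lengths, maxlen)
    start = (rng.random(n) * (maxlen - lengths + 1)).astype(np.int64)
    return pd.DataFrame(
        {
            "chrom": chroms[pick],
            "start": start,
            "end": start + lengths,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
        }
    )


def _apply_mapq(rng: np.random.Generator, df: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    mapq = np.full(len(df), 60, dtype=np.int64)
    n_low = int(round(config.low_mapq_fraction * len(df)))
    if n_low:
        low = rng.choice(len(df), size=n_low, replace=False)
        mapq[low] = 7
    df["mapq"] = mapq
    return df


def _damage_geometry(truth: pd.DataFrame, L: int) -> pd.DataFrame:
    """Read coordinates for Damage-seq: 5' end immediately 3' of the lesion."""
    pos = truth["position"].to_numpy(np.int64)
    plus = (truth["strand"] == "+").to_numpy()
    start = np.where(plus, pos + 2, pos - 1 - L)
    end = start + L
    return pd.DataFrame(
        {
            "chrom": truth["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "strand": truth["strand"].to_numpy(),
            "lesion_id": truth["lesion_id"].to_numpy(),
        }
    )


def emit_damage_reads(
    truth: pd.DataFrame,
    genome: GenomeRef,
    config: SimConfig,
    sample: str = "s1",
    n_reads: int | None = 0,
) -> pd.DataFrame:
    """Emit aligned Damage-seq reads from unrepaired lesions.

    ``n_reads=0`` uses config.n_reads_per_assay; ``n_reads=None`` emits
    exactly one read per unrepaired lesion (library yield proportional to
    adduct load) with no background. Reads that would overrun a chromosome
    end are resampled in fixed-depth mode and dropped in yield mode.
    """
    config.require_valid()
    rng = substream(config.seed, f"damage_reads:{sample}")
    unrepaired = truth[~truth["repaired_by_T"]].reset_index(drop=True)
    L = config.damage_read_length
    lens = {c: n for c, n in genome.lengths.items()}

    if n_reads is None:
        reads = _damage_geometry(unrepaired, L)
        ok = (reads["start"] >= 2) & (
            reads["end"].to_numpy() + 2 <= reads["chrom"].map(lens).to_numpy()
        )
        reads = reads[ok.to_numpy()].reset_index(drop=True)
    else:
        n = n_reads or config.n_reads_per_assay
        n_bg = rng.binomial(n, config.background_read_fraction)
        n_sig = n - n_bg
        if n_sig > 0 and len(unrepaired) == 0:
            raise ValueError("no unrepaired lesions to sample Damage-seq reads from")
        parts = []
        need = n_sig
        while need > 0:
            idx = rng.integers(0, len(unrepaired), size=need)
            cand = _damage_geometry(unrepaired.iloc[idx].reset_index(drop=True), L)
            ok = (cand["start"] >= 2) & (
                cand["end"].to_numpy() + 2 <= cand["chrom"].map(lens).to_numpy()
            )
            cand = cand[ok.to_numpy()]
            parts.append(cand)
            need -= len(cand)
        bg = _background_reads(rng, genome, n_bg, np.full(n_bg, L, dtype=np.int64))
        bg["lesion_id"] = [f"bg{i}" for i in range(n_bg)]
        reads = pd.concat(parts + [bg], ignore_index=True) if parts or n_bg else _damage_geometry(
            unrepaired.iloc[:0], L
        )

    reads = reads.reset_index(drop=True)
    reads["read_id"] = [
        f"{sample}:dmg:{i}:{lid}" for i, lid in enumerate(reads["lesion_id"])
    ]
    reads = _apply_mapq(rng, reads, config)
    return reads[["read_id", "chrom", "start", "end", "strand", "mapq", "lesion_id"]]


def _xr_candidate(
    truth: pd.DataFrame, lengths: np.ndarray, offsets: np.ndarray
) -> pd.DataFrame:
    """XR read coordinates for lesions with window placement offset j.

    j is the GG start offset inside the 4-nt window (0, 1 or 2; j = 2 puts
    the GG closest to the 3' end).
    """
    pos = truth["position"].to_numpy(np.int64)
    plus = (truth["strand"] == "+").to_numpy()
    end_plus = pos + 8 - offsets
    start_plus = end_plus - lengths
    start_minus = pos - 7 + offsets
    end_minus = start_minus + lengths
    return pd.DataFrame(
        {
            "chrom": truth["chrom"].to_numpy(),
            "start": np.where(plus, start_plus, start_minus),
            "end": np.where(plus, end_plus, end_minus),
            "strand": truth["strand"].to_numpy(),
            "lesion_id": truth["lesion_id"].to_numpy(),
        }
    )


def _xr_valid_mask(reads: pd.DataFrame, genome: GenomeRef, truth: pd.DataFrame) -> np.ndarray:
    """A placement is valid iff the filter's 3'-most-GG rule recovers the
    emitted lesion and the read lies fully inside its chromosome."""
    lens = reads["chrom"].map(genome.lengths).to_numpy()
    ok = (reads["start"].to_numpy() >= 0) & (reads["end"].to_numpy() <= lens)
    # the window itself must be in bounds too
    plus = (reads["strand"] == "+").to_numpy()
    ok &= np.where(plus, reads["end"].to_numpy() - 8 >= 0, reads["start"].to_numpy() + 8 <= lens)
    if not ok.any():
        return ok
    probe = reads.loc[ok].copy()
    probe["mapq"] = 60
    probe["read_id"] = np.arange(len(probe))
    calls, _ = _reads.filter_xr_reads(probe, genome)
    recovered = np.full(int(ok.sum()), -1, dtype=np.int64)
    recovered[calls["read_id"].to_numpy(np.int64)] = calls["lesion_start"].to_numpy(np.int64)
    out = np.zeros(len(reads), dtype=bool)
    out[np.flatnonzero(ok)] = recovered == truth.loc[ok.nonzero()[0], "position"].to_numpy(np.int64)
    return out


def emit_xr_reads(
    truth: pd.DataFrame,
    genome: GenomeRef,
    config: SimConfig,
    sample: str = "s1",
    n_reads: int | None = 0,
) -> pd.DataFrame:
    """Emit XR-seq oligomer reads from lesions excised in (T - delta, T].

    Lengths are uniform over ``xr_len_range``; the GG placement offset within
    the 5-8 nt window is drawn uniformly from the placements the filter can
    invert (the 3'-most slot is always one of them). ``n_reads`` semantics as
    in :func:`emit_damage_reads`.
    """
    config.require_valid()
    rng = substream(config.seed, f"xr_reads:{sample}")
    lo_t = config.T - config.xr_snapshot_window
    window = truth[(truth["repair_time"] > lo_t) & (truth["repair_time"] <= config.T)]
    window = window.reset_index(drop=True)
    xlo, xhi = config.xr_len_range

    def draw(subset: pd.DataFrame) -> pd.DataFrame:
        lengths = rng.integers(xlo, xhi + 1, size=len(subset))
        # uniform over valid placements: evaluate all three, then pick
        valid = np.zeros((len(subset), 3), dtype=bool)
        cands = []
        for j in range(3):
            off = np.full(len(subset), j, dtype=np.int64)
            cand = _xr_candidate(subset, lengths, off)
            valid[:, j] = _xr_valid_mask(cand, genome, subset)
            cands.append(cand)
        n_valid = valid.sum(axis=1)
        pickable = n_valid > 0
        choice = np.zeros(len(subset), dtype=np.int64)
        u = rng.random(len(subset))
        cum = np.cumsum(valid, axis=1)
        target = np.ceil(u * n_valid.clip(min=1)).astype(np.int64)
        for j in range(3):
            choice[(cum[:, j] == target) & (choice == 0) & valid[:, j]] = j
        rows = [cands[j][(choice == j) & pickable] for j in range(3)]
        return pd.concat(rows, ignore_index=True)

    if n_reads is None:
        reads = draw(window)
    else:
        n = n_reads or config.n_reads_per_assay
        n_bg = rng.binomial(n, config.background_read_fraction)
        n_sig = n - n_bg
        if n_sig > 0 and len(window) == 0:
            raise ValueError("no lesions excised in the snapshot window")
        parts, need = [], n_sig
        while need > 0:
            idx = rng.integers(0, len(window), size=need)
            got = draw(window.iloc[idx].reset_index(drop=True))
            parts.append(got)
            need -= len(got)
        bg_len = rng.integers(xlo, xhi + 1, size=n_bg)
        bg = _background_reads(rng, genome, n_bg, bg_len)
        bg["lesion_id"] = [f"bg{i}" for i in range(n_bg)]
        frames = parts + ([bg] if n_bg else [])
        reads = (
            pd.concat(frames, ignore_index=True)
            if frames
            else _xr_candidate(window.iloc[:0], np.empty(0, np.int64), np.empty(0, np.int64))
        )

    reads = reads.reset_index(drop=True)
    reads["read_id"] = [f"{sample}:xr:{i}:{lid}" for i, lid in enumerate(reads["lesion_id"])]
    reads = _apply_mapq(rng, reads, config)
    return reads[["read_id", "chrom", "start", "end", "strand", "mapq", "lesion_id"]]


# ------------------------------------------------------------------ RNA-seq


def emit_rnaseq_counts(
    expression: pd.Series,
    genes: pd.DataFrame,
    config: SimConfig,
    sample_names: list[str] | None = None,
    library_sizes: list[float] | None = None,
    depth: int = 1_000_000,
) -> pd.DataFrame:
    """Negative-binomial gene x sample counts, mean ~ e_g x length x depth.

    variance = mu + mu^2 / dispersion; dispersion -> inf recovers Poisson.
    """
    config.require_valid()
    rng = substream(config.seed, "rnaseq")
    if sample_names is None:
        sample_names = [f"rna_r{i + 1}" for i in range(config.n_samples)]
    if library_sizes is None:
        library_sizes = [1.0] * len(sample_names)
    e = expression.reindex(genes["gene_id"]).fillna(0.0).to_numpy()
    len_kb = (genes["end"] - genes["start"]).to_numpy() / 1e3
    weight = e * len_kb
    total = weight.sum()
    base_mu = weight / total * depth if total > 0 else np.zeros_like(weight)
    disp = config.rnaseq_dispersion
    out = {}
    for name, lib in zip(sample_names, library_sizes):
        mu = base_mu * lib
        counts = np.zeros(len(mu), dtype=np.int64)
        pos = mu > 0
        p = disp / (disp + mu[pos])
        counts[pos] = rng.negative_binomial(disp, p)
        out[name] = counts
    return pd.DataFrame(out, index=pd.Index(genes["gene_id"].to_numpy(), name="gene_id"))


# ------------------------------------------------------------------ bundle


@dataclass
class SimBundle:
    """Everything one simulation run produces, ready for the pipeline."""

    config: SimConfig
    genome: GenomeRef
    genes: pd.DataFrame
    expression: pd.Series
    truth: dict[str, pd.DataFrame]  # per sample lesion histories
    kinetics: pd.DataFrame
    damage_reads: dict[str, pd.DataFrame] = field(default_factory=dict)
    xr_reads: dict[str, pd.DataFrame] = field(default_factory=dict)
    rnaseq: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        from .quantify import genes_to_bed

        genes_to_bed(self.genes, outdir / "genes.bed")
        self.genes[GENE_COLUMNS].to_csv(outdir / "gene_model.tsv", sep="\t", index=False)
        self.expression.rename_axis("gene_id").to_csv(outdir / "expression_truth.tsv", sep="\t")
        self.kinetics.to_csv(outdir / "kinetics.tsv", sep="\t", index=False)
        for sample, df in self.truth.items():
            df.to_csv(outdir / f"lesion_truth_{sample}.tsv", sep="\t", index=False)
        for assay, pool in (("damage", self.damage_reads), ("xr", self.xr_reads)):
            for sample, df in pool.items():
                _reads.write_sam(df, self.genome, str(outdir / f"{assay}_{sample}.sam"))
                _reads.write_bed6(
                    df.assign(read_id=df["lesion_id"]), str(outdir / f"{assay}_{sample}.bed")
                )
        if self.rnaseq is not None:
            self.rnaseq.to_csv(outdir / "rnaseq_counts.tsv", sep="\t")


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Run the full forward model: genome, expression, per-sample lesion
    histories, and Damage-seq / XR-seq / RNA-seq outputs."""
    config.require_valid()
    genome, genes = simulate_genome(config)
    expression = simulate_expression(config, genes)
    samples = [f"r{i + 1}" for i in range(config.n_samples)]
    truth, damage, xr = {}, {}, {}
    kinetics = None
    for s in samples:
        t, kin = simulate_lesions(genome, genes, expression, config, label=f"lesions:{s}")
        truth[s] = t
        if kinetics is None:
            kinetics = kin
        damage[s] = emit_damage_reads(t, genome, config, sample=s)
        xr[s] = emit_xr_reads(t, genome, config, sample=s)
    rnaseq = emit_rnaseq_counts(expression, genes, config, sample_names=[f"rna_{s}" for s in samples])
    return SimBundle(
        config=config,
        genome=genome,
        genes=genes,
        expression=expression,
        truth=truth,
        kinetics=kinetics,
        damage_reads=damage,
        xr_reads=xr,
        rnaseq=rnaseq,
    )
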