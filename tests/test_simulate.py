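"""Forward-simulator behaviour: determinism, packing, kinetics, read geometry."""

import numpy as np
import pandas as pd
import pytest

from strandrepair import (
    SimConfig,
    emit_damage_reads,
    emit_rnaseq_counts,
    emit_xr_reads,
    simulate_genome,
    simulate_lesions,
)
from strandrepair.genome import GenomeRef
from strandrepair.reads import READ_COLUMNS, read_gg_signature_fraction


def brute_gg(seq: str, strand: str) -> int:
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        seq = seq.translate(comp)[::-1]
    return sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "GG")


def test_same_seed_reproduces_identical_genome_and_annotation(tmp_path):
    cfg = SimConfig(seed=3, n_genes=10, chrom_length=30_000)
    g1, a1 = simulate_genome(cfg)
    g2, a2 = simulate_genome(cfg)
    p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
    g1.to_fasta(p1)
    g2.to_fasta(p2)
    assert p1.read_bytes() == p2.read_bytes()
    pd.testing.assert_frame_equal(a1, a2)


def test_pure_gc_genome_has_brute_force_verified_gg_counts():
    cfg = SimConfig(seed=4, gc_content=1.0, n_genes=8, chrom_length=20_000)
    genome, genes = simulate_genome(cfg)
    assert set("".join(genome.sequences.values())) <= {"G", "C"}
    for row in genes.itertuples(index=False):
        seq = genome.fetch(row.chrom, row.start, row.end)
        plus, minus = brute_gg(seq, "+"), brute_gg(seq, "-")
        want_nts, want_ts = (plus, minus) if row.strand == "+" else (minus, plus)
        assert (row.gg_nts, row.gg_ts) == (want_nts, want_ts)


def test_zero_genes_yields_valid_genome_with_empty_annotation():
    genome, genes = simulate_genome(SimConfig(seed=1, n_genes=0))
    assert len(genes) == 0
    assert len(genome.sequences) == SimConfig().n_chromosomes + 1  # + chrM


def test_genes_are_non_overlapping_strand_balanced_and_gg_floored():
    cfg = SimConfig(seed=9, n_genes=30)
    _, genes = simulate_genome(cfg)
    assert set(genes["strand"]) == {"+", "-"}
    assert (genes[["gg_ts", "gg_nts"]] >= 10).all().all()
    for _, sub in genes.groupby("chrom"):
        sub = sub.sort_values("start")
        assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()


def test_infeasible_packing_raises_configuration_error():
    cfg = SimConfig(seed=0, n_genes=10, chrom_length=5_000, n_chromosomes=1,
                    gene_length_range=(1_000, 1_000))
    with pytest.raises(ValueError, match="infeasible"):
        simulate_genome(cfg)


@pytest.fixture()
def small_sim():
    cfg = SimConfig(seed=21, n_genes=10, chrom_length=50_000, n_chromosomes=1)
    genome, genes = simulate_genome(cfg)
    expr = pd.Series(1.0, index=genes["gene_id"].to_numpy())
    return cfg, genome, genes, expr


def test_zero_rates_leave_every_lesion_unrepaired(small_sim):
    cfg, genome, genes, expr = small_sim
    cfg = SimConfig(**{**cfg.__dict__, "tcr_rate_coef": 0.0, "gr_rate_ts": 0.0, "gr_rate_nts": 0.0})
    truth, kin = simulate_lesions(genome, genes, expr, cfg)
    assert not truth["repaired_by_T"].any()
    assert (kin["repaired_fraction_by_T"] == 0.0).all()


def test_saturating_tcr_repairs_virtually_all_ts_lesions(small_sim):
    cfg, genome, genes, expr = small_sim
    cfg = SimConfig(**{**cfg.__dict__, "tcr_rate_coef": 1e3, "gr_rate_ts": 0.0, "gr_rate_nts": 0.0})
    truth, kin = simulate_lesions(genome, genes, expr, cfg)
    ts = truth[truth["strand_class"] == "TS"]
    assert ts["repaired_by_T"].all()
    assert (kin.loc[kin["strand_class"] == "TS", "repaired_fraction_by_T"] > 0.999).all()


def test_lesion_count_matches_poisson_expectation_within_3_sigma():
    # 500 GG sites on + only ("GGAT" repeat), d=0.2, no repair
    genome = GenomeRef({"chr1": "GGAT" * 500})
    genes = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand",
                                  "length", "gg_ts", "gg_nts", "is_mito"])
    cfg = SimConfig(seed=8, damage_rate=0.2, tcr_rate_coef=0.0, gr_rate_ts=0.0, gr_rate_nts=0.0)
    truth, _ = simulate_lesions(genome, genes, pd.Series(dtype=float), cfg)
    mean = 0.2 * 500
    assert abs(len(truth) - mean) < 3 * np.sqrt(mean)
    assert not truth["repaired_by_T"].any()


def test_unrepaired_counts_match_kinetics_prediction(default_bundle):
    """Observed unrepaired lesions per gene/strand ~ Poisson with mean
    total_damage x (1 - repaired_fraction_by_T)."""
    b = default_bundle
    truth = b.truth["r1"]
    unrep = (
        truth[(~truth["repaired_by_T"]) & (truth["gene_id"] != "")]
        .groupby(["gene_id", "strand_class"])
        .size()
    )
    kin = b.kinetics.set_index(["gene_id", "strand_class"])
    z = []
    for key, row in kin.iterrows():
        mu = row["total_damage"] * (1.0 - row["repaired_fraction_by_T"])
        if mu < 5:
            continue
        obs = unrep.get(key, 0)
        z.append((obs - mu) / np.sqrt(mu))
    z = np.array(z)
    assert (np.abs(z) < 3).mean() > 0.95
    assert np.abs(z).max() < 5


def test_transcribed_strand_keeps_less_damage_than_nts(default_bundle):
    b = default_bundle
    truth = b.truth["r1"]
    expressed = b.expression[b.expression > b.expression.median()].index
    unrep = (
        truth[(~truth["repaired_by_T"]) & truth["gene_id"].isin(expressed)]
        .groupby("strand_class")
        .size()
    )
    assert unrep["TS"] < unrep["NTS"]


def test_damage_read_geometry_places_gg_upstream_of_5prime_end():
    # lesion on - strand occupying (p-1, p): alignment must end at p-1
    genome = GenomeRef({"chr1": "A" * 100 + "CC" + "A" * 100})
    truth = pd.DataFrame(
        {
            "lesion_id": ["L1"],
            "chrom": ["chr1"],
            "strand": ["-"],
            "position": [101],  # 5' G of the GG on the damaged (-) strand
            "gene_id": [""],
            "strand_class": ["intergenic"],
            "repair_time": [np.inf],
            "repaired_by_T": [False],
        }
    )
    cfg = SimConfig(seed=0, background_read_fraction=0.0)
    reads = emit_damage_reads(truth, genome, cfg, n_reads=None)
    assert len(reads) == 1
    assert reads.loc[0, "end"] == 100  # half-open end just 5' of the CC pair
    assert reads.loc[0, "strand"] == "-"


def test_xr_read_lengths_stay_inside_the_oligomer_range(clean_bundle):
    b = clean_bundle
    for df in b.xr_reads.values():
        lengths = (df["end"] - df["start"]).to_numpy()
        assert lengths.min() >= 21 and lengths.max() <= 31


def test_background_fraction_sets_the_gg_signature_rate():
    """With background fraction b, observed signature fraction ~ (1-b) + b q,
    q the genomic chance of GG at the signature positions."""
    cfg = SimConfig(seed=17, background_read_fraction=0.5, n_reads_per_assay=40_000,
                    gc_content=0.30)
    genome, genes = simulate_genome(cfg)
    expr = pd.Series(1.0, index=genes["gene_id"].to_numpy())
    truth, _ = simulate_lesions(genome, genes, expr, cfg)
    reads = emit_damage_reads(truth, genome, cfg)
    got = read_gg_signature_fraction(reads[READ_COLUMNS], genome, "damage")["fraction"]
    q = 0.15 ** 2  # P(GG) at the two signature positions under 30% GC
    expect = 0.5 + 0.5 * q
    assert abs(got - expect) < 0.01


class TestRnaseqCounts:
    def test_unexpressed_gene_gets_zero_counts(self, small_sim):
        cfg, genome, genes, expr = small_sim
        expr = expr.copy()
        expr.iloc[0] = 0.0
        counts = emit_rnaseq_counts(expr, genes, cfg)
        assert (counts.loc[expr.index[0]] == 0).all()
        assert (counts.loc[expr.index[1]] > 0).any()

    def test_same_seed_reproduces_the_table(self, small_sim):
        cfg, genome, genes, expr = small_sim
        c1 = emit_rnaseq_counts(expr, genes, cfg)
        c2 = emit_rnaseq_counts(expr, genes, cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_large_dispersion_approaches_poisson_variance(self, small_sim):
        cfg, genome, genes, expr = small_sim
        cfg = SimConfig(**{**cfg.__dict__, "rnaseq_dispersion": 1e7})
        names = [f"s{i}" for i in range(2_000)]
        counts = emit_rnaseq_counts(expr, genes, cfg, sample_names=names, depth=10_000)
        ratio = counts.var(axis=1) / counts.mean(axis=1)
        assert np.abs(ratio - 1.0).max() < 0.15

    def test_small_dispersion_is_overdispersed(self, small_sim):
        cfg, genome, genes, expr = small_sim
        cfg = SimConfig(**{**cfg.__dict__, "rnaseq_dispersion": 0.5})
        names = [f"s{i}" for i in range(2_000)]
        counts = emit_rnaseq_counts(expr, genes, cfg, sample_names=names, depth=10_000)
        ratio = counts.var(axis=1) / counts.mean(axis=1)
        assert (ratio > 2.0).all()


def test_invalid_configs_are_reported_not_silently_run():
    assert SimConfig(xr_len_range=(31, 21)).validate()
    assert SimConfig(background_read_fraction=1.0).validate()
    assert SimConfig(T=0.0).validate()
    assert SimConfig().validate() == []
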