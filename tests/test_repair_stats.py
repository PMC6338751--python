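"""TCR-fraction estimator, quantile profiles, relative damage, track signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from strandrepair import (
    gene_track_signal,
    marker_correlations,
    mito_background_contrast,
    quantile_stratify,
    relative_damage,
    tcr_fraction,
)
from strandrepair.genome import GenomeRef
from strandrepair.normalize import NormalizedMatrix
from strandrepair.reads import READ_COLUMNS, filter_xr_reads
from strandrepair.quantify import build_count_matrix
from strandrepair.simulate import (
    SimConfig,
    emit_xr_reads,
    simulate_genome,
    simulate_lesions,
)
from strandrepair._rng import substream


class TestTcrFraction:
    @pytest.mark.parametrize("ts,nts,expected", [(0.5, 1.0, 0.5), (1.0, 1.0, 0.0), (0.0, 2.0, 1.0)])
    def test_known_values(self, ts, nts, expected):
        assert tcr_fraction(ts, nts) == pytest.approx(expected)

    def test_zero_nts_damage_is_nan(self):
        assert np.isnan(tcr_fraction(0.3, 0.0))

    def test_noise_can_push_the_estimate_negative_and_it_is_kept(self):
        assert tcr_fraction(1.2, 1.0) == pytest.approx(-0.2)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            tcr_fraction(-0.1, 1.0)


def _nm(values: pd.DataFrame, assay="damage") -> NormalizedMatrix:
    return NormalizedMatrix(
        assay=assay, mode="gg", values=values,
        size_factors=pd.Series(dtype=float), dropped=values.iloc[:0],
    )


def _long(genes, cls_values, sample="s1"):
    rows = []
    for g, per_cls in cls_values.items():
        for cls, v in per_cls.items():
            rows.append((g, cls, sample, 0, 1.0, v))
    return pd.DataFrame(
        rows, columns=["gene_id", "strand_class", "sample", "raw", "denominator", "value"]
    )


class TestQuantileStratify:
    def build(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n)]
        expr = pd.Series(rng.gamma(1.0, 1.0, n), index=genes)
        vals = {g: {"TS": float(expr[g] * 2), "NTS": 1.0} for g in genes}
        return expr, {"xr": _nm(_long(genes, vals), "xr")}

    def test_bins_partition_genes_evenly(self):
        expr, mats = self.build(43)
        prof = quantile_stratify(expr, mats, n_bins=10)
        sizes = prof.bins.query("assay=='xr' and strand_class=='TS'")["n_genes"]
        assert sizes.sum() == 43
        assert sizes.max() - sizes.min() <= 1

    def test_monotone_value_gives_positive_rho_and_rising_bins(self):
        expr, mats = self.build()
        prof = quantile_stratify(expr, mats, n_bins=5)
        rho = prof.correlations.set_index(["assay", "strand_class"]).loc[("xr", "TS"), "spearman_rho"]
        assert rho == pytest.approx(1.0)
        means = prof.bins.query("assay=='xr' and strand_class=='TS'").sort_values("bin")["mean_log"]
        assert means.is_monotonic_increasing

    def test_gene_order_permutation_changes_nothing(self):
        expr, mats = self.build()
        prof1 = quantile_stratify(expr, mats, n_bins=5)
        perm = expr.sample(frac=1.0, random_state=7)
        prof2 = quantile_stratify(perm, mats, n_bins=5)
        pd.testing.assert_frame_equal(prof1.bins, prof2.bins)

    def test_constant_expression_is_flagged_degenerate(self):
        expr, mats = self.build()
        prof = quantile_stratify(pd.Series(1.0, index=expr.index), mats, n_bins=5)
        assert prof.degenerate_expression
        assert prof.correlations["spearman_rho"].isna().all()

    def test_too_few_bins_rejected(self):
        expr, mats = self.build()
        with pytest.raises(ValueError):
            quantile_stratify(expr, mats, n_bins=1)


class TestRelativeDamage:
    def test_identical_samples_are_all_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(5, 100, 50)
        tab = pd.DataFrame({"a": col, "b": col, "c": col})
        gg = pd.Series(10, index=tab.index)
        assert np.allclose(relative_damage(tab, gg), 1.0)

    def test_uniform_multiplier_is_recovered_after_mean_scaling(self):
        rng = np.random.default_rng(1)
        base = rng.integers(50, 500, 300)
        tab = pd.DataFrame({"a": base * 2, "b": base, "c": base})
        gg = pd.Series(rng.integers(10, 50, 300), index=tab.index)
        got = relative_damage(tab, gg)
        target = np.array([2.0, 1.0, 1.0]) / (4 / 3)
        assert np.allclose(got, target)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            relative_damage(pd.DataFrame({"a": [1, 2]}), pd.Series([5, 5]))


class TestMitoContrast:
    def reads(self, rows):
        return pd.DataFrame(rows, columns=READ_COLUMNS)

    def test_compartments_are_scored_separately(self):
        genome = GenomeRef({"chr1": "A" * 98 + "GG" + "A" * 100, "chrM": "A" * 200})
        rows = [
            ("r1", "chr1", 100, 150, "+", 60),  # GG at 98-99 => signature
            ("r2", "chrM", 50, 100, "+", 60),   # no GG anywhere on chrM
        ]
        out = mito_background_contrast(self.reads(rows), genome, "damage")
        assert out["nuclear"]["fraction"] == 1.0
        assert out["mito"]["fraction"] == 0.0

    def test_missing_compartment_reports_nan(self):
        genome = GenomeRef({"chr1": "A" * 200, "chrM": "A" * 100})
        rows = [("r1", "chrM", 10, 60, "+", 60)]
        out = mito_background_contrast(self.reads(rows), genome, "damage")
        assert np.isnan(out["nuclear"]["fraction"])
        assert out["mito"]["denominator"] == 1


class TestGeneTrackSignal:
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "start": [100, 500],
                "end": [200, 700],
                "strand": ["+", "-"],
            }
        )

    def test_uniform_track_gives_the_constant(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "intensity": [3.5]})
        out = gene_track_signal(track, self.genes())
        assert np.allclose(out, 3.5)

    def test_half_coverage_at_two_averages_to_one(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [150], "intensity": [2.0]})
        out = gene_track_signal(track, self.genes())
        assert out["g1"] == pytest.approx(1.0)
        assert out["g2"] == 0.0

    def test_promoter_window_follows_the_tss_strand(self):
        # signal only near position 700 = TSS of the - strand gene g2
        track = pd.DataFrame({"chrom": ["chr1"], "start": [650], "end": [750], "intensity": [1.0]})
        out = gene_track_signal(track, self.genes(), region_mode="promoter", promoter_window=100)
        assert out["g2"] == pytest.approx(0.5)
        assert out["g1"] == 0.0

    def test_malformed_intervals_rejected(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [100], "intensity": [1.0]})
        with pytest.raises(ValueError):
            gene_track_signal(track, self.genes())


class TestMarkerCorrelations:
    def test_perfect_rank_correlation_scores_one(self):
        idx = [f"g{i}" for i in range(20)]
        x = pd.Series(np.arange(20.0), index=idx)
        out = marker_correlations(pd.DataFrame({"m": x}), pd.DataFrame({"q": x ** 3}))
        assert out.loc[0, "spearman_rho"] == pytest.approx(1.0)

    def test_under_three_genes_yields_nan(self):
        idx = ["g1", "g2"]
        x = pd.Series([1.0, 2.0], index=idx)
        out = marker_correlations(pd.DataFrame({"m": x}), pd.DataFrame({"q": x}))
        assert np.isnan(out.loc[0, "spearman_rho"])

    def test_independent_marker_rarely_exceeds_rho_point_one(self):
        """Null calibration: an uninformative marker should clear |rho| > 0.1
        in at most ~20% of repeated simulations at n = 300 genes."""
        rng = substream(99, "null-marker")
        idx = [f"g{i}" for i in range(300)]
        target = pd.DataFrame({"q": rng.random(300)}, index=idx)
        hits = 0
        for _ in range(100):
            marker = pd.DataFrame({"m": rng.random(300)}, index=idx)
            out = marker_correlations(marker, target)
            if abs(out.loc[0, "spearman_rho"]) > 0.1:
                hits += 1
        assert hits <= 20

    def test_spearman_is_invariant_to_monotone_transforms(self):
        rng = substream(4, "monotone")
        idx = [f"g{i}" for i in range(50)]
        m = pd.Series(rng.random(50), index=idx)
        q = pd.Series(rng.random(50), index=idx)
        a = marker_correlations(pd.DataFrame({"m": m}), pd.DataFrame({"q": q}))
        b = marker_correlations(pd.DataFrame({"m": np.exp(5 * m)}), pd.DataFrame({"q": q ** 3}))
        assert a.loc[0, "spearman_rho"] == pytest.approx(b.loc[0, "spearman_rho"])


def test_openness_coupled_global_repair_is_detected():
    """When per-gene global repair tracks a synthetic openness score, NTS
    repair read counts correlate positively with that score."""
    cfg = SimConfig(seed=55, n_chromosomes=2, chrom_length=300_000, n_genes=150,
                    gene_length_range=(1500, 3000), damage_rate=1.0,
                    tcr_rate_coef=0.0, gr_rate_ts=0.0, gr_rate_nts=0.08,
                    background_read_fraction=0.0, n_reads_per_assay=100_000)
    genome, genes = simulate_genome(cfg)
    rng = substream(55, "openness")
    openness = pd.Series(rng.uniform(0.2, 3.0, len(genes)), index=genes["gene_id"].to_numpy())
    truth, _ = simulate_lesions(genome, genes, openness * 0.0, cfg)
    # dividing an Exponential(r) waiting time by c is exactly Exponential(c*r):
    # scale per-gene repair rates by the openness score
    gmap = openness.reindex(truth["gene_id"]).fillna(1.0).to_numpy()
    truth = truth.assign(repair_time=truth["repair_time"] / gmap)
    truth["repaired_by_T"] = truth["repair_time"] <= cfg.T
    reads = emit_xr_reads(truth, genome, cfg, sample="open")
    calls, _ = filter_xr_reads(reads[READ_COLUMNS], genome)
    mat = build_count_matrix({"s": calls}, genes, assay="xr")
    nts = mat.wide("NTS")["s"].reindex(openness.index).fillna(0)
    rho = sps.spearmanr(openness, nts).statistic
    assert rho > 0.3
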