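"""Signature-filter behaviour, checked against an independent brute-force
re-scan written with plain string slicing."""

import numpy as np
import pandas as pd
import pytest

from strandrepair import filter_damage_reads, filter_xr_reads, read_gg_signature_fraction
from strandrepair.experiments import random_reads
from strandrepair.genome import GenomeRef, revcomp
from strandrepair.reads import READ_COLUMNS
from strandrepair.simulate import SimConfig, simulate_genome


def make_read(chrom="chr1", start=100, end=150, strand="+", mapq=60, read_id="r1"):
    return pd.DataFrame(
        [[read_id, chrom, start, end, strand, mapq]], columns=READ_COLUMNS
    )


@pytest.fixture()
def gg_genome():
    # GG at 98-99, CC at 200-201, rest A
    seq = list("A" * 300)
    seq[98:100] = "GG"
    seq[200:202] = "CC"
    return GenomeRef({"chr1": "".join(seq)})


class TestDamageFilter:
    def test_mapq_threshold_is_strict(self, gg_genome):
        calls, tally = filter_damage_reads(make_read(mapq=20), gg_genome)
        assert tally.mapq == 1 and len(calls) == 0
        calls, tally = filter_damage_reads(make_read(mapq=21), gg_genome)
        assert tally.mapq == 0 and len(calls) == 1

    def test_plus_read_with_upstream_gg_localizes_the_5prime_g(self, gg_genome):
        calls, _ = filter_damage_reads(make_read(start=100, end=150), gg_genome)
        assert calls.loc[0, "lesion_start"] == 98
        assert calls.loc[0, "dinucleotide"] == "GG"

    def test_minus_read_uses_the_downstream_cc_pair(self, gg_genome):
        calls, _ = filter_damage_reads(make_read(start=150, end=200, strand="-"), gg_genome)
        # CC at (200, 201) on + strand == GG on the read strand; 5' G at 201
        assert calls.loc[0, "lesion_start"] == 201

    def test_signature_window_off_chromosome_is_out_of_bounds(self, gg_genome):
        _, tally = filter_damage_reads(make_read(start=1, end=40), gg_genome)
        assert tally.out_of_bounds == 1
        _, tally = filter_damage_reads(make_read(start=250, end=300, strand="-"), gg_genome)
        assert tally.out_of_bounds == 1

    def test_unknown_chromosome_is_an_input_error(self, gg_genome):
        with pytest.raises(KeyError):
            filter_damage_reads(make_read(chrom="chr9"), gg_genome)


class TestXrFilter:
    def window_read(self, gg_genome, length=26):
        # place a GG so that it sits 6-7 nt from the 3' end of a + read
        # read end must satisfy: GG at (98,99) => end-8+j = 98 with j=1 -> end=105
        return make_read(start=105 - length, end=105)

    def test_length_bounds_are_inclusive_21_to_31(self, gg_genome):
        for L, ok in ((20, False), (21, True), (31, True), (32, False)):
            reads = make_read(start=105 - L, end=105)
            calls, tally = filter_xr_reads(reads, gg_genome)
            assert (len(calls) == 1) == ok
            assert (tally.length == 1) == (not ok)

    def test_gg_six_to_seven_from_3prime_end_is_accepted(self, gg_genome):
        calls, _ = filter_xr_reads(self.window_read(gg_genome), gg_genome)
        assert len(calls) == 1
        assert calls.loc[0, "lesion_start"] == 98

    def test_three_prime_most_placement_wins_on_ggg(self):
        # GGG at 96-98: placements at window offsets overlap; the 3'-most GG
        # (closest to the read 3' end) must be chosen
        seq = "A" * 96 + "GGG" + "A" * 100
        genome = GenomeRef({"chr1": seq})
        calls, _ = filter_xr_reads(make_read(start=104 - 26, end=104), genome)
        # window covers 96..99; GG placements at 96 and 97; 97 is 3'-most
        assert calls.loc[0, "lesion_start"] == 97

    def test_minus_strand_window_mirrors_plus(self):
        seq = "A" * 100 + "CC" + "A" * 100
        genome = GenomeRef({"chr1": seq})
        # - read: window + coords [start+4, start+8) must cover (100, 101)
        calls, _ = filter_xr_reads(make_read(start=95, end=121, strand="-"), genome)
        assert len(calls) == 1
        assert calls.loc[0, "lesion_start"] == 101  # 5' G on the - strand


def brute_force_verdict(assay, seq, start, end, strand, mapq):
    if mapq <= 20:
        return None
    L = len(seq)
    if assay == "damage":
        if strand == "+":
            if start < 2 or end > L:
                return None
            return start - 2 if seq[start - 2 : start] == "GG" else None
        if end + 2 > L:
            return None
        return end + 1 if revcomp(seq[end : end + 2]) == "GG" else None
    if not 21 <= end - start <= 31:
        return None
    if strand == "+":
        if end - 8 < 0 or end > L:
            return None
        w = seq[end - 8 : end - 4]
    else:
        if start + 8 > L or end > L:
            return None
        w = revcomp(seq[start + 4 : start + 8])
    hits = [j for j in range(3) if w[j : j + 2] == "GG"]
    if not hits:
        return None
    j = max(hits)
    return end - 8 + j if strand == "+" else start + 7 - j


@pytest.mark.parametrize("assay", ["damage", "xr"])
def test_filters_agree_with_brute_force_on_random_reads(assay):
    cfg = SimConfig(seed=31, n_genes=0, chrom_length=40_000)
    genome, _ = simulate_genome(cfg)
    reads = random_reads(genome, 10_000, seed=31)
    filt = filter_damage_reads if assay == "damage" else filter_xr_reads
    calls, tally = filt(reads, genome)
    got = dict(zip(calls["read_id"], calls["lesion_start"]))
    expected = {}
    for row in reads.itertuples(index=False):
        verdict = brute_force_verdict(
            assay, genome.sequences[row.chrom], row.start, row.end, row.strand, row.mapq
        )
        if verdict is not None:
            expected[row.read_id] = verdict
    assert got == expected
    assert tally.total == len(reads)
    assert tally.accepted == len(expected)


def test_filter_is_order_invariant(gg_genome):
    reads = pd.concat(
        [
            make_read(start=100, end=150, read_id="a"),
            make_read(start=150, end=200, strand="-", read_id="b"),
            make_read(start=5, end=60, read_id="c"),
        ],
        ignore_index=True,
    )
    fwd, t1 = filter_damage_reads(reads, gg_genome)
    rev, t2 = filter_damage_reads(reads.iloc[::-1], gg_genome)
    assert t1.as_dict() == t2.as_dict()
    assert sorted(fwd["read_id"]) == sorted(rev["read_id"])
    merged = fwd.set_index("read_id")["lesion_start"]
    assert merged.equals(rev.set_index("read_id")["lesion_start"].reindex(merged.index))


def test_rejection_precedence_mapq_before_signature(gg_genome):
    # fails both mapq and signature: must be tallied under mapq only
    _, tally = filter_damage_reads(make_read(start=10, end=60, mapq=5), gg_genome)
    assert tally.mapq == 1 and tally.non_gg == 0
    # XR: fails mapq, length and signature -> mapq
    _, tally = filter_xr_reads(make_read(start=10, end=60, mapq=5), gg_genome)
    assert tally.mapq == 1 and tally.length == 0


class TestSignatureFraction:
    def test_pure_background_sits_at_chance_level(self):
        cfg = SimConfig(seed=23, n_genes=0, chrom_length=60_000, gc_content=0.5)
        genome, _ = simulate_genome(cfg)
        reads = random_reads(genome, 30_000, seed=23)
        got = read_gg_signature_fraction(reads, genome, "damage")
        assert abs(got["fraction"] - 0.25 ** 2) < 0.01

    def test_pure_signal_reads_score_one(self, clean_bundle):
        b = clean_bundle
        got = read_gg_signature_fraction(
            b.damage_reads["r1"][READ_COLUMNS], b.genome, "damage"
        )
        assert got["fraction"] == 1.0

    def test_region_without_reads_reports_nan(self, gg_genome):
        got = read_gg_signature_fraction(make_read(), gg_genome, "damage", chroms=set())
        assert np.isnan(got["fraction"]) and got["denominator"] == 0
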