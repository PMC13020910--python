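"""Exclusion caller tests: binning, classification, bridging, annotation."""

import numpy as np
import pandas as pd
import pytest

from excludekit import (BinGrid, BinTable, CallerParams, GenomeSpec,
                        aggregate_bins, bin_counts, bin_mappability,
                        call_exclusion_regions, classify_bins, run_caller,
                        make_genome, plant_truth, simulate_reads)
from excludekit.caller import COMBINED, BinFlags, SampleBins


def make_reads(positions, chrom="chr1", read_len=100):
    pos = np.asarray(positions)
    return pd.DataFrame({"chrom": chrom, "start": pos, "end": pos + read_len,
                         "strand": "+"})


@pytest.fixture
def small_genome():
    return GenomeSpec([("chr1", 100_000)])


class TestBinGrid:
    def test_overlap_must_be_smaller_than_size(self):
        with pytest.raises(ValueError):
            BinGrid(1000, 1000)

    def test_partial_terminal_bins_keep_true_width(self):
        table = BinTable.from_genome(BinGrid(1000, 500), GenomeSpec([("chr1", 2300)]))
        assert table.ends[-1] == 2300
        assert table.is_partial.sum() >= 1
        assert (table.ends <= 2300).all()


class TestBinCounts:
    def test_single_read_hits_every_covering_bin(self, small_genome):
        grid = BinGrid(1000, 500)
        sb = bin_counts(make_reads([1250]), grid, small_genome)
        hit = np.flatnonzero(sb.raw)
        # position 1250 lies in bins [500,1500) and [1000,2000)
        assert [(sb.table.starts[i], sb.table.ends[i]) for i in hit] == \
            [(500, 1500), (1000, 2000)]

    def test_uniform_reads_mean_rpm_near_expectation(self):
        genome = GenomeSpec([("chr1", 1_000_000)])
        rng = np.random.default_rng(0)
        n = 1_000_000
        sb = bin_counts(make_reads(rng.integers(0, 1_000_000, size=n)),
                        BinGrid(1000, 500), genome)
        # each full 1 kb bin expects n * (1000/1e6) = 1000 reads -> 1000 RPM
        full = ~sb.table.is_partial
        mean_rpm = sb.rpm[full].mean()
        sigma = np.sqrt(1000) / np.sqrt(full.sum())
        assert abs(mean_rpm - 1000) < 3 * sigma

    def test_empty_reads_rejected(self, small_genome):
        with pytest.raises(ValueError):
            bin_counts(make_reads([]), BinGrid(), small_genome)

    def test_minus_strand_uses_five_prime_end(self, small_genome):
        df = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [600],
                           "strand": ["-"]})
        sb = bin_counts(df, BinGrid(1000, 500), small_genome)
        hit = np.flatnonzero(sb.raw)
        # 5' base is 599: bins [0,1000) and [500,1500)
        assert [(sb.table.starts[i], sb.table.ends[i]) for i in hit] == \
            [(0, 1000), (500, 1500)]


class TestBinMappability:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    def test_constant_track(self, small_genome):
        table = BinTable.from_genome(BinGrid(1000, 500), small_genome)
        m = bin_mappability(self.track([("chr1", 0, 100_000, 1.0)]), table)
        assert np.allclose(m, 1.0)

    def test_half_and_half_bin(self):
        table = BinTable.from_genome(BinGrid(1000, 0), GenomeSpec([("chr1", 1000)]))
        m = bin_mappability(self.track([("chr1", 0, 500, 0.0),
                                        ("chr1", 500, 1000, 1.0)]), table)
        assert m[0] == pytest.approx(0.5)

    def test_uncovered_bases_count_as_zero(self):
        table = BinTable.from_genome(BinGrid(1000, 0), GenomeSpec([("chr1", 2000)]))
        m = bin_mappability(self.track([("chr1", 0, 1000, 1.0)]), table)
        assert m[0] == pytest.approx(1.0)
        assert m[1] == 0.0

    def test_out_of_range_value_rejected(self, small_genome):
        table = BinTable.from_genome(BinGrid(), small_genome)
        with pytest.raises(ValueError):
            bin_mappability(self.track([("chr1", 0, 10, -0.2)]), table)


class TestAggregateBins:
    def make_sample(self, table, values, sid="s"):
        return SampleBins(sid, table, np.asarray(values), int(np.sum(values)) or 1)

    def test_single_sample_identity(self, small_genome):
        table = BinTable.from_genome(BinGrid(), small_genome)
        raw = np.arange(len(table))
        s = self.make_sample(table, raw)
        assert np.allclose(aggregate_bins([s]), s.rpm)

    def test_median_across_samples(self):
        table = BinTable.from_genome(BinGrid(1000, 0), GenomeSpec([("chr1", 3000)]))
        n = len(table)
        samples = [SampleBins(f"s{v}", table, np.full(n, v), 1_000_000)
                   for v in (1, 2, 9)]
        assert np.allclose(aggregate_bins(samples), 2.0)

    def test_grid_mismatch_rejected(self):
        t1 = BinTable.from_genome(BinGrid(1000, 0), GenomeSpec([("chr1", 3000)]))
        t2 = BinTable.from_genome(BinGrid(1000, 500), GenomeSpec([("chr1", 3000)]))
        s1 = SampleBins("a", t1, np.zeros(len(t1)), 1)
        s2 = SampleBins("b", t2, np.zeros(len(t2)), 1)
        with pytest.raises(ValueError, match="grid mismatch"):
            aggregate_bins([s1, s2])

    def test_outlier_sample_moves_median_at_most_to_next_order_stat(self):
        table = BinTable.from_genome(BinGrid(1000, 0), GenomeSpec([("chr1", 1000)]))
        base = [1.0, 2.0, 9.0]
        samples = [SampleBins(f"s{i}", table, np.array([v]), 1_000_000)
                   for i, v in enumerate(base)]
        med = aggregate_bins(samples)[0]
        outlier = SampleBins("out", table, np.array([1e6]), 1_000_000)
        med2 = aggregate_bins(samples + [outlier])[0]
        upper = sorted(s.rpm[0] for s in samples)[-1]
        assert med <= med2 <= upper


class TestClassifyBins:
    def test_flat_signal_yields_no_high_signal_flags(self):
        params = CallerParams()
        flags = classify_bins(np.full(1000, 5.0), np.ones(1000), params)
        assert not flags.high_signal.any()

    def test_all_zero_signal_warns(self):
        with pytest.warns(UserWarning, match="all-zero"):
            flags = classify_bins(np.zeros(100), np.ones(100), CallerParams())
        assert not flags.high_signal.any()

    def test_planted_high_bins_flagged_with_low_false_rate(self):
        rng = np.random.default_rng(2)
        n = 20_000
        signal = rng.poisson(50, size=n).astype(float)
        planted = rng.choice(n, size=100, replace=False)
        signal[planted] = rng.poisson(1000, size=100)
        flags = classify_bins(signal, np.ones(n), CallerParams())
        assert flags.high_signal[planted].all()
        false = flags.high_signal.copy()
        false[planted] = False
        assert false.sum() / n < 0.005

    def test_zero_mappability_flagged_regardless_of_signal(self):
        signal = np.array([1000.0, 5.0, 5.0])
        mapp = np.array([0.0, 0.0, 1.0])
        flags = classify_bins(signal, mapp, CallerParams())
        assert flags.low_mappability.tolist() == [True, True, False]

    def test_raising_percentile_never_adds_flags(self):
        rng = np.random.default_rng(9)
        signal = rng.poisson(50, size=5000).astype(float)
        signal[:200] = 2000.0
        mapp = np.ones(5000)
        counts = [classify_bins(signal, mapp,
                                CallerParams(hs_percentile=p)).high_signal.sum()
                  for p in (0.9, 0.95, 0.99, 0.999)]
        assert counts == sorted(counts, reverse=True)


class TestCallExclusionRegions:
    def make_flags(self, table, hs_idx=(), lm_idx=()):
        hs = np.zeros(len(table), dtype=bool)
        lm = np.zeros(len(table), dtype=bool)
        hs[list(hs_idx)] = True
        lm[list(lm_idx)] = True
        return BinFlags(hs, lm)

    def test_mixed_region_gets_combined_label(self):
        genome = GenomeSpec([("chr1", 50_000)])
        table = BinTable.from_genome(BinGrid(1000, 0), genome)
        # hs bins [0,2000), lm bins [10000,12000), bridge 20000 -> one region
        flags = self.make_flags(table, hs_idx=(0, 1), lm_idx=(10, 11))
        out = call_exclusion_regions(flags, table, CallerParams(bin_overlap=0))
        assert [(r.start, r.end, r.label) for r in out] == [(0, 12_000, COMBINED)]

    def test_lm_before_hs_still_canonical_combined_label(self):
        genome = GenomeSpec([("chr1", 50_000)])
        table = BinTable.from_genome(BinGrid(1000, 0), genome)
        flags = self.make_flags(table, hs_idx=(10, 11), lm_idx=(0, 1))
        out = call_exclusion_regions(flags, table, CallerParams(bin_overlap=0))
        assert out[0].label == COMBINED

    def test_pure_classes_keep_own_labels(self):
        genome = GenomeSpec([("chr1", 100_000)])
        table = BinTable.from_genome(BinGrid(1000, 0), genome)
        flags = self.make_flags(table, hs_idx=(0, 1), lm_idx=(60, 61))
        out = call_exclusion_regions(flags, table, CallerParams(bin_overlap=0))
        assert [(r.start, r.end, r.label) for r in out] == \
            [(0, 2000, "High Signal"), (60_000, 62_000, "Low Mappability")]

    def test_no_flags_empty_set(self):
        genome = GenomeSpec([("chr1", 10_000)])
        table = BinTable.from_genome(BinGrid(1000, 0), genome)
        assert len(call_exclusion_regions(self.make_flags(table), table,
                                          CallerParams())) == 0

    def test_bridge_monotonicity(self):
        genome = GenomeSpec([("chr1", 200_000)])
        table = BinTable.from_genome(BinGrid(1000, 0), genome)
        rng = np.random.default_rng(1)
        flags = self.make_flags(table, hs_idx=rng.choice(200, 30, replace=False))
        counts = [len(call_exclusion_regions(
            flags, table, CallerParams(bin_overlap=0, bridge=b, min_region=0)))
            for b in (0, 1000, 10_000, 20_000)]
        assert counts == sorted(counts, reverse=True)

    def test_output_respects_bridge_and_min_width(self):
        genome = make_genome(1, [5_000_000], 1)
        bundle = plant_truth(genome, n_hs=4, hs_width_range=(5000, 20_000),
                             n_lm=2, lm_width_range=(10_000, 30_000), seed=3)
        reads = simulate_reads(bundle, n_samples=3, depth=250_000, seed=3)
        params = CallerParams()
        called = run_caller(reads, bundle.mappability, genome, params)
        assert all(r.width >= params.min_region for r in called)
        by_chrom = called.by_chrom()
        for regs in by_chrom.values():
            gaps = [b.start - a.end for a, b in zip(regs, regs[1:])]
            assert all(g > params.bridge for g in gaps)
        labels = {r.label for r in called}
        assert labels <= {"High Signal", "Low Mappability", COMBINED}


class TestRunCaller:
    def test_deterministic_repeat(self):
        genome = make_genome(1, [2_000_000], 5)
        bundle = plant_truth(genome, n_hs=2, hs_width_range=(5000, 20_000),
                             n_lm=1, lm_width_range=(10_000, 30_000), seed=5)
        reads = simulate_reads(bundle, n_samples=2, depth=100_000, seed=5)
        a = run_caller(reads, bundle.mappability, genome)
        b = run_caller(reads, bundle.mappability, genome)
        assert [(r.chrom, r.start, r.end, r.label) for r in a] == \
            [(r.chrom, r.start, r.end, r.label) for r in b]
        assert a.metadata["params"] == b.metadata["params"]
        assert a.metadata["kmer"] == 36

    def test_no_artifacts_small_footprint(self):
        genome = make_genome(1, [2_000_000], 8)
        bundle = plant_truth(genome, n_hs=0, n_lm=0, seed=8)
        reads = simulate_reads(bundle, n_samples=3, depth=100_000, seed=8)
        called = run_caller(reads, bundle.mappability, genome)
        assert called.footprint_width < 0.01 * genome.total_size
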