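"""Accessibility windows, on/off ratios, down-sampling, relative metrics."""

from __future__ import annotations

import math

import numpy as np
import pytest

import genomepam as g
from genomepam.genome_io import Occurrence
from genomepam.profiles import aggregate_relative


def make_record(contig, start, reads, mismatches=0):
    positions = tuple(range(1, mismatches + 1))
    site = g.TargetSite(
        Occurrence(contig, start, start + 20, "+"), mismatches, positions, "A" * 10
    )
    return g.CleavageRecord(site, reads)


@pytest.fixture
def small_index():
    return g.GenomeIndex({"c1": "A" * 1000, "c2": "C" * 450})


class TestAccessibility:
    def test_single_window_takes_all(self, small_index):
        records = [make_record("c1", 150, 5), make_record("c1", 120, 3)]
        prof = g.accessibility_profile(records, small_index, window_size=100)
        assert prof.proportions[("c1", 1)] == 1.0
        assert sum(prof.proportions.values()) == pytest.approx(1.0)

    def test_grid_tiles_all_contigs_with_partial_last_window(self, small_index):
        records = [make_record("c2", 440, 1)]
        prof = g.accessibility_profile(records, small_index, window_size=100)
        assert prof.grid == {"c1": 10, "c2": 5}
        assert prof.proportions[("c2", 4)] == 1.0

    def test_proportions_invariant_to_read_scaling(self, small_index):
        a = [make_record("c1", 10, 2), make_record("c1", 510, 6)]
        b = [make_record("c1", 10, 20), make_record("c1", 510, 60)]
        pa = g.accessibility_profile(a, small_index, 100)
        pb = g.accessibility_profile(b, small_index, 100)
        assert pa.proportions == pytest.approx(pb.proportions)

    def test_zero_reads_rejected(self, small_index):
        with pytest.raises(ValueError, match="zero"):
            g.accessibility_profile([make_record("c1", 10, 0)], small_index, 100)

    def test_self_comparison_all_zero(self, small_index):
        records = [make_record("c1", 10, 2), make_record("c1", 510, 6)]
        prof = g.accessibility_profile(records, small_index, 100)
        ratios = g.relative_accessibility(prof, [prof])
        finite = [v for v in ratios.values() if math.isfinite(v)]
        assert finite and all(v == 0.0 for v in finite)

    def test_doubled_proportion_gives_ratio_one(self, small_index):
        ref = g.accessibility_profile(
            [make_record("c1", 10, 4), make_record("c1", 510, 4)], small_index, 100
        )
        sample = g.accessibility_profile(
            [make_record("c1", 10, 8), make_record("c1", 510, 4)], small_index, 100
        )
        ratios = g.relative_accessibility(sample, [ref])
        assert ratios[("c1", 0)] == pytest.approx(math.log2(8 / 12 / 0.5))

    def test_grid_mismatch_rejected(self, small_index):
        prof100 = g.accessibility_profile([make_record("c1", 10, 1)], small_index, 100)
        prof200 = g.accessibility_profile([make_record("c1", 10, 1)], small_index, 200)
        with pytest.raises(ValueError, match="grid"):
            g.relative_accessibility(prof100, [prof200])

    def test_zero_reference_nan_unless_pseudocount(self, small_index):
        prof = g.accessibility_profile([make_record("c1", 10, 1)], small_index, 100)
        other = g.accessibility_profile([make_record("c1", 510, 1)], small_index, 100)
        ratios = g.relative_accessibility(prof, [other])
        assert math.isnan(ratios[("c1", 0)])
        smoothed = g.relative_accessibility(prof, [other], pseudocount=1e-6)
        assert math.isfinite(smoothed[("c1", 0)])


class TestOnOff:
    def test_equal_strata_unit_ratio(self):
        records = [make_record("c1", i * 100, 1) for i in range(10)]
        records += [make_record("c1", 2000 + i * 100, 1, mismatches=2) for i in range(10)]
        s = g.on_off_summary(records)
        assert s.site_ratio == 1.0
        assert s.on_sites == s.off_sites == 10

    def test_no_off_targets_flagged_infinite(self):
        s = g.on_off_summary([make_record("c1", 0, 3)])
        assert s.site_ratio == math.inf and s.read_ratio == math.inf


class TestDownsample:
    def _records(self, rng, n=50):
        return [
            make_record("c1", i * 100, int(r))
            for i, r in enumerate(rng.integers(1, 40, size=n))
        ]

    def test_full_depth_is_identity(self):
        rng = np.random.default_rng(1)
        records = self._records(rng)
        total = sum(r.read_count for r in records)
        assert g.downsample_reads(records, total, seed=0) == records

    def test_zero_depth_empty(self):
        rng = np.random.default_rng(1)
        assert g.downsample_reads(self._records(rng), 0, seed=0) == []

    def test_depth_above_total_rejected(self):
        rng = np.random.default_rng(1)
        records = self._records(rng)
        with pytest.raises(ValueError):
            g.downsample_reads(records, 10 ** 9, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        records = self._records(rng)
        a = g.downsample_reads(records, 100, seed=7)
        b = g.downsample_reads(records, 100, seed=7)
        assert a == b

    def test_surviving_sites_nondecreasing_in_depth(self):
        rng = np.random.default_rng(2)
        records = self._records(rng, n=200)
        total = sum(r.read_count for r in records)
        depths = np.linspace(total // 20, total, 10, dtype=int)
        mean_sites = []
        for depth in depths:
            survivors = [
                len(g.downsample_reads(records, int(depth), seed=1000 + rep))
                for rep in range(50)
            ]
            mean_sites.append(np.mean(survivors))
        diffs = np.diff(mean_sites)
        assert all(d >= -1.0 for d in diffs)  # monotone up to MC noise
        assert mean_sites[-1] > mean_sites[0]

    def test_two_stage_matches_direct_marginally(self):
        rng = np.random.default_rng(3)
        records = self._records(rng, n=40)
        total = sum(r.read_count for r in records)
        n1, n2 = int(total * 0.6), int(total * 0.3)
        direct, staged = [], []
        for rep in range(300):
            direct.append(len(g.downsample_reads(records, n2, seed=rep)))
            mid = g.downsample_reads(records, n1, seed=10_000 + rep, detection_min=0)
            staged.append(len(g.downsample_reads(mid, n2, seed=20_000 + rep)))
        se = math.sqrt(np.var(direct) / 300 + np.var(staged) / 300)
        assert abs(np.mean(direct) - np.mean(staged)) < 4 * se


class TestRelativeMetrics:
    def _summary(self, label, on, off):
        records = [make_record("c1", i * 50, 2) for i in range(on)]
        records += [make_record("c1", 5000 + i * 50, 1, mismatches=1) for i in range(off)]
        return g.on_off_summary(records, label)

    def test_reference_identities(self):
        summaries = [self._summary("wt", 10, 20), self._summary("hf1", 8, 4)]
        out = g.relative_metrics(summaries, "wt", "hf1")
        wt = next(s for s in out if s.label == "wt")
        hf1 = next(s for s in out if s.label == "hf1")
        assert wt.relative_activity == pytest.approx(1.0)
        assert hf1.relative_specificity == pytest.approx(1.0)

    def test_scale_free(self):
        a = [self._summary("wt", 10, 20), self._summary("v", 5, 5)]
        b = [self._summary("wt", 20, 40), self._summary("v", 10, 10)]
        ra = g.relative_metrics(a, "wt", "wt")
        rb = g.relative_metrics(b, "wt", "wt")
        for x, y in zip(ra, rb):
            assert x.relative_activity == pytest.approx(y.relative_activity)
            assert x.relative_specificity == pytest.approx(y.relative_specificity)

    def test_missing_reference_rejected(self):
        with pytest.raises(KeyError):
            g.relative_metrics([self._summary("wt", 5, 5)], "absent", "wt")

    def test_replicates_aggregate_mean_sd(self):
        summaries = [
            self._summary("wt", 10, 20),
            self._summary("wt", 12, 20),
            self._summary("v", 5, 5),
        ]
        out = g.relative_metrics(summaries, "wt", "wt")
        agg = aggregate_relative(out)
        assert set(agg["label"]) == {"wt", "v"}
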