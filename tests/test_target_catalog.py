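"""Target-site enumeration and cleavage-record classification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import genomepam as g
from genomepam.genome_io import Occurrence
from genomepam.simulate import SimConfig, simulate_genome
from genomepam.target_catalog import hamming_neighbors

from conftest import naive_hamming_scan, sites_as_dict

REP1 = "GTGAGCCACTGTGCCTGGCC"


@pytest.fixture(scope="module")
def small_sim():
    cfg = SimConfig(genome_length=50_000, n_perfect=30, n_mismatch=20, seed=13)
    return simulate_genome(cfg)


class TestEnumerate:
    def test_trivial_perfect_matches(self):
        ix = g.GenomeIndex({"c1": "AAGGTTAAGGTTAA"})
        # no PAM window requested beyond what fits: use short window
        sites = g.enumerate_targets(ix, "GGTT", 0, pam_window_length=2)
        assert [(s.occurrence.start, s.occurrence.strand) for s in sites] == [
            (2, "+"),
            (8, "+"),
        ]
        assert all(s.mismatches == 0 for s in sites)

    def test_validation(self):
        ix = g.GenomeIndex({"c1": "ACGTACGT"})
        with pytest.raises(ValueError):
            g.enumerate_targets(ix, "ACNT", 0)
        with pytest.raises(ValueError):
            g.enumerate_targets(ix, "ACG", 3)

    def test_matches_naive_oracle(self, small_sim):
        ix, _ = small_sim
        sites = g.enumerate_targets(ix, REP1, 3, pam_window_length=10)
        # the oracle is edge-agnostic; apply the same PAM-window edge rule
        oracle = naive_hamming_scan(ix, REP1, 3)
        L, W = len(REP1), 10
        clen = ix.lengths["c1"]
        oracle = {
            (c, s): v
            for (c, s), v in oracle.items()
            if W <= s and s + L + W <= clen
        }
        assert sites_as_dict(sites) == oracle

    def test_monotone_in_mismatch_budget(self, small_sim):
        ix, _ = small_sim
        prev: set = set()
        for m in range(3):
            cur = set(sites_as_dict(g.enumerate_targets(ix, REP1, m)))
            assert prev <= cur
            prev = cur

    def test_exact_mismatch_counts_match_neighbor_enumeration(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        ix = g.GenomeIndex({"c1": seq})
        proto = "GTCAGGTC"
        by_scan = {
            m: len(g.enumerate_targets(ix, proto, m, pam_window_length=1))
            for m in range(3)
        }
        by_neighbors = {
            m: len(
                g.enumerate_targets(
                    ix, proto, m, pam_window_length=1, strategy="neighbors"
                )
            )
            for m in range(3)
        }
        assert by_scan == by_neighbors
        # exactly-k counts via the subset identity
        exact1 = by_scan[1] - by_scan[0]
        n_patterns = sum(1 for _ in hamming_neighbors(proto, 1)) - 1
        assert n_patterns == len(proto) * 3
        assert exact1 >= 0

    def test_planted_perfect_copies_all_found(self, small_sim):
        ix, truth = small_sim
        sites = g.enumerate_targets(ix, REP1, 0)
        found = {(s.occurrence.contig, s.occurrence.start) for s in sites}
        planted = {
            (s.contig, s.start) for s in truth.sites if s.mismatches == 0
        }
        assert planted <= found

    def test_mismatch_positions_protospacer_strand(self):
        # plant a single mismatch at protospacer position 3 on the minus strand
        proto = "GGATCCGT"
        mutated = list(proto)
        mutated[2] = "C"
        from genomepam.genome_io import revcomp

        ix = g.GenomeIndex({"c1": "TTTT" + revcomp("".join(mutated)) + "TTTT"})
        sites = g.enumerate_targets(ix, proto, 2, pam_window_length=2)
        minus = [s for s in sites if s.occurrence.strand == "-"]
        assert minus and minus[0].mismatch_positions == (3,)


class TestMatchCleavage:
    def test_perfect_row_recovers_planted_flank(self, small_sim):
        ix, truth = small_sim
        site = next(s for s in truth.sites if s.mismatches == 0)
        table = pd.DataFrame(
            [
                {
                    "chrom": site.contig,
                    "start": site.start,
                    "end": site.end,
                    "strand": site.strand,
                    "read_count": 7,
                }
            ]
        )
        records, report = g.match_cleavage_sites(table, ix, REP1)
        assert report.n_matched == 1 and not report.errors
        rec = records[0]
        assert rec.match_class == "perfect"
        assert rec.site.mismatch_positions == ()
        assert rec.site.pam_window == site.flank3

    def test_rows_beyond_mismatch_cap_excluded(self, small_sim):
        ix, _ = small_sim
        # a random background interval is ~15 mismatches from the protospacer
        table = pd.DataFrame(
            [{"chrom": "c1", "start": 100, "end": 120, "strand": "+", "read_count": 3}]
        )
        records, report = g.match_cleavage_sites(table, ix, REP1, max_mismatch=6)
        assert records == [] and report.n_excluded_mismatch == 1

    def test_duplicate_rows_merged_reads_summed(self, small_sim):
        ix, truth = small_sim
        site = next(s for s in truth.sites if s.mismatches == 0)
        row = {
            "chrom": site.contig,
            "start": site.start,
            "end": site.end,
            "strand": site.strand,
            "read_count": 5,
        }
        records, report = g.match_cleavage_sites(pd.DataFrame([row, row]), ix, REP1)
        assert len(records) == 1
        assert records[0].read_count == 10
        assert report.n_merged_duplicates == 1

    def test_row_errors_collected_with_line_numbers(self, small_sim):
        ix, _ = small_sim
        table = pd.DataFrame(
            [
                {"chrom": "c9", "start": 0, "end": 20, "strand": "+", "read_count": 1},
                {"chrom": "c1", "start": -5, "end": 20, "strand": "+", "read_count": 1},
            ]
        )
        _, report = g.match_cleavage_sites(table, ix, REP1)
        assert len(report.errors) == 2
        assert report.errors[0].startswith("row 1:")
        assert report.errors[1].startswith("row 2:")

    def test_one_based_flag(self, small_sim):
        ix, truth = small_sim
        site = next(s for s in truth.sites if s.mismatches == 0)
        table = pd.DataFrame(
            [
                {
                    "chrom": site.contig,
                    "start": site.start + 1,  # 1-based inclusive start
                    "end": site.end,
                    "strand": site.strand,
                    "read_count": 1,
                }
            ]
        )
        records, _ = g.match_cleavage_sites(table, ix, REP1, one_based=True)
        assert records[0].site.occurrence.start == site.start

    def test_pam_window_reextraction_invariant(self, small_sim):
        ix, truth = small_sim
        from genomepam.simulate import simulate_cleavage

        table = simulate_cleavage(
            g.SimTruth(truth.sites, {}, truth.accessibility_window, truth.config),
            seed=99,
        )
        records, report = g.match_cleavage_sites(table, ix, REP1)
        assert not report.errors
        for rec in records:
            occ = rec.site.occurrence
            assert g.get_flank(ix, occ, "3prime", 10) == rec.site.pam_window


class TestStratify:
    def _record(self, mismatches):
        occ = Occurrence("c1", 0, 4, "+")
        positions = tuple(range(1, mismatches + 1))
        site = g.TargetSite(occ, mismatches, positions, "AAAA")
        return g.CleavageRecord(site, 1)

    def test_partition_sizes(self):
        records = [self._record(0)] * 10 + [self._record(2)] * 5
        strata = g.stratify(records)
        assert len(strata["perfect"]) == 10
        assert len(strata["mismatch"]) == 5

    def test_empty_input(self):
        strata = g.stratify([])
        assert strata == {"perfect": [], "mismatch": []}

    def test_perfect_only_cleavage_yields_empty_mismatch_stratum(self):
        cfg = SimConfig(
            genome_length=60_000,
            n_perfect=30,
            n_mismatch=20,
            pam_model={"default": 1.0},
            mismatch_activity_factor=0.0,  # mismatch copies never cleave
            seed=3,
        )
        ix, truth = simulate_genome(cfg)
        from genomepam.simulate import simulate_cleavage

        table = simulate_cleavage(truth, seed=4)
        records, _ = g.match_cleavage_sites(table, ix, REP1)
        strata = g.stratify(records)
        assert strata["mismatch"] == []
        assert len(strata["perfect"]) == 30
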