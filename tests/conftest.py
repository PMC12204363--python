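"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import pytest

import genomepam as g
from genomepam.genome_io import revcomp

REP1 = "GTGAGCCACTGTGCCTGGCC"


# ---------------------------------------------------------------- oracles


def naive_count(seq: str, kmer: str) -> int:
    """Sliding-window overlapping occurrence count (position-by-position)."""
    k = len(kmer)
    return sum(seq[i : i + k] == kmer for i in range(len(seq) - k + 1))


def naive_hamming_scan(index, protospacer: str, max_mismatch: int):
    """Both-strand Hamming scan with the one-report-per-interval rule.

    Pure-python early-exit loop, independent of the package's vectorized
    enumeration. Returns {(contig, start): (strand, mismatches)}.
    """
    L = len(protospacer)
    rc = revcomp(protospacer)
    hits = {}
    for contig, seq in index.contigs.items():
        for i in range(len(seq) - L + 1):
            win = seq[i : i + L]
            if "N" in win:
                continue
            df = 0
            for a, b in zip(win, protospacer):
                if a != b:
                    df += 1
                    if df > max_mismatch:
                        break
            dr = 0
            for a, b in zip(win, rc):
                if a != b:
                    dr += 1
                    if dr > max_mismatch:
                        break
            if df <= max_mismatch and df <= dr:
                hits[(contig, i)] = ("+", df)
            elif dr <= max_mismatch:
                hits[(contig, i)] = ("-", dr)
    return hits


def sites_as_dict(sites):
    return {
        (s.occurrence.contig, s.occurrence.start): (s.occurrence.strand, s.mismatches)
        for s in sites
    }


def longhand_pearson_chi2(table):
    """Textbook Pearson chi-square sum((O-E)^2 / E) on a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    chi2 = 0.0
    for i, obs_row in enumerate(table):
        for j, obs in enumerate(obs_row):
            exp = rows[i] * cols[j] / n
            chi2 += (obs - exp) ** 2 / exp
    return chi2


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def ngg_fixture():
    return g.end_to_end_fixture("ngg_recovery", seed=0)


@pytest.fixture(scope="session")
def ngg_analysis(ngg_fixture):
    """Matched records, strata and perfect-match catalog for the NGG run."""
    fx = ngg_fixture
    records, report = g.match_cleavage_sites(fx.site_table, fx.index, fx.config.repeat)
    catalog = g.enumerate_targets(fx.index, fx.config.repeat, 0)
    return {
        "fixture": fx,
        "records": records,
        "report": report,
        "strata": g.stratify(records),
        "catalog": catalog,
    }


@pytest.fixture(scope="session")
def null_fixture():
    return g.end_to_end_fixture("null_uniform", seed=0)


@pytest.fixture(scope="session")
def null_catalog(null_fixture):
    return g.enumerate_targets(null_fixture.index, null_fixture.config.repeat, 0)
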