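"""Genome-wide target-site enumeration and cleavage-site classification.

A target site is one genomic window (either strand) within a Hamming-
distance budget of the protospacer, annotated with its mismatch positions
and the candidate PAM window read from the genome. Detected cleavage sites
(GUIDE-seq-style identified-site tables) are resolved against the genome to
the best protospacer alignment and classified perfect/mismatch.

Mismatch positions are numbered 1..L from the protospacer 5' end on the
protospacer strand (PAM-distal = 1 for a 3'-PAM nuclease).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, Occurrence, find_occurrences, get_flank, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"

# below this many bases the sliding Hamming scan is always used; above it,
# neighbor-pattern enumeration (exact lookups) kicks in for small budgets
SCAN_BP_LIMIT = 50_000_000


@dataclass(frozen=True)
class TargetSite:
    occurrence: Occurrence
    mismatches: int
    mismatch_positions: tuple[int, ...]
    pam_window: str

    def __post_init__(self) -> None:
        if self.mismatches != len(self.mismatch_positions):
            raise ValueError("mismatches != len(mismatch_positions)")


@dataclass(frozen=True)
class CleavageRecord:
    site: TargetSite
    read_count: int
    sample: str = "sample"

    @property
    def match_class(self) -> str:
        return "perfect" if self.site.mismatches == 0 else "mismatch"


@dataclass
class MatchReport:
    """Row-level accounting for match_cleavage_sites."""

    n_input: int = 0
    n_matched: int = 0
    n_excluded_mismatch: int = 0
    n_dropped_pam_edge: int = 0
    n_merged_duplicates: int = 0
    ties: list[int] = field(default_factory=list)  # input row indices
    errors: list[str] = field(default_factory=list)


def _mismatch_positions(window_protospacer_strand: str, protospacer: str) -> tuple[int, ...]:
    return tuple(
        i + 1
        for i, (a, b) in enumerate(zip(window_protospacer_strand, protospacer))
        if a != b
    )


def _protospacer_strand_seq(index: GenomeIndex, occ: Occurrence) -> str:
    return index.fetch(occ.contig, occ.start, occ.end, occ.strand)


def _make_site(
    index: GenomeIndex,
    occ: Occurrence,
    protospacer: str,
    pam_side: str,
    pam_window_length: int,
) -> TargetSite:
    """Build a TargetSite; raises ValueError if the PAM window is truncated."""
    seq = _protospacer_strand_seq(index, occ)
    positions = _mismatch_positions(seq, protospacer)
    pam = get_flank(index, occ, pam_side, pam_window_length)
    return TargetSite(occ, len(positions), positions, pam)


def _scan_contig(
    seq: str, protospacer: str, max_mismatch: int
) -> list[tuple[int, str, int]]:
    """Vectorized both-strand Hamming scan of one contig.

    Returns (start, strand, mismatches) with one entry per genomic interval;
    an interval matching on both strands is reported once with the smaller
    mismatch count (tie -> '+'). Windows containing N never match.
    """
    L = len(protospacer)
    G = len(seq)
    if G < L:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    proto = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    proto_rc = np.frombuffer(revcomp(protospacer).encode(), dtype=np.uint8)
    n_win = G - L + 1
    mm_f = np.zeros(n_win, dtype=np.int16)
    mm_r = np.zeros(n_win, dtype=np.int16)
    for j in range(L):
        col = arr[j : j + n_win]
        mm_f += col != proto[j]
        mm_r += col != proto_rc[j]
    is_n = (arr == ord("N")).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    has_n = (cs[L:] - cs[:-L]) > 0
    hits = []
    cand = np.nonzero(
        (~has_n) & ((mm_f <= max_mismatch) | (mm_r <= max_mismatch))
    )[0]
    for i in cand:
        f, r = int(mm_f[i]), int(mm_r[i])
        if f <= max_mismatch and f <= r:
            hits.append((int(i), "+", f))
        else:
            hits.append((int(i), "-", r))
    return hits


def hamming_neighbors(protospacer: str, max_mismatch: int) -> Iterable[str]:
    """All strings within Hamming distance <= max_mismatch (incl. itself)."""
    L = len(protospacer)
    yield protospacer
    for d in range(1, max_mismatch + 1):
        for positions in itertools.combinations(range(L), d):
            alt_sets = [
                [b for b in BASES if b != protospacer[p]] for p in positions
            ]
            for alts in itertools.product(*alt_sets):
                s = list(protospacer)
                for p, b in zip(positions, alts):
                    s[p] = b
                yield "".join(s)


def _enumerate_by_neighbors(
    index: GenomeIndex, protospacer: str, max_mismatch: int
) -> dict[tuple[str, int], tuple[str, int]]:
    """interval -> (strand, mismatches) via exact search of every neighbor."""
    best: dict[tuple[str, int], tuple[str, int]] = {}
    for pattern in hamming_neighbors(protospacer, max_mismatch):
        d = sum(a != b for a, b in zip(pattern, protospacer))
        for occ in find_occurrences(index, pattern, "forward"):
            key = (occ.contig, occ.start)
            cur = best.get(key)
            if cur is None or d < cur[1] or (d == cur[1] and cur[0] == "-"):
                best[key] = ("+", d)
        rc = revcomp(pattern)
        for occ in find_occurrences(index, rc, "forward"):
            key = (occ.contig, occ.start)
            cur = best.get(key)
            if cur is None or d < cur[1]:
                best[key] = ("-", d)
    return best


def enumerate_targets(
    index: GenomeIndex,
    protospacer: str,
    max_mismatch: int = 0,
    pam_side: str = "3prime",
    pam_window_length: int = 10,
    strategy: str = "auto",
) -> list[TargetSite]:
    """All genomic windows (both strands) within the mismatch budget.

    Each genomic interval is reported once (smaller mismatch count wins a
    both-strand tie, then '+'). Sites whose PAM window would cross a contig
    edge are dropped and logged. ``strategy`` is 'scan' (sliding Hamming),
    'neighbors' (explicit neighbor patterns, exact lookups) or 'auto'.
    """
    if any(c not in BASES for c in protospacer):
        raise ValueError("protospacer must be ACGT-only")
    if not 0 <= max_mismatch <= 6:
        raise ValueError("max_mismatch must be in 0..6")
    if max_mismatch >= len(protospacer):
        raise ValueError("max_mismatch must be smaller than protospacer length")
    if strategy == "auto":
        strategy = (
            "neighbors"
            if index.total_length > SCAN_BP_LIMIT and max_mismatch <= 2
            else "scan"
        )
    sites: list[TargetSite] = []
    dropped = 0
    if strategy == "scan":
        hit_iter = (
            (contig, start, strand, mm)
            for contig, seq in index.contigs.items()
            for start, strand, mm in _scan_contig(seq, protospacer, max_mismatch)
        )
    elif strategy == "neighbors":
        best = _enumerate_by_neighbors(index, protospacer, max_mismatch)
        hit_iter = (
            (contig, start, strand, mm)
            for (contig, start), (strand, mm) in sorted(best.items())
        )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    L = len(protospacer)
    for contig, start, strand, _mm in hit_iter:
        occ = Occurrence(contig, start, start + L, strand)
        try:
            sites.append(
                _make_site(index, occ, protospacer, pam_side, pam_window_length)
            )
        except ValueError:
            dropped += 1
    if dropped:
        logger.info(
            "enumerate_targets: dropped %d sites with edge-truncated PAM windows",
            dropped,
        )
    sites.sort(key=lambda s: (s.occurrence.contig, s.occurrence.start))
    return sites


REQUIRED_COLUMNS = ("chrom", "start", "end", "strand", "read_count")


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a detected-site TSV (GUIDE-seq identified-sites dialect)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing required columns: {missing}")
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _best_placement(
    index: GenomeIndex, contig: str, start: int, end: int, strand: str, protospacer: str
) -> tuple[int, int, list[int]]:
    """Best protospacer placement for a detected window.

    Candidate placements are every protospacer-length window inside the
    detected interval (or, for intervals shorter than the protospacer, every
    window containing it). Returns (placement start, mismatches, tied starts).
    """
    L = len(protospacer)
    seq = index.contigs[contig]
    if end - start >= L:
        lo, hi = start, end - L
    else:
        lo, hi = end - L, start
    lo = max(lo, 0)
    hi = min(hi, len(seq) - L)
    if hi < lo:
        raise ValueError("window cannot hold the protospacer")
    target = protospacer if strand == "+" else revcomp(protospacer)
    best_mm, best_starts = None, []
    for s in range(lo, hi + 1):
        window = seq[s : s + L]
        if "N" in window:
            continue
        mm = sum(a != b for a, b in zip(window, target))
        if best_mm is None or mm < best_mm:
            best_mm, best_starts = mm, [s]
        elif mm == best_mm:
            best_starts.append(s)
    if best_mm is None:
        raise ValueError("no N-free placement in window")
    return best_starts[0], best_mm, best_starts


def match_cleavage_sites(
    site_table: pd.DataFrame | str | Path,
    index: GenomeIndex,
    protospacer: str,
    max_mismatch: int = 6,
    pam_side: str = "3prime",
    pam_window_length: int = 10,
    one_based: bool = False,
) -> tuple[list[CleavageRecord], MatchReport]:
    """Resolve detected-site rows to classified CleavageRecords.

    Each row's interval is aligned to the protospacer on the row's strand
    (minimum mismatches, ties broken by smallest coordinate and logged);
    rows exceeding ``max_mismatch`` are excluded and counted. Duplicate rows
    resolving to the same genomic site (within one sample) are merged with
    read counts summed. Coordinates are 0-based half-open unless
    ``one_based``.
    """
    if isinstance(site_table, (str, Path)):
        site_table = read_site_table(site_table)
    report = MatchReport(n_input=len(site_table))
    merged: dict[tuple[TargetSite, str], int] = {}
    L = len(protospacer)
    for idx, row in enumerate(site_table.itertuples(index=False)):
        try:
            contig = str(row.chrom)
            start, end = int(row.start), int(row.end)
            if one_based:
                start -= 1
            strand = str(row.strand)
            reads = int(row.read_count)
            sample = str(getattr(row, "sample", "sample"))
            if contig not in index.contigs:
                raise ValueError(f"unknown contig {contig!r}")
            if not (0 <= start < end <= index.lengths[contig]):
                raise ValueError(f"coordinates {start}-{end} outside {contig}")
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if reads < 0:
                raise ValueError("negative read_count")
        except (ValueError, TypeError) as exc:
            report.errors.append(f"row {idx + 1}: {exc}")
            continue
        try:
            s, mm, tied = _best_placement(index, contig, start, end, strand, protospacer)
        except ValueError as exc:
            report.errors.append(f"row {idx + 1}: {exc}")
            continue
        if len(tied) > 1:
            report.ties.append(idx + 1)
            logger.info("row %d: %d tied placements, kept leftmost", idx + 1, len(tied))
        if mm > max_mismatch:
            report.n_excluded_mismatch += 1
            continue
        occ = Occurrence(contig, s, s + L, strand)
        try:
            site = _make_site(index, occ, protospacer, pam_side, pam_window_length)
        except ValueError:
            report.n_dropped_pam_edge += 1
            continue
        key = (site, sample)
        if key in merged:
            report.n_merged_duplicates += 1
        merged[key] = merged.get(key, 0) + reads
    records = [
        CleavageRecord(site, reads, sample)
        for (site, sample), reads in merged.items()
    ]
    records.sort(key=lambda r: (r.site.occurrence.contig, r.site.occurrence.start, r.sample))
    report.n_matched = len(records)
    return records, report


def stratify(records: Sequence[CleavageRecord]) -> dict[str, list[CleavageRecord]]:
    """Partition records into perfect-match and mismatch strata."""
    out: dict[str, list[CleavageRecord]] = {"perfect": [], "mismatch": []}
    for rec in records:
        out[rec.match_class].append(rec)
    return out


def catalog_to_bed(
    sites: Sequence[TargetSite], name: str, path: str | Path
) -> None:
    """Export a target catalog as BED6+ (mismatches, pam_window columns)."""
    with open(path, "w") as fh:
        for s in sites:
            o = s.occurrence
            fh.write(
                f"{o.contig}\t{o.start}\t{o.end}\t{name}\t0\t{o.strand}"
                f"\t{s.mismatches}\t{s.pam_window}\n"
            )


def records_to_table(records: Sequence[CleavageRecord]) -> pd.DataFrame:
    """Flatten records back into the site-table dialect (plus annotations)."""
    rows = []
    for r in records:
        o = r.site.occurrence
        rows.append(
            {
                "chrom": o.contig,
                "start": o.start,
                "end": o.end,
                "strand": o.strand,
                "read_count": r.read_count,
                "sample": r.sample,
                "mismatches": r.site.mismatches,
                "mismatch_positions": ",".join(map(str, r.site.mismatch_positions)),
                "pam_window": r.site.pam_window,
                "match_class": r.match_class,
            }
        )
    return pd.DataFrame(rows)


def with_read_count(record: CleavageRecord, read_count: int) -> CleavageRecord:
    return replace(record, read_count=read_count)
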