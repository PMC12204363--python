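"""Genome-wide discovery of repeat protospacers with diverse flanks.

A good repeat protospacer occurs many times and is flanked by nearly random
sequence, so that its flank population covers the PAM space a nuclease might
recognize (ideally all 4^L PAMs of the target length L). Candidates are
k-mers (default 20) filtered for a 5' G (required by most gRNA scaffolds)
and against AAA/TTT/CCC/GGG homopolymer runs, then scored by the number of
distinct flanks and the per-position Shannon entropy of the flank base
composition (2 bits/position = uniform random).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, find_occurrences, get_flank, revcomp

logger = logging.getLogger(__name__)

BASES = "ACGT"
HOMOPOLYMERS = ("AAA", "TTT", "CCC", "GGG")

# refuse whole-genome k-mer enumeration above this many bases; larger genomes
# must supply an explicit k-mer list to query
DEFAULT_GENOME_BP_BUDGET = 100_000_000


@dataclass
class FlankProfile:
    """Diversity summary of a set of equal-length flanks."""

    n_flanks: int
    unique_count: dict[int, int]  # flank prefix length -> distinct strings
    pfm: pd.DataFrame  # positions x ACGT, columns sum to 1
    mean_entropy_bits: float


@dataclass
class RepeatCandidate:
    sequence: str
    k: int
    count: int
    unique_flank_count: dict[int, int] = field(default_factory=dict)
    flank_pfm: pd.DataFrame | None = None
    mean_entropy_bits: float = float("nan")
    profiles: dict[str, FlankProfile] = field(default_factory=dict)
    suitable: bool | None = None


def passes_filters(
    kmer: str, require_5prime_g: bool = True, forbid_homopolymer3: bool = True
) -> bool:
    """Apply the candidate-protospacer sequence filters to one k-mer."""
    if require_5prime_g and not kmer.startswith("G"):
        return False
    if forbid_homopolymer3 and any(h in kmer for h in HOMOPOLYMERS):
        return False
    return True


def _count_kmers_forward(index: GenomeIndex, k: int) -> Counter:
    counts: Counter = Counter()
    for seq in index.contigs.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] += 1
    return counts


def shannon_entropy(column_probs: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log0 := 0 convention."""
    p = np.asarray(column_probs, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def flank_profile(flanks: Sequence[str]) -> FlankProfile:
    """Unique-flank counts, base frequency matrix and mean entropy.

    All flanks must have equal length; flanks containing N are dropped
    (and logged) before profiling. Raises on an empty (or all-N) input.
    """
    if not flanks:
        raise ValueError("empty flank list")
    lengths = {len(f) for f in flanks}
    if len(lengths) != 1:
        raise ValueError(f"flanks of mixed lengths: {sorted(lengths)}")
    clean = [f for f in flanks if "N" not in f]
    dropped = len(flanks) - len(clean)
    if dropped:
        logger.info("flank_profile: dropped %d N-containing flanks", dropped)
    if not clean:
        raise ValueError("all flanks contain N")
    L = len(clean[0])
    unique_count = {
        ell: len({f[:ell] for f in clean}) for ell in range(1, L + 1)
    }
    mat = np.zeros((L, 4))
    idx = {b: j for j, b in enumerate(BASES)}
    for f in clean:
        for pos, b in enumerate(f):
            mat[pos, idx[b]] += 1
    probs = mat / mat.sum(axis=1, keepdims=True)
    pfm = pd.DataFrame(probs, columns=list(BASES), index=range(1, L + 1))
    mean_entropy = float(np.mean([shannon_entropy(row) for row in probs]))
    return FlankProfile(len(clean), unique_count, pfm, mean_entropy)


def _collect_flanks(
    index: GenomeIndex, kmer: str, strand_mode: str, side: str, length: int
) -> list[str]:
    flanks = []
    skipped = 0
    for occ in find_occurrences(index, kmer, strand_mode):
        try:
            flanks.append(get_flank(index, occ, side, length))
        except ValueError:
            skipped += 1
    if skipped:
        logger.info(
            "%s: discarded %d occurrences with edge-truncated %s flanks",
            kmer, skipped, side,
        )
    return flanks


def find_candidates(
    index: GenomeIndex,
    k: int = 20,
    min_count: int = 2,
    require_5prime_g: bool = True,
    forbid_homopolymer3: bool = True,
    strand_mode: str = "forward",
    flank_length: int = 10,
    pam_side: str = "3prime",
    kmers: Iterable[str] | None = None,
    genome_bp_budget: int = DEFAULT_GENOME_BP_BUDGET,
) -> list[RepeatCandidate]:
    """Repeat-protospacer candidates sorted by count (desc), then sequence.

    By default every genomic k-mer is enumerated; for genomes above
    ``genome_bp_budget`` an explicit ``kmers`` list must be supplied
    (query-only mode). Both the 3' and 5' flanks of each candidate are
    profiled so the same repeat can serve 3'-PAM nucleases directly and
    5'-PAM nucleases through its reverse complement; the headline fields
    reflect ``pam_side``.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    if all(k > n for n in index.lengths.values()):
        raise ValueError(f"k={k} larger than the longest contig")

    if kmers is None:
        if index.total_length > genome_bp_budget:
            raise ValueError(
                f"genome of {index.total_length} bp exceeds the enumeration "
                f"budget ({genome_bp_budget} bp); pass an explicit k-mer list"
            )
        forward = _count_kmers_forward(index, k)
        if strand_mode == "both":
            counts = {}
            for w, c in forward.items():
                rc = revcomp(w)
                counts[w] = c if rc == w else c + forward.get(rc, 0)
        else:
            counts = dict(forward)
        universe = counts.items()
    else:
        universe = []
        from .genome_io import count_kmer

        for w in kmers:
            if len(w) != k:
                raise ValueError(f"queried k-mer {w!r} is not length {k}")
            universe.append((w, count_kmer(index, w, strand_mode)))

    out: list[RepeatCandidate] = []
    for kmer, count in universe:
        if count < min_count:
            continue
        if not passes_filters(kmer, require_5prime_g, forbid_homopolymer3):
            continue
        cand = RepeatCandidate(sequence=kmer, k=k, count=count)
        for side in ("3prime", "5prime"):
            flanks = _collect_flanks(index, kmer, strand_mode, side, flank_length)
            if flanks:
                cand.profiles[side] = flank_profile(flanks)
        prof = cand.profiles.get(pam_side)
        if prof is not None:
            cand.unique_flank_count = prof.unique_count
            cand.flank_pfm = prof.pfm
            cand.mean_entropy_bits = prof.mean_entropy_bits
        out.append(cand)
    out.sort(key=lambda c: (-c.count, c.sequence))
    return out


def rank_candidates(
    candidates: Sequence[RepeatCandidate],
    pam_length_target: int,
    threshold_fraction: float = 0.75,
) -> list[RepeatCandidate]:
    """Annotate candidates as suitable for a PAM of the target length.

    Suitable iff the number of distinct flank prefixes of that length is at
    least ``threshold_fraction * 4**pam_length_target`` — i.e. the flank
    population nearly saturates the PAM space. Returns candidates ordered
    suitable-first, then by count.
    """
    if pam_length_target < 1:
        raise ValueError("pam_length_target must be >= 1")
    need = threshold_fraction * 4 ** pam_length_target
    for cand in candidates:
        uniq = cand.unique_flank_count.get(pam_length_target, 0)
        cand.suitable = uniq >= need
    return sorted(
        candidates, key=lambda c: (not c.suitable, -c.count, c.sequence)
    )


def candidates_to_tsv(
    candidates: Sequence[RepeatCandidate], path: str | Path
) -> pd.DataFrame:
    """Candidate report: sequence, count, unique flank counts, entropy."""
    rows = []
    for c in candidates:
        row = {
            "sequence": c.sequence,
            "k": c.k,
            "count": c.count,
            "mean_entropy_bits": c.mean_entropy_bits,
            "suitable": c.suitable,
        }
        for ell, n in sorted(c.unique_flank_count.items()):
            row[f"unique_flanks_{ell}"] = n
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def pfm_to_tsv(pfm: pd.DataFrame, path: str | Path) -> None:
    """Write a position x base frequency matrix for logo-plotting tools."""
    pfm.to_csv(path, sep="\t", index_label="position")
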