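"""Genome loading, k-mer counting and flank retrieval.

All coordinates are 0-based half-open on the plus strand; conversion to or
from 1-based happens only at I/O boundaries. Sequences are stored uppercase
over the alphabet {A, C, G, T, N}; any other symbol is mapped to N at load
time. Windows that contain an N never match a k-mer.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# every byte not in ACGTN becomes N after upper-casing
_SANITIZE = str.maketrans(
    {chr(c): "N" for c in range(256) if chr(c) not in "ACGTN"}
)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Occurrence:
    """One genomic interval carrying a strand.

    ``start``/``end`` are plus-strand 0-based half-open regardless of
    ``strand``; for strand ``-`` the occurring sequence is the reverse
    complement of the plus-strand slice.
    """

    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")


class GenomeIndex:
    """In-memory genome: ordered map of contig name -> uppercase sequence."""

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("empty genome: no contigs")
        self.contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if name in self.contigs:
                raise ValueError(f"duplicate contig name: {name!r}")
            self.contigs[name] = seq.upper().translate(_SANITIZE)
        self.lengths = {name: len(s) for name, s in self.contigs.items()}

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def sequence(self, contig: str) -> str:
        return self.contigs[contig]

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Slice a contig; strand '-' returns the reverse complement."""
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"{contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_genome(fasta_path: str | Path, hard_mask_lowercase: bool = False) -> GenomeIndex:
    """Load a (possibly gzipped) FASTA into a :class:`GenomeIndex`.

    Lowercase (soft-masked) bases are used as ordinary bases unless
    ``hard_mask_lowercase`` is set, in which case they become N. Duplicate
    contig names are a hard error.
    """
    contigs: dict[str, str] = {}
    with _open_text(fasta_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name: {rec.id!r}")
            seq = str(rec.seq)
            if hard_mask_lowercase:
                seq = "".join("N" if c.islower() else c for c in seq)
            contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return GenomeIndex(contigs)


def write_fasta(index: GenomeIndex, path: str | Path, width: int = 80) -> None:
    """Write the index back out as plain FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for name, seq in index.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _validate_kmer(index: GenomeIndex, kmer: str) -> None:
    if not kmer or any(c not in "ACGT" for c in kmer):
        raise ValueError(f"k-mer must be non-empty ACGT-only, got {kmer!r}")
    if all(len(kmer) > n for n in index.lengths.values()):
        raise ValueError(f"k-mer longer than every contig (k={len(kmer)})")


def _forward_positions(seq: str, kmer: str) -> Iterator[int]:
    """Overlapping forward-strand match positions of kmer in seq."""
    i = seq.find(kmer)
    while i != -1:
        yield i
        i = seq.find(kmer, i + 1)


def find_occurrences(
    index: GenomeIndex, kmer: str, strand_mode: str = "forward"
) -> list[Occurrence]:
    """Exact occurrences of ``kmer``, sorted by (contig, start).

    ``strand_mode='both'`` additionally reports plus-strand matches of the
    reverse complement as strand '-' occurrences; a palindromic k-mer is
    reported once per genomic interval (as '+').
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    _validate_kmer(index, kmer)
    k = len(kmer)
    out: list[Occurrence] = []
    rc = revcomp(kmer)
    for contig, seq in index.contigs.items():
        starts = {i: "+" for i in _forward_positions(seq, kmer)}
        if strand_mode == "both" and rc != kmer:
            for i in _forward_positions(seq, rc):
                starts.setdefault(i, "-")
        out.extend(
            Occurrence(contig, i, i + k, s) for i, s in sorted(starts.items())
        )
    out.sort(key=lambda o: (o.contig, o.start))
    return out


def count_kmer(index: GenomeIndex, kmer: str, strand_mode: str = "forward") -> int:
    """Number of (overlapping) occurrences of ``kmer``; see find_occurrences."""
    return len(find_occurrences(index, kmer, strand_mode))


def get_flank(
    index: GenomeIndex, occ: Occurrence, side: str, length: int
) -> str:
    """Flanking sequence of an occurrence, in the occurrence's orientation.

    ``side`` is '5prime' or '3prime' relative to the occurring (strand-
    oriented) sequence. Raises ValueError when the flank would cross a
    contig edge; callers discard such sites rather than pad them.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError(f"side must be 5prime or 3prime, got {side!r}")
    if length < 1:
        raise ValueError("flank length must be >= 1")
    clen = index.lengths[occ.contig]
    if occ.start < 0 or occ.end > clen:
        raise ValueError(f"occurrence {occ} outside contig (length {clen})")
    # on the plus strand: 5' flank is upstream of start, 3' downstream of end;
    # on the minus strand the roles swap and the slice is reverse-complemented.
    downstream = (side == "3prime") == (occ.strand == "+")
    if downstream:
        lo, hi = occ.end, occ.end + length
    else:
        lo, hi = occ.start - length, occ.start
    if lo < 0 or hi > clen:
        raise ValueError(
            f"{side} flank of {occ} (length {length}) crosses contig edge"
        )
    return index.fetch(occ.contig, lo, hi, occ.strand)


def occurrences_to_bed(
    occurrences: Iterable[Occurrence], name: str, path: str | Path
) -> None:
    """Export occurrences as BED6 (score 0, name = the query k-mer)."""
    with open(path, "w") as fh:
        for occ in occurrences:
            fh.write(
                f"{occ.contig}\t{occ.start}\t{occ.end}\t{name}\t0\t{occ.strand}\n"
            )
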