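"""PAM statistics: frequency matrices, PAM cleavage values and heatmaps.

The PAM cleavage value (PCV) of a PAM k-mer is the ratio of its share among
captured (cleaved) sites to its share among all k-mers of the same length in
the genome; the relative PCV is log2(PCV / max PCV), so the best PAM maps
to 0 and every other PAM is <= 0. Captured shares are read-weighted by
default (weighting='reads'), with a sites-only alternative; the choice is
recorded in output metadata because either convention is defensible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex, revcomp
from .target_catalog import CleavageRecord, TargetSite

logger = logging.getLogger(__name__)

BASES = "ACGT"


@dataclass
class PamCount:
    site_count: int = 0
    read_sum: int = 0


@dataclass
class PamCountTable:
    pam_length: int
    counts: dict[str, PamCount]
    stratum: str = "all"

    @property
    def total_sites(self) -> int:
        return sum(c.site_count for c in self.counts.values())

    @property
    def total_reads(self) -> int:
        return sum(c.read_sum for c in self.counts.values())


@dataclass
class PcvTable:
    pam_length: int
    pcv: dict[str, float]
    relative_pcv: dict[str, float]
    background_freq: dict[str, float]
    weighting: str = "reads"
    stratum: str = "all"
    metadata: dict = field(default_factory=dict)


@dataclass
class PositionFrequencyMatrix:
    probs: pd.DataFrame  # positions (1..W) x ACGT
    weighting: str

    @property
    def window_length(self) -> int:
        return len(self.probs)


def pam_counts(
    records: Sequence[CleavageRecord],
    pam_length: int = 4,
    offset: int = 0,
    stratum: str = "all",
) -> PamCountTable:
    """Tally site counts and read sums per PAM substring.

    The PAM is the ``pam_length`` bases of each record's PAM window starting
    ``offset`` bases from the protospacer-proximal end. Records with N in
    that substring are dropped and logged.
    """
    counts: dict[str, PamCount] = {}
    dropped = 0
    for rec in records:
        window = rec.site.pam_window
        if pam_length + offset > len(window):
            raise ValueError(
                f"pam_length+offset ({pam_length + offset}) exceeds window "
                f"length {len(window)}"
            )
        pam = window[offset : offset + pam_length]
        if "N" in pam:
            dropped += 1
            continue
        c = counts.setdefault(pam, PamCount())
        c.site_count += 1
        c.read_sum += rec.read_count
    if dropped:
        logger.info("pam_counts: dropped %d records with N in the PAM", dropped)
    return PamCountTable(pam_length, counts, stratum)


def position_frequency_matrix(
    records: Sequence[CleavageRecord], weighting: str = "reads"
) -> PositionFrequencyMatrix:
    """Per-position base probabilities over PAM windows (logo input).

    weighting='reads' weights each record by its read count (the convention
    used for cleavage logos); 'sites' counts each record once. N bases are
    excluded per column; a column that is all N is an error.
    """
    if not records:
        raise ValueError("no records")
    if weighting not in ("reads", "sites"):
        raise ValueError(f"unknown weighting {weighting!r}")
    W = len(records[0].site.pam_window)
    mat = np.zeros((W, 4))
    idx = {b: j for j, b in enumerate(BASES)}
    for rec in records:
        w = 1.0 if weighting == "sites" else float(rec.read_count)
        for pos, b in enumerate(rec.site.pam_window):
            if b in idx:
                mat[pos, idx[b]] += w
    colsums = mat.sum(axis=1)
    if np.any(colsums == 0):
        raise ValueError("a PAM window column has no informative (non-N) base")
    probs = pd.DataFrame(
        mat / colsums[:, None], columns=list(BASES), index=range(1, W + 1)
    )
    return PositionFrequencyMatrix(probs, weighting)


def _kmer_counts_array(seq: str, k: int) -> np.ndarray:
    """Counts of all 4^k k-mers in one forward sequence (N windows skipped)."""
    code = np.full(256, -1, dtype=np.int64)
    for j, b in enumerate(BASES):
        code[ord(b)] = j
    arr = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = arr.size - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = arr[j : j + n]
        valid &= col >= 0
        vals = vals * 4 + np.where(col >= 0, col, 0)
    return np.bincount(vals[valid], minlength=4 ** k)


def _index_to_kmer(i: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[i % 4])
        i //= 4
    return "".join(reversed(out))


def all_kmers(k: int) -> list[str]:
    return [_index_to_kmer(i, k) for i in range(4 ** k)]


def background_pam_freq(
    index: GenomeIndex,
    pam_length: int,
    mode: str = "genome_kmers",
    catalog: Sequence[TargetSite] | None = None,
    offset: int = 0,
) -> dict[str, float]:
    """Background frequency of every PAM k-mer.

    mode='genome_kmers': frequency over all genomic positions, both strands
    (each window counted forward and as its reverse complement).
    mode='catalog_flanks': frequency over the PAM windows of a perfect-match
    target catalog, using the same substring convention as pam_counts.
    """
    if pam_length < 1:
        raise ValueError("pam_length must be >= 1")
    k = pam_length
    if mode == "genome_kmers":
        counts = np.zeros(4 ** k, dtype=np.int64)
        for seq in index.contigs.values():
            counts += _kmer_counts_array(seq, k)
            counts += _kmer_counts_array(revcomp(seq), k)
        total = counts.sum()
        if total == 0:
            raise ValueError("no valid k-mer windows in the genome")
        return {
            _index_to_kmer(i, k): counts[i] / total for i in range(4 ** k)
        }
    if mode == "catalog_flanks":
        if not catalog:
            raise ValueError("catalog_flanks mode requires a target catalog")
        tallies: dict[str, int] = {p: 0 for p in all_kmers(k)}
        n = 0
        for site in catalog:
            pam = site.pam_window[offset : offset + k]
            if "N" in pam:
                continue
            tallies[pam] += 1
            n += 1
        if n == 0:
            raise ValueError("no N-free PAM windows in the catalog")
        return {p: c / n for p, c in tallies.items()}
    raise ValueError(f"unknown mode {mode!r}")


def compute_pcv(
    pam_table: PamCountTable,
    background: Mapping[str, float],
    weighting: str = "reads",
    pseudocount: float = 0.0,
) -> PcvTable:
    """PAM cleavage values and relative (log2, max-normalized) PCVs.

    pcv(p) = captured fraction of p / background fraction of p. PAMs present
    in the background but never captured get pcv 0 and relative_pcv -inf
    (blank heatmap cells) unless a pseudocount (> 0 sites, each carrying one
    read) is supplied. A captured PAM with zero background frequency is an
    error naming the PAM.
    """
    if weighting not in ("reads", "sites"):
        raise ValueError(f"unknown weighting {weighting!r}")
    weights: dict[str, float] = {}
    for pam in background:
        c = pam_table.counts.get(pam)
        base = 0.0
        if c is not None:
            base = float(c.read_sum if weighting == "reads" else c.site_count)
        weights[pam] = base + pseudocount
    for pam, c in pam_table.counts.items():
        if pam not in background or background[pam] == 0:
            raise ValueError(f"captured PAM {pam!r} has zero background frequency")
    total = sum(weights.values())
    if total == 0:
        raise ValueError("no captured PAMs (all weights zero)")
    pcv = {p: (w / total) / background[p] for p, w in weights.items()}
    max_pcv = max(pcv.values())
    if max_pcv <= 0:
        raise ValueError("all PCVs are zero")
    relative = {
        p: (math.log2(v / max_pcv) if v > 0 else float("-inf"))
        for p, v in pcv.items()
    }
    return PcvTable(
        pam_table.pam_length,
        pcv,
        relative,
        dict(background),
        weighting,
        pam_table.stratum,
        metadata={
            "captured_weighting": weighting,
            "pseudocount": pseudocount,
            "total_captured_weight": total,
        },
    )


def pcv_to_frame(pcv_table: PcvTable, pam_table: PamCountTable | None = None) -> pd.DataFrame:
    rows = []
    for pam in sorted(pcv_table.pcv):
        c = pam_table.counts.get(pam) if pam_table else None
        rows.append(
            {
                "pam": pam,
                "site_count": c.site_count if c else 0,
                "read_sum": c.read_sum if c else 0,
                "background_freq": pcv_table.background_freq[pam],
                "pcv": pcv_table.pcv[pam],
                "relative_pcv": pcv_table.relative_pcv[pam],
                "stratum": pcv_table.stratum,
                "weighting": pcv_table.weighting,
            }
        )
    return pd.DataFrame(rows)


def pcv_to_tsv(
    pcv_table: PcvTable, path: str | Path, pam_table: PamCountTable | None = None
) -> pd.DataFrame:
    df = pcv_to_frame(pcv_table, pam_table)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def pcv_heatmap_table(pcv_table: PcvTable) -> pd.DataFrame:
    """4-base relative-PCV heatmap: rows = first two PAM positions,
    columns = last two; -inf (never captured) rendered as NaN (blank)."""
    if pcv_table.pam_length != 4:
        raise ValueError("heatmap layout is defined for 4-base PAMs")
    duos = ["".join(p) for p in __import__("itertools").product(BASES, repeat=2)]
    mat = pd.DataFrame(index=duos, columns=duos, dtype=float)
    for pam, rel in pcv_table.relative_pcv.items():
        mat.loc[pam[:2], pam[2:]] = rel if math.isfinite(rel) else math.nan
    return mat


def pfm_to_tsv(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Write the PFM as a logo-plotter-ready TSV (position x base)."""
    df = pfm.probs.copy()
    df.to_csv(path, sep="\t", index_label="position")
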