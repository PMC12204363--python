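"""Genome-scale derived metrics.

Chromatin accessibility is summarized as the proportion of cleavage reads
falling in each fixed-size chromosomal window (default 5 Mb), compared
between cell types as log2 ratios against the mean of reference replicates.
Nuclease potency and fidelity are summarized per variant from the perfect
(on-target) and mismatch (off-target) strata: site and read ratios, and
activity/specificity relative to named reference variants. Read
down-sampling draws reads without replacement across detected sites
(multivariate hypergeometric), approximating shallower sequencing of the
same library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeIndex
from .target_catalog import CleavageRecord, stratify

DEFAULT_WINDOW = 5_000_000


@dataclass
class AccessibilityProfile:
    window_size: int
    proportions: dict[tuple[str, int], float]  # (contig, window idx) -> prop
    total_reads: int
    grid: dict[str, int]  # contig -> number of windows


@dataclass
class VariantSummary:
    label: str
    on_sites: int
    off_sites: int
    on_reads: int
    off_reads: int
    site_ratio: float = math.nan  # inf when off_sites == 0 (flagged, not error)
    read_ratio: float = math.nan
    relative_activity: float = math.nan
    relative_specificity: float = math.nan


def _window_grid(index: GenomeIndex, window_size: int) -> dict[str, int]:
    return {
        name: max(1, -(-length // window_size))
        for name, length in index.lengths.items()
    }


def accessibility_profile(
    records: Sequence[CleavageRecord],
    index: GenomeIndex,
    window_size: int = DEFAULT_WINDOW,
) -> AccessibilityProfile:
    """Per-window read proportions; a site belongs to the window containing
    its start coordinate. Windows tile each contig from 0 (last one may be
    partial); every window is present, zeros included."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    grid = _window_grid(index, window_size)
    reads: dict[tuple[str, int], int] = {
        (c, i): 0 for c, n in grid.items() for i in range(n)
    }
    total = 0
    for rec in records:
        occ = rec.site.occurrence
        key = (occ.contig, occ.start // window_size)
        if key not in reads:
            raise ValueError(f"record at {occ} outside the window grid")
        reads[key] += rec.read_count
        total += rec.read_count
    if total == 0:
        raise ValueError("zero total reads")
    props = {k: v / total for k, v in reads.items()}
    return AccessibilityProfile(window_size, props, total, grid)


def relative_accessibility(
    profile: AccessibilityProfile,
    reference_profiles: Sequence[AccessibilityProfile],
    pseudocount: float = 0.0,
) -> dict[tuple[str, int], float]:
    """log2(sample proportion / mean reference proportion) per window.

    Windows whose reference mean is zero give NaN unless a pseudocount is
    added to both numerator and denominator. Grids must match exactly.
    """
    if not reference_profiles:
        raise ValueError("at least one reference profile required")
    for ref in reference_profiles:
        if ref.grid != profile.grid or ref.window_size != profile.window_size:
            raise ValueError("window grid mismatch between sample and reference")
    out: dict[tuple[str, int], float] = {}
    n_ref = len(reference_profiles)
    for key, p in profile.proportions.items():
        ref_mean = sum(r.proportions[key] for r in reference_profiles) / n_ref
        num, den = p + pseudocount, ref_mean + pseudocount
        if den == 0:
            out[key] = math.nan
        elif num == 0:
            out[key] = -math.inf
        else:
            out[key] = math.log2(num / den)
    return out


def on_off_summary(records: Sequence[CleavageRecord], label: str = "sample") -> VariantSummary:
    """Site and read counts/ratios for the perfect vs mismatch strata.

    A zero off-target denominator flags the ratio as +inf rather than
    raising, so fully specific runs remain representable.
    """
    strata = stratify(records)
    on, off = strata["perfect"], strata["mismatch"]
    s = VariantSummary(
        label=label,
        on_sites=len(on),
        off_sites=len(off),
        on_reads=sum(r.read_count for r in on),
        off_reads=sum(r.read_count for r in off),
    )
    s.site_ratio = s.on_sites / s.off_sites if s.off_sites else math.inf
    s.read_ratio = s.on_reads / s.off_reads if s.off_reads else math.inf
    return s


def downsample_reads(
    records: Sequence[CleavageRecord],
    n_reads: int,
    seed: int | np.random.Generator,
    detection_min: int = 1,
) -> list[CleavageRecord]:
    """Draw ``n_reads`` without replacement across records.

    Read counts are resampled jointly (multivariate hypergeometric on the
    per-record counts); records keeping at least ``detection_min`` reads
    survive. Deterministic under a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.array([r.read_count for r in records], dtype=np.int64)
    total = int(counts.sum())
    if n_reads > total:
        raise ValueError(f"n_reads {n_reads} exceeds total reads {total}")
    if n_reads == total:
        return list(records)
    new_counts = rng.multivariate_hypergeometric(counts, n_reads)
    return [
        replace(rec, read_count=int(c))
        for rec, c in zip(records, new_counts)
        if c >= detection_min
    ]


def relative_metrics(
    summaries: Sequence[VariantSummary],
    activity_reference_label: str,
    specificity_reference_label: str,
) -> list[VariantSummary]:
    """Fill relative activity/specificity against the named references.

    relative_activity(v)   = on_sites(v)   / mean on_sites(activity ref)
    relative_specificity(v) = site_ratio(v) / mean site_ratio(specificity ref)

    Replicates (repeated labels) are supported: reference values are means
    over the reference replicates, and each summary keeps its own relative
    value (aggregate with :func:`aggregate_relative`).
    """
    act_ref = [s for s in summaries if s.label == activity_reference_label]
    spec_ref = [s for s in summaries if s.label == specificity_reference_label]
    if not act_ref:
        raise KeyError(f"activity reference {activity_reference_label!r} absent")
    if not spec_ref:
        raise KeyError(f"specificity reference {specificity_reference_label!r} absent")
    act_base = float(np.mean([s.on_sites for s in act_ref]))
    spec_base = float(np.mean([s.site_ratio for s in spec_ref]))
    if act_base == 0:
        raise ValueError("activity reference has zero on-target sites")
    if not math.isfinite(spec_base) or spec_base == 0:
        raise ValueError("specificity reference ratio is zero or undefined")
    out = []
    for s in summaries:
        out.append(
            replace(
                s,
                relative_activity=s.on_sites / act_base,
                relative_specificity=(
                    s.site_ratio / spec_base if math.isfinite(s.site_ratio) else math.inf
                ),
            )
        )
    return out


def aggregate_relative(summaries: Sequence[VariantSummary]) -> pd.DataFrame:
    """Per-label mean +/- SD of the relative metrics (scatter-plot input)."""
    df = pd.DataFrame(
        {
            "label": [s.label for s in summaries],
            "relative_activity": [s.relative_activity for s in summaries],
            "relative_specificity": [s.relative_specificity for s in summaries],
        }
    )
    return (
        df.groupby("label")
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def summaries_to_frame(summaries: Sequence[VariantSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def profile_to_bedgraph(profile: AccessibilityProfile, path: str | Path) -> None:
    """Raw window proportions as bedGraph."""
    with open(path, "w") as fh:
        for (contig, wi), prop in sorted(profile.proportions.items()):
            start = wi * profile.window_size
            end = start + profile.window_size
            fh.write(f"{contig}\t{start}\t{end}\t{prop:.8g}\n")


def ratios_to_tsv(
    ratios: Mapping[tuple[str, int], float],
    window_size: int,
    path: str | Path,
) -> pd.DataFrame:
    """log2 ratios as NA-aware TSV."""
    rows = [
        {
            "contig": contig,
            "window_start": wi * window_size,
            "log2_ratio": (r if math.isfinite(r) else math.nan),
        }
        for (contig, wi), r in sorted(ratios.items())
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return df
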