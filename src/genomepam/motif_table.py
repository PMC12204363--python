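"""Iterative seed-extension search for enriched PAM motifs.

The table algorithm asks, position by position, which concrete bases in the
candidate PAM window are over-represented among cleaved sites relative to
the genomic background of perfect-match targets:

1. Seed: over all window positions x 4 bases, find the single-base motif
   whose edited value is most significantly enriched (chi-square on a 2x2
   table of edited value vs genomic totals, motif vs all other motifs in the
   same window; two-sided, 1 df, no Yates correction by default).
2. Extend the seed one base at a time, 5' or 3', keeping whichever extension
   is most significant, until both ends of the window are reached.
3. Report the step sequence, retaining only steps whose percent of genomic
   targets edited strictly increases (and that stay significant after a
   Bonferroni correction over the candidates evaluated at that step).

The edited value of a motif m is det(m) + reads(m) * s, where det is the
number of detected sites matching m, reads their read-count sum, and
s = max_m' det(m') / max_m' reads(m') within the current window, so the
rescaled read contribution has the same maximum as the site counts. If all
reads are zero the edited value degenerates to det.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

from .target_catalog import CleavageRecord, TargetSite

logger = logging.getLogger(__name__)

BASES = "ACGT"

_MIN_P = 1e-300  # p-values are clamped into (0, 1]

IUPAC_CODES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("AC"): "M", frozenset("GT"): "K",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


@dataclass
class MotifResult:
    positions: tuple[int, int]  # 1-based inclusive interval in the PAM window
    motif: str
    edited_sites: int
    genomic_total: int
    edited_value: float
    percent_edited: float
    chi2: float
    p_value: float
    p_adjusted: float
    n_candidates: int
    retained: bool = False
    # all candidate motifs evaluated at this step (incl. the chosen one)
    alternatives: list["MotifResult"] = field(default_factory=list)


@dataclass
class TableRun:
    steps: list[MotifResult]
    retained: list[MotifResult]
    alpha: float
    seed_significant: bool
    window_length: int
    metadata: dict = field(default_factory=dict)


@dataclass
class CollapsedMotif:
    positions: tuple[int, int]
    motif: str  # IUPAC string over the interval
    merged_bases: str  # bases merged at the newly added position
    percent_range: tuple[float, float]


def _window_tallies(
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
    p: int,
    q: int,
) -> dict[str, list[float]]:
    """motif -> [det_sites, det_reads, genomic_total] for window [p..q]."""
    tallies: dict[str, list[float]] = {}
    lo, hi = p - 1, q
    for site in catalog:
        m = site.pam_window[lo:hi]
        if "N" in m:
            continue
        t = tallies.setdefault(m, [0, 0, 0])
        t[2] += 1
    for rec in detections:
        m = rec.site.pam_window[lo:hi]
        if m not in tallies:
            # detected site absent from the catalog window (e.g. N); skip
            continue
        t = tallies[m]
        t[0] += 1
        t[1] += rec.read_count
    return tallies


def _edited_values(tallies: dict[str, list[float]]) -> dict[str, float]:
    max_det = max((t[0] for t in tallies.values()), default=0)
    max_reads = max((t[1] for t in tallies.values()), default=0)
    s = (max_det / max_reads) if max_reads > 0 else 0.0
    return {m: t[0] + t[1] * s for m, t in tallies.items()}


def edited_value(
    motif: str,
    positions: tuple[int, int],
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
) -> float:
    """Edited value E(m) of one concrete motif within its window."""
    tallies = _window_tallies(detections, catalog, *positions)
    return _edited_values(tallies).get(motif, 0.0)


def pearson_chi2_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Two-sided Pearson chi-square (1 df) for the 2x2 table [[a,b],[c,d]].

    Fractional entries are used as-is. A table with a zero margin yields
    (0.0, 1.0) by convention.
    """
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if n == 0 or any(m == 0 for m in margins):
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff * diff / math.prod(margins)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(min(p, 1.0), _MIN_P)


def motif_chi2(
    motif: str,
    positions: tuple[int, int],
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
    yates: bool = False,
) -> tuple[float, float]:
    """Chi-square of one motif's edited value against the window background.

    The 2x2 table is [[E(m), E(not m)], [total(m), total(not m)]] over all
    motifs of the same window observed in the catalog.
    """
    tallies = _window_tallies(detections, catalog, *positions)
    E = _edited_values(tallies)
    e_m = E.get(motif, 0.0)
    t_m = tallies.get(motif, [0, 0, 0])[2]
    e_rest = sum(E.values()) - e_m
    t_rest = sum(t[2] for t in tallies.values()) - t_m
    return pearson_chi2_2x2(e_m, e_rest, t_m, t_rest, yates=yates)


def _evaluate_window(
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
    p: int,
    q: int,
    restrict: Sequence[str] | None = None,
    yates: bool = False,
) -> list[MotifResult]:
    """Chi-square results for every (or selected) motif of window [p..q]."""
    tallies = _window_tallies(detections, catalog, p, q)
    if not tallies:
        return []
    E = _edited_values(tallies)
    sum_e = sum(E.values())
    sum_t = sum(t[2] for t in tallies.values())
    motifs = restrict if restrict is not None else sorted(tallies)
    results = []
    for m in motifs:
        t = tallies.get(m, [0, 0, 0])
        e_m = E.get(m, 0.0)
        chi2, pval = pearson_chi2_2x2(
            e_m, sum_e - e_m, t[2], sum_t - t[2], yates=yates
        )
        total = int(t[2])
        pct = 100.0 * t[0] / total if total > 0 else 0.0
        results.append(
            MotifResult(
                positions=(p, q),
                motif=m,
                edited_sites=int(t[0]),
                genomic_total=total,
                edited_value=e_m,
                percent_edited=pct,
                chi2=chi2,
                p_value=pval,
                p_adjusted=1.0,
                n_candidates=0,
            )
        )
    # warn once per window when expected counts run low
    if sum_e > 0 and sum_t > 0:
        n_all = sum_e + sum_t
        for r in results:
            colsum = r.edited_value + r.genomic_total
            if 0 < colsum and min(
                sum_e * colsum / n_all, sum_t * colsum / n_all
            ) < 5:
                logger.warning(
                    "window %s motif %s: expected count < 5 in chi-square",
                    (p, q), r.motif,
                )
                break
    return results


def _tie_key(r: MotifResult) -> tuple:
    # smaller p, larger percent edited, 5'-most position, alphabetical base
    return (r.p_value, -r.percent_edited, r.positions[0], r.motif)


def _adjust(results: list[MotifResult]) -> None:
    n = len(results)
    for r in results:
        r.n_candidates = n
        r.p_adjusted = min(1.0, r.p_value * n)


def seed_scan(
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
    window_length: int,
    yates: bool = False,
) -> list[MotifResult]:
    """All W x 4 single-base motif tests, Bonferroni-adjusted together."""
    results: list[MotifResult] = []
    for pos in range(1, window_length + 1):
        results.extend(
            _evaluate_window(detections, catalog, pos, pos, list(BASES), yates)
        )
    _adjust(results)
    return results


def run_table(
    detections: Sequence[CleavageRecord],
    catalog: Sequence[TargetSite],
    window_length: int = 10,
    alpha: float = 0.05,
    yates: bool = False,
) -> TableRun:
    """Run the full seed-extension table.

    ``catalog`` must be the perfect-match target set and ``detections`` the
    cleavage records matched to it (the perfect-match stratum by default;
    run the mismatch stratum separately if desired). Deterministic: ties are
    broken by smaller p, larger percent edited, 5'-most position, then
    alphabetical motif.
    """
    meta = {
        "alpha": alpha,
        "chi2_table": "2x2 motif vs other motifs in window",
        "yates": yates,
        "adjustment": "Bonferroni over candidates per step",
    }
    if not detections:
        logger.warning("run_table: no detections; empty table")
        return TableRun([], [], alpha, False, window_length, meta)
    seeds = seed_scan(detections, catalog, window_length, yates)
    if not seeds:
        logger.warning("run_table: empty catalog window; empty table")
        return TableRun([], [], alpha, False, window_length, meta)
    seed = min(seeds, key=_tie_key)
    seed.alternatives = [
        s for s in seeds if s.positions == seed.positions
    ]
    steps = [seed]
    p, q = seed.positions
    motif = seed.motif
    while p > 1 or q < window_length:
        candidates: list[MotifResult] = []
        if p > 1:
            candidates.extend(
                _evaluate_window(
                    detections, catalog, p - 1, q,
                    [b + motif for b in BASES], yates,
                )
            )
        if q < window_length:
            candidates.extend(
                _evaluate_window(
                    detections, catalog, p, q + 1,
                    [motif + b for b in BASES], yates,
                )
            )
        _adjust(candidates)
        if not candidates:
            break
        best = min(candidates, key=_tie_key)
        best.alternatives = [
            c for c in candidates if c.positions == best.positions
        ]
        steps.append(best)
        p, q = best.positions
        motif = best.motif
    retained: list[MotifResult] = []
    seed_significant = seed.p_adjusted < alpha
    for step in steps:
        if step.p_adjusted >= alpha:
            continue
        if retained and step.percent_edited <= retained[-1].percent_edited:
            continue
        step.retained = True
        retained.append(step)
    return TableRun(steps, retained, alpha, seed_significant, window_length, meta)


def collapse_iupac(
    step: MotifResult, fold_threshold: float = 0.8, alpha: float = 0.05
) -> CollapsedMotif:
    """Collapse a step's newly added position into an IUPAC code.

    Among the base alternatives evaluated at the step's window, every base
    whose individual p-value is below ``alpha`` and whose percent edited is
    at least ``fold_threshold`` times the best base's percent is merged; the
    reported percentage becomes the min-max range over merged bases.
    """
    alts = [a for a in step.alternatives if a.positions == step.positions]
    if not alts:
        raise ValueError("step carries no evaluated alternatives")
    # the added position: alternatives share the interval but differ at one end
    motifs = [a.motif for a in alts]
    width = len(step.motif)
    diff_at = [
        i for i in range(width) if len({m[i] for m in motifs}) > 1
    ]
    new_idx = diff_at[0] if diff_at else 0
    best_pct = step.percent_edited
    passing = [
        a for a in alts
        if a.p_value < alpha and a.percent_edited >= fold_threshold * best_pct
    ]
    if not passing:
        passing = [step]
    bases = frozenset(a.motif[new_idx] for a in passing)
    code = IUPAC_CODES[bases]
    pcts = [a.percent_edited for a in passing]
    motif_chars = list(step.motif)
    motif_chars[new_idx] = code
    return CollapsedMotif(
        positions=step.positions,
        motif="".join(motif_chars),
        merged_bases="".join(sorted(bases)),
        percent_range=(min(pcts), max(pcts)),
    )


def collapse_run(run: TableRun, fold_threshold: float = 0.8, alpha: float = 0.05) -> list[CollapsedMotif]:
    """IUPAC presentation of every retained step of a run."""
    return [collapse_iupac(s, fold_threshold, alpha) for s in run.retained]


def run_to_frame(run: TableRun) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(run.steps):
        rows.append(
            {
                "step": i,
                "kind": "seed" if i == 0 else "extension",
                "motif": s.motif,
                "positions": f"{s.positions[0]}-{s.positions[1]}",
                "edited_sites": s.edited_sites,
                "genomic_total": s.genomic_total,
                "percent_edited": s.percent_edited,
                "edited_value": s.edited_value,
                "chi2": s.chi2,
                "p_value": s.p_value,
                "p_adjusted": s.p_adjusted,
                "retained": "Y" if s.retained else "N",
            }
        )
    return pd.DataFrame(rows)


def run_to_tsv(run: TableRun, path: str | Path) -> pd.DataFrame:
    df = run_to_frame(run)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df


def run_to_json(run: TableRun, path: str | Path) -> None:
    """Full run, including non-chosen candidates, as JSON."""

    def plain(s: MotifResult) -> dict:
        # a step can appear in its own candidate list; never recurse
        return {k: v for k, v in vars(s).items() if k != "alternatives"}

    def encode(step: MotifResult) -> dict:
        d = plain(step)
        d["alternatives"] = [plain(a) for a in step.alternatives]
        return d

    payload = {
        "alpha": run.alpha,
        "window_length": run.window_length,
        "seed_significant": run.seed_significant,
        "metadata": run.metadata,
        "steps": [encode(s) for s in run.steps],
        "retained": [s.motif for s in run.retained],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
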