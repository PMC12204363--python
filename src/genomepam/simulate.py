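"""Seeded synthetic data: genomes with planted repeats and PAM-dependent
cleavage tables.

The generator emulates the structure of a repeat-protospacer cleavage
experiment: an iid background genome, non-overlapping planted copies of a
repeat protospacer (perfect and mismatched — mismatches are genomic
sequence changes concentrated at protospacer positions 8-11 and biased
toward transitions, mirroring how genomic repeat copies actually diverge),
iid flanks on both sides, a PAM model mapping IUPAC motifs to cleavage
probabilities, per-window accessibility multipliers, and a read model
reads | cleaved ~ 1 + Poisson(mu * pam_prob * accessibility). The emitted
site table uses the same TSV dialect the catalog module ingests, and a
truth registry records every planted site with its ground-truth cleavage
probability.

All randomness flows through one integer seed; outputs are byte-identical
across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_io import GenomeIndex, revcomp, write_fasta

BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT", "N": "ACGT",
}

REP1 = "GTGAGCCACTGTGCCTGGCC"


@dataclass
class SimConfig:
    genome_length: int = 1_000_000
    gc_fraction: float = 0.41  # human-like background
    n_contigs: int = 1
    repeat: str = REP1
    n_perfect: int = 500
    n_mismatch: int = 0
    # genomic divergence of mismatch copies: distance distribution and
    # positional bias (default concentrated at protospacer positions 8-11)
    mismatch_distance_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    mismatch_position_weights: dict[int, float] | None = None
    transition_bias: float = 0.8
    flank_length: int = 10
    flank_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pam_side: str = "3prime"
    # IUPAC motifs anchored at PAM window position 1; most specific wins;
    # 'default' applies when nothing matches
    pam_model: dict[str, float] = field(
        default_factory=lambda: {"NGG": 0.9, "NAG": 0.2, "default": 0.01}
    )
    mismatch_activity_factor: float = 0.5  # per-mismatch cleavage penalty
    accessibility_window: int = 5_000_000
    accessibility: dict[str, float] = field(default_factory=dict)  # "contig:wi" -> mult
    read_mu: float = 50.0
    sample: str = "sim"
    seed: int = 0

    def position_weights(self) -> np.ndarray:
        L = len(self.repeat)
        if self.mismatch_position_weights is not None:
            w = np.array(
                [self.mismatch_position_weights.get(i, 0.0) for i in range(1, L + 1)]
            )
        else:
            w = np.ones(L)
            for pos in (8, 9, 10, 11):
                if pos <= L:
                    w[pos - 1] = 6.0
        return w / w.sum()


@dataclass
class PlantedSite:
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]
    protospacer_seq: str  # planted protospacer-strand sequence (with mismatches)
    flank5: str
    flank3: str
    pam: str
    cleavage_prob: float  # ground truth, before accessibility


@dataclass
class SimTruth:
    sites: list[PlantedSite]
    accessibility: dict[str, float]
    accessibility_window: int
    config: SimConfig


def _motif_specificity(motif: str) -> tuple[float, str]:
    # a motif constrains the PAM space to prod(|set_c|)/4^len of sequences
    # with the same trailing-N extension; smaller fraction = more specific
    import math

    log_fraction = sum(math.log(len(IUPAC_SETS[c]), 4) for c in motif) - len(motif)
    return (log_fraction, motif)


def pam_probability(pam: str, pam_model: Mapping[str, float]) -> float:
    """Cleavage probability for a PAM window under an IUPAC motif model.

    Motifs are anchored at window position 1 and resolved most-specific
    first; 'default' is the fallback.
    """
    entries = [
        (m, p) for m, p in pam_model.items() if m != "default"
    ]
    entries.sort(key=lambda mp: _motif_specificity(mp[0]))
    for motif, prob in entries:
        if len(motif) <= len(pam) and all(
            b in IUPAC_SETS[c] for b, c in zip(pam, motif)
        ):
            return prob
    return pam_model.get("default", 0.0)


def _draw_seq(rng: np.random.Generator, n: int, probs) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=list(probs)))


def _mutate(rng: np.random.Generator, proto: str, weights: np.ndarray, d: int, transition_bias: float) -> tuple[str, tuple[int, ...]]:
    L = len(proto)
    positions = rng.choice(L, size=d, replace=False, p=weights)
    positions = tuple(sorted(int(p) + 1 for p in positions))
    s = list(proto)
    for pos in positions:
        ref = s[pos - 1]
        if rng.random() < transition_bias:
            s[pos - 1] = TRANSITION[ref]
        else:
            tv = [b for b in BASES if b != ref and b != TRANSITION[ref]]
            s[pos - 1] = tv[rng.integers(len(tv))]
    return "".join(s), positions


def simulate_genome(config: SimConfig) -> tuple[GenomeIndex, SimTruth]:
    """Background genome with planted repeat copies and recorded flanks.

    Planted footprints (flank + protospacer + flank) never overlap; raises
    if placement fails after bounded retries (genome too small).
    """
    L = len(config.repeat)
    F = config.flank_length
    footprint = L + 2 * F
    n_total = config.n_perfect + config.n_mismatch
    if config.genome_length < 3 * footprint * max(n_total, 1):
        raise ValueError(
            "genome too small for the requested plantings; need length >= "
            f"{3 * footprint * n_total}"
        )
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    bg_probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    contig_len = config.genome_length // config.n_contigs
    contigs: dict[str, np.ndarray] = {}
    for i in range(config.n_contigs):
        seq = rng.choice(np.frombuffer(BASES.encode(), dtype=np.uint8),
                         size=contig_len, p=bg_probs)
        contigs[f"c{i + 1}"] = seq

    # non-overlapping placement of protospacer starts (footprint-aware)
    placements: list[tuple[str, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    names = list(contigs)
    retries = 0
    max_retries = 50 * max(n_total, 1)
    while len(placements) < n_total:
        if retries > max_retries:
            raise ValueError(
                "could not place all repeat copies without overlap; "
                "increase genome_length"
            )
        contig = names[rng.integers(len(names))]
        start = int(rng.integers(F, contig_len - L - F + 1))
        span = (start - F, start + L + F)
        if any(a < span[1] and span[0] < b for a, b in occupied[contig]):
            retries += 1
            continue
        occupied[contig].append(span)
        placements.append((contig, start))
    placements.sort()

    weights = config.position_weights()
    distances = sorted(config.mismatch_distance_probs)
    dprobs = np.array([config.mismatch_distance_probs[d] for d in distances])
    dprobs = dprobs / dprobs.sum()

    # first n_perfect placements are perfect copies, the rest mismatched
    kinds = [0] * config.n_perfect + [1] * config.n_mismatch
    rng.shuffle(kinds)

    sites: list[PlantedSite] = []
    for (contig, start), kind in zip(placements, kinds):
        strand = "+" if rng.random() < 0.5 else "-"
        if kind == 0:
            proto_seq, mpos = config.repeat, ()
        else:
            d = int(rng.choice(distances, p=dprobs))
            proto_seq, mpos = _mutate(
                rng, config.repeat, weights, d, config.transition_bias
            )
        flank5 = _draw_seq(rng, F, config.flank_base_probs)
        flank3 = _draw_seq(rng, F, config.flank_base_probs)
        local = flank5 + proto_seq + flank3
        planted = local if strand == "+" else revcomp(local)
        arr = contigs[contig]
        arr[start - F : start + L + F] = np.frombuffer(
            planted.encode(), dtype=np.uint8
        )
        pam = flank3 if config.pam_side == "3prime" else flank5
        prob = pam_probability(pam, config.pam_model) * (
            config.mismatch_activity_factor ** len(mpos)
        )
        sites.append(
            PlantedSite(
                contig=contig,
                start=start,
                end=start + L,
                strand=strand,
                mismatches=len(mpos),
                mismatch_positions=mpos,
                protospacer_seq=proto_seq,
                flank5=flank5,
                flank3=flank3,
                pam=pam,
                cleavage_prob=float(prob),
            )
        )

    index = GenomeIndex(
        {name: arr.tobytes().decode() for name, arr in contigs.items()}
    )
    truth = SimTruth(
        sites=sites,
        accessibility=dict(config.accessibility),
        accessibility_window=config.accessibility_window,
        config=config,
    )
    return index, truth


def _site_accessibility(truth: SimTruth, site: PlantedSite) -> float:
    wi = site.start // truth.accessibility_window
    return truth.accessibility.get(f"{site.contig}:{wi}", 1.0)


def simulate_cleavage(
    truth: SimTruth, seed: int | None = None, sample: str | None = None
) -> pd.DataFrame:
    """Detected-site table from one cleavage experiment over the truth.

    Each planted site is cleaved independently with probability
    min(1, cleavage_prob * accessibility); cleaved sites receive
    1 + Poisson(mu * cleavage_prob * accessibility) reads. The result is a
    valid input to the catalog matcher (0-based half-open coordinates).
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sample = sample or cfg.sample
    rows = []
    for site in truth.sites:
        access = _site_accessibility(truth, site)
        p = min(1.0, site.cleavage_prob * access)
        if rng.random() >= p:
            continue
        reads = 1 + int(rng.poisson(cfg.read_mu * site.cleavage_prob * access))
        rows.append(
            {
                "chrom": site.contig,
                "start": site.start,
                "end": site.end,
                "strand": site.strand,
                "read_count": reads,
                "sample": sample,
                "site_sequence": site.protospacer_seq,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "strand",
            "read_count", "sample", "site_sequence",
        ],
    )


@dataclass
class Fixture:
    name: str
    config: SimConfig
    index: GenomeIndex
    truth: SimTruth
    site_table: pd.DataFrame
    expectations: dict
    extra_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


FIXTURE_PROFILES = (
    "ngg_recovery",
    "nnnnryac_recovery",
    "pamless",
    "null_uniform",
    "accessibility_2x",
    "two_variant",
)


def _fixture_config(profile_name: str, seed: int) -> tuple[SimConfig, dict]:
    if profile_name == "ngg_recovery":
        cfg = SimConfig(
            genome_length=1_000_000,
            n_perfect=500,
            n_mismatch=100,
            pam_model={"NGG": 0.9, "NAG": 0.2, "default": 0.01},
            read_mu=50.0,
            seed=seed,
        )
        exp = {
            "seed_base": "G",
            "seed_positions": [2, 3],
            "extension_motif": "GG",
            "extension_positions": [2, 3],
        }
    elif profile_name == "nnnnryac_recovery":
        cfg = SimConfig(
            genome_length=1_000_000,
            n_perfect=2000,
            n_mismatch=0,
            pam_model={"NNNNRYAC": 0.9, "default": 0.01},
            read_mu=50.0,
            seed=seed,
        )
        exp = {
            "motif_positions": [5, 8],
            "collapsed_codes": ["R", "Y", "A", "C"],
        }
    elif profile_name in ("pamless", "null_uniform"):
        cfg = SimConfig(
            genome_length=200_000,
            n_perfect=500,
            n_mismatch=0,
            pam_model={"default": 0.3},
            read_mu=5.0,
            seed=seed,
        )
        exp = {"retained_motifs": [], "seed_significant": False}
    elif profile_name == "accessibility_2x":
        cfg = SimConfig(
            genome_length=1_000_000,
            n_perfect=500,
            n_mismatch=0,
            pam_model={"default": 1.0},
            read_mu=100.0,
            accessibility_window=100_000,
            accessibility={"c1:5": 2.0},
            seed=seed,
        )
        exp = {"boosted_window": "c1:5", "expected_log2_ratio": 1.0}
    elif profile_name == "two_variant":
        cfg = SimConfig(
            genome_length=1_000_000,
            n_perfect=2000,
            n_mismatch=500,
            pam_model={"NGG": 0.9, "NAG": 0.2, "default": 0.01},
            read_mu=150.0,
            seed=seed,
        )
        exp = {"scale_second_variant": 0.5, "expected_relative_activity": 0.5}
    else:
        raise ValueError(
            f"unknown profile {profile_name!r}; choose from {FIXTURE_PROFILES}"
        )
    return cfg, exp


def end_to_end_fixture(profile_name: str, seed: int = 0) -> Fixture:
    """Bundled synthetic inputs plus machine-readable expected outcomes.

    Profiles: ngg_recovery (NGG-preferring nuclease; table should seed on G
    at PAM position 2 or 3 and extend to GG), nnnnryac_recovery (long 8-nt
    PAM dependency at positions 5-8), pamless / null_uniform (PAM-independent
    cleavage; no motif should be retained), accessibility_2x (one window with
    doubled accessibility), two_variant (a second nuclease at half the
    cleavage probability of the first).
    """
    cfg, exp = _fixture_config(profile_name, seed)
    index, truth = simulate_genome(cfg)
    site_table = simulate_cleavage(truth, seed=cfg.seed + 1)
    fixture = Fixture(profile_name, cfg, index, truth, site_table, exp)
    if profile_name == "two_variant":
        scale = exp["scale_second_variant"]
        half = SimTruth(
            sites=[
                PlantedSite(**{**asdict(s), "cleavage_prob": s.cleavage_prob * scale,
                               "mismatch_positions": s.mismatch_positions})
                for s in truth.sites
            ],
            accessibility=truth.accessibility,
            accessibility_window=truth.accessibility_window,
            config=cfg,
        )
        fixture.extra_tables["variant_half"] = simulate_cleavage(
            half, seed=cfg.seed + 2, sample="variant_half"
        )
    return fixture


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    rows = []
    for s in truth.sites:
        d = asdict(s)
        d["mismatch_positions"] = ",".join(map(str, s.mismatch_positions))
        rows.append(d)
    return pd.DataFrame(rows)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, truth TSV, site table(s) and expectations JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "truth": outdir / "truth.tsv",
        "sites": outdir / "sites.tsv",
        "expectations": outdir / "expectations.json",
    }
    write_fasta(fixture.index, paths["fasta"])
    truth_to_frame(fixture.truth).to_csv(paths["truth"], sep="\t", index=False)
    fixture.site_table.to_csv(paths["sites"], sep="\t", index=False)
    paths["expectations"].write_text(json.dumps(fixture.expectations, indent=2))
    for name, table in fixture.extra_tables.items():
        p = outdir / f"sites_{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


def load_config(path: str | Path) -> SimConfig:
    """Read a SimConfig from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    if "mismatch_distance_probs" in data:
        data["mismatch_distance_probs"] = {
            int(k): float(v) for k, v in data["mismatch_distance_probs"].items()
        }
    if "flank_base_probs" in data:
        data["flank_base_probs"] = tuple(data["flank_base_probs"])
    return SimConfig(**data)
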