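# genomepam

Characterizing the protospacer adjacent motif (PAM) of a CRISPR-Cas nuclease
directly in cells is possible without synthetic oligo libraries: a genomic
repeat that occurs thousands of times with nearly random flanking sequence is
itself a complete PAM library. Target the repeat with a single gRNA, recover
the cleaved sites genome-wide (e.g. with GUIDE-seq), and the flanks of the
cleaved subset reveal the PAM. This package implements the computational side
of that strategy for anyone analyzing such experiments or evaluating nuclease
variants: repeat-protospacer discovery, target-site enumeration, PAM
statistics, motif enrichment, and genome-scale activity/specificity and
chromatin-accessibility profiles — plus a seeded simulator so the whole
pipeline is testable without sequencing data.

## What it computes

- **Repeat discovery** (`repeat_finder`): all genomic *k*-mers (default
  *k* = 20) passing a 5′-G filter and a homopolymer exclusion
  (no AAA/TTT/CCC/GGG), scored by the number of distinct flanks and the
  per-position Shannon entropy of the flank composition. A candidate is
  suitable for a PAM of length *L* when its distinct flanks nearly saturate
  the 4^L PAM space.
- **Target catalog** (`target_catalog`): every genomic window on either
  strand within a Hamming-distance budget of the protospacer (exact scan; no
  aligner), with mismatch positions numbered 1..L from the protospacer 5′
  end and the candidate PAM window read from the genome. Detected cleavage
  sites (TSV: `chrom, start, end, strand, read_count`) are resolved against
  this catalog and stratified into perfect-match and mismatch records.
- **PAM cleavage value** (`pam_stats`): for a PAM *p* of length *L*,

      PCV(p) = (share of p among captured PAMs) / (share of p among all
               genomic L-mers),
      relative PCV(p) = log2( PCV(p) / max PCV ),

  so the best PAM maps to 0 and the 16×16 four-base heatmap reads directly
  as log2 fold preference. Captured shares are read-weighted by default.
  Read-weighted position frequency matrices (logo input) are exported
  per stratum.
- **Seed-extension motif table** (`motif_table`): the edited value of a
  motif *m* is `E(m) = det(m) + reads(m)·s`, with
  `s = max det / max reads` inside the current window, so the rescaled read
  term has the same maximum as the site counts. Each motif is tested with a
  two-sided 2×2 Pearson chi-square (edited value vs genomic totals, motif vs
  all other motifs in its window). The most significant single base seeds the
  table; the motif then grows one base at a time (5′ or 3′, whichever is more
  significant) until the window ends, and the report retains the steps whose
  percent of genomic targets edited strictly increases. Near-equivalent bases
  at a position collapse to IUPAC codes (e.g. G/A → R) with a percent range.
- **Profiles** (`profiles`): on/off-target site and read ratios, relative
  activity/specificity against named reference variants, read down-sampling
  (multivariate hypergeometric), and chromatin accessibility as per-window
  (default 5 Mb) read proportions with log2 ratios against reference
  replicates.
- **Simulator** (`simulate`): seeded genomes with planted repeat copies
  (perfect and mismatched, divergence concentrated at protospacer positions
  8–11 and transition-biased), iid flanks, IUPAC PAM-to-probability cleavage
  models, per-window accessibility multipliers, and
  `1 + Poisson(mu·p·accessibility)` read counts — emitted as valid inputs for
  everything above, with a ground-truth registry.

## Worked example

Simulate an NGG-preferring nuclease (cleavage probability 0.9 for NGG, 0.2
for NAG, 0.01 otherwise) on 500 planted repeat copies in a 1-Mb genome, then
run the table:

```python
import genomepam as g

fx = g.end_to_end_fixture("ngg_recovery", seed=0)
records, report = g.match_cleavage_sites(fx.site_table, fx.index, fx.config.repeat)
strata = g.stratify(records)
catalog = g.enumerate_targets(fx.index, fx.config.repeat, 0)
run = g.run_table(strata["perfect"], catalog, window_length=10)
print(g.motif_table.run_to_frame(run).head(3).to_string(index=False))
```

```
 step motif positions  edited_sites  genomic_total  percent_edited   p_adjusted retained
    0     G       3-3            38            107       35.514019 1.229846e-38        Y
    1    GG       2-3            34             36       94.444444 3.517536e-67        Y
    2   AGG       1-3            14             14      100.000000 1.315806e-25        Y
```

Read: of the 107 perfect-match targets whose PAM has G at position 3, 38
(35.5%) were edited; restricting to GG at positions 2–3 raises that to 34 of
36 (94.4%) — the table recovers the planted NGG preference from 41 detected
sites. The PCV table agrees: the top four-base PAMs are all NGGN
(`CGGC` PCV 60.2, relative 0.0; `AGGC` 57.0, relative −0.08), i.e. ~60-fold
enriched over their genomic background share.

The same objects export TSVs for logo plotting and heatmaps
(`pam_stats.pfm_to_tsv`, `pam_stats.pcv_to_tsv`, `pcv_heatmap_table`), and a
`genomepam` CLI wraps the common paths (`genomepam simulate`,
`genomepam analyze`, `genomepam enumerate-targets`, ...; see `--help`).

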