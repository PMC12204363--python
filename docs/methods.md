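# Methods

## The measurement model

A repeat protospacer that occurs *n* times in a genome with (nearly) random
10-nt flanks exposes each nuclease to ~*n* candidate PAMs drawn from the
genomic background. After cleavage detection, the PAM preference is the
contrast between the flanks of cleaved sites and the flanks available
genome-wide. Everything in this package is a view of that contrast:

- the **position frequency matrix** is the descriptive view (read-weighted,
  because read counts track cleavage efficiency at a site);
- the **PAM cleavage value** is the per-PAM enrichment ratio
  `PCV(p) = captured share(p) / genomic share(p)`, log2-transformed and
  max-normalized for display (`relative PCV`, best PAM = 0, uncaptured PAMs
  = −inf, rendered blank);
- the **seed-extension table** is the inferential view, asking which
  contiguous base constraints significantly raise the fraction of genomic
  targets edited.

## Coordinates, matching, and conventions

All internal coordinates are 0-based half-open; 1-based conversion happens
only at I/O (`--one-based` for incoming site tables, BED/bedGraph output is
0-based by construction). Mismatch positions are 1..L from the protospacer
5′ end on the protospacer strand, so position 1 is PAM-distal for a 3′-PAM
nuclease. Windows containing N never match a k-mer; flanks or PAM windows
that would cross a contig edge are discarded (and counted in logs), never
padded. Soft-masked bases are used as ordinary bases by default
(`hard_mask_lowercase` converts them to N); repeat-derived protospacers live
in soft-masked sequence, so hard-masking is not the default. On a
both-strand search, an interval matching on both strands is reported once
(smaller mismatch count, tie to `+`). A detected interval with several tied
protospacer placements takes the minimum-mismatch, smallest-coordinate
placement; ties are logged.

Target enumeration switches between a vectorized sliding Hamming scan
(O(G·L), exact) and neighbor-pattern exact lookups (O(C(L,k)·3^k) searches)
above 50 Mb with small budgets; both are exact and tested equivalent.

## The table statistic

The edited value `E(m) = det(m) + reads(m)·s` with
`s = max_m' det(m') / max_m' reads(m')` taken within the current motif
window. This max-to-max scaling keeps the read term on the scale of the site
counts (its maximum equals the highest detected-site count in the window)
and degenerates to `E = det` when all reads are zero. Each motif is tested
against the window's remaining motifs in a 2×2 table
`[[E(m), E(¬m)], [T(m), T(¬m)]]` (T = perfect-match catalog totals) with a
two-sided 1-df Pearson chi-square, no Yates correction by default (flag
available); fractional edited values are used as-is, and expected counts
below 5 log a warning rather than failing. The 2×2 construction (rather than
a 2×4^w omnibus) is recorded in the run metadata.

The seed is the minimum-p single base over all W×4 candidates; each
extension evaluates up to 8 one-base 5′/3′ candidates. p-values are reported
raw and Bonferroni-adjusted over the candidates evaluated at that step.
Retention requires the adjusted p below alpha (default 0.05) *and* strictly
increasing percent edited — "strictly" chosen so that flat extensions (pure
conditioning on fewer targets) do not accumulate. Ties break by smaller p,
larger percent edited, 5′-most position, then alphabetical motif, making
runs bit-reproducible. Because denominators shrink geometrically as motifs
lengthen, late steps with tiny totals (e.g. 3 of 3 targets edited) can
remain nominally significant; readers should weight retained steps by their
`genomic_total`. The IUPAC collapse is a presentation rule: at a step's new
position, bases with individual p < alpha and percent edited within
`fold_threshold` (default 0.8) of the best base merge into one degenerate
code, reported with the min–max percent range.

Denominators come from the perfect-match catalog; the mismatch stratum can
be run as its own table but is excluded by default.

## PCV details

Captured shares are read-weighted by default (`weighting="sites"`
available); the choice is stored in output metadata since both conventions
appear in practice. The genomic background uses all L-mer windows on both
strands; a catalog-flank background (shares over the perfect-match
catalog's PAM windows) is available when the comparison set should be the
targetable sites rather than the whole genome. PAMs captured but absent
from the background raise an error; background PAMs never captured get
PCV 0 (blank heatmap cell) unless a pseudocount is requested — no signal is
fabricated by default.

## The simulator, and what passing tests mean

`simulate` plants non-overlapping copies of the repeat (protospacer +
both flanks are written into the genome, so truth and sequence are
mutually consistent by construction) on random strands in an iid background
(default GC 0.41, human-like). Mismatch copies are genomic sequence
variants — divergence concentrated at protospacer positions 8–11 with a
0.8 transition bias, matching how repeat families actually diverge — not
sequencing errors. Cleavage is Bernoulli per site with probability
`pam_model(PAM) × accessibility(window) × penalty^mismatches`
(penalty default 0.5 per mismatch); reads are
`1 + Poisson(mu·p·accessibility)`, the simplest model giving every detected
site ≥ 1 read (a negative-binomial alternative was considered and not
needed for these tests). IUPAC PAM models resolve most-specific-first, with
`default` as fallback.

Default study conditions follow the fixture profiles: `ngg_recovery` uses a
1-Mb genome, 500 perfect + 100 mismatch copies, NGG 0.9 / NAG 0.2 / else
0.01, mu = 50 — about 40 detected perfect-match sites, comparable to the
per-PAM statistics of a shallow screen. `null_uniform`/`pamless` use uniform
0.3 cleavage (mu = 5) on 500 copies in 200 kb. `accessibility_2x` saturates
cleavage (probability 1) so the 2× window multiplier acts once, through
reads (mu = 100, ~50k reads against 100-kb windows); with unsaturated
cleavage the multiplier would act twice (detection and reads) and the
expected proportion ratio would not be 2. `two_variant` scales all cleavage
probabilities of the second variant by 0.5 on 2000 copies (mu = 150, ~20k
reads). Problem sizes are chosen so each recovery is decisively powered at
desk scale while the whole suite runs in seconds.

What the simulator does *not* emulate: GUIDE-seq library chemistry (UMI
structure, dsODN junction reads, PCR duplicates), bulged (gapped)
off-target alignment, chromatin-driven correlation between nearby sites, and
repeat-family sequence correlation between flanks. Passing tests therefore
demonstrate that the statistics recover a known planted signal and control
false positives under the stated noise model — not that any particular real
dataset is analyzed correctly end-to-end from raw reads.

Down-sampling acts on identified-site read counts (multivariate
hypergeometric without replacement), approximating raw-read down-sampling
under the assumption that site identification is stable across depths; this
is a documented limitation, not an equivalence claim.

## Numerical and degenerate-input choices

Chi-square p-values are clamped into (0, 1]; an all-zero or zero-margin 2×2
returns (0, 1) by convention and is logged. Empty detection sets yield an
empty table run with a warning rather than an error. Entropy uses log2 with
0·log 0 = 0. Whole-genome k-mer enumeration refuses genomes above a 100-Mb
budget (query-listed-k-mers mode remains available). Accessibility windows
tile every contig from 0 with a possibly partial last window; a site belongs
to the window containing its start (sites are ≤ ~30 bp against ≥ 100-kb
windows). Zero reference proportions give NA log2 ratios unless a
pseudocount is supplied; zero off-target counts flag ratios as infinite
rather than erroring. The suitability threshold for repeat candidates
(distinct flanks ≥ 0.75 × 4^L) is an exposed default, not a measured
constant.
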