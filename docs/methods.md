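# Methods

This note documents the models, conventions and design choices behind
`chromage`, in the spirit of a statistical-software methods appendix. It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Coordinates and gene models

All internal coordinates are 0-based half-open; BED input is consumed
natively and the 1-based-inclusive ibed interaction dialect is converted at
parse time, nowhere else. A gene is a single stranded interval with one TSS
(`start` on '+', `end−1` on '−') and one TES; transcript isoforms are out of
scope. The promoter window around a TSS is strand-aware:
`[tss−up, tss+down)` on '+' and its transcript-coordinate mirror
`[tss−down+1, tss+up+1)` on '−', so both strands cover transcript offsets
−up .. down−1; a zero-width or fully clipped request degenerates to the
single TSS base.

## Annotation rules

- **Polycomb target**: an H3K27me3 peak contains the single TSS base
  (`peak.start ≤ tss < peak.end`). The strictest reading of TSS
  localization; users wanting slack can aggregate over a promoter window
  instead.
- **LAD gene**: ≥ 1 bp overlap between the gene body and any selected LAD
  under half-open semantics (touching intervals do not overlap). LADs may
  carry constitutive/facultative labels; the mode parameter selects all,
  constitutive-only or facultative-only.
- **Promoter CpG / methylation**: sites are points; the per-gene methylation
  value is the unweighted mean of site scores in the window (default
  TSS ± 1 kb, configurable to ± 3 kb). Genes with no site are missing, not
  zero, and are excluded from category means.
- **Differential expression**: up iff log2FC > 2 and adjusted p < 0.1; down
  symmetric; missing adjusted p ⇒ unclassified. These thresholds are the
  analysis defaults throughout.
- **Metagene profiles** resample a binned coverage track into fixed bins
  centred on the TSS, orientation-flipped for '−' genes; bin values are
  coverage-weighted means of covered positions and uncovered bins drop out
  of the category average.

## Chromatin networks

Interaction calls with CHiCAGO score strictly greater than 5 are kept.
Identical fragments merge into one node carrying the union of gene labels;
duplicate contacts collapse; bait = other-end rows are dropped. A node is a
promoter node iff it hosts ≥ 1 gene TSS; gene-to-fragment assignment is
re-derived from coordinates (a fragment hosts gene g iff it contains g's
TSS), with any annotation strings in the file treated as advisory only —
coordinates win. Edge distance is the absolute difference of fragment
midpoints for cis contacts; trans contacts carry a flag and are excluded
from distance binning but kept in the graph. The default promoter
subnetwork is strict (promoter–promoter edges only); an inclusive mode
keeping promoter–other-end contacts is exposed.

Multi-gene fragments are multi-label: a per-category indicator is 1 if any
resident gene belongs to the category (OR lifting for binary features,
arithmetic mean for continuous ones). Nodes none of whose genes carry a
value stay undefined and are excluded edgewise — an edge contributes to
ChAs only if both endpoints are defined. This avoids silent imputation bias.

## ChAs, the distance-matched null, and ΔChAs

ChAs of a node feature is the Pearson correlation over the symmetrized
oriented edge list; it is exactly the classical attribute assortativity for
continuous features and the phi correlation of the indicator for binary
ones. Degenerate inputs (constant feature on the used nodes, fewer than two
usable edges) raise rather than returning a silent NaN; the categorical
wrapper converts per-category degeneracy to a missing value with a warning.

The null model rewires topology with feature values held fixed: each cis
edge is replaced by a same-chromosome node pair from the same genomic
distance bin (log10 width 0.1, distances < 1 kb pooled — PCHi-C distances
are log-spread and the reference implementation's internal binning is not
published), each trans edge by a uniform inter-chromosomal pair; no
self-loops or duplicates; per-bin histograms are preserved exactly. A plain
feature-permutation null is exposed for comparison, but distance matching
is the default because a feature shuffle cannot preserve edge distances.

Mechanically the rewiring enumerates, once per network, every
same-chromosome node pair grouped by distance bin and samples uniformly
within a bin, falling back to per-edge rejection sampling (with binary
search over sorted fragment midpoints) above five million pairs. If a bin
offers no unused alternative within the attempt cap (1000), the original
edge is kept and counted (`n_fallback_edges`), which guarantees termination
and preserves the histogram.

z-scores use the sample (n−1) standard deviation over `n_rand` rewired
networks (default 100). Several features can share one null stream
(`chas_zscore_multi`); ΔChAs always does, so the difference
z(group ∩ feature) − z(group \ feature) benefits from common random
numbers. The usual significance convention is |z| > 2.

## Pol II pausing

PI = mean promoter bin value / mean body bin value, with regions
TSS−30..TSS+300 and TSS+300..TES (TES base inclusive) in transcript
orientation. Density is the unweighted mean of all bins overlapping the
region by ≥ 1 bp — the literal "overlapping bins averaged" rule — with a
length-weighted option. Pipeline order: (1) length filter (< 1 kb, an
annotation-only rule, applied first); (2) PI per gene and cell state,
undefined when the body is empty or has zero density (never infinity);
(3) per-cell Tukey fences, quartiles by linear interpolation between order
statistics, k = 1.5; (4) cross-cell expression floor on the sum of
*surviving* PIs (missing treated as absent, not 0); (5) per-cell min–max to
[0, 1] (a degenerate all-equal surviving set maps to 0.5). The outlier /
sum-filter order and the surviving-PI sum are pinned choices where the
narrative order is ambiguous; the opposite order is available via
`sum_filter_first`. The pipeline accepts any number of cell states ≥ 1 (the
reference analysis uses three). Rank comparisons use the two-sided
Wilcoxon–Mann–Whitney test, exact for small tie-free samples, tie-corrected
normal approximation otherwise.

## Statistics

Age trends default to class-mean level: the 16 class indices against
per-class mean values (n = 16 points), matching how class-wise trends are
usually displayed; a gene-level mode exists. Fisher enrichment uses the
two-sided conditional exact test; the odds ratio is the sample
cross-product ratio, with a flagged 0.5 continuity correction only when a
zero cell would make it 0/0 and a flagged infinity for a clean zero
denominator. Expression-variability groups are rank deciles with ties
broken by gene id (deterministic). The report driver applies
Benjamini–Hochberg within each family of comparisons and reports both raw
and adjusted p; primitives never correct internally.

## Synthetic data: what it emulates and what it does not

The generator plants every signal the pipeline is meant to detect, under
one master seed with per-generator derived streams (adding a generator
never perturbs the others; identical config + seed ⇒ byte-identical files).

Defaults are the study conditions: 16 age classes whose category shares are
38.1 / 44.7 / 17.1 % (UC/EM/MM, the published census proportions spread
uniformly within categories at the default (3, 9) bounds — the exact
16-to-3 boundary is not published, so it is configurable); Polycomb
promoter rates 16 / 34 / 14 %; LAD gene-overlap rates ≈ 7 / 13 / 15 % at
12 % genome coverage; planted pausing means 2.5 / 1.8 / 1.2 declining with
recency, scaled 1.2 / 1.0 / 1.4 across the hESC / B-cell / B-CLL states
(pausing relaxes on differentiation, tightens in the leukemic state); DE
up-rates 14 / 32 / 59 % and down-rates 5 / 3 / 2 %; age–expression trend
target |rho| = 0.95 (expression falling, variability rising with class
index). Genes sit on a jittered grid (no overlaps) with log-normal lengths
(median ≈ 2.2 kb, σ = 1), so ≈ 20 % fall under 1 kb and exercise the length
filter. Networks put one promoter fragment per gene (an option co-hosts two
genes on ~5 % of fragments), draw 5 % trans edges, and mix within-category
and random pairs so the same-category edge fraction is
p_within + (1 − p_within)·q with q the random-pairing rate — which makes
p_within recoverable by moment inversion. Coverage bins are chopped from
region starts so no bin straddles the promoter/body boundary; in the
noiseless limit the measured PI equals the planted ratio exactly. Noise is
truncated-Gaussian per bin — the simplest model with exact noiseless
limits. The expression generator scales class-level jitter as
σ_x·√(1/ρ² − 1) (the inverse of the attenuation of a Pearson correlation by
additive noise), a first-order calibration that is exact for Pearson and
approximate for Spearman at 16 points.

The two cell-state scenarios are matched constructions sharing genome, ages
and chromatin features, differing only in how a fixed within-category edge
budget (half of all edges) is split: "differentiated" 64 / 26 / 6 % and
"oncogenesis" 56 / 5 / 38 % across UC / EM / MM. Within-category edges are
drawn only among feature-positive genes (UC ← Pol II, EM ← Polycomb,
MM ← LAD), so the features genuinely mediate the clustering and ΔChAs has a
planted positive sign; the shares were calibrated once so the construction
realizes the intended qualitative pattern (oldest genes most assortative in
the differentiated state; EM clustering collapses and MM strengthens under
the oncogenesis rewiring) robustly across seeds. Planted pairs are drawn
without a cis constraint, so much of the planted signal sits on trans
edges; the null rewires trans edges as trans, so the signal is preserved —
but the cis/trans ratio of scenario networks is not realistic for PCHi-C.

What passing tests on these data do **not** show: the generator has no
read-level noise, no CHiCAGO statistical model, no chromatin polymer
physics, no correlated epigenetic marks, and clean block-structured
signals. Results on real PCHi-C, ChIP-seq and methylation data depend on
upstream processing (peak calling, coverage normalization, interaction
calling) that is explicitly out of scope here; the tests validate the
statistics and the filter chain, not those upstream steps.

## Problem sizes and numerics

Test and acceptance runs use networks of a few hundred nodes and
500–1500 edges with 30–60 randomizations, and 20–200 repetitions for rate
estimates — sizes chosen so the full validation chain runs in minutes on a
laptop core while keeping Monte-Carlo error well inside the asserted
margins. Exactness claims (oracle agreement, planted-partition ChAs,
noiseless PI) are asserted at 1e-12; null-calibration and recovery checks
are asserted in expectation over fixed seed families. The distance-binned
pair enumeration is cached per network object and shared with its rewired
copies.

## Known limitations

- The distance-matched rewiring is this package's reading of
  "randomization preserving genomic distances"; the reference R
  implementation's exact internal algorithm is not published, and bin-width
  sensitivity is the user's responsibility (`DistanceBinning`).
- Binary features on very small groups give noisy z-scores; `n_rand = 100`
  keeps the sd estimate's relative error near 7 %, and comparisons of
  z-scores across networks of different size or density are deliberately
  not offered.
- CHiCAGO scores act only as a filter; weighted-edge assortativity is out
  of scope.
- The EV decile grouping and the ± 1 kb CpG window are documented choices
  where the source analyses leave the convention open.
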