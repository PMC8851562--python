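# Methods

## Scope and data model

The package analyses one knockout-versus-wild-type chromatin study with an
accompanying agonist contrast: an ATAC-seq peak set with raw counts for two
replicates per condition, gene models, two differential-expression tables
(KO vs WT; agonist vs vehicle), ChIP binding-site sets for a basal and an
agonist condition, peak sequences, a PWM library, and optional per-base
cut-count tracks. All coordinates are 0-based half-open internally (BED
convention); 1-based GTF-like gene tables are converted on read. Library
sizes come from the sample metadata (total mapped reads), never from
in-peak counts, because the RPKM denominator refers to the whole library.

Upstream processing — read alignment, peak calling, DE model fitting — is
out of scope: peak counts and DE tables are inputs. The footprint module is
a deliberate simplification of HMM-based footprinters: it aggregates raw
cut counts and scores a protection ratio; it applies no Tn5 sequence-bias
model and, on synthetic tracks, no +4/−5 offset (the generator emits cut
positions directly; an optional flag applies the standard offset to real
data). Its outputs are comparable in kind (profiles, protection depths) to
such tools, not numerically.

## The ranked-bin landscape

Peaks with fewer than 10 raw counts summed across all four samples are
removed. Two readings of that filter exist (sum over samples vs per
sample); the sum is used because it is the stricter filter and matches the
intent of removing near-empty peaks; the threshold is a config key.
Ranking uses the signed RPKM difference (KO − WT) by default, ascending,
so losses occupy the leading bins; an absolute-difference mode and a
raw-count-mean mode are provided because the quantitation underlying
published rank analyses is often ambiguous between the two. Ties break by
peak id, lexicographically, making every ordering deterministic.

Binning produces `max(floor(n / bin_size), 1)` contiguous bins; the
remainder is spread one peak each over the leading bins, so bin sizes
differ by at most one. At full study scale this arithmetic yields 73 bins
of ~1,000 from 73,597 peaks.

Per bin and motif the enrichment statistic is the one-sided hypergeometric
upper tail against all binned peaks as background. The known-motif tools
used in published work do not document their exact statistic;
the hypergeometric is the transparent choice, is exactly testable by
enumeration, and its permutation null (shuffling bin labels) is the same
distribution by construction — the test suite exploits both. GC-matched
background sampling is out of scope and noted as a limitation. The
displayed landscape is raw −log10 p per bin; Benjamini–Hochberg correction
is applied only in ranked subset-enrichment tables.

Motif filtering: "enriched anywhere" means −log10 p ≥ 3 in at least one
bin; "changing" means a −log10 p range ≥ 1 across bins. Both are config
keys with no canonical published values. Family merging uses best-offset
Pearson correlation of aligned PWM probability columns (≥ 4 overlapping
columns, reverse complement considered), merging same-family motifs above
0.90 by single-linkage transitive closure; the merged row is the per-bin
elementwise best (max −log10 p). Single linkage is the permissive choice;
it is documented rather than claimed to reproduce any specific tool.

## PWM scanning

Scores are log2 odds against a background base composition (uniform by
default, configurable). The hit threshold is a fraction (default 0.80) of
the motif's maximum achievable score — simple, monotone, and free of
per-site p-value machinery. Positions containing N score −∞. Scanning both
strands makes presence reverse-complement invariant, which is asserted as
a property test.

## Footprint scoring

Profiles aggregate per-base cut counts in ±window (default 100 bp) around
occurrence centers, flipped for minus-strand hits, and are normalized by
the total cuts across all aggregated windows (a uniform track therefore
gives the flat profile 1/(2w+1)). Protection depth is
1 − mean(in-motif)/mean(flank), the in-motif span being the central
motif-length positions and the flank the outer 25% of the window per side.
Condition differences are reported with a bootstrap-over-sites CI (200
resamples). Windows must lie inside the chromosome; for parameter-recovery
analyses on synthetic data, occurrences are restricted to those whose
window lies inside the carrying peak, so flanks measure the peak's own
rate rather than its edge.

## Regulatory-mode classification

DE classes use adjusted p < α (default 0.05) and an optional |log2FC| gate
that defaults to zero, i.e. significance alone, matching the stated
criterion of the study design this emulates. Binding is assigned per gene
by nearest TSS of the site midpoint (ties to the lexicographically smaller
gene id); a span-containment rule (gene span extended by the promoter
window) is available because published "putative target" radii are rarely
stated. The four direct segments are the discordant/nonresponsive
knockout × agonist combinations gated on binding; agonist-only binding
(site present only in the agonist set) is tracked separately from basal
evidence. DE genes without binding are "indirect". Genes whose knockout
and agonist responses are concordant in sign fall outside the four
segments and are labelled "none" (their binding flag is retained); the
generator plants no concordant mode, so these arise only through chance
p-values. Mode heatmap export uses per-row unit-variance scaling
((x − mean)/sd).

Proportion comparisons use Fisher's exact test and accessibility-change
comparisons the Mann–Whitney U test; the published figures this style of
analysis appears in mark significance without naming tests, so the
standard nonparametric choices are used.

## Peak annotation

Classification is at the peak midpoint with precedence promoter > TTS >
exon > intron > intergenic, which forces a single class per peak; the
promoter window is −1000/+100 bp around the TSS on the gene strand and the
TTS window ±100 bp, matching common annotator defaults, all configurable.
Midpoint classification (rather than any-overlap) is a documented dialect
choice. Nearest gene is nearest TSS by absolute midpoint distance. The
interval-tree index is verified against a quadratic all-pairs scan at
10^4 × 10^2 scale.

## The synthetic study

The generator defines the conditions every test and the acceptance script
run under. Defaults: 2 chromosomes of 3 Mb, 500 non-overlapping genes of
3–8 kb with 2–8 exons, 6,000 peaks of 300–600 bp, two replicates per
condition, library sizes ~2×10^7.

Counts are negative binomial (gamma–Poisson, Var = μ + φμ², φ = 0.05 by
default) around a lognormal baseline (median 100, log-sd 0.7; promoters
×2, reflecting open promoters). Accessibility effects have two layers:
(i) feature-class structure — 15% of intergenic/intronic peaks get log2
effects in (−3, −1.5) (losses toward closed), 20% of promoter peaks get
(+1, +2.5) (already-open promoters opening further); (ii) binding-coupled
structure — modes and binding sites are simulated first, one peak is
seeded at each binding site, site-overlapping peaks drift mildly toward
loss (uniform(−0.8, +0.15)), sites of knockout-down genes lose strongly
(additional uniform(−2, −0.8)) and sites of knockout-up genes gain
(uniform(+0.2, +1)). Simulating binding before peaks puts the causal
arrow the right way round — binding loss drives accessibility loss — and
gives the cross-tabulations their expected signs (down-gene binding sites
least accessible; a majority of binding-site peaks losing accessibility).

Motif planting: each peak gets an i.i.d. background sequence (uniform base
composition by default; GC-skew configurable); each configured motif is
planted with probability given by a logistic function of the peak's
true-effect rank fraction, with instances sampled column-wise from the PWM
on a random strand. The default panel is synthetic: two deliberately
near-duplicate DR4 nuclear-receptor motifs (16 bp with a fuzzy 4-nt
spacer), a DR1, a CCAAT-box (NF-Y), a CTCF-like motif, forkhead, C/EBP and
ETS; consensus probability 0.92–0.95 per column so that sampled instances
are usually recoverable at the 0.8-of-max scan threshold while still
carrying realistic degeneracy. Loss-associated motifs (NR, CTCF, FOX) ramp
from ~0.3–0.4 at the loss end to ~0.02 at the gain end; the CCAAT motif
runs the other way; ETS and C/EBP are flat controls.

DE tables are drawn directly from the planted mode (log2FC ~ ±N(1.6,
0.3²) with log-uniform adjusted p in 10^(−6..−2) for responsive
contrasts; ~N(0, 0.15²) with uniform p otherwise): DE model fitting is out
of scope, so p-values are planted, not fitted. Mode proportions default to
6% ligand-activated, 3% ligand-repressed, 10/5% basal-required/-repressed
nonresponsive, 4% agonist-only, 6% indirect. Bound genes get 1–3 sites of
200 bp, the first anchored at the TSS; the basal set keeps the anchor site
for every direct-mode gene (guaranteeing basal evidence) plus 40% of the
rest, so agonist-only binding exists and basal ⊆ agonist.

Cut tracks are Poisson with a genome-wide rate field: each peak adds a
flat rate proportional to its condition mean over its width, then each
occupied footprint-motif span multiplies the field by 1 − depth (defaults
0.5 in WT, 0.1 in KO). Building the field before applying dips means
overlapping peaks cannot wash protection out.

Everything is deterministic under the config seed (independent
sub-streams per stage via seed sequences), every emitted file is readable
by the package's own readers, and every planted entity is recorded in a
JSON truth manifest keyed by the ids in the emitted files.

**What the generator does not emulate:** Tn5 sequence bias and fragment-
length structure, GC-dependent coverage, peak-width/signal correlation,
cell-type mixtures (a whole-tissue study aggregates several cell types),
correlated motif co-occurrence beyond what rank-coupling induces, and
realistic p-value/effect joint distributions from a fitted count model.
Passing tests therefore demonstrate that the statistics recover planted
structure of the assumed form at realistic noise, not that the pipeline is
robust to every artifact of real libraries.

## Problem sizes and numerics

The default desk-scale study (6,000 peaks / 500 genes, ~20 bins of 300)
was chosen so the full chain — simulation, scanning, landscape,
footprints, integration — completes in well under a minute, and the test
suite in well under half an hour, while leaving every statistic enough
events to be sharp (binomial/bootstrap errors of a few percent).
Acceptance analyses use 5,000–10,000-unit nulls, 20 localization seeds,
5–10 footprint seeds with ≥200 sites each, and a 500-gene mode-recovery
simulation. p-values are clipped at 10^−300 before taking logs; the
depth bootstrap discards resamples with empty flanks; empty DE classes
and empty mode segments are reported with tests suppressed rather than
raised.
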