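# atacmodes

Integrative analysis of chromatin accessibility (ATAC-seq), transcription-
factor binding (ChIP-seq) and gene expression (RNA-seq) around a nuclear
receptor studied by knockout and by pharmacological agonist. The package
implements the full analysis chain — ranked-bin motif-accessibility
landscapes, genomic-feature annotation of differential peaks,
binding/expression/accessibility cross-tabulation, cut-site footprinting,
and classification of direct target genes into regulatory modes — together
with a synthetic-data generator that reproduces the statistical structure
of such a study at desk scale, so every stage runs and is testable in
seconds.

It is written for computational biologists who want a transparent,
reproducible re-implementation of this style of regulatory-genomics
analysis: every statistic is a plain, documented formula rather than a
call into an opaque motif-analysis suite.

## The analysis

**Ranked-bin enrichment landscape.** Peaks are RPKM-normalized
(`counts / (width_kb x library_size / 10^6)`), peaks with fewer than 10 raw
counts summed over all four samples are removed, replicates are averaged
per condition, and peaks are ranked by the difference in mean accessibility
(KO − WT, largest losses first). The ranked list is cut into equal-sized
contiguous bins (sizes differ by at most one; `floor(n / bin_size)` bins).
For each motif *m* and bin *b*, with *N* binned peaks of which *K* carry
the motif and *n* in the bin of which *k* carry it, the enrichment is the
one-sided hypergeometric upper tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp; X ~ Hypergeom(N, K, n),

and the landscape is the motifs × bins matrix of −log10 p. Motifs that are
never enriched (−log10 p < 3 everywhere) or flat across bins (range < 1)
are dropped; same-family PWMs with best-offset Pearson similarity > 0.90
(reverse complement considered) are merged by single linkage, taking the
per-bin best p.

**Motif presence** is log-odds PWM scanning: score(i) = Σ_j log2(p_bj /
q_b) over both strands, a hit being any position reaching 80% of the
motif's maximum score.

**Footprinting.** Per-base cut counts are aggregated in ±100 bp windows
around motif occurrences, strand-oriented, normalized to the total cuts in
the aggregated windows. Protection depth is 1 − (mean in-motif rate / mean
flank rate) with the flank the outer 25% of the window per side; conditions
are compared by the signed depth difference with a bootstrap-over-sites CI.

**Regulatory modes.** Genes are classified per contrast (down / up /
unchanged at adjusted p < 0.05), and the joint knockout × agonist response,
gated on ChIP binding evidence, assigns each gene a mode:
ligand-activated (down in KO, up with agonist, bound), ligand-repressed
(up in KO, down with agonist, bound), basal-required- and
basal-repressed-nonresponsive (KO-responsive, agonist-unchanged, bound),
agonist-only, and indirect (differentially expressed without binding).

## Worked example

The numbered drivers under `analysis/` run the whole chain on the built-in
synthetic study (6,000 peaks, 500 genes, 2+2 samples, seed 0) and write
small tables under `results/`:

```
cd analysis
python 01_simulate.py
python 02_rank_and_annotate.py
python 03_motif_landscape.py
python 04_footprints.py
python 05_integrate_modes.py
```

`02_rank_and_annotate.py` prints

```
6000 peaks kept; 20 bins of ~300
all:      promoter 0.16, intergenic+intron 0.71, within 1 kb of TSS 0.26
top_loss: promoter 0.23, intergenic+intron 0.68, within 1 kb of TSS 0.33
top_gain: promoter 0.34, intergenic+intron 0.55, within 1 kb of TSS 0.43
```

— the top-gain peaks are promoter- and TSS-enriched relative to the top
losses, which stay dominated by intergenic/intronic peaks, exactly the
structure the generator plants. `04_footprints.py` prints

```
protection depth WT 0.467 (95% CI 0.437..0.495), KO 0.088 (95% CI 0.054..0.119); difference +0.379
```

recovering the planted protection depths (0.5 in WT, 0.1 in KO) from the
simulated cut tracks. `05_integrate_modes.py` cross-tabulates binding with
expression — 84% of knockout-down genes are bound versus 7% of unchanged
genes, 72.7% of binding-site peaks lose accessibility — and recovers every
planted ligand-activated and ligand-repressed gene in its segment.

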