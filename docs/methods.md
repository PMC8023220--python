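# Methods

This note documents the statistical models, conventions, and parameter
choices behind `trilayer`, and what the synthetic-data suite does and
does not establish about real data.

## Design and data model

The analysis assumes a triad design: two inbred parents (P1, P2) and
their F1 hybrid, each measured by three assays — mRNA input RNA-seq,
m6A immunoprecipitation, and polysome profiling — with at least two
biological replicates per genotype and assay. All genomic coordinates
are internally 0-based half-open (BED convention); GFF3 input is
converted at the boundary, so that window arithmetic has a single
convention. One representative transcript per gene (the longest mRNA)
anchors all geometry; count tables are gene-level and the exon-union
length is used for FPKM.

## Quantification

**FPKM.** `fpkm = count x 1e9 / (library_size x mature_length)`, with
per-sample library sizes computed over the genes in the matrix. A gene is
*expressed* in a (genotype, assay) group when its mean replicate FPKM is
at least `fpkm_min` (default 1.0). The mean-of-replicates rule (rather
than per-replicate) is a package convention.

**Translational efficiency.** `TE = mean polysome FPKM / mean input
FPKM` per genotype, defined only where the gene is expressed in the
input assay. TE is invariant under common library rescaling of both
assays.

**Consensus m6A peaks.** Only peaks reproduced in both biological
replicates are kept: candidate pairs with >= 1 bp overlap are matched
greedily by decreasing overlap, each peak used at most once. The
consensus interval is the union of the pair (preserving evidence from
both replicates), the summit comes from the replicate with larger fold
enrichment, and the peak-level m6A level is the mean of the two fold
enrichments. The per-gene m6A level is the maximum over the gene's
consensus peaks — the strongest site defines the gene; the mean is a
reasonable alternative that tracks multi-peak genes differently.

**Segment assignment.** The peak summit is mapped to spliced-transcript
coordinates and classified with priority: a `window_nt` (default 200 nt,
boundaries inclusive) window centered on the start codon; the same
window on the stop codon; then 5'UTR, CDS, 3'UTR by position; summits in
introns are `intron`; summits outside any gene are `intergenic` and
excluded from segment fractions. Codon windows dominate UTR/CDS because
the six segments overlap by construction.

## Differential testing

One decision contract serves all layers: a gene is called differential
when its adjusted p-value is below `alpha` (default 0.01; BH-FDR by
default, raw p optionally) **and** its absolute fold change is at least
`fc_threshold` (default 1.5). A 0.5 pseudocount is applied to all
normalized-count log ratios.

**NB Wald engine.** Counts are normalized by median-of-ratios size
factors (geometric-mean reference over genes nonzero in every sample;
total-count fallback when no such gene exists). Gene-wise NB dispersions
are estimated by pooled within-group method of moments and shrunk 50/50
toward a trend `a0 + a1/mean` fitted across genes. The Wald statistic
for `log2((mean_a + 0.5)/(mean_b + 0.5))` uses the delta-method variance
`(1/mu + phi)/n` per group, referred to a t distribution with
`(n_a + n_b - 2) + 12` degrees of freedom. The 12 prior df credit the
genome-wide trend the gene-wise dispersions are shrunk toward
(quasi-likelihood-style moderation); in null simulations (2000 genes,
n = 3/side, dispersion 0.1) this choice keeps the rejection rate at
alpha = 0.05 between 0.044 and 0.057 across trials, while an
unmoderated normal reference is anticonservative (0.065-0.081) and
t with n_a+n_b-2 df is severely conservative.

**Mid-parent contrasts.** The mid-parent value (MPV) is realized as
pseudo-samples: P1 and P2 replicates are normalized jointly with F1,
paired in replicate order (discarding unpaired replicates with a logged
warning), and averaged; the pseudo-counts are rounded to integers and
tested against the F1 replicates with the same NB engine under unit size
factors. This lets one test engine serve the parent-parent,
hybrid-parent, and hybrid-MPV contrasts identically.

**TE contrasts.** Per replicate, `log2 TE = log2((poly_norm + 0.5) /
(input_norm + 0.5))` with replicates paired across assays by replicate
number. Groups are compared by a Welch test with empirical-Bayes
variance moderation: gene-wise variances are shrunk toward the group
mean variance with 12 prior df (as in limma) and floored at the 10th
percentile of the moderated variance distribution; the
Welch-Satterthwaite df uses the moderated per-group df. TE-MPV
contrasts reuse the mid-parent pseudo-replicates in both assays.

**m6A contrasts.** After the replicate-consensus step no replicate
variance remains, so the m6A layer uses a threshold rule: a gene is
differential between two genotypes when it is modified in exactly one of
them, or modified in both with a level ratio >= `fc_threshold` in either
direction; no p-value is reported. The m6A mid-parent level is the mean
of the parental levels with an unmodified parent contributing 0. For
heterosis classification the hybrid's m6A-modified gene set is the
universe, and absence of a level counts as evidence (level 0), not
missingness.

## Heterosis classification

A gene with a complete set of contrasts is *additive* when F1 vs MPV is
not significant. Otherwise, with HPv/LPv the higher/lower parental value
(decided per gene): **AHP** if F1 is significantly above HPv; **BLP** if
significantly below LPv; **HP** if above MPV and not significantly
different from HPv; **LP** if below MPV and not significantly different
from LPv; the residual genes (significant against MPV and both parents
yet between the parents) are binned to the nearer parent on the log
scale, since the scheme has no fifth bin. AHP+HP form the up-regulated
direction, LP+BLP the down-regulated one. Percentages are reported with
`percent_round` (half away from zero, one decimal), matching the
reporting convention of published count tables.

An intrinsic power asymmetry is worth knowing: an HP gene's F1-to-MPV
ratio is bounded by 2 x f/(f+1) < 2 (f the parental fold), so under
realistic dispersions HP genes sit much closer to the detection boundary
than LP genes (whose ratio grows without bound as parents diverge).
Label-recovery figures on synthetic data therefore report overall
accuracy over all genes; the HP class recall is systematically the
weakest.

## Allele-specific regulation

Allelic balance in the hybrid is tested per gene by an exact two-sided
binomial test of the P1-origin read count against 0.5, with two-sided
p = twice the smaller tail (capped at 1; equal to the symmetric exact
test at p0 = 0.5, e.g. 30 vs 0 reads gives 2 x 0.5^30). Genes with fewer
than 10 informative reads are not tested.

For cis/trans classification, parental divergence *A* is tested by a
binomial test of the raw parental SNP-covered counts against the
library-size expectation (equivalent to testing library-normalized
counts against 1:1), F1 allelic divergence *B* by the allelic balance
test, and *A* vs *B* by a Fisher exact test on the 2x2 table of
(normalized, rounded) parental counts against F1 allele counts — all at
unadjusted p < alpha, matching the per-gene cutoff convention of allelic
analyses. The category table: cis only (A, B significant, A=B);
trans only (A significant, B not, A!=B); cis-and-trans (all three
significant — *enhancing* when the cis effect (B) and trans effect
(A - B) share a sign, *compensating* otherwise); fully compensatory
(A not significant, B and A!=B significant), folded into cis-and-trans;
conserved otherwise. Boolean combinations outside the table are counted
as conserved, never dropped.

## Integration

The union of non-additive genes across the three layers is described by
ECDF percentiles (`pct(g) = #(values <= value(g)) / N`, upper tie value,
missing layer values entering at 0 so unmodified genes populate the low
end rather than disappearing) and clustered by Euclidean k-means with
k-means++ initialization, 100 restarts, fixed seed; cluster ids are
renumbered by decreasing size because raw k-means numbering is
arbitrary. Per-cluster gene-set enrichment uses the hypergeometric upper
tail with a min-p permutation family correction: the corrected p is the
fraction of random same-size draws from the universe whose minimum raw p
over all sets reaches the observed one; significance at corrected
p < 0.001. The universe is the expressed gene set; annotations are
supplied by the user as a two-column mapping.

## Synthetic data

The generator emulates the study design: three genotypes x three assays
x two replicates by default; NB counts (gamma-Poisson) with per-gene
dispersion drawn uniformly from 0.01-0.1 — the realistic range for
isogenic material grown in a controlled chamber — and log-normal
baseline expression (median ~245 counts). Default planted fractions
follow the published layer structure: ~5.7% / 44.3% / 10.2% non-additive
genes at the mRNA / m6A / TE layers with the reported up:down splits, a
peak-segment distribution dominated by the 3'UTR (69.9%) and stop-codon
window (21.1%), and cis/trans architecture fractions near the reported
mRNA-layer table. HP/LP genes receive a strong parental fold (8x)
because those patterns are undefined without parental separation; AHP
multiplies the higher-parent value by 3 by default. True peaks are
jittered +/-20 bp between replicates (guaranteeing consensus overlap);
false peaks are planted in one replicate only to exercise the consensus
filter. Allele counts are binomial conditional on a Poisson total, the
standard allele-specific expression model.

What the synthetic suite does **not** emulate: mapping bias and reference
bias in allele assignment, peak-caller boundary noise beyond uniform
jitter, correlated library composition effects, isoform switching, and
any sequence content. Passing recovery tests therefore demonstrates
correctness of the statistical machinery under the generative model, not
robustness to alignment artifacts.

## Numerical choices and degenerate inputs

Dispersions are clipped to [1e-8, 10]; genes all-zero in both groups are
excluded from testing and reported NA; a sample with zero total counts
is a hard error; identical values in an ECDF layer yield all-1
percentiles with a warning; `percent_round` refuses a zero denominator;
window boundaries are inclusive, with the start-codon window taking
priority over the stop-codon window if both cover a summit (only
possible for CDS shorter than the window). Equal-enrichment replicate
peaks take the summit of the first argument; consensus is otherwise
symmetric in the two replicates.

## Problem sizes

The bundled test suite and the acceptance script run at desk scale:
2000-gene simulations for calibration and recovery, a 5000-gene fixture
for the end-to-end run (about half a minute on one CPU). These sizes
give Monte-Carlo error comfortably inside the asserted tolerances while
keeping a full run fast.
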