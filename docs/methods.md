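# Methods

This note documents the models, estimators, numeric choices and known
limitations of `ripscreen`. It is written for users deciding whether the
defaults fit their data, and for maintainers wondering why a choice was
made where several were defensible.

## Abundance measures

RPM(g, s) = count(g, s) / total(s) x 10^6 with total(s) the column sum of
the count table. A count table cannot recover reads that an upstream
counter assigned to no gene, so "all mapped reads" is realized as the sum
of per-gene counts; pipelines whose deposited totals include unassigned
reads will differ by a per-sample constant factor. RPKM divides RPM by the
transcript length in kb, the length being the **longest isoform**: from a
GTF, each transcript's length is its exon-length sum on 1-based inclusive
coordinates (end − start + 1), exons taken as given without overlap
merging (isoform length is transcript length, not genomic union), and the
gene length is the per-gene maximum. Each matrix is normalized on its own
totals; matrices from different experiments are never pooled.

A sample with zero total counts is an error, not a zero-fill: an empty
library is an upstream failure the pipeline should not paper over.

## RIP-seq enrichment and bound calling

Enrichment of a transcript is FC = (RPM_IP + 1)/(RPM_mock + 1). The +1
pseudocount keeps FC finite and equal to 1 when both libraries are empty
for the gene. Bound transcripts satisfy FC >= 4 and IP-sample RPKM >= 1,
both inclusive; the mock RPKM is never used. When IP or mock has replicate
columns they are averaged *before* the ratio (the formula is defined on
single values). Cross-condition binding summaries compare per-transcript
IP RPM between condition pairs (fraction higher / tied) plus bound-set
sizes per condition.

A consequence of RPM being compositional deserves emphasis: if the bound
set carries a fraction *s* of the library's read mass, its average IP/mock
RPM ratio cannot exceed 1/s regardless of the true biochemical enrichment.
The FC >= 4 rule therefore presupposes that bound transcripts are a
minority of library mass. The synthetic generator respects this: its
defaults plant 5% of genes as bound with a 16-fold input enrichment,
yielding a realized RPM-scale fold of ~9 — comfortably above the
threshold, while a 30%-mass bound set would be mathematically uncallable
at FC >= 4 (its ratio would cap at ~3.3).

## Differential expression

The two-group stage is a self-contained NB(mu, alpha) analysis
(variance = mu + alpha mu^2):

- **Size factors**: median-of-ratios against per-gene geometric means,
  restricted to genes positive in all samples, rescaled to geometric mean
  1; with no all-positive gene it falls back to total-count ratios with a
  logged warning.
- **Dispersions**: gene-wise method of moments on normalized counts pooled
  across groups, alpha_hat = (s^2 − m)/(m^2 − s^2/n), floored at 1e-8. The
  denominator m^2 − s^2/n is the unbiased estimate of mu^2 (the naive m^2
  overstates mu^2 by Var(m) and systematically underestimates dispersion at
  small n). A trend alpha(mu) = a0 + a1/mu is fitted by non-negative least
  squares with one outlier-trimming pass; the final value shrinks the raw
  estimate toward the trend on the log scale with weight 0.5 (configurable).
  All-zero genes take the trend value.
- **Wald test**: per-group means are NB maximum likelihood with
  size-factor offsets (Fisher scoring on log q, ~50 iterations, step
  clipped to ±3). log2FC = log2((q_t + 0.5)/(q_r + 0.5)); the 0.5
  pseudocount on normalized means bounds the statistic for zero groups.
  SE comes from the NB expected information evaluated at the pseudocounted
  means (finite even when a group is all-zero), inflated by
  sqrt(n/(n − 2)) to account for the two fitted mean parameters the
  plug-in information ignores. p is two-sided normal; q is
  Benjamini–Hochberg over tested genes; genes with zero counts everywhere
  are excluded from testing and from the BH denominator.

Under the package's own null simulation (5 vs 5, 5000 genes, dispersion
0.1) the raw-p rejection rate at 0.05 is ~0.040–0.045 across seeds —
slightly conservative, which is the right side to err on with moment-based
dispersions. Without the two corrections above the test was measurably
anticonservative (~0.066–0.074).

The differential filter is strict: fold change > 2 and q < 0.05. A
`use_raw_p` switch substitutes the raw p value for analyses that were
originally filtered on unadjusted p. The stage does not claim bit-for-bit
equivalence with any packaged NB tool (no shrunken log-fold-changes,
outlier replacement or independent filtering); a cross-check test verifies
that its fold-change estimates track an independent NB implementation
(r > 0.95 on a planted-effect fixture). Precomputed differential tables —
e.g. from a microarray analysis — are ingested via `load_external_de`
(gene_id, fold_change, p and/or q; missing q is BH-computed from p).

With only 2 replicates per group (the design the pipeline targets),
dispersion information is pooled across groups; this stabilizes estimates
at the cost of assuming roughly equal within-group dispersion.

## Classification, SEF and rescue

Expressed genes have mean RPKM strictly > 1 across the named samples
(replicate handling configurable to all/any). Class I = up ∩ bound,
class II = down ∩ bound; the unbound complements are retained so the
partition is auditable. Binding enrichment uses Pearson's chi-square
without continuity correction, df = 1, on (group vs rest) x (bound vs
unbound); the universe defaults to the gonad-expressed genes plus the
differential sets. Degenerate margins return statistic 0 / p 1, and any
expected cell < 1 flags the result `low_count` (still computed).

SEF = (RPKM_whole + 2)/(RPKM_gonad + 2), replicates averaged first, the
gene universe being the intersection of the two inputs. SEF is strictly
increasing in the whole-animal RPKM, strictly decreasing in the gonad
RPKM, and bounded by (RPKM_whole + 2)/2. Group comparisons run on log SEF
(a ratio statistic; logs symmetrize it): one-way ANOVA plus Dunnett
comparisons of each group against the reference (default `total`), using
the equicorrelated multivariate-t implementation in scipy. The paper-style
usage compares overlapping groups (class I is a subset of the total);
p-values are then conservative, which is acceptable for the qualitative
direction being tested.

Rescue: a class-I gene is *rescued* when (rescue_mean + 2)/(wt_mean + 2)
< 2 — i.e. rescue expression within 2-fold of wild type, with the SEF
pseudocount damping low-expression ratios. No numeric rule is standard for
heat-map-style rescue claims; this one is symmetric with the other
thresholds and exposed in `AnalysisConfig.rescue_fc_max`. Heat-map rows
are ordered by mutant/wild-type ratio, descending.

Somatic direct targets: candidates = soma-upregulated ∩ bound;
somatic_targets = candidates minus the gonad-upregulated set (the
*significant* up set, not any nominal increase).

## Oil Red O quantification

Images are rescaled to [0, 1] (8/16-bit integer inputs divided by the
dtype maximum). Stain excess per pixel is max(red − blue, 0), zero outside
the worm; blue surplus carries no lipid signal. The lipid index is the
excess summed over stained pixels (excess > threshold, default 0.05)
divided by worm area, making it invariant to background and linear in
stain intensity below saturation. Group reports divide by the control
group's mean index. Segmentation, when no mask is supplied, is Otsu
thresholding of inverted luminance (worms are darker than background),
largest connected component, holes filled; objects under 100 px are
rejected with a pointer to supply an explicit mask. Segmentation accuracy
on a synthetic ellipse is within 5% of the analytic area — boundary-pixel
ambiguity on a ~100-px-wide object makes tighter guarantees unrealistic,
which is why accuracy-critical analyses should pass explicit masks (the
generator provides them).

## Synthetic data

The generator plants a complete study design from one seed: baseline gene
expression is log-normal (sigma = 1) over 5000 genes; counts are NB with
dispersion 0.05 at 5 x 10^6 reads per sample (about 1000 reads per gene on
average); 5% of genes are bound (16-fold IP enrichment, see the
compositional argument above); 3% are class I — soma genes, attenuated
10-fold in the wild-type gonad, 8-fold up in the mutant gonad, 8-fold up
in the soma profile; 0.5% are class II (8-fold down in the mutant); the
whole-animal sample is a 50/50 mixture of the gonad and soma profiles,
reflecting that real whole-animal data contain the gonad; the rescue
strain restores a seeded 80% subset of class-I genes to wild-type means,
the rest staying at mutant levels; gonad conditions have 2 replicates,
mirroring the hard minimal design. Transcript lengths are uniform
300–15000 nt. Fold parameters of exactly 1 are allowed so a no-effect null
run is expressible.

Worm images are a dark ellipse on a light background with circular stain
blobs of uniform red excess; the analytic lipid index is the clean excess
raster summed over the worm divided by its area (exact under blob
overlap). Cohorts draw per-worm amplitudes log-normally (CV 0.15) around a
group mean, capped at 0.45 to stay clear of channel saturation; channel
noise is N(0, 0.005), far below the 0.05 stain threshold.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: GC/length biases, batch effects, isoform
switching, variable library quality, mock-IP background structure
correlated with abundance, multi-worm images, uneven illumination, and
staining artifacts. Recovery metrics on this generator are a correctness
check of the statistical machinery under its stated assumptions, not a
benchmark of robustness.

`evaluate_recovery` scores called sets by sensitivity/precision/F1
(undefined values reported as NaN, not 0), the SEF separation as the
Mann–Whitney AUC of class-I vs background SEF ranks, and the rescue
fraction by absolute error against the planted efficiency.

## Numerical and interface choices

- Closed metadata vocabularies (tissue, genotype) fail fast at load;
  variant genotypes use the `variant-<label>` form.
- All result tables are written as deterministic TSV (sorted rows, 6
  significant digits); runs under a fixed seed and config are
  byte-reproducible, and `run-all` writes a manifest with SHA-256 hashes
  of all inputs and outputs.
- Thresholds live in one `AnalysisConfig` (defaults: FC >= 4, RPKM >= 1,
  expressed RPKM > 1, DE FC > 2 with q < 0.05, pseudocounts +1 and +2,
  rescue within 2-fold, stain threshold 0.05); every report echoes the
  values actually used.
- Problem sizes in the test suite (500–5000 genes, 2–5 replicates, 30
  worms per group) are chosen to make each statistical property measurable
  with stable margins while keeping the default suite fast on one CPU.

## Known limitations

- The NB stage is a documented approximation; analyses requiring exact
  replication of a specific packaged tool should pass that tool's output
  through the `--de-table` bypass.
- Chi-square backgrounds depend on the chosen universe (gonad-expressed by
  default); published contingency p-values are not reproducible without
  knowing the original universe.
- The SEF universe is whatever both RPKM inputs cover; no attempt is made
  to reproduce a particular published transcript count.
- Single-sample IP/mock designs carry no replicate error estimate; the
  FC threshold is the only noise control, as in the original protocol.
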