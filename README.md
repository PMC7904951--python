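# ripscreen

`ripscreen` is a tested re-implementation of the computational analysis used
to characterize a secreted *C. elegans* endoribonuclease (ENDU-2) that binds
mRNAs and silences soma-specific genes in the germline. It is aimed at
transcriptomics analysts who start from gene-level count tables and need
four things done reproducibly:

1. **RIP-seq target calling.** Transcripts co-immunoprecipitated with the
   protein are called from an IP / mock-IP pair via the pseudo-counted
   enrichment ratio

   FC = (RPM_IP + 1) / (RPM_mock + 1),

   where RPM = (reads mapped to gene) / (all mapped reads) x 10^6 and
   RPKM = RPM x 10^3 / L, with L the longest-isoform transcript length in
   nucleotides. A transcript is *bound* when FC >= 4 **and** RPKM_IP >= 1
   (both inclusive).

2. **Germline target classification.** A two-group negative-binomial Wald
   test (or an externally supplied differential table) compares mutant vs
   wild-type gonad counts; genes with fold change > 2 and BH-adjusted
   q < 0.05 split into up/down sets, which intersect with the bound set
   into **class I** (bound & up: genes the enzyme normally represses) and
   **class II** (bound & down: genes it sustains). Binding enrichment of
   each set is tested with Pearson's chi-square on the 2x2 table.

3. **Soma-enrichment scoring.** Per gene, the soma enrichment factor

   SEF = (RPKM_whole-animal + 2) / (RPKM_gonad + 2)

   quantifies soma-vs-germline expression bias (the +2 damps ratios driven
   by tiny RPKMs); group SEF distributions are compared by one-way ANOVA
   with Dunnett contrasts on the log scale. Rescue-strain expression is
   scored per class-I gene as restored when it sits within 2-fold of wild
   type (same pseudocount).

4. **Oil Red O quantification.** Per worm image, lipid staining is the
   red-channel excess over blue (clipped at zero) summed over stained
   pixels and normalized by worm area, reported relative to a control
   group.

A seeded synthetic-data generator (`ripscreen.synthetic_data`) emulates the
whole study design — IP/mock pair, 2+2 gonad replicates, rescue strain,
whole-animal sample, stained-worm images — with planted ground truth, so
every stage is verifiable end to end without any data download.

## Worked example

```
ripscreen --seed 1 --outdir sim simulate
ripscreen --outdir run run-all --bundle-dir sim
```

or equivalently in Python:

```python
import ripscreen as rs

bundle = rs.simulate_bundle(rs.SimulationConfig(seed=1))
result = rs.run_bundle(bundle)
print(result.report())
```

which prints (abridged):

```
n_bound: 250            # transcripts passing FC>=4 & RPKM>=1 (250 planted)
n_up: 149  n_down: 27   # mutant-gonad differential call (FC>2, q<0.05)
n_class_i: 145          # bound & up   -> "145 of 149" upregulated genes bound
n_class_ii: 25          # bound & down
up_enrichment_chi2: 2770.7   (p ~ 0)   # binding enrichment of the up set
sef_median_total: 0.92  sef_median_class_i: 15.4
fraction_rescued: 0.80  # class-I genes back within 2-fold of wild type
```

Reading it: of 5000 genes the bound-transcript call recovers the planted
250; 145 of the 149 upregulated genes are bound (class I), a massive
binding enrichment relative to the ~5% background rate; class-I targets
have a median SEF ~17-fold above the transcriptome median, i.e. they are
soma-biased genes misexpressed in the mutant germline; and 80% of them are
restored by the rescue transgene, matching the planted rescue efficiency.
`result.recovery` additionally scores the calls against the planted truth
(here: bound F1 = 1.00, class-I sensitivity 0.967, precision 1.00, SEF
rank-AUC > 0.999).

Real data enter the same way: lay out count TSVs, a sample-metadata TSV and
an annotation (TSV or GTF) as written by `simulate`, or drive the stages
individually (`normalize`, `rip-call`, `de` with an optional `--de-table`
bypass, `classify`, `sef`, `oro`).

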