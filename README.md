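# tripkit

Analysis pipeline for **tethered TRIP** (Thousands of Reporters Integrated
in Parallel) experiments: barcoded reporter assays in which ~1000 identical
reporters are integrated at random genomic positions and a chromatin
protein (here *Drosophila* HP1a, fused to the Gal4 DNA-binding domain) is
recruited to each reporter's promoter. Sequencing barcode counts before and
after recruitment turns the cell pool into a parallel measurement of how
the local chromatin context modulates the protein's regulatory effect.

The package covers the full computational path from raw count tables to
context statistics, plus a calibrated synthetic-data generator so that
every stage is testable end to end without external data:

* **barcodes** — Hamming-distance collapsing of sequencing-mutant barcodes
  (abundance-ordered greedy with the directional `2n − 1` rule) and
  spike-in/reporter splitting;
* **mapping** — integration-site calling from inverse-PCR read pairs:
  single-linkage clustering (500 nt forward / 20 nt reverse windows) and
  the acceptance filters (>2 reads per mate, ≥80 % top cluster, <10 %
  second cluster, mapq ≥ 10, mate concordance);
* **expression** — spike-anchored normalization
  `norm_expr = (cDNA / spike_sum) / gDNA_cpm`, the ≥100-read gDNA cutoff,
  and replicate averaging with the zero-dropout rule;
* **context** — per-reporter fold changes `fc = tethered / control`,
  chromatin-state overlay (nine-state BED segmentation), state-vs-rest
  Wilcoxon rank-sum tests, expression-matched control selection,
  occupancy-track correlations, and the day-16 memory summary;
* **simulate** — a seeded generative model reproducing the assay's
  observed statistics: 1093 uniquely mapped reporters, >30-fold
  state-dependent expression differences, a repression mixture (18 %
  silenced, 70 % more than twofold down, 0.27 % upregulated, mean fold
  change 0.23 among detectable reporters), stronger silencing in
  pericentromeric heterochromatin coupled to local HP1 occupancy
  (r = −0.35), H3K36me3 attenuation (1.4-fold), a 2.5 % spike-in pool,
  and loss of silencing by day 16 (fold change 0.92 ± 0.53).

## Worked example

```python
import tripkit as tk

cfg = tk.SimConfig(seed=1)           # defaults = the study conditions
sim = tk.simulate_experiment(cfg)    # counts, iPCR reads, states, tracks
res = tk.run_pipeline(sim, seed=1)   # collapse -> normalize -> map -> stats

s = res.summary
print(f"mapped integrations : {res.mapping_summary.n_accepted}")
print(f"> 2-fold down       : {s['frac_down2x']:.1%}")
print(f"completely silenced : {s['frac_silenced']:.1%}")
print(f"mean fold change    : {s['mean_fc_both_detectable']:.2f} "
      f"+/- {s['sd_fc_both_detectable']:.2f}")
t7 = res.state_tests[7]
print(f"state 7 vs rest     : {t7.median_ratio:.2f}-fold stronger repression "
      f"(p = {t7.pvalue:.2g}, n = {t7.n_group})")
print(f"day-16 fold change  : {res.memory.mean_fc:.2f} +/- {res.memory.sd_fc:.2f}")
```

prints, for this seed:

```
mapped integrations : 1093
> 2-fold down       : 76.3%
completely silenced : 17.3%
mean fold change    : 0.22 +/- 0.30
state 7 vs rest     : 2.46-fold stronger repression (p = 0.02, n = 70)
day-16 fold change  : 0.93 +/- 0.51
```

All 1093 true barcodes pass the mapping filters (every decoy is rejected
with its diagnostic reason); roughly one reporter in six is silenced
outright, repression is about twice as strong in pericentromeric state 7,
and by day 16 expression has returned to baseline. Single-seed values
scatter around the calibrated targets (e.g. 18 % silenced, mean fold
change 0.23); seed-averaged recovery is what the acceptance script checks.

The same stages are exposed as a CLI:

```sh
trip simulate --seed 1 --outdir sim/
trip collapse --in sim/cdna_control_rep1.tsv --out collapsed.tsv
trip map --records sim/mapping_reads.tsv --out sites.tsv
trip quantify --cdna sim/cdna_control_rep1.tsv --gdna sim/gdna_rep1.tsv \
              --spike sim/spike_gdna.tsv --out expr_control.tsv
trip analyze --control expr_control.tsv --tethered expr_tethered.tsv \
             --sites sites.tsv --states sim/states.bed --out out/
```

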