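# oligomir

Statistical toolkit for asking whether microRNAs over-expressed in
*oligometastatic* tumour samples — patients with a limited, potentially
curable burden of metastases — are concentrated in a genomic miRNA cluster
(the 14q32 / DLK1-DIO3 locus), co-target metastasis pathways, co-repress
shared genes after transfection, and stratify recurrence-free survival.

It is written for computational biologists who want the full statistical
chain of such a study as a tested, reusable pipeline, exercisable end to
end on synthetic data with planted ground truth (no array downloads or
patient-level data required).

## The statistics

- **Locus enrichment.** For a differential set of $n$ miRNAs drawn from an
  array panel of $N$ with $K$ locus members, the observed locus count $k$
  is tested against whole-set resampling without replacement ($10^6$
  replicates by default); the add-one empirical p-value
  $(r+1)/(B+1)$ is accompanied by its exact oracle, the upper-tail
  hypergeometric $P(X \ge k)$, $X \sim \mathrm{Hypergeom}(N, K, n)$.
- **Pathway co-targeting.** Target scores (microT-style confidences) are
  thresholded at $\tau = 0.6$; each (miR, pathway) pair gets an upper-tail
  hypergeometric over-representation p-value over the gene universe;
  per-pathway evidence is combined across miRNAs with Fisher's method,
  $X^2 = -2\sum_i \ln p_i \sim \chi^2_{2k}$. Pathways carry functional
  groups (AIM: adhesion/invasion/motility; ICS: intracellular signaling;
  CSS: cancer-specific signaling) and locus miRNAs are ranked by their
  significant-AIM burden.
- **Co-repression.** Transfection expression matrices are
  quantile-normalized; suppressed probes are called with a SAM-style
  moderated statistic $d = \Delta\bar{x} / (s + s_0)$ and exhaustive
  balanced-relabeling FDR, gated at FDR ≤ 5% and fold change ≥ 1.4
  (≥ 2.0 for pathway input); sharing across miRNAs is quantified by Venn
  membership patterns and Pearson $\chi^2$ 2×2 overlap tests over the
  detected-probe population.
- **Survival.** Patients are split at the median of mean miRNA expression
  and compared by Kaplan–Meier curves and a log-rank test.

## Worked example

```bash
oligomir run-all --seed 11 --out demo-run
```

runs the whole chain on a freshly simulated bundle. The report it prints
(abridged):

```
[simulate]
  planted_mirs: sim-miR-0073, sim-miR-0084, sim-miR-0094, sim-miR-0116
[locus-test]
  locus_fraction: 15/39 (38%)
  p_empirical: 9.99999000001e-07
  p_printed: < 0.0001
[enrich]
  pathways_combined_significant: 6
  top_aim_mir: sim-miR-0084
  network_pathways: 3
[de]
  n_suppressed[sim-miR-0094]: 138
[overlap]
  common_all: 72
  frac_union_ge2: 0.3074
  max_pairwise_p: 4.106594115956178e-126
[survival]
  n_high: 24  n_low: 24
  logrank_p: 0.00018803837911140784
  S5y_high: 0.7389  S5y_low: 0.1688
```

Reading: 15 of the 39 differential miRNAs fell in the planted 14q32-style
locus — no resampling replicate in 10⁶ matched that, so the enrichment
p-value is reported as "< 0.0001"; the top-ranked miR by AIM-pathway
burden (`sim-miR-0084`) is one of the four planted miRs; about 31% of the
recovered suppressed probes are shared by two or more miRs, with every
pairwise overlap far beyond chance; and the high-expression group shows
markedly better five-year recurrence-free survival (74% vs 17%) with
log-rank p ≈ 2×10⁻⁴. Every number is recomputed from the seeded
simulation; `ground_truth.json` in the output directory records the
planted structure the run recovered.

Per-stage commands (`simulate`, `locus-test`, `enrich`, `de`, `overlap`,
`survival`) operate on plain TSV/GMT files; see `oligomir --help`.

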