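# Methods

This note documents the statistical models implemented in oligomir, the
synthetic study conditions they are validated against, and the numerical
and design choices a maintainer needs to know.

## Locus-enrichment permutation test (`oligomir.locus`)

**Model.** The array panel of `N` miRNAs with `K` members of one
prespecified genomic locus is the sampling frame. The null treats the
differential set as a uniform size-`n` draw without replacement; each of
`n_perm` replicates resamples a whole set and counts locus members. The
test is one-sided (upper tail) because the scientific claim is enrichment,
and replicates tying the observed count are counted as exceedances (the
standard conservative convention). The empirical p-value uses the add-one
estimator `(r + 1) / (n_perm + 1)`, which never reports 0; with zero
exceedances at `n_perm = 10^6` it returns ≈10⁻⁶ and the report layer
prints "< 0.0001". The marginal of this null is exactly
`Hypergeom(N, K, n)`, so `exact_locus_test` (upper-tail hypergeometric
survival function) is both a cross-check in every result object and the
analytic limit of the Monte-Carlo estimate.

A defensible alternative reading of "randomly choosing a particular
microRNA … comparing the incidence" is single Bernoulli draws per
replicate; whole-set resampling was chosen because the tested statistic is
the incidence of the observed *set*, and the two are marginally
equivalent. The panel used as the frame contains miRNA records only (no
control probes).

**Numerics.** Replicates are generated as chunked Fisher–Yates row
permutations of the locus indicator vector (≈8 × 10⁶ matrix elements per
chunk), so `n_perm = 10^6` over a 377-miR panel runs in seconds and is
bit-reproducible given `(seed, n_perm)`.

**Parameters.** `n_perm` defaults to 10⁶ (the convention for this test);
the packaged pipeline profile uses 10⁴–10⁵ for speed, and the value
actually applied is always recorded in run provenance.

## Pathway co-targeting (`oligomir.enrichment`)

Target scores in [0, 1] are thresholded at `tau = 0.6` (the conventional
microT operating point) to form per-miR target gene sets. Each
(miR, pathway) pair is scored with the upper-tail hypergeometric
over-representation p-value over the gene universe; the universe defaults
to the union of all scored genes and is configurable to an explicit
background list (prediction services do not state theirs, so it must be a
caller decision). Per-pathway p-values are combined **across miRNAs**
with Fisher's method (`-2 Σ ln p ~ χ²_{2k}`); this matches the column
semantics of a miR × pathway heatmap whose columns are retained when the
combined p ≤ `alpha = 0.05`. A p-value floor of 10⁻³⁰⁰ is applied before
the log so the method stays defined when an upstream tail underflows;
exact zeros are rejected as caller bugs.

Per-cell p-values are deliberately not multiplicity-corrected on the
default path (matching the conventional use of this enrichment chain); a
Benjamini–Hochberg adjustment (`bh_adjust`, via
`scipy.stats.false_discovery_control`) is available off the default path.

Row clustering of the −log10(p) matrix uses Euclidean distance with
average linkage — neither is canonical for such heatmaps, so the common
default was fixed once; scipy's lowest-index-first tie rule makes the
dendrogram deterministic. AIM-burden ranking sorts miRNAs by (number of
significant AIM pathways, summed −log10 p over them), ties broken
lexicographically. The pathway–miR network export is a plain edge table of
pathways with ≥ `min_mirs` significant miR associations (default 2), the
text stand-in for a network figure.

## Differential suppression (`oligomir.suppression`)

**Quantile normalization** maps every array onto the reference
distribution formed by across-column means of sorted values; tied entries
within a column receive the mean of the reference values at the tied rank
positions. The transform is idempotent and makes column value-multisets
exactly equal. Missing values are rejected — imputation
(`impute_row_mean`) is an explicit upstream step, never silent.

**SAM-style calls.** Per probe, `d = (mean_t − mean_c)/(s + s0)` with `s`
the pooled standard error and `s0` a positive fudge constant; `s0`
defaults to the median of the per-probe `s` values (robust and
deterministic; a percentile-search rule adds tuning without changing the
calls at this scale), and must be given explicitly for noiseless data
where every `s` is 0. With duplicate arrays (2 vs 2) the permutation null
is the *exhaustive* set of 6 balanced relabelings, identity included —
randomness adds nothing when the group is this small; larger designs fall
back to seeded random relabelings. The q-value at each probe's |d|
threshold is the median false-call count across relabelings divided by
the observed call count, capped at 1 and monotonized (a tighter threshold
never gets a larger q). With 6 relabelings the q granularity is coarse —
multiples of per-relabeling medians — which is inherent to duplicate
designs and the reason the suppressed-set recovery on noisy duplicates is
partial rather than complete (see the generator section).

Suppression gates follow the conventional constants of this analysis
chain: fold change treated/control
≤ 1/1.4 at FDR ≤ 5% for the co-repression analysis, and a stricter ≤ 1/2.0
gate for the set handed to pathway over-representation. The fold-change
boundary is inclusive, with a 10⁻¹² relative tolerance absorbing floating
round-off at exact thresholds. Analysis is probe-level throughout; an
optional collapse to genes is deliberately out of the default path because
probe-to-gene collapse rules are platform conventions, not statistics.

**Overlap.** Venn membership patterns are exact element classifications
(2–4 sets). Pairwise overlap uses the Pearson χ² on the 2×2 table over an
explicitly supplied detected-probe population size `N` — whether "probes
detected" means detected on any or on all arrays is a data-processing
decision, so `N` is a required argument rather than a default. No Yates
correction is applied (the plain contingency χ² is the named test); a
zero expected cell raises an error pointing to the exact hypergeometric
fallback (`pairwise_overlap_exact`).

## Survival (`oligomir.survival`)

Patients are scored by the arithmetic mean of the chosen miRNA panel and
split at the joint cohort median; "high" requires a score strictly greater
than the median, so ties fall to "low" (the literal reading of "greater
than the median"). Kaplan–Meier curves and the two-group log-rank test are
delegated to lifelines; censoring at an event time leaves the subject in
the risk set for that event. Greenwood confidence bands are carried on the
curve object but play no role in testing. "Five years" is 60 on the months
time scale.

## Synthetic study conditions (`oligomir.synthetic`)

The generator emulates every input with planted, recoverable structure;
all planted choices are recorded in a ground-truth sidecar so each stage
can be scored for recovery. Defaults define the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| `n_array_mirs` / `n_locus_mirs` | 377 / 20 | a 377-assay miRNA card with a ~20-member locus cluster; cards of this class do not publish a locus composition, so these are stand-ins and stay configurable |
| `n_diff` | 39 | the surgical differential-set size |
| `locus_enrichment_odds` | 17 | under the sequential renormalized-weight sampler this gives a mean realized locus count ≈14 of 39, the reference configuration (the naive odds-ratio value ≈30 overshoots because sequential sampling over-represents heavy weights) |
| `n_planted_mirs` | 4 | the four-miR candidate panel |
| `n_genes`, `n_pathways`, `pathway_size_range` | 2000, 30, (20, 60) | scaled-down gene universe and KEGG-like collection keeping hypergeometric tails well away from degeneracy |
| `targeting_concentration`, `background_target_rate` | 0.7, 0.05 | 100 above-threshold targets per miR, 70% of a planted miR's drawn from its designated pathways; the above-threshold count is fixed (not Bernoulli) so the null of the downstream hypergeometric is exact |
| `n_probes`, `n_replicates`, `n_suppressed_per_mir` | 2000, 2, 150 | duplicate arrays; 7.5% of probes suppressed per miR, the same order as suppressed-probeset counts reported on whole-genome arrays (a few percent of probes) |
| `suppression_log2fc`, `noise_sd` | 1.0, 0.15 | 2-fold planted shifts over homoscedastic log2 Gaussian noise (SAM's exchangeability assumption); 0.15 reflects the high technical reproducibility of bead-array duplicates — at markedly higher noise the coarse 6-relabeling FDR makes per-miR call counts erratic, which is a property of duplicate designs, not of the pipeline |
| `shared_fraction` | 0.31 | fraction of the union of suppressed probes shared by ≥2 miRs (the reference study condition); realized by one all-miR shared pool plus disjoint unique remainders sized as `m·f·k/(f·k + 1 − f)` |
| `n_patients_per_group`, `hazard_ratio`, `censor_rate`, `followup_horizon` | 24, 3, 0.2, 60 | two 24-patient cohorts; the high group's exponential rate is set so S(60 mo) = 0.6, the low group's is 3× larger; a 20% fraction is censored uniformly before the event, everyone else is observed to the event or administratively censored at the horizon |

What the generator does **not** emulate: probe-level heteroscedasticity
and intensity-dependent variance of real arrays, correlated probes within
genes, miRNA families with overlapping seed sequences, batch effects, and
non-exponential (e.g. cure-fraction) survival. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under its
own assumptions, not that any particular real expression matrix would
reproduce a given count. Survival group assignment is separable by construction
(mean-score gap around the median), so the median split recovers the
generating groups exactly; that is a deliberate identifiability choice,
not a claim about clinical data.

Reproducibility: one seed drives per-stage independent `SeedSequence`
streams, so the same `(seed, config)` yields bit-identical bundles and
each stage is reproducible in isolation.

## Calibration checks and problem sizes

The test suite validates, at desk scale: exact reference locus fractions
(14/39 → 36%, 5/29 → 17%); Monte-Carlo/exact agreement on 50 random small
panels at 10⁵ replicates; the Fisher single-p identity to 10⁻¹²;
hypergeometric tails against exhaustive subset enumeration for all
universes ≤ 12; null calibration of pathway p-values over 500 seeds and
log-rank p-values over 200 seeds; SAM null behaviour over 100 seeds
(median call count 0 at FDR 5%) with exact noiseless recovery; overlap
statistics against brute-force classification and the hand-computed
χ² = 12.698 table; the hand product-limit example; and 20 full pipeline
runs recovering every planted structure. Pathway hypergeometric p-values
are discrete and super-uniform (the atom at the modal overlap can exceed
0.2), so their uniformity check is the one-sided KS test for an excess of
small p-values — the calibration property a discrete test can and must
satisfy; the log-rank p-value is effectively continuous and gets the
two-sided check. Simulation sizes (e.g. 300–2000 probes, 500 seeds) were
chosen as the smallest scales at which these distributional checks are
stable.

## Known limitations

- The SAM q-value estimator omits the π₀ (true-null proportion)
  correction; with 6 relabelings its granularity dominates anyway, and the
  omission is conservative.
- The χ² overlap test is asymptotic; small margins must use the exact
  fallback.
- The locus test assumes a single prespecified locus; no multi-locus scan
  correction, coordinate liftover, or miRBase version reconciliation.
- Quantities that depend on external prediction-database versions or on
  unpublished patient-level data (total predicted target counts, vendor
  pathway-tool outputs, clinical five-year figures) are consumed
  concepts, not reproduction targets.
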