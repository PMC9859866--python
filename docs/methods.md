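# Methods

## SEM definition and thresholds

A stochastic epigenetic mutation (SEM) is a beta value strictly outside the
Tukey extreme fences of a reference distribution computed per probe:
`Q1 − 3·IQR` (hypo) and `Q3 + 3·IQR` (hyper). Conventions that matter:

- **Quartiles** use linear interpolation between order statistics at
  position `1 + (n − 1)·q` (numpy's default). This convention reproduces the
  packaged clinical cohort's printed ln-burden quantiles exactly; other
  quantile dialects do not.
- **Fences are not clamped** to [0, 1]. A probe whose lower fence is
  negative simply cannot yield a hypo call; this is the correct behaviour
  for near-unmethylated probes rather than a defect.
- **Strict inequalities**: a value equal to a fence is not a SEM.
- **Reference set**: configurable; default is the whole cohort (cases and
  controls), matching the common practice of calling outliers against the
  pooled study population. An external reference matrix can be supplied, and
  a leave-one-out mode recomputes fences excluding the evaluated sample. At
  least 4 reference samples are required (quartiles are meaningless below
  that); no leave-one-out correction is applied by default.
- **Unusable probes**: IQR below `iqr_floor` (default 1e-6, i.e. only
  numerically constant probes) or any missing reference value. Missing
  target values are never called.
- Thresholds are computed on the beta scale. The outlier definition is a
  robust-quantile rule, so the variance-stabilising M transform is not
  needed for calling; M-values are used only in the differential stage.

A finite-sample caveat documented here because it shapes the tests: for a
Gaussian reference the probability that a value falls outside its own
cohort's 3·IQR fences is ~2×10⁻⁴ at n = 40 reference samples, falling to
~2×10⁻⁵ at n = 120 (the fences are noisy estimates at small n; the effect
is scale-invariant, so lowering noise does not remove it). Burden contrasts
are unaffected (the background is group-symmetric), but absolute counts
include this floor, and exact truth-recovery checks use larger cohorts.

## Burden model

Per subject and direction the SEM count and its natural log are reported;
zero counts keep count 0 with the log left undefined, and such subjects are
excluded from that direction's model and quantiles (no pseudo-count: the
printed quantiles of the clinical cohort require `ln(count)` exactly).
Group comparison is a linear mixed model `ln(count) ~ group + sex` with a
family-level random intercept, fitted by REML; the case-vs-control effect
is a Wald test on the group coefficient (single coefficient; likelihood-
ratio would require refitting under ML and offers no practical advantage
here). When the random-intercept variance estimate hits the zero boundary —
routine when family effects are truly absent, as in Poisson-spiked
synthetic cohorts — the model degenerates to OLS, and the implementation
refits with family-cluster-robust standard errors (t reference with
cluster-count degrees of freedom) and flags `method="ols_cluster"`. Applied
to the packaged clinical cohort this model yields a case excess of 0.25
ln-units with p ≈ 0.021.

A Wilcoxon signed-rank companion runs on complete discordant pairs only
(exact null distribution up to 25 pairs). It conditions on within-pair
contrasts and therefore uses less information than the mixed model when
concordant pairs exist.

## Region enrichment scan

Per sample and direction, every run of `window_probes = 10` consecutive
usable probes on a chromosome (step 1) is tested: the window SEM count k
against the upper tail of Binomial(10, r), where r is that sample's
genome-wide rate (calls / usable probes, per direction). BH correction is
applied across all windows of a sample×direction; windows with q ≤ 0.05
and k ≥ 3 are merged when overlapping (merged regions keep the minimum
p/q and count distinct SEM probes). Choices worth stating:

- The window is defined in **probes, not basepairs**: invariant to probe
  density, and the exact binomial tail behaves well at small counts.
- **Per-sample testing** mirrors the per-subject reporting of epimutated
  loci; a cohort-level scan would dilute private events.
- **Direction purity**: hypo and hyper windows are scanned separately;
  mixed windows are not combined.
- The k ≥ 3 floor suppresses two-probe coincidences that can reach small
  p at very low genome-wide rates.
- Overlapping windows are strongly dependent, so BH is conservative here;
  q-values are rank statistics for thresholding, not literal FDR levels.
- Note that scattered single-probe spikes occasionally form genuine
  3-in-a-window coincidences; the scan correctly reports them, so an
  "empty null" holds only for cohorts with no epimutations at all.

## Gene sets and the candidate screen

A gene enters a population×direction set when ≥1 SEM of that direction in
≥1 sample of that population lies on a probe annotated to it (multi-gene
probes feed all their genes; unannotated probes feed none; symbols match by
exact case-sensitive string, the manifest being the single authority).
"Univocal" sets are three-way set differences (cases minus controls minus
reference, and symmetrically); cross-direction intersections combine
univocal sets of opposite directions and groups. Because the published
"both directions in cases" list is ambiguous about whether it is restricted
to univocal genes, both variants are computed and labelled
(`cases_both_directions` and `cases_both_directions_univocal`). The
candidate screen is a transparent membership filter of a configurable gene
list (default: CH dyshormonogenesis/dysgenesis candidates plus imprinted
loci) against the univocal sets — a deliberate, auditable stand-in for
knowledge-base prioritization tools.

## Paired differential methylation

Betas are clamped to [1e-3, 1 − 1e-3] and transformed to
M = log2(β/(1−β)). For each discordant pair the case-minus-control M
difference is formed; per site a one-sample t against zero, BH across
sites. Region level (genes; promoters = 1500 bp upstream of a gene's first
probe; CpG islands from the manifest class; 5-kb tilings) averages member
M-values per sample first, then applies the same paired test with BH within
the region class. Zero-variance, zero-mean rows get p = 1; probes with
fewer than 3 complete pairs carry no statistic; effect sizes are reported
as mean paired beta differences alongside M-scale tests. This stage is
intentionally plain — no empirical-Bayes moderation, no combined-rank
scoring — because its scientific role in this design is the null result:
group-level methylation shifts are absent while SEM burdens differ.

## Synthetic cohorts

The generator emulates what matters statistically about a twin methylome
cohort, with defaults chosen as a desk-scale version of the clinical study:

| parameter | default | meaning |
|---|---|---|
| n_pairs_mz / n_pairs_dz | 10 / 10 | twin pairs per zygosity |
| n_concordant_pairs | 4 | both-affected pairs (rest discordant, twin A affected) |
| n_probes / n_chromosomes | 20 000 / 4 | manifest size |
| probes_per_gene | 10 | consecutive probes per synthetic gene |
| inter-probe gap | U(200, 2000) bp | manifest spacing |
| baseline modes | 0.10 / 0.85 (45%/45%), U(0.3, 0.7) (10%) | array-like bimodal betas |
| family_effect_sd | 0.02 | per-(family, probe) shared shift |
| mz_pair_effect_sd | 0.015 | extra MZ-shared shift (MZ correlation > DZ) |
| noise_sd | 0.025 | i.i.d. Gaussian, values clipped to [0, 1] |
| sem_rate_control | 100 | expected spikes per control sample (both directions) |
| hypo_fraction | 0.5 | share of spikes that are hypo |
| sem_rate_case_multiplier | 1.5 | case excess on the hypo rate (≈ the clinical ratio e^0.36) |
| spike displacement | ≥0.15 (clusters ≥0.20) beyond the clean fence | callability guarantee |

Spike counts are Poisson with the group-specific rate (a negative-binomial
dispersion switch exists, off by default). Spiked values are set beyond the
fences computed on the *clean* (pre-spike) matrix by at least the stated
displacement plus a small uniform jitter, clamped to [0.001, 0.999]; spike
probes are drawn only where that guarantee is attainable inside the unit
interval (a probe near β = 0 cannot host a hypo outlier), and a given
(sample, probe) is spiked in at most one direction. Cluster spans get
their baseline forced to the opposite methylation mode before fences are
computed so every span is callable; spans are recorded with their probes in
the truth set. What the generator does **not** emulate: Infinium I/II
chemistry differences, batch effects beyond a label, cell-composition
structure, genome-scale probe counts, and family effects on spike *rates*
(family shifts act on methylation levels only). Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to array artefacts.

## Problem sizes and calibration checks

Test and acceptance runs use deliberately desk-scale instances: 2 000–5 000
probes and 20 pairs for Monte-Carlo loops (200 null seeds for mixed-model
type-I error, 50 seeds for power/sign and recovery rates), 20 000 probes for
the single-cohort differential-null calibration, 60 pairs where exact
truth-recovery needs tight fences. Observed on these conditions: spiked-SEM
sensitivity ~100%, cluster detection ~100%, mixed-model type-I error ~5–9%
(slightly anti-conservative with 20 clusters and normal-based Wald
reference), differential-null p < 0.05 fraction ~4.5–5%.

## Clinical fixture conventions

Case status is the affected-row status of the source tables, not the final
diagnosis: subject 9B (euthyroid through the study window, hypothyroid only
years later) is a control, which is required to reproduce the 27/19 split
and the gland-in-situ counts. A variant carrier is any subject with a
non-wild-type annotation regardless of classification (pathogenic, benign,
or uncertain) — the convention that reproduces the published 11/27. One
subject's morphology is printed as gland-in-situ in the table but described
as hypoplasia in the source's narrative; the table value is used, matching
the published counts. Hyper-methylated counts were not published and are
absent from the fixture. The packaged CSV is checksummed at load.

## Known limitations

- SEM calling assumes a reasonably large reference set; below ~40 samples
  the fences are noisy and absolute burdens include a finite-sample
  background (see above).
- The Wald p-value from REML uses a normal reference; with few families it
  is mildly liberal. The cluster-robust fallback uses a t reference but
  relies on ≥ ~15 clusters.
- Region q-values are computed over heavily overlapping windows and should
  be read as ranking devices.
- Gene annotation performs no symbol aliasing; manifests from different
  annotation releases must be harmonised upstream.
- The differential stage does not emulate variance-moderated pipelines; its
  p-values are exact paired-t, which is conservative for small pair counts
  relative to moderated alternatives.
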