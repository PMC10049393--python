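# Methods

## Measurement model and preprocessing

RT-qPCR expression is analysed on the ΔCq scale: target Cq minus the
per-sample reference, where the reference is the mean of an exogenous
spike-in (cel-miR-2-3p, added at a fixed 1.5 pg per extraction) and an
endogenous control (hsa-miR-16-5p). Higher ΔCq means lower relative
abundance; the four panel miRNAs all shift toward *higher* ΔCq in PDAC,
i.e. reduced exosomal abundance. The ΔCq sign convention is
target − reference throughout.

Preprocessing applies a fixed order of operations to each measurement:

1. **Censoring.** A detected Cq above 35 cycles, or a non-detect after 40
   cycles, becomes the sentinel 36. The sentinel encodes "absent", not a
   measured quantity, so it is never volume-adjusted. Censoring before
   replicate averaging (rather than after) keeps a half-detected duplicate
   interpretable: {34, non-detect} averages to 35, not to 34. Censoring is
   idempotent because the sentinel exceeds the ceiling.
2. **Volume normalization.** Plasma inputs vary; all endogenous
   measurements are rescaled to 750 µL via Cq_norm = Cq_raw − log₂(750/X).
   The published formula is typographically garbled ("log2(750 uLX)");
   it is read as log₂(750/X), the only reading under which halving the
   input (half the template, one extra cycle) normalizes back exactly.
   The spike-in is exempt by default: its physical dose is
   volume-independent, so adjusting it would *introduce* a volume artifact
   (`volume_adjust_spike_in=True` applies the correction uniformly for
   users whose protocols dose proportionally).
3. **Replicate averaging** (arithmetic mean of the censored, normalized
   duplicates), then the reference mean, then ΔCq. A sample whose
   reference assays are entirely non-detected cannot be normalized and is
   dropped with a logged warning rather than imputed.

The **detectability filter** removes a candidate non-detected (no
replicate amplified within 40 cycles) in strictly more than 80% of
samples; "over 80%" is read as a strict inequality, so a miRNA missing in
exactly 80% of samples is retained. The filter uses raw detection flags,
before censoring.

## Group statistics

Group summaries use the t-based two-sided CI of the mean,
mean ± t₀.₉₉₅,ₙ₋₁·SD/√n (sample SD, ddof = 1), interpreted as a CI of the
mean rather than a prediction interval. Control-vs-PDAC screening uses
Student's two-tailed pooled-variance t-test (Welch available;
`ttest_variant="welch"`), with the conventional 0.05/0.01/0.001 star
ladder. Stage-stratified tests compare each PDAC bucket — early (stages
I–II), mid (III), late (IV) — against the full control group; buckets with
fewer than two samples are skipped with a warning. Raw p-values are
reported with no multiplicity correction, matching common practice for an
11-candidate screen; Benjamini–Hochberg adjustment is available but off by
default. Demographics use Pearson's χ² on group × category tables
(zero-total rows/columns dropped with a warning); age is binned into
decades first, since χ² is undefined on a continuous variable, and a plain
t-test on age is provided alongside.

## Thresholds, scoring, ROC

The dual cutoffs per panel miRNA are the upper limit of the control 99% CI
(control_upper) and the lower limit of the PDAC 99% CI (pdac_lower). No
ordering between them is assumed — for miR-425-5p the published pdac_lower
(9.59) lies *above* control_upper (9.16), and the scoring handles either
orientation. All comparisons are strict (">"), including the CA19-9 rule
(positive iff > 37 U/mL). Hits per miRNA are the number of cutoffs
exceeded (0–2 in combined mode; 0–1 in the single-threshold modes, where
combined hits decompose exactly as their sum). The binary call cutoff is
"at least one hit": the only hit-count rule consistent with the published
12/15 sensitivity and 18/19 specificity given that a single control showed
any hits. It is configurable (`call_cutoff`). Thresholds are derived on
the same cohort they are applied to — deliberately mirroring the original
resubstitution design, with derivation and application separated in the
API so held-out evaluation is possible.

ROC curves treat the hit total as an ordinal score (≤ 9 distinct values
for a 4-miRNA panel): one operating point per distinct cutoff (predict
positive iff score ≥ cutoff), ties grouped, endpoints added. Trapezoidal
AUC then equals the tie-adjusted Mann–Whitney estimate, which the test
suite verifies by exhaustive pair counting. Uncertainty defaults to a
stratified bootstrap (2,000 resamples, percentile interval, seeded;
resamples with all scores tied contribute AUC 0.5); DeLong's
midrank-based asymptotic variance is implemented as the fast alternative.
The p-value against AUC = 0.5 comes from the same machinery as the chosen
interval (bootstrap tail proportion, two-sided, resolution-limited at
2/n_boot; DeLong normal approximation).

## Synthetic cohort generator

The generator emulates the study conditions: 19 controls vs 15 PDAC
(stages I:3, II:2, III:3, IV:7 → early 5 / mid 3 / late 7), 18 candidate
miRNAs plus the two references, technical duplicates, variable input
volumes, and group-dependent CA19-9. Per-group ΔCq draws are Gaussian —
the minimal assumption consistent with t-based inference — with the four
panel miRNAs' (mean, SD) recovered from the published 99% CI pairs by
exact inversion (sd = halfwidth·√n / t₀.₉₉₅,ₙ₋₁). A raw target Cq is

    ref_level_i + ΔCq_im + log₂(750/volume_i) + ε_imr,

with ref_level ~ N(18, 0.75) (a typical abundant-reference Cq), replicate
noise ε ~ N(0, 0.15) (routine TaqMan duplicate agreement), and volumes
drawn from {750, 600, 500, 375} µL with weights {0.4, 0.3, 0.2, 0.1}.
Non-detects arise two ways: a per-measurement Bernoulli detection draw and
the 40-cycle ceiling. Seven candidates default to detect_prob = 0.03 so
that, with duplicates, their sample-level non-detection fraction sits
safely above the 80% exclusion bar — reproducing the 7-of-18 dropout count
(the study never names the seven, so the fixture encodes the count, not
identities). The seven retained non-panel candidates get equal group means
spread over ΔCq 9–12 with SD 1.5. CA19-9 is log-normal; the PDAC median is
set exactly at the 37 U/mL clinical cutoff (so about half of PDAC draws
are elevated, matching the reported 8/15) with σ = 1.0, controls at median
10, σ = 0.5. Demographics are drawn categorically from the reported group
frequencies. Everything is driven by one `numpy` Generator, so cohorts are
byte-identical under a fixed config + seed.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: within-sample correlation between
miRNAs, heavy-tailed or clustered (non-Gaussian) control distributions,
extraction/amplification-efficiency variation, batch effects, and
outlier control subjects. The published operating point (94.7% specificity
at the ≥1-hit cutoff) depends precisely on such clustering: under
independent Gaussians, CI-of-the-mean cutoffs lie only ~0.7 within-group
SDs above the control mean, so a typical control crosses some cutoff and
simulated specificity at that cutoff is low even when AUC matches the
published ≈0.88. The pipeline's correctness claims rest on the
rule-application and calibration tests, not on reproducing the published
confusion table, whose per-sample inputs were never released.

## Numerical and design notes

- CI inversion and re-formation use the same t quantile, so the
  round-trip is exact to float precision; tests cross-check the quantile
  by independent CDF inversion (Brent root-finding) and, for df = 1, the
  closed form tan(π·0.495).
- Degenerate t-test input (both groups identical constants) returns
  t = 0, p = 1 instead of NaN.
- Identical-score ROC input degenerates to the diagonal endpoints with
  AUC 0.5; bootstrap resamples that collapse to a single tied value are
  scored 0.5 rather than dropped.
- Threshold derivation requires n ≥ 2 per group per panel miRNA; a panel
  miRNA absent from the ΔCq matrix (e.g. removed by the detectability
  filter) is a configuration error, not a silent skip.
- Pipeline stage isolation: changing the threshold mode or scoring
  parameters cannot alter the ΔCq matrix; the report serializes the full
  config, its hash, and library versions.
- Statistical suite sizes: calibration checks (type-I error, CI coverage)
  use 10,000 seeded replicates; end-to-end cohort checks use 200 seeded
  replicates of the full 34-sample workflow; the binormal AUC limit uses
  10,000 scores per class.

## Known limitations

Thresholds are resubstitution estimates (no cross-validation), matching
the original design; sensitivity/specificity from them are optimistic.
The bootstrap p-value cannot resolve below 2/n_boot. The generator draws
miRNAs independently within a sample, which understates the variance of
hit totals relative to correlated real panels. Amplification-efficiency
correction, standard curves, and fold-change (2^−ΔΔCq) reporting are out
of scope: the analysis operates on the ΔCq scale throughout.
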