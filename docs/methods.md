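# Methods

## Problem and data model

`pdkeys` analyses natural-typing keystroke logs as a motor biomarker for
Parkinson's disease (PD). A typing session is an ordered sequence of
keystrokes, each with a press instant `P_n` and release instant `R_n`
(seconds, session-relative). Four interval series are derived:

| series | definition | notes |
|---|---|---|
| hold latency `HL_n` | `R_n − P_n` | ≥ 0 by construction |
| interkey latency `IL_n` | `P_{n+1} − R_n` | negative under rollover typing |
| press latency `PL_n` | `P_{n+1} − P_n` | `= HL_n + IL_n` |
| release latency `RL_n` | `R_{n+1} − R_n` | `= IL_n + HL_{n+1}` |

Consecutiveness is defined by press order over **all** keys, including
specials (backspace, shift, …). The two identities above hold exactly and
are enforced by property tests.

## Fluctuation statistic

The dispersion of each series is summarised by the sample standard
deviation (n−1 denominator) of the natural log of the quotient of
consecutive intervals:

    X_SD = SD{ ln(I_{n+1} / I_n) }

This statistic is scale-free (multiplying all intervals by c > 0 leaves it
unchanged) and sequential (permuting the series changes it). For intervals
with iid Normal(μ, σ²) logarithms the log-ratios are Normal(0, 2σ²), so
`X_SD → √2·σ`; this closed form both calibrates the synthetic generator and
serves as a recovery check. Two variants are computed per subject:

* **all-keystroke** `HL_SD`, `IL_SD`, `PL_SD`, `RL_SD`;
* **restricted-key** `sd_restricted`: the same construction on HL but
  keeping only alphanumeric, symbol and space-bar keystrokes (the earlier
  hold-time construction in the literature). The key filter is applied
  before outlier cleaning. Whether the original restricted method used the
  log-ratio construction or a plain SD of HL is not restated in the source
  material; this package uses the log-ratio construction for both variants,
  as a documented interpretation.

Non-positive values reaching the statistic (possible only when negative
removal is disabled) are excluded with both adjacent ratios dropped
(logarithm domain). After cleaning, ratios are formed over consecutive
survivors by default ("compact"); a "strict" policy that discards pairs
spanning a removed value is available (`pair_policy="strict"`). Compaction
maximises retained pairs and matches the reading that outliers are removed
from the analysis altogether.

A statistic is **missing, never zero**, when the cleaned series has fewer
than 3 values or fewer than 2 valid ratios.

## Outlier policy

Cleaning is per subject and per latency kind, in two deterministic steps:

1. drop negative values (invalid a priori; letting them shift quartiles
   would contaminate the fence);
2. compute `[Q1 − k·IQR, Q3 + k·IQR]` on the remaining values and drop
   anything outside.

Defaults: `k = 12`, linear-interpolation ("type 7") quantiles. The
classical extreme-outlier fence `k = 3` discards too much of these
heavy-tailed interval distributions; `k = 12` removes only recording
glitches (mean removal on clean log-normal data ≪ 0.1% of points). The
quantile convention is a named, switchable policy field — at `k = 12` the
choice is almost never decisive, but reproducibility demands it be pinned.
There is no interactive inspection step: the deterministic fence plus the
per-(subject, kind) removal report replaces visual examination. Removal
percentages are reported both per kind and pooled per subject.

## Word count and typing speed

The logs carry no text, so "word" is a convention, isolated behind one
operation: by default, word count = number of space presses + 1 if any
non-space key was typed; speed = words / elapsed minutes (last release −
first press). An alternative `token_runs` convention (maximal runs of
non-space keys) can be selected. Published magnitudes (~1,300–1,650
"samples", ~100 words/min) cannot disambiguate the definition.

## Screening statistics

Each feature is a univariate classifier with a declared orientation
(fluctuation statistics and the composite typing index are *higher* in PD;
tapping scores, typing speed and word count *lower*). An auto-orient
fallback flips — and logs — any feature whose oriented AUC is below 0.5.

* **ROC**: thresholds at midpoints between adjacent distinct scores plus
  ±∞ sentinels; trapezoidal AUC equals the Mann–Whitney concordance
  probability with ties counted ½ (asserted to 1e−12).
* **AUC 95% CI**: exact binomial (Clopper–Pearson) treating
  `round(AUC·n)` successes in `n = n_cases + n_controls` trials. The
  effective `n` in this convention is not derivable from the source
  analyses; this is the tabulation convention of common clinical
  statistics packages, implemented in one place so it can be swapped.
* **DeLong paired test** for correlated AUCs via placement values, with
  the standard covariance estimator; degenerate zero-variance comparisons
  return p = 1 when the AUCs are equal and raise otherwise.
* **Operating point**: maximal Youden index `J = sens + spec − 1`; ties
  broken toward higher sensitivity, then the lower threshold in the case
  direction (the more inclusive point, appropriate for screening).
* Subjects missing a feature (e.g. the alternating-finger tapping score)
  are dropped for that feature only, with the exclusion counted.

## Cohort statistics

Group comparisons use Kruskal–Wallis (tie-corrected) as the nonparametric
omnibus, followed by a Tukey-type rank post hoc: Nemenyi on mean ranks with
the studentized-range reference (Dunn z-tests with Holm adjustment behind a
flag). "Nonparametric ANOVA with Tukey post hoc" has no unique referent;
Nemenyi is the standard Tukey-type rank procedure, and results near
p = 0.05 may differ across post hoc variants. Descriptive cells are
mean ± SD over non-missing values even though tests are rank-based. No
multiplicity correction is applied beyond the post hoc procedure itself.

Severity correlations are Spearman rank correlations (average ranks for
ties) of each feature against UPDRS-III within a patient group; p-values
are exact by full permutation enumeration for n ≤ 9 and the t
approximation with n − 2 df otherwise.

Contrasts are explicit and never pooled: newly diagnosed (de novo,
treatment-naïve) and treated early-PD patients are screened against
controls separately, because treatment changes which markers discriminate.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions of the reanalysed cohort, shipped as
`src/pdkeys/data/reference_cohort.yaml`:

* group sizes 43 / 24 / 18 (controls, de novo PD, early PD);
* log-normal hold and gap distributions whose log-scale sigmas are the
  published group `IL_SD`/`HL_SD` values divided by √2 (e.g. controls
  `IL_SD` 1.15 → σ = 0.813), with between-subject jitter set to the
  published between-subject SDs divided by √2;
* session lengths from truncated normals matching the published
  per-group sample counts (1634 ± 793 etc.);
* glitch outliers: each hold/gap independently inflated ×30–100 at the
  published per-group removal rates (0.56 / 0.40 / 0.36% of points);
* rollover: a gap becomes a negative overlap (10–90% of the preceding
  hold, preserving press order) with probability 0.5% — the source
  material states no rollover rate, but its total removal percentages
  (which include negatives) bound it below ~0.5%, so a rate at that bound
  was chosen once;
* clinical covariates from truncated group normals (UPDRS-III, sTap,
  afTap, nQi), with afTap missing for 4 controls and 5 early-PD subjects;
* severity links: a shared latent z drives UPDRS-III and, through
  configured target Spearman correlations (mapped to Pearson via
  ρ = 2·sin(π·ρₛ/6)), typing speed (−0.757 in early PD, −0.371 de novo)
  and session length (−0.733 / −0.452);
* pace: when a words-per-minute target is set, the gap location parameter
  is solved so mean press-to-press time = space_rate·60/wpm minus the
  mean hold (55 ms default — a deliberately short hold so the published
  ~100 words/min speeds are attainable with positive mean gaps);
* keys: space with rate 1/6 (≈ five letters per word), backspace 3%
  (free corrections; exercised by the restricted-key filter), letters
  otherwise.

Everything is deterministic given the master seed (numpy `SeedSequence`
spawning per group and subject).

**What the generator does not emulate**, hence what passing tests do not
show about real data: no linguistic structure (no digraph-specific timing,
no burst/pause structure, no typo-correction dynamics), no within-session
serial correlation of intervals (an AR(1) option on log-intervals is the
designated extension point), no within-subject drift, and `PL`/`RL`
fluctuation is *implied* by the HL/IL construction rather than
independently controlled — so `RL_SD` separation between groups emerges
smaller than its published counterpart. Parameter-recovery results
therefore validate the pipeline's correctness under the stated model, not
the clinical effect sizes themselves.

Two further calibration notes. First, the measured pooled removal
percentage on synthetic cohorts (~0.6–0.9%) modestly overshoots the
injected glitch rate because an inflated hold or gap also contaminates the
derived PL/RL values, and rollover negatives add to the IL removals;
whether the published percentages pooled the four kinds or counted unique
time points is unknown, so the report exposes both per-kind and pooled
figures. Second, with glitches present the elapsed-time-based typing speed
underestimates the pace target by the inflated time; at sub-percent rates
this is a few percent and rank-based analyses are unaffected.

## Numerical choices

* Sample SD (n−1) throughout; the single most likely source of
  ±0.001-level discrepancies against other implementations.
* Log-ratios are computed as `ln(v_{i+1}/v_i)` (not differences of logs)
  so constant-ratio series return exactly 0.
* Fences are computed after negative removal, on the remaining values,
  once (cleaning is idempotent in practice at `k = 12`).
* Event ordering ties are broken by (press, release, key id), making the
  reader invariant to input row shuffling.
* Reader rejects (and counts) events with release < press; timestamps are
  re-based to the session's first press, so all statistics are invariant
  to absolute time offsets.
* The `nqmitcsxpd` archive adapter is a config file with a **default
  guess** of the column mapping; the raw schema is undocumented in the
  analyses this package implements and must be validated by whoever
  downloads the archive.

## Problem sizes used in validation

The test suite validates identities on 1,000 random sessions (2–2,000
events), the fluctuation statistic against a two-pass oracle on 10,000
short series, closed-form σ recovery over 100 sessions of 1,500
keystrokes, AUC/Youden against exhaustive enumeration on 5,000 instances,
DeLong and Kruskal–Wallis calibration on 2,000 Monte-Carlo replicates, and
the end-to-end IL-vs-HL screening comparison on 100 reference cohorts —
sizes chosen to keep Monte-Carlo error well inside the asserted bands
while the whole suite runs in a couple of minutes.

## Known limitations

* The composite typing index (nQi) is consumed as a metadata column only;
  its trained model is out of scope.
* Tapping tasks (sTap/afTap) enter as scalar scores; raw tapping signals
  are not processed.
* No smoothed/binormal ROC fitting, partial AUC, or bootstrap CIs.
* The exact post hoc procedure used by the source analyses is unknowable
  from the text; pairwise p-values near 0.05 should be read with that in
  mind.
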