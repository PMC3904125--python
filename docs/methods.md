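# Methods

## Measurement model

A startle trial is scored as the maximal peak-to-peak voltage
(`max − min`) of the piezo trace within the first 200 samples
(nominal 1 ms each) after burst onset. Traces longer than the window
are truncated; shorter traces are scored whole with a warning. The
session summary is the arithmetic mean of the 30 trial amplitudes
(the source protocol does not fix mean vs median; the mean matches
its use of averages elsewhere, and a median variant is exposed as
`session_asr_median`). Baseline ASR is the mean of exactly three
pre-stress session summaries. No habituation correction is applied
across trials.

Behavioral endpoints are plain ratios of raw times: freezing,
immobility and social-zone times as percent of session time; EPM
open-arm time as percent of open + closed arm time (center excluded);
the CPA shift as post-minus-pre seconds on the shock-paired floor.
Social-zone latency is stored when present but never scored.

## Scoring

The decline ratio `(before − after)/before × 100` is undefined for
animals with no measurable baseline startle; the pipeline excludes
`baseline_asr ≤ 0` animals up front and records the exclusion, the
way such animals are dropped from a real cohort. A ratio strictly
above the 10 % cutoff is classified Declined; equality goes to
Not-Declined, the conservative side of a boundary the verbal
definition leaves open ("higher than" / "less than").

Ranks for the composite score are computed over the **pooled** cohort
(shock + control) so group comparisons of the composite live on one
scale. Orientations: freezing and immobility rank higher-is-worse;
social time, open-arm time and CPA shift rank lower-is-worse. Two of
these are genuinely contestable and therefore config-overridable:

* **CPA shift** — the protocol defines shift = post − pre (so more
  avoidance = more negative) yet describes larger shifts as more
  avoidant; we follow the arithmetic definition.
* **EPM** — shocked animals can show *more* open-arm time (escape-like
  behavior), which inverts the classical anxiety reading; we keep the
  classical lower-is-worse orientation by default.

The extreme split takes `k = round_half_up(fraction × N)` animals per
tail (fraction 0.25, so k = 5 at N = 19), with ties at the cut broken
deterministically by ascending animal id.

## Statistical battery

Two-group comparisons dispatch by a per-sample Shapiro–Wilk gate at
α = 0.05 (the normality criterion is a package choice; no specific
test was named by the protocol): both samples pass → pooled-variance
t (df n₁+n₂−2); otherwise Mann–Whitney U, reported as a tie-corrected,
continuity-corrected normal-approximation Z, or by exact enumeration
of all C(n₁+n₂, n₁) assignments when the pooled n ≤ 12. Samples too
small for the gate (n < 3) or with zero within-group variance go to
the nonparametric branch; a zero-variance pooled sample returns
t = 0, p = 1 by convention.

Repeated-measures ANOVA is fitted via statsmodels' `AnovaRM` with no
sphericity correction (Greenhouse–Geisser available as an option);
the mixed design is fitted via pingouin's `mixed_anova`, and simple
effects are per-timepoint one-way between-group ANOVAs — the only
construction that yields the (1, n−2) dfs the design's printed
statistics imply. Degenerate noise-free null cells (0/0 F ratios) are
reported as F = 0, p = 1. Spearman correlation is Pearson on average
ranks with the two-sided t-approximation p.

Everything is two-sided and **no multiple-testing correction is
applied anywhere**: the battery deliberately mirrors the
one-comparison-at-a-time reporting style of the field, and its output
should be read descriptively.

## Synthetic cohort generator

Each animal gets an independent RNG substream spawned from
`SeedSequence([seed, animal_index])`, so cohorts are reproducible and
independent of generation order. Per shocked animal:

* latent class: vulnerable with probability `vuln_prevalence`
  (default 0.459);
* 1 h decline ratio = `coupling_1h · 1[vulnerable] + N(0, σ)` with
  coupling 20 percentage points and σ = 11 points;
* 24 h decline ratio: same mixture shape, but the high component is
  entered by an independent coin flip (weight 0.585) — identical
  marginal behavior, zero predictive power;
* endpoints: one draw per test from the latent class's stratum;
* baseline ASR: lognormal, mean 1500 (arbitrary voltage units),
  CV 0.5 — the large between-animal spread typical of startle data —
  with post-stress summaries `baseline · (1 − decline/100)` and
  decline capped at 100 % (startle cannot go negative).

Controls use the control strata and pure-noise "decline ratios"
(ASR is measured at every timepoint for controls too).

**Stratum parameters.** Vulnerable and resilient strata carry the
published declined / not-declined subgroup means, with SD recovered
as SEM × √n (n = 9 and 10). Percent endpoints are drawn from a
truncated normal on [0, 100] whose *location is solved so the
truncated mean equals the stratum mean* — with a naive location the
heavily truncated social-zone stratum (mean 2.44, SD 7.8) would land
~5 points high. Under strong truncation the realized SD is smaller
than the nominal scale; means are exact, which is what the
calibration targets. The CPA shift is an untruncated normal. Control
strata are not published and are package choices (open-arm 28 %,
social 16 %, shift 0 s, immobility 17 %, freezing 12 %), set so every
shock-vs-control contrast points the observed way, including the
reversed EPM effect.

**Calibration.** `vuln_prevalence` and the 24 h weight are solved in
closed form so each shocked animal is Declined with probability 9/19
at 1 h and 11/19 at 24 h, putting the median declined counts at
exactly 9 and 11. The decline-noise SD was then tuned numerically
(cohort-level Monte-Carlo sweep) so the median within-shock Spearman
correlation between 1 h decline ratio and composite score is ≈ 0.45;
with coupling 20 the cutoff sits midway between the class means,
balancing D/ND misclassification. At this noise level about one in
five Declined animals is latently resilient, so pooled D/ND endpoint
means are diluted a few points toward each other relative to the
stratum targets (e.g. declined-subgroup immobility ≈ 34 vs the 36.6
stratum mean) — well within one published SEM, and an honest
consequence of classifying on a noisy measure.

The marginal distribution of decline ratios is **not** published; the
two-component normal mixture is an assumption of this package, chosen
as the simplest shape consistent with a binary trait. A continuous
trait would be a config-level extension.

**What the generator does not emulate:** footshock physiology,
corticosterone dynamics, startle habituation within sessions,
session-order effects, video tracking noise, or any correlation among
endpoints beyond that induced by the latent class. Passing
calibration tests therefore shows the analysis machinery recovers the
structure this model encodes — not that real cohorts satisfy the
model.

**Trial-level synthesis.** When sessions are requested, per-trial
amplitudes are positive lognormal draws rescaled so the session mean
reproduces the stored summary exactly, and the three baseline
sessions jitter around the baseline with their mean pinned to it.
Synthesized traces are a deterministic biphasic pulse (±amplitude/2)
plus optional white noise, so the noise-free peak-to-peak equals the
requested amplitude exactly.

## Problem sizes and numerical choices

Monte-Carlo checks use 500 cohorts for pooled subgroup means and
stratum-mean recovery (MC error ≪ 1 point), 200–500 for count and
correlation medians, and 10⁴ replicates for null-level calibration of
the tests (binomial SE ≈ 0.002 at α = 0.05). Truncated-normal
locations are solved by bracketing + Brent to 1e−9 and cached;
truncated draws use inverse-CDF sampling. Exact Mann–Whitney
enumeration is quadratic-factorial and capped at pooled n = 12
(C(12,6) = 924 assignments). Report CSVs round means/SEMs to one
decimal and statistics to three; JSON keeps full precision, and
nothing is rounded before testing.

## Known limitations

* The latent trait is binary; graded vulnerability would spread the
  decline distribution differently.
* Endpoints are conditionally independent given the class, so the
  composite score's variance is likely optimistic relative to real,
  positively correlated test batteries.
* The normality gate at n = 19 has modest power; borderline
  distributions will sometimes be routed to the t branch.
* Mann–Whitney Z uses the large-sample approximation at n = 19 + 19,
  as is conventional, though mid-p exact methods exist.
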