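# Methods

## The screening model

Two maximal performances are measured per subject: handgrip maximal
voluntary contraction force (MVC, decanewtons; best of up to three trials,
with the within-subject coefficient of variation as the repeatability
measure, sample-SD over mean) and maximal power on a progressive cycle
ergometer (MP, watts). Each is normalized by a normative prediction:

- **MVC (DaN)** — linear in forearm circumference (cm), sex and age:
  `2.699·circ + 5.979·[male] − 0.244·age − 22.776`. The anthropometric
  covariate is interpreted as forearm *circumference*: plausible
  circumferences (24–28 cm) put the prediction on the observed 35–45 DaN
  scale, whereas a literal forearm diameter (~8 cm) would drive it
  negative. A non-positive prediction raises an error naming the inputs
  (outside the calibration range).
- **MP (W)** — sex-specific allometric equations,
  male `245.48·h^2.7·age^−0.46`, female `157.95·h^2.8·age^−0.43` with
  height `h` in meters. Evaluated in meters the control predictions sit at
  ~200 W, the physiologic scale; centimeter heights are a unit trap and are
  rejected by a hard range guard (1.0–2.3 m). The cohort reader offers a
  `height_in_cm` dialect flag for clinical sheets that record centimeters.

The screening index is `ratio = %Pred MVC / %Pred MP`. Because a 3–5 s
isometric effort draws on the alactic anaerobic system while ~10 min of
incremental cycling is mostly aerobic, defects of intermediary metabolism
depress %Pred MP more than %Pred MVC and push the ratio above 1.

The incremental protocol is scaled to an estimated maximal power
(EMP = predicted MP × a user-supplied exercise-intolerance factor in
(0, 1], default 1; no intolerance model is built in): 2 min at 20% EMP,
then one-minute steps at 30%, 40%, …, 100% EMP, so warm-up plus eight
steps reach EMP at minute ten.

## Diagnostic accuracy

The index is a higher-is-diseased test with the positivity rule
*score ≥ cutoff*. Candidate cutoffs are the observed values plus a sentinel
above the maximum; the AUC is computed as the Mann–Whitney statistic (ties
counted ½), which equals the trapezoidal area under the empirical (1−sp,
se) polyline — both routes are asserted against each other in the tests.

- **AUC CI** — DeLong placement-value variance by default (needs raw
  scores); Hanley–McNeil (with the exponential approximation
  Q1 = A/(2−A), Q2 = 2A²/(1+A)) when only a summary AUC is available.
- **Cutoff selection** — Youden's J = se + sp − 1, maximized over observed
  values; ties break toward higher sensitivity (screening context), then
  the lower cutoff. An all-tied score set yields a flagged degenerate
  result with J = 0.
- **Likelihood ratios** — exact count fractions; 95% CIs on the log scale
  with Var(ln LR+) = (1/tp − 1/(tp+fn)) + (1/fp − 1/(fp+tn)) and the
  symmetric form for LR−; z is fixed at 1.96.
- **DOR** — (tp·tn)/(fn·fp), identical to LR+/LR−, with the Woolf log CI,
  SE = √(1/tp + 1/fn + 1/fp + 1/tn).
- **Zero cells** — estimates become 0/∞ and are flagged `unbounded`;
  an optional Haldane–Anscombe +0.5 correction on all four cells is
  available but off by default.
- **Bayes updating** — posttest odds = pretest odds × LR; a subject whose
  ratio is at or above the cutoff gets LR+, otherwise LR−.

Published rates are converted back to integer counts by rounding se·n₁ and
sp·n₀ (`confusion_from_rates`); with 23 diseased and 60 non-diseased this
recovers tp=16, tn=58 from the printed 69.6% / 96.7%.

Three printed values are *not* reproducible from exact count fractions and
are documented rather than matched: a negative likelihood ratio printed as
0.32 where (7/23)/(58/60) = 0.315 rounds to 0.31; a specificity printed as
94.6% where 33/35 forces 94.3% (the printed DOR 59.4 = 18·33/(5·2)
confirms the counts); and a DOR CI upper bound printed as 350.7 where the
log method gives 350.8. The acceptance tests pin the exact-fraction values.

## Group statistics

Per variable: group mean ± sample SD, Levene's test centered at the group
mean (the classic/SPSS default), one-way ANOVA, then pairwise post-hoc
comparisons — Scheffé (pooled error,
F_pair = (mᵢ−mⱼ)²/(MSW·(1/nᵢ+1/nⱼ)·(k−1)) on F(k−1, N−k)) when Levene's
p ≥ 0.05, Games–Howell (Welch-type t with Welch–Satterthwaite fractional
df, referred to the studentized-range distribution via t·√2) when
p < 0.05. Levene is applied per variable. P-values are two-sided; no
multiplicity correction beyond the post-hoc procedures. Zero-variance
degenerate pairs return p = 1 (equal means) or p = 0 (unequal).
Levene and the ANOVA are delegated to scipy; Scheffé and Games–Howell are
implemented here (with `scipy.stats.studentized_range` as the CDF) and
cross-checked in the tests against an independent formula oracle and
pingouin respectively.

## Synthetic cohort generator

The generator emulates the published group-level structure — five groups
with n = 35/60/10/9/4, their female/male ratios, age mean ± SD, and
%Pred MVC / %Pred MP mean ± SD — because no subject-level data are
published. Design choices:

- %Pred values are drawn directly from a truncated bivariate normal per
  group (truncation [5, 250] %; ages truncated to [18, 85] y), since the
  published distributions exist only at the %Pred level. Raw MVC and MP
  are then back-computed through the normative equations, so the
  percent-predicted layer inverts the generation exactly (asserted to
  1e−9 for every subject).
- The correlation rho between the two %Pred performances is unpublished;
  default 0, configurable. The ratio's simulated AUC rises from ≈0.77 at
  rho = 0 to ≈0.84 at rho = 0.6 (reported by the tests, not asserted).
- Heights and forearm circumferences come from sex-conditional normals
  (1.77 ± 0.07 / 1.63 ± 0.06 m; 27 ± 2 / 24 ± 2 cm), adult European
  reference values chosen once; they only carry the back-computation and
  do not affect the %Pred distributions.
- Three grip trials are emitted per subject with the best equal to the
  recorded MVC and the other two a few percent lower (half-normal
  shortfall, SD 5%), exercising the max-of-three reduction.
- One integer master seed; each group draws from its own spawned
  substream, so cohorts are reproducible and groups independent.
- Truncation whose mean lies > 4 SD outside the bounds raises an error
  rather than looping forever.

What the generator does *not* emulate: measurement error separate from
biological variation, sex/age dependence of the %Pred moments within a
group, missingness, and any real-data deviation from (truncated)
normality. Passing tests therefore validate the pipeline's statistics on
cohorts with the published moments, not the published per-subject data —
in particular the study's exact AUC of 0.843 and its CI are not
desk-reproducible and are never asserted; the simulated AUC is only
required to fall inside the published 95% CI.

## Numerical and testing choices

- All 95% intervals use z = 1.96; reports serialize floats at six
  significant digits, making pipeline re-runs byte-identical.
- Statistical tests at fixed seeds use calibrated bounds: sample means are
  standardized against the *truncated*-normal generative moments (the
  untruncated mean is the wrong target once a bound carries mass — for
  respiratory-chain %Pred MP, 67.5 ± 30.7 truncated at 5, the offset is
  ≈ +1.6), and the ten simultaneous group-mean z-scores must satisfy the
  Bonferroni 99% family bound plus a joint χ² calibration check. A
  per-cell ±2 SE rule applied to ten cells at once would fail ~40% of
  seeds by construction; the family-level version is strictly more
  sensitive to genuine generator bias. Sampler unbiasedness was verified
  separately at n = 5·10⁵ draws against closed-form truncated-normal
  moments.
- Monte-Carlo problem sizes: Levene null-uniformity 4000 replicates of
  3×60 (the F reference is asymptotic; small groups visibly deviate),
  type-I error of the full Levene→post-hoc branch 2000 replicates of
  3×10 against the family-wise 5% plus 3 binomial sigmas,
  DeLong-vs-bootstrap 10⁴ resamples, oracle sweeps 300–1000 random
  instances. The large-cohort simulation uses 2000 subjects per group.
- The Games–Howell ↔ Tukey convergence check uses moderate effect sizes
  (p ≈ 0.1–0.9) where relative agreement of p-values is well-conditioned;
  far-tail p-values amplify the Welch-vs-pooled variance difference.

## Known limitations

- The normative equations are those of the source laboratory; no
  alternative reference sets are bundled.
- Predicted peak V'O₂ is not computed (no equation is built in); a
  precomputed %Pred V'O₂ column can be supplied.
- The Bader exercise-intolerance adjustment is exposed only as the
  user-supplied EMP factor.
- Multi-class ROC, covariate-adjusted ROC and decision-curve analysis are
  out of scope.
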