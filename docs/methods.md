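# Methods

`amputebias` is a controlled-experiment pipeline for studying what listwise
deletion does to factorial and change-score ANOVA results. It emulates two
real intervention studies as seeded synthetic cohorts, deletes data from the
complete tables under declarative loss mechanisms at graded loss rates, refits
the studies' analysis models on the available cases, and measures the
percentage bias of every tracked statistic against its complete-data value.
This note records the models, the parameter choices that were genuinely open,
the numerical conventions, and what the synthetic cohorts do and do not
capture.

## Missing-data mechanisms as deletion plans

Following Rubin's taxonomy, a loss is MCAR when the deletion probability is
unrelated to any study variable, MAR when it depends only on observed
variables, and MNAR when it depends on the unobserved value itself. The
package realizes losses as *amputation plans* over a complete table:

* **MCAR** — `round(loss_rate * n)` subjects drawn uniformly without
  replacement (round-half-to-even; stated once, used everywhere).
* **MAR_STRATA** — the conditioning variable is either a categorical factor
  with declared ordered levels (e.g. sex) or a numeric column segmented at
  its P25/P75 sample percentiles into low/mid/high. The stratum weights give
  the *composition of the lost cases* — "80% boys / 20% girls" means 80% of
  the deleted subjects are boys, not that 80% of boys are deleted (the latter
  reading is incompatible with a 10% overall loss rate). The total is
  converted to exact integer per-stratum counts by largest-remainder
  rounding, ties broken by stratum order, capacity overflow reassigned in
  proportion to the remaining positive weights; a plan that cannot be placed
  raises an infeasibility error naming the strata. Within a stratum the draw
  is uniform, so the realized composition is exact, not merely expected.

The school study manipulates five conditions at 10/20/30/40% loss: MCAR;
MAR1a (sex-conditioned, weights 0.80/0.20); MAR1b (baseline-score-conditioned,
weights 0.75/0.23/0.02 over low/mid/high); and MAR2a/MAR2b, their inverses
(weights reversed across the ordered strata). The prison study manipulates
MCAR and a dependence-conditioned MAR at 10% (all losses above P75 of years
of dependence) and 30% (monotone weights 0.10/0.30/0.60 over low/mid/high,
a configurable simplex honoring "mostly the long-dependence subjects"),
always allocating losses to arms in proportion to arm size. Whether a
stratified condition is "really" MAR or MNAR depends on whether the
conditioning variable is recorded; the mechanism identifier is a label, the
package does not adjudicate.

Deletion is at the whole-subject level for the post and follow-up occasions:
baseline values of deleted subjects stay in the table and are excluded by the
downstream listwise analyses. Applying a mask never mutates the source table.

## The school cohort emulator

A 2x2x2 layout — Treatment (EG/CG) x Sex x Course (3rd/4th year) — with
n=915 and near-equal cells (largest-remainder allocation of the cell
simplex). Per subject, with effect codes x_T, x_S, x_C and a standard-normal
baseline deviation z:

    pre  = 50 + (0.562/2) x_S + (course_pre_md/2) x_C + (0.931/4) x_T x_C + 2.0 z
    gain = tau(course) (1 - 0.4 z) 1[EG] - 0.5 * 2.0 * z + u
    post = pre + gain

with tau(3P)=2.532, tau(4P)=1.601, and u zero-mean normal with variance
(sigma^2 - 1) scaled by exp(-2*0.2*z) (normalized to mean one) and by a
0.8 girls/boys variance ratio. The pieces and why:

* **Error scale.** sigma = 2.378 is derived from the published complete-data
  treatment block via F = (MD/sigma)^2 n/4 with F=145.98, MD=1.90, n=915. The
  published post-score and change-score blocks imply *equal* error SDs on the
  two scales; with an independent baseline that is impossible (post error
  would exceed change error by the baseline variance), so baseline and gain
  are drawn jointly with a gain-on-baseline regression slope of -0.5
  (regression to the mean), which makes Var(pre + gain) = Var-component of
  gain exactly. The implied baseline-gain correlation is -0.42 and the
  pre/post correlation about 0.5.
* **Baseline imbalance.** The published analyses select an *additive* model
  for the post score while the change score carries a clear
  treatment-by-course interaction. Since post = pre + gain, this is only
  possible if the baseline carries an offsetting course-by-treatment
  imbalance — exactly what a non-equivalent control-group design produces.
  The emulator therefore gives the baseline a pure interaction contrast of
  +0.931 (= 2.532 - 1.601), leaving the baseline treatment main effect at
  zero (the published baseline check) and the post-score interaction at zero.
* **Why sex and course live on the baseline.** The sex difference (MD 0.562)
  and most of the course difference appear in the post score but not in the
  change score, so they are generated as baseline differences; the course
  effect on post (0.833) is the sum of a baseline course gap and the
  course-specific treatment gain averaged over arms.
* **Informative structure.** Treatment gains decline with baseline ability
  (slope 0.4 SD^-1 of the subject's course effect) and residual spread
  shrinks with baseline ability (exp(-0.2 z)) and is 20% smaller for girls.
  These three parameters are not printed anywhere; they encode the study's
  qualitative statements (girls respond better and more homogeneously;
  weaker starters respond differently; the strong starters who remain under
  baseline-conditioned loss respond more homogeneously) and they are what
  makes MAR1a/MAR1b/MAR2a/MAR2b informative. The modification and
  heteroscedasticity defaults were fixed analytically at design time so that
  each mechanism's population bias direction (below) has a strictly positive
  margin at every loss rate; they are deliberately moderate and are ordinary
  spec fields, not constants.

Consequences the package's own tests verify: MCAR leaves MSe unbiased;
MAR1b biases MSe, partial eta^2 and MD downward, monotonically in the loss
rate, MAR2b upward; F falls under every mechanism (sample-size loss
dominates); the additive model is selected for the post score and the
interaction model for the change score on complete data. One known gap: the
published treatment MD on the post score is 1.90 while the two printed
simple effects average 2.07 — the emulator honors the simple effects, so its
post-score treatment MD and F run above the printed 1.90/145.98 (the derived
sigma is checked instead by a dedicated simulation with the simple effects
scaled to average exactly 1.90).

## The prison cohort emulator

n=50 women randomized 19/18/13 to CBT, ACT and a control group; outcomes ASI
Total, ASI Cognitive (lower = better) and AAQ-II (higher = better) at pre,
post and 6 months. Years of dependence is generated by a quantile-matching
sampler: stratified uniforms pushed through a monotone piecewise-linear
quantile function pinned at the published quartiles (10, 16.5, 20.25) with
density-continuous Gaussian tails, floored at 0.5 years — the printed
quartiles are asymmetric, so forcing a normal would miss them. Outcome
baselines correlate with standardized years of dependence at 0.35 (ASI
Total, significant at n=50), 0.22 (ASI Cognitive, positive but not
significant) and 0.0 (AAQ-II). Change scores are group shifts plus a
dependence trend (slope 1.0 / 0.6 / 0 score units per SD) plus
heteroscedastic noise widening with dependence — long-dependence subjects
respond worse and less consistently, which is what makes the
dependence-conditioned MAR conditions informative.

The post-change noise SD of the two ASI outcomes is *calibrated in closed
form* from the published group effects: with group shifts delta_g, the
population noncentrality sum(n_g (delta_g - mean)^2)/sigma_c^2 is set equal
to F*df1 for the printed F (5.52 and 6.84, i.e. partial eta^2 0.190 and
0.225). Shift profiles are config, not code: ASI Total (-6, 0, +2),
ASI Cognitive (-4, -2.5, +1.5), AAQ-II (+4, +3.5, 0) with change SD 7 (no
F is printed for AAQ-II). Follow-up shifts encode the published qualitative
pattern (CBT drifts back toward baseline, ACT keeps improving, the control
group does not recover); the AAQ-II follow-up shifts are set so the
treated-arm change rates are about +19% (CBT) and +26% (ACT) of baseline,
the published improvement readings. The complete table is complete; the
18% follow-up dropout (4/3/2 per arm, uniform within arm) is emitted as a
preset deletion mask and applied to every follow-up analysis, complete or
amputed. The published follow-up error df of 39 is internally inconsistent
with 41 retained subjects in three groups; the engine reports its own df
(38).

## The analysis engine

Least-squares fits with sum-to-zero factor coding; Type-III sums of squares
(each term's SS is the SSE increase when its columns leave the full design),
the convention professional packages apply to unbalanced data, identical to
the sequential decomposition on balanced data. Per effect the engine reports
error df, MSe, F, p (central F), partial eta^2 = SS/(SS+SSE) =
F df1/(F df1 + df2), observed power as P(F' > F_crit) for F' noncentral with
lambda = F df1 at alpha = 0.05 (the convention that reproduces the published
post-hoc powers to three decimals; one printed power, 0.902 for F=5.52 with
df (2,47), does not reproduce under any standard convention — the neighbour
block prints 0.904 which does, so it is treated as a typo), and the mean
difference of model-based marginal means with off-factor levels equally
weighted (never raw means — under amputation the cells are unbalanced).
Simple effects test one factor inside each level of another via linear
contrasts on the full model's coefficients, using the pooled MSe and error
df. Model selection is hierarchical over a candidate list: every candidate
term is tested in one encompassing Type-III fit, an interaction enters iff
p < alpha, a main effect is retained iff p < alpha or required by an
included interaction, and the candidate matching the inclusion set wins
(nearest by symmetric difference on ties, earlier candidate first).

Numerical conventions: sample quantiles use linear interpolation (numpy
default) everywhere, with cutpoint ties assigned to the middle stratum; a
residual SS below 1e-12 of the response's total SS is treated as an exact
zero fit, whose nonzero effects report an infinite F, eta^2 = 1, power 1;
an empty design cell raises an inestimability error naming the cell rather
than silently dropping a term.

Bias is 100 (theta_available - theta_complete)/theta_complete, undefined at a
zero reference. Across the loss-rate set of one mechanism the statistic's
mean values are summarized by mean, sample SD (n-1) and CV = SD/M (flagged
undefined at M = 0). The clinical change rate (ChR) is a group's mean change
as a percentage of its baseline mean, sign-adjusted by the outcome's
improvement direction; the denominator convention (baseline mean) is the
package's own definition, validated only against the published qualitative
readings.

## Replication and seeding

The original demonstration appears to ampute once per condition; a single
draw confounds mechanism effects with draw noise, so the package defaults to
200 replicated amputations per condition and reports Monte-Carlo means (set
`replications=1` to mimic a single-draw reading). Every condition cell's
seed derives from the grid's base seed plus stable keys (study, mechanism
name, rate, replicate) via `SeedSequence`, collision-checked, so any cell is
reproducible in isolation, results are invariant to which other conditions
run alongside, and a manifest round-trip reproduces byte-identical outputs.
The cohort is generated once per grid; bias is therefore *paired* — each
amputed fit is compared with the complete fit of the same cohort — which
removes cohort-level noise from the bias estimates. Default problem sizes
(n=915 and n=50 cohorts, 200 replicates, 200 selection cohorts) keep the
full school grid under two minutes on one CPU.

## What the emulator does not capture

Synthetic cohorts reproduce the published summary structure, not the data:
real PROLEC-R and ASI/AAQ-II instruments are bounded, discrete and skewed
where the emulator is Gaussian; outcome-to-outcome correlations within
subject and school/prison clustering are not modeled; the prison outcomes
are mutually independent given years of dependence; post-change and
follow-up-change noises are independent. Passing tests therefore show that
the *mechanism arithmetic and the direction and ordering of listwise-deletion
bias* behave as published under a faithful population structure — not that
the original record-level tables are reproduced (their raw data and the
supplementary bias tables are not public). Cell-level (intermittent)
missingness, multiple imputation, maximum-likelihood and MNAR-model recovery
are out of scope: the demonstration is about what goes wrong, not about
repairing it.
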