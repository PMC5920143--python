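"""Synthetic cohorts emulating the two demonstration studies.

Two generators are provided:

``generate_school_cohort``
    A quasi-experimental school cohort (default n=915): a 2x2x2 layout of
    Treatment (EG/CG) x Sex (girl/boy) x Course (3P/4P) with a pre and a post
    reading score. The data-generating model draws the baseline score and the
    pre-to-post gain jointly, with a negative baseline-gain correlation
    (regression to the mean) calibrated so that the post-score ANOVA and the
    change-score ANOVA have the same error standard deviation -- the structure
    the published complete-data F blocks imply. The treatment effect is
    course-specific, declines with baseline ability, and the residual spread
    shrinks with baseline ability and is smaller for girls; these features are
    what make loss mechanisms conditioned on sex or on the baseline score
    informative rather than innocuous.

``generate_prison_cohort``
    A small randomized trial (n=50) of two therapies (CBT, ACT) against a
    control group for substance-use disorder in a women's prison, with three
    outcomes (ASI Total, ASI Cognitive, AAQ-II) at pre, post and a 6-month
    follow-up, a "years of dependence" covariate hitting stated quartiles, and
    a preset follow-up dropout mask (4/3/2 per group = 18%) emitted alongside
    the complete table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ParameterError
from .table import StudyTable, make_table

__all__ = [
    "SchoolCohortSpec",
    "OutcomeDef",
    "PrisonCohortSpec",
    "generate_school_cohort",
    "generate_prison_cohort",
    "derive_residual_sd",
    "implied_f",
]

TREATMENT_LEVELS = ["CG", "EG"]
SEX_LEVELS = ["boy", "girl"]
COURSE_LEVELS = ["3P", "4P"]
PRISON_GROUPS = ["CBT", "ACT", "CG"]


def derive_residual_sd(mean_difference: float, n: float, f_value: float) -> float:
    """Error SD implied by a balanced two-level main effect.

    For a balanced design with ``n`` subjects split over two levels,
    ``F = (MD/sigma)^2 * n / 4``; solving for sigma gives the residual SD
    consistent with a printed (F, MD, n) triplet.
    """
    if f_value <= 0 or n <= 0:
        raise ParameterError("n and f_value must be positive")
    return abs(mean_difference) * math.sqrt(n / (4.0 * f_value))


def implied_f(mean_difference: float, n: float, residual_sd: float) -> float:
    """Inverse of :func:`derive_residual_sd`."""
    return (mean_difference / residual_sd) ** 2 * n / 4.0


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    shares = total * np.asarray(weights, dtype=float)
    counts = np.floor(shares).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(shares - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# School cohort
# ---------------------------------------------------------------------------

@dataclass
class SchoolCohortSpec:
    """Parameters of the school-cohort emulator.

    Effects are in raw score units of the reading test. ``residual_sd`` is the
    error SD of both the post-score and change-score ANOVAs; the default is
    derived from the published complete-data treatment block (F=145.98,
    MD=1.90, n=915) via ``derive_residual_sd``.
    """

    n_subjects: int = 915
    effect_treatment: float = 1.90
    effect_sex: float = 0.562
    effect_course: float = 0.833
    simple_effect_3P: float = 2.532
    simple_effect_4P: float = 1.601
    residual_sd: float = field(
        default_factory=lambda: derive_residual_sd(1.90, 915, 145.98)
    )
    pre_mean: float = 50.0
    pre_sd: float = 2.0
    # cells ordered as the cross (treatment, sex, course) with course fastest
    cell_proportions: tuple = tuple([1.0 / 8] * 8)
    seed: int | None = None
    # secondary shape parameters (see docs/methods.md)
    sex_variance_ratio: float = 0.8
    effect_modification: float = 0.4
    heteroscedasticity: float = 0.2
    maturation: float = 0.0
    baseline_interaction: float | None = None
    gain_regression: float = -0.5

    def __post_init__(self) -> None:
        if self.baseline_interaction is None:
            # baseline course-by-treatment imbalance that exactly offsets the
            # change-score interaction on the post scale (non-equivalent groups)
            self.baseline_interaction = self.simple_effect_3P - self.simple_effect_4P
        self.validate()

    def validate(self) -> None:
        props = np.asarray(self.cell_proportions, dtype=float)
        if props.shape != (8,) or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ParameterError("cell_proportions must be a simplex over 8 cells")
        if self.residual_sd <= 0:
            raise ParameterError("residual_sd must be positive")
        if self.pre_sd <= 0:
            raise ParameterError("pre_sd must be positive")
        if self.residual_sd ** 2 <= (self.gain_regression * self.pre_sd) ** 2:
            raise ParameterError(
                "residual_sd too small for the requested baseline-gain regression"
            )
        if self.sex_variance_ratio <= 0:
            raise ParameterError("sex_variance_ratio must be positive")
        if self.n_subjects < 16:
            raise ParameterError("need at least two subjects per design cell")
        avg_simple = self.change_treatment_md
        if abs(avg_simple - self.effect_treatment) > 0.25:
            raise ParameterError(
                "simple effects must average to approximately effect_treatment "
                f"(got {avg_simple:.3f} vs {self.effect_treatment:.3f})"
            )

    # -- derived design quantities -----------------------------------------
    @property
    def change_treatment_md(self) -> float:
        """Population treatment MD in the change-score metric (courses equally weighted)."""
        props = np.asarray(self.cell_proportions, dtype=float).reshape(2, 2, 2)
        course_w = props.sum(axis=(0, 1))
        course_w = course_w / course_w.sum()
        return float(
            course_w[0] * self.simple_effect_3P + course_w[1] * self.simple_effect_4P
        )

    @property
    def course_pre_md(self) -> float:
        """Course MD carried by the baseline so the post-score course MD equals effect_course."""
        change_course_md = (self.simple_effect_4P - self.simple_effect_3P) / 2.0
        return self.effect_course - change_course_md

    @property
    def post_error_sd(self) -> float:
        """Error SD of the post-score ANOVA implied by the joint baseline-gain
        model, before the treated-arm effect-modification variance."""
        b = self.gain_regression
        s1, s2 = self.pre_sd, self.residual_sd
        return math.sqrt((1 + b) ** 2 * s1 ** 2 + (s2 ** 2 - b ** 2 * s1 ** 2))


def generate_school_cohort(spec: SchoolCohortSpec) -> StudyTable:
    """Draw a complete school cohort under ``spec``.

    The model, per subject i with effect-coded factors x_T (EG=+1), x_S
    (girl=+1), x_C (4P=+1) and standard-normal baseline deviation z_i::

        pre_i    = pre_mean + (effect_sex/2) x_S + (course_pre_md/2) x_C
                   + (baseline_interaction/4) x_T x_C + pre_sd * z_i
        gain_i   = maturation + tau_i 1[EG] + gain_regression * pre_sd * z_i + u_i
        post_i   = pre_i + gain_i

    where tau_i = simple_effect(course) * (1 - effect_modification * z_i) and
    Var(u_i) = (residual_sd^2 - (gain_regression*pre_sd)^2) scaled by the
    sex-variance ratio and by exp(-2*heteroscedasticity*z_i) (normalized to
    mean one). There is no treatment main effect on the baseline.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    counts = _largest_remainder(n, np.asarray(spec.cell_proportions))
    treatment, sex, course = [], [], []
    for idx, c in enumerate(counts):
        t, s, k = idx >> 2 & 1, idx >> 1 & 1, idx & 1
        treatment += [TREATMENT_LEVELS[t]] * c
        sex += [SEX_LEVELS[s]] * c
        course += [COURSE_LEVELS[k]] * c
    treatment = np.array(treatment)
    sex = np.array(sex)
    course = np.array(course)
    x_t = np.where(treatment == "EG", 1.0, -1.0)
    x_s = np.where(sex == "girl", 1.0, -1.0)
    x_c = np.where(course == "4P", 1.0, -1.0)

    z = rng.standard_normal(n)
    pre = (
        spec.pre_mean
        + 0.5 * spec.effect_sex * x_s
        + 0.5 * spec.course_pre_md * x_c
        + 0.25 * spec.baseline_interaction * x_t * x_c
        + spec.pre_sd * z
    )

    tau_course = np.where(course == "4P", spec.simple_effect_4P, spec.simple_effect_3P)
    tau = np.where(x_t > 0, tau_course * (1.0 - spec.effect_modification * z), 0.0)

    h = spec.heteroscedasticity
    het_w = np.exp(-2.0 * h * z) / math.exp(2.0 * h * h)  # E[het_w] = 1
    vr = spec.sex_variance_ratio
    sex_w = np.where(x_s > 0, 2.0 * vr / (1.0 + vr), 2.0 / (1.0 + vr))
    u_var = (spec.residual_sd ** 2 - (spec.gain_regression * spec.pre_sd) ** 2)
    u = rng.standard_normal(n) * np.sqrt(u_var * het_w * sex_w)

    gain = spec.maturation + tau + spec.gain_regression * spec.pre_sd * z + u
    post = pre + gain

    return make_table(
        {
            "subject_id": np.arange(1, n + 1),
            "treatment": treatment,
            "sex": sex,
            "course": course,
            "pre": pre,
            "post": post,
        },
        factors={
            "treatment": TREATMENT_LEVELS,
            "sex": SEX_LEVELS,
            "course": COURSE_LEVELS,
        },
        occasions={"pre": ["pre"], "post": ["post"]},
    )


# ---------------------------------------------------------------------------
# Prison cohort
# ---------------------------------------------------------------------------

@dataclass
class OutcomeDef:
    """One repeated outcome of the prison trial.

    ``post_shift`` / ``followup_shift`` are population mean change scores per
    group (post-pre and 6m-pre). ``change_sd`` is the total error SD of the
    one-way change-score ANOVA; if ``f_target`` is given instead, change_sd is
    calibrated so the population noncentrality reproduces that F statistic
    (lambda = F * df1). ``dependence_slope`` moves the individual change score
    with the standardized years-of-dependence covariate and
    ``dependence_heteroscedasticity`` widens the residual spread with it,
    making dependence-conditioned losses informative. ``improvement`` states
    the direction that counts as clinical improvement.
    """

    name: str
    baseline_mean: float
    baseline_sd: float
    rho_dependence: float
    post_shift: Mapping[str, float]
    followup_shift: Mapping[str, float]
    change_sd: float | None = None
    f_target: float | None = None
    dependence_slope: float = 0.0
    dependence_heteroscedasticity: float = 0.0
    improvement: str = "lower"  # "lower" or "higher" is better

    def validate(self, group_sizes: Sequence[int]) -> None:
        if self.baseline_sd <= 0:
            raise ParameterError(f"{self.name}: baseline_sd must be positive")
        if not -1.0 <= self.rho_dependence <= 1.0:
            raise ParameterError(f"{self.name}: rho_dependence outside [-1, 1]")
        if self.improvement not in ("lower", "higher"):
            raise ParameterError(f"{self.name}: improvement must be 'lower' or 'higher'")
        for shift in (self.post_shift, self.followup_shift):
            if set(shift) != set(PRISON_GROUPS):
                raise ParameterError(f"{self.name}: shifts must cover groups {PRISON_GROUPS}")
        if (self.change_sd is None) == (self.f_target is None):
            raise ParameterError(
                f"{self.name}: exactly one of change_sd / f_target must be set"
            )
        if self.resolved_change_sd(group_sizes) ** 2 <= self.dependence_slope ** 2:
            raise ParameterError(f"{self.name}: change_sd too small for dependence_slope")

    def resolved_change_sd(self, group_sizes: Sequence[int]) -> float:
        if self.change_sd is not None:
            return self.change_sd
        n_g = np.asarray(group_sizes, dtype=float)
        delta = np.array([self.post_shift[g] for g in PRISON_GROUPS])
        lam = self.f_target * (len(PRISON_GROUPS) - 1)
        between = float(np.sum(n_g * (delta - np.average(delta, weights=n_g)) ** 2))
        if between <= 0:
            raise ParameterError(f"{self.name}: f_target needs a non-flat shift profile")
        return math.sqrt(between / lam)


def _default_outcomes() -> list[OutcomeDef]:
    return [
        OutcomeDef(
            name="asi_total",
            baseline_mean=30.0,
            baseline_sd=8.0,
            rho_dependence=0.35,
            post_shift={"CBT": -6.0, "ACT": 0.0, "CG": 2.0},
            followup_shift={"CBT": -2.0, "ACT": -3.0, "CG": 2.0},
            f_target=5.52,
            dependence_slope=1.0,
            dependence_heteroscedasticity=0.2,
            improvement="lower",
        ),
        OutcomeDef(
            name="asi_cognitive",
            baseline_mean=12.0,
            baseline_sd=4.0,
            rho_dependence=0.22,
            post_shift={"CBT": -4.0, "ACT": -2.5, "CG": 1.5},
            followup_shift={"CBT": -2.5, "ACT": -4.0, "CG": -0.5},
            f_target=6.84,
            dependence_slope=0.6,
            dependence_heteroscedasticity=0.2,
            improvement="lower",
        ),
        OutcomeDef(
            name="aaq",
            baseline_mean=32.0,
            baseline_sd=8.0,
            rho_dependence=0.0,
            post_shift={"CBT": 4.0, "ACT": 3.5, "CG": 0.0},
            followup_shift={"CBT": 6.2, "ACT": 8.45, "CG": 0.0},
            change_sd=7.0,
            improvement="higher",
        ),
    ]


@dataclass
class PrisonCohortSpec:
    group_sizes: tuple = (19, 18, 13)  # CBT, ACT, CG
    dependence_quantiles: tuple = (10.0, 16.5, 20.25)  # P25, P50, P75, in years
    outcome_defs: list = field(default_factory=_default_outcomes)
    followup_dropout: tuple = (4, 3, 2)  # per group, 18% of 50
    years_floor: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        if sum(self.group_sizes) != 50:
            raise ParameterError("group_sizes must sum to 50")
        q = self.dependence_quantiles
        if not (q[0] < q[1] < q[2]):
            raise ParameterError("dependence_quantiles must be strictly increasing")
        if any(d > g for d, g in zip(self.followup_dropout, self.group_sizes)):
            raise ParameterError("followup_dropout exceeds a group size")
        for od in self.outcome_defs:
            od.validate(self.group_sizes)


def _dependence_quantile_function(
    u: np.ndarray, quantiles: Sequence[float], floor: float
) -> np.ndarray:
    """Monotone quantile transform through the three stated quartiles.

    Piecewise linear between P25/P50/P75, with density-continuous Gaussian
    tails outside, floored at ``floor`` years. The stated quartiles are
    asymmetric, so a plain normal cannot be forced through them.
    """
    p25, p50, p75 = quantiles
    z25 = stats.norm.ppf(0.25)
    phi25 = stats.norm.pdf(z25)
    slope_low = (p50 - p25) / 0.25
    slope_high = (p75 - p50) / 0.25
    out = np.empty_like(u, dtype=float)
    lo, hi = u < 0.25, u > 0.75
    mid_lo = (~lo) & (u <= 0.5)
    mid_hi = (~hi) & (u > 0.5)
    out[mid_lo] = p25 + slope_low * (u[mid_lo] - 0.25)
    out[mid_hi] = p50 + slope_high * (u[mid_hi] - 0.5)
    out[lo] = p25 + slope_low * phi25 * (stats.norm.ppf(u[lo]) - z25)
    out[hi] = p75 + slope_high * phi25 * (-z25 - stats.norm.isf(u[hi]))
    return np.maximum(out, floor)


def generate_prison_cohort(spec: PrisonCohortSpec):
    """Draw the complete 50-subject trial table and its preset dropout mask.

    Returns ``(table, dropout_mask)``. The table itself is complete: the
    6-month dropout (4/3/2 per group) is a planned deletion emitted as a
    :class:`~amputebias.amputation.DeletionMask` over the follow-up occasion,
    applied downstream like any other mask.
    """
    from .amputation import DeletionMask  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.group_sizes)

    # quantile-matched covariate: stratified uniforms through the quartile map
    u = rng.permutation((np.arange(n) + 0.5) / n)
    years = _dependence_quantile_function(u, spec.dependence_quantiles, spec.years_floor)
    z_years = (years - years.mean()) / years.std(ddof=1)

    group = rng.permutation(
        np.repeat(PRISON_GROUPS, spec.group_sizes)
    )

    columns: dict = {
        "subject_id": np.arange(1, n + 1),
        "group": group,
        "years_dependence": years,
    }
    occasions: dict[str, list[str]] = {"pre": [], "post": [], "followup": []}
    for od in spec.outcome_defs:
        rho = od.rho_dependence
        e = rng.standard_normal(n)
        pre = od.baseline_mean + od.baseline_sd * (
            rho * z_years + math.sqrt(1.0 - rho ** 2) * e
        )
        sd_eff = od.resolved_change_sd(spec.group_sizes)
        g = od.dependence_heteroscedasticity
        het = np.exp(2.0 * g * z_years) / math.exp(2.0 * g * g)
        noise_sd = np.sqrt((sd_eff ** 2 - od.dependence_slope ** 2) * het)
        shift_post = np.vectorize(od.post_shift.get)(group).astype(float)
        shift_fu = np.vectorize(od.followup_shift.get)(group).astype(float)
        trend = od.dependence_slope * z_years
        post = pre + shift_post + trend + rng.standard_normal(n) * noise_sd
        fu = pre + shift_fu + trend + rng.standard_normal(n) * noise_sd
        columns[f"{od.name}_pre"] = pre
        columns[f"{od.name}_post"] = post
        columns[f"{od.name}_fu6"] = fu
        occasions["pre"].append(f"{od.name}_pre")
        occasions["post"].append(f"{od.name}_post")
        occasions["followup"].append(f"{od.name}_fu6")

    table = make_table(
        columns,
        factors={"group": PRISON_GROUPS},
        covariates=["years_dependence"],
        occasions=occasions,
    )

    dropped: list[int] = []
    counts = {}
    ids = table.data["subject_id"].to_numpy()
    for g_name, k in zip(PRISON_GROUPS, spec.followup_dropout):
        pool = ids[group == g_name]
        dropped += list(rng.choice(pool, size=k, replace=False))
        counts[g_name] = k
    mask = DeletionMask(
        deleted_subject_ids=frozenset(int(i) for i in dropped),
        realized_counts_per_stratum=counts,
        target_total=sum(spec.followup_dropout),
    )
    return table, mask
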