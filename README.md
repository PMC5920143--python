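# amputebias

**Planned missing-data amputation and the cost of listwise deletion.**

Dropping incomplete cases is still the default reflex in much of applied
clinical and educational research. This package is a controlled-experiment
pipeline that makes the consequences measurable: it emulates two real
intervention studies as seeded synthetic cohorts, deletes data from the
complete tables under declarative MCAR/MAR-style mechanisms at graded loss
rates (PdL 10–40%), refits the studies' ANOVA models on the
listwise-available cases, and quantifies how every reported statistic —
MSe, F, partial η², and the estimated mean difference — drifts from its
complete-data value. It is written for methodologists and applied
researchers who want to run loss-sensitivity experiments on study-shaped
data without access to the original records.

The two emulated designs:

* **School study** — quasi-experimental, n = 915 children in a 2×2×2 layout
  (Treatment EG/CG × Sex × Course 3°P/4°P) with pre/post reading scores;
  analyzed by a Type-III factorial ANOVA on the post score and on the change
  score (post − pre), with simple effects of the treatment-by-course
  interaction.
* **Prison trial** — randomized, n = 50 women (CBT 19 / ACT 18 / control 13)
  with ASI Total, ASI Cognitive and AAQ-II at pre/post/6-month follow-up, a
  years-of-dependence covariate hitting the quartiles (10, 16.5, 20.25), and
  a preset 18% follow-up dropout (4/3/2 per arm); analyzed by one-way
  change-score ANOVAs.

Core quantities, in the usual notation: partial
η² = SS_eff/(SS_eff + SS_err) = F·df₁/(F·df₁ + df₂); observed power
1−β = P(F′ > F_crit(α, df₁, df₂)) with F′ noncentral-F at λ = F·df₁;
percentage bias 100·(θ̂_available − θ̂_complete)/θ̂_complete; and the
clinical change rate ChR = 100·(mean change)/(baseline mean), sign-adjusted
for the outcome's improvement direction. Loss mechanisms are *compositions
of the lost cases* over strata (e.g. 80% boys / 20% girls; 75/23/2 over
baseline-score terciles), realized as exact integer allocations by
largest-remainder rounding, drawn uniformly within strata.

## Worked example

```python
import numpy as np
import amputebias as ab
from amputebias.experiment import school_statistics, derive_seed
from amputebias.amputation import school_mechanisms

cohort = ab.generate_school_cohort(ab.SchoolCohortSpec(seed=11))
complete, _ = school_statistics(cohort)

mech = school_mechanisms(0.30)["MAR1b"]      # 30% loss, mostly weak starters
stats = ("ms_error", "f_value", "partial_eta_sq", "mean_difference")
bias = {s: [] for s in stats}
for rep in range(50):                        # replicated amputations
    mask = ab.ampute(cohort, mech, seed=derive_seed(11, rep))
    available, _ = school_statistics(ab.apply_mask(cohort, mask))
    for s in stats:
        bias[s].append(ab.bias_percent(available["post_treatment"][s],
                                       complete["post_treatment"][s]))
for s in stats:
    print(f"{s:16s} complete {complete['post_treatment'][s]:8.3f}   "
          f"mean bias over 50 amputations {np.mean(bias[s]):+6.1f}%")
```

prints

```
ms_error         complete    4.998   mean bias over 50 amputations  -12.1%
f_value          complete  208.159   mean bias over 50 amputations  -34.5%
partial_eta_sq   complete    0.186   mean bias over 50 amputations   -5.3%
mean_difference  complete    2.133   mean bias over 50 amputations   -9.2%
```

— a 30% loss concentrated on the weakest starters (MAR1b: 75% of the lost
cases from below P25 of the baseline) leaves a sample whose retained pupils
respond more homogeneously and less strongly: the error variance, the effect
size and the estimated treatment benefit are all understated relative to the
complete data, while under MCAR at the same rate the same statistics stay
within Monte-Carlo error of their complete-data values (only F falls, with
the sample size). Any single amputation is noisier than these means — which
is exactly why the pipeline replicates deletions instead of drawing once.
The full grids live in the numbered drivers:

```bash
python analysis/01_generate_cohorts.py --seed 0        # cohorts + schemas
python analysis/02_complete_data_analysis.py --seed 0  # complete-data reference blocks
python analysis/03_school_loss_grid.py --seed 0        # 5 mechanisms x 4 rates x 200
python analysis/04_prison_loss_grid.py --seed 0        # 2 mechanisms x 2 rates x 200
```

(`03` writes, among others, `results/school/wide_bias__post_treatment.csv`,
whose MAR1b row for MSe reads −4.3 / −9.8 / −18.1 / −22.4% across the
10/20/30/40% loss rates, and whose MCAR row stays within ±0.2%.) The same
pipeline is scriptable from a shell via the `amputebias` CLI
(`generate`, `ampute`, `analyze`, `demo`, `report`; YAML configs; exit
codes 2 = config error, 3 = infeasible plan).

## Layout

```
src/amputebias/    cohorts | amputation | anova | bias | experiment | config | cli
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit, property, acceptance)
docs/methods.md    models, calibration, conventions, limitations
```
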