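"""Orchestration of the full missing-data demonstration grid.

One :class:`ExperimentGrid` names a study (``school`` or ``prison``), the
loss mechanisms and loss rates to manipulate, and the number of replicated
amputations per condition. ``run_demonstration`` generates the study cohort
once, fits the complete-data analyses, and then for every condition cell
(mechanism x rate x replicate) amputes, refits on the listwise-available
data, and records the percentage bias of every tracked statistic (MSe, F,
partial eta-squared, MD) against the complete-data value.

Seeding is explicit and collision-checked: each cell's seed derives from the
grid's base seed plus stable condition keys, so any single condition can be
reproduced in isolation and results are invariant to which other conditions
run alongside.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .amputation import (
    DeletionMask,
    MechanismSpec,
    ampute,
    ampute_study2_mar,
    apply_mask,
    school_mechanisms,
)
from .anova import ModelSpec, fit_anova, simple_effects
from .bias import BiasSummary, bias_percent
from .cohorts import (
    PrisonCohortSpec,
    SchoolCohortSpec,
    generate_prison_cohort,
    generate_school_cohort,
)
from .errors import InestimableTermError, InfeasiblePlanError, ParameterError
from .table import StudyTable

__all__ = [
    "ExperimentGrid",
    "RunResult",
    "DemonstrationResult",
    "run_demonstration",
    "write_report",
    "derive_seed",
    "school_grid",
    "prison_grid",
    "SCHOOL_POST_MODEL",
    "SCHOOL_CHANGE_MODEL",
    "TRACKED_STATISTICS",
]

TRACKED_STATISTICS = ("ms_error", "f_value", "partial_eta_sq", "mean_difference")

SCHOOL_POST_MODEL = ModelSpec(
    "post", ("treatment", "sex", "course"), (("treatment",), ("sex",), ("course",))
)
SCHOOL_CHANGE_MODEL = ModelSpec(
    "change",
    ("treatment", "course"),
    (("treatment",), ("course",), ("treatment", "course")),
)

_STUDY_CODE = {"school": 1, "prison": 2}

_SCHOOL_FACTORS = ("treatment", "sex", "course")


def school_post_candidates() -> list[ModelSpec]:
    """Candidate models for the post-score analysis.

    The additive model and the models adding or dropping the substantive
    treatment-by-course interaction; sex may drop out.
    """
    mains = (("treatment",), ("sex",), ("course",))
    tc = ("treatment", "course")
    return [
        ModelSpec("post", _SCHOOL_FACTORS, mains),
        ModelSpec("post", _SCHOOL_FACTORS, mains + (tc,)),
        ModelSpec("post", _SCHOOL_FACTORS, (("treatment",), ("course",))),
        ModelSpec("post", _SCHOOL_FACTORS, (("treatment",), ("course",), tc)),
    ]


def school_change_candidates() -> list[ModelSpec]:
    """Candidate models for the change-score analysis."""
    tc = ("treatment", "course")
    return [
        ModelSpec("change", _SCHOOL_FACTORS, (("treatment",), ("sex",), ("course",))),
        ModelSpec("change", _SCHOOL_FACTORS, (("treatment",), ("course",), tc)),
        ModelSpec(
            "change", _SCHOOL_FACTORS, (("treatment",), ("sex",), ("course",), tc)
        ),
    ]


def derive_seed(base_seed: int, *keys) -> int:
    """Stable per-condition seed below 2^31."""
    ints = [int(base_seed)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()))
        elif isinstance(k, float):
            ints.append(int(round(k * 1000)))
        else:
            ints.append(int(k))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class ExperimentGrid:
    study: str
    mechanisms: tuple
    loss_rates: tuple
    replications: int
    base_seed: int

    def __post_init__(self) -> None:
        if self.study not in _STUDY_CODE:
            raise ParameterError(f"unknown study {self.study!r}")
        if self.replications < 1:
            raise ParameterError("replications must be >= 1")
        for r in self.loss_rates:
            if not 0.0 < r < 1.0:
                raise ParameterError(f"loss rate {r} outside (0, 1)")
        object.__setattr__(self, "mechanisms", tuple(self.mechanisms))
        object.__setattr__(self, "loss_rates", tuple(float(r) for r in self.loss_rates))
        seeds = {}
        for key, seed in self.cell_seeds().items():
            if seed in seeds and seeds[seed] != key:
                raise ParameterError(f"seed collision between {seeds[seed]} and {key}")
            seeds[seed] = key

    def cell_seeds(self) -> dict:
        code = _STUDY_CODE[self.study]
        return {
            (m, r, rep): derive_seed(self.base_seed, code, m, r, rep)
            for m in self.mechanisms
            for r in self.loss_rates
            for rep in range(self.replications)
        }

    def cohort_seed(self) -> int:
        return derive_seed(self.base_seed, _STUDY_CODE[self.study], "cohort")

    def to_dict(self) -> dict:
        return {
            "study": self.study,
            "mechanisms": list(self.mechanisms),
            "loss_rates": list(self.loss_rates),
            "replications": self.replications,
            "base_seed": self.base_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentGrid":
        return cls(
            study=d["study"],
            mechanisms=tuple(d["mechanisms"]),
            loss_rates=tuple(d["loss_rates"]),
            replications=int(d["replications"]),
            base_seed=int(d["base_seed"]),
        )


def school_grid(
    base_seed: int,
    replications: int = 200,
    loss_rates: Sequence[float] = (0.10, 0.20, 0.30, 0.40),
    mechanisms: Sequence[str] = ("MCAR", "MAR1a", "MAR1b", "MAR2a", "MAR2b"),
) -> ExperimentGrid:
    return ExperimentGrid("school", tuple(mechanisms), tuple(loss_rates), replications, base_seed)


def prison_grid(
    base_seed: int,
    replications: int = 200,
    loss_rates: Sequence[float] = (0.10, 0.30),
    mechanisms: Sequence[str] = ("MCAR", "MAR"),
) -> ExperimentGrid:
    return ExperimentGrid("prison", tuple(mechanisms), tuple(loss_rates), replications, base_seed)


@dataclass
class RunResult:
    study: str
    mechanism: str
    loss_rate: float
    replicate: int
    seed: int
    n_deleted: int = 0
    available_stats: dict | None = None
    available_tables: dict | None = None
    bias: dict | None = None
    error: str | None = None


@dataclass
class DemonstrationResult:
    grid: ExperimentGrid
    cohort: StudyTable
    complete_stats: dict
    complete_tables: dict
    runs: list = field(default_factory=list)

    def __iter__(self) -> Iterator[RunResult]:
        return iter(self.runs)

    def __len__(self) -> int:
        return len(self.runs)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for run in self.runs:
            if run.error is not None:
                continue
            for effect, stats_ in run.available_stats.items():
                for stat in TRACKED_STATISTICS:
                    rows.append(
                        {
                            "study": run.study,
                            "mechanism": run.mechanism,
                            "loss_rate": run.loss_rate,
                            "replicate": run.replicate,
                            "effect": effect,
                            "statistic": stat,
                            "complete_value": self.complete_stats[effect][stat],
                            "value": stats_[stat],
                            "bias_percent": run.bias[effect][stat],
                        }
                    )
        return pd.DataFrame(rows)

    def failures(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "study": r.study,
                    "mechanism": r.mechanism,
                    "loss_rate": r.loss_rate,
                    "replicate": r.replicate,
                    "error": r.error,
                }
                for r in self.runs
                if r.error is not None
            ]
        )

    def mean_bias(self) -> pd.DataFrame:
        """Mean bias_percent across replicates per condition/effect/statistic."""
        long = self.to_long()
        if long.empty:
            return long
        return (
            long.groupby(["mechanism", "loss_rate", "effect", "statistic"], sort=False)
            .agg(bias_percent=("bias_percent", "mean"), value=("value", "mean"))
            .reset_index()
        )

    def summaries(self) -> list:
        """BiasSummary per (effect, statistic, mechanism) across the loss-rate set."""
        mean = self.mean_bias()
        out = []
        if mean.empty or len(self.grid.loss_rates) < 2:
            return out
        for (mech, effect, stat), sub in mean.groupby(
            ["mechanism", "effect", "statistic"], sort=False
        ):
            per_rate_value = dict(zip(sub["loss_rate"], sub["value"]))
            per_rate_bias = dict(zip(sub["loss_rate"], sub["bias_percent"]))
            out.append(
                BiasSummary.from_values(stat, mech, effect, per_rate_value, per_rate_bias)
            )
        return out


# ---------------------------------------------------------------------------
# per-study analyses
# ---------------------------------------------------------------------------

def _with_change(table: StudyTable) -> StudyTable:
    out = table.copy()
    out.data["change"] = out.data["post"] - out.data["pre"]
    return out


def school_statistics(table: StudyTable) -> tuple[dict, dict]:
    """The two tracked effects of the school demonstration.

    ``post_treatment``: the treatment main effect of the additive post-score
    ANOVA. ``chs_treatment_in_3P``: the simple treatment effect among
    3rd-year pupils in the change-score model with the treatment-by-course
    interaction, with the change-model MSe.
    """
    work = _with_change(table)
    post_tab = fit_anova(work, SCHOOL_POST_MODEL)
    change_tab = fit_anova(work, SCHOOL_CHANGE_MODEL)
    simple_tab = simple_effects(work, SCHOOL_CHANGE_MODEL, "treatment", "course")
    t_row = post_tab["treatment"]
    s_row = simple_tab["treatment | course=3P"]
    stats_ = {
        "post_treatment": {
            "ms_error": post_tab.ms_error,
            "f_value": t_row.f_value,
            "partial_eta_sq": t_row.partial_eta_sq,
            "mean_difference": t_row.mean_difference,
        },
        "chs_treatment_in_3P": {
            "ms_error": change_tab.ms_error,
            "f_value": s_row.f_value,
            "partial_eta_sq": s_row.partial_eta_sq,
            "mean_difference": s_row.mean_difference,
        },
    }
    tables = {"post": post_tab, "change": change_tab, "change_simple": simple_tab}
    return stats_, tables


def prison_statistics(table: StudyTable, dropout_mask: DeletionMask) -> tuple[dict, dict]:
    """One-way change-score ANOVAs per outcome and occasion for the prison trial.

    Post-treatment change scores use all listwise-available subjects; the
    6-month change scores additionally exclude the preset follow-up dropout.
    """
    stats_: dict = {}
    tables: dict = {}
    fu_table = apply_mask(table, dropout_mask, occasions=("followup",))
    outcome_names = [c[: -len("_pre")] for c in table.occasions["pre"]]
    for name in outcome_names:
        for occasion, src in (("post", table), ("fu6", fu_table)):
            work = src.copy()
            col = f"{name}_{'post' if occasion == 'post' else 'fu6'}"
            work.data["change"] = work.data[col] - work.data[f"{name}_pre"]
            spec = ModelSpec("change", ("group",), (("group",),))
            tab = fit_anova(work, spec)
            row = tab["group"]
            key = f"{name}_chs_{occasion}"
            stats_[key] = {
                "ms_error": tab.ms_error,
                "f_value": row.f_value,
                "partial_eta_sq": row.partial_eta_sq,
                "mean_difference": row.mean_difference,
            }
            tables[key] = tab
    return stats_, tables


# ---------------------------------------------------------------------------
# the demonstration loop
# ---------------------------------------------------------------------------

def run_demonstration(
    grid: ExperimentGrid,
    school_spec: SchoolCohortSpec | None = None,
    prison_spec: PrisonCohortSpec | None = None,
) -> DemonstrationResult:
    """Run every condition cell of the grid; deterministic given the base seed.

    Conditions that fail (e.g. an exhausted stratum or an inestimable term at
    a high loss rate) are recorded per cell, not fatal.
    """
    cell_seeds = grid.cell_seeds()
    if grid.study == "school":
        spec = school_spec or SchoolCohortSpec(seed=grid.cohort_seed())
        cohort = generate_school_cohort(spec)
        complete_stats, complete_tables = school_statistics(cohort)

        def run_cell(mech_name, rate, seed):
            mech = school_mechanisms(rate)[mech_name]
            mask = ampute(cohort, mech, seed=seed)
            avail = apply_mask(cohort, mask)
            stats_, tables = school_statistics(avail)
            return mask, stats_, tables

    else:
        spec = prison_spec or PrisonCohortSpec(seed=grid.cohort_seed())
        cohort, dropout = generate_prison_cohort(spec)
        complete_stats, complete_tables = prison_statistics(cohort, dropout)

        def run_cell(mech_name, rate, seed):
            if mech_name == "MCAR":
                mask = ampute(cohort, MechanismSpec("MCAR", rate, label="MCAR"), seed=seed)
            elif mech_name == "MAR":
                mask = ampute_study2_mar(cohort, rate, seed=seed)
            else:
                raise ParameterError(f"unknown prison mechanism {mech_name!r}")
            avail = apply_mask(cohort, mask)
            stats_, tables = prison_statistics(avail, dropout)
            return mask, stats_, tables

    result = DemonstrationResult(grid, cohort, complete_stats, complete_tables)
    for mech_name in grid.mechanisms:
        for rate in grid.loss_rates:
            for rep in range(grid.replications):
                seed = cell_seeds[(mech_name, rate, rep)]
                run = RunResult(grid.study, mech_name, rate, rep, seed)
                try:
                    mask, stats_, tables = run_cell(mech_name, rate, seed)
                    run.n_deleted = len(mask)
                    run.available_stats = stats_
                    run.available_tables = tables
                    run.bias = {
                        effect: {
                            stat: bias_percent(vals[stat], complete_stats[effect][stat])
                            for stat in TRACKED_STATISTICS
                        }
                        for effect, vals in stats_.items()
                    }
                except (InfeasiblePlanError, InestimableTermError) as err:
                    run.error = f"{type(err).__name__}: {err}"
                result.runs.append(run)
    return result


def write_report(
    results: DemonstrationResult, out_dir: str | Path, plots: bool = False
) -> list[Path]:
    """Emit the demonstration's tables under ``out_dir``.

    Writes the long replicate-level CSV, one wide mean-bias table per tracked
    effect (rows statistic x mechanism, columns loss rates), the
    complete-data statistic blocks, any per-condition failures, and a JSON
    manifest from which the run can be reproduced exactly.
    """
    if len(results) == 0:
        raise ParameterError("no results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    long = results.to_long()
    long_path = out / "long.csv"
    long.to_csv(long_path, index=False)
    written.append(long_path)

    mean = results.mean_bias()
    if not mean.empty:
        for effect, sub in mean.groupby("effect", sort=False):
            wide = sub.pivot_table(
                index=["statistic", "mechanism"],
                columns="loss_rate",
                values="bias_percent",
                sort=False,
            )
            p = out / f"wide_bias__{effect}.csv"
            wide.to_csv(p)
            written.append(p)

    complete_rows = []
    for block, tab in results.complete_tables.items():
        frame = tab.to_frame()
        frame.insert(0, "block", block)
        frame.insert(1, "n_used", tab.n_used)
        complete_rows.append(frame)
    complete_path = out / f"complete__{results.grid.study}.csv"
    pd.concat(complete_rows, ignore_index=True).to_csv(complete_path, index=False)
    written.append(complete_path)

    failures = results.failures()
    if not failures.empty:
        p = out / "failures.csv"
        failures.to_csv(p, index=False)
        written.append(p)

    manifest = {
        "grid": results.grid.to_dict(),
        "package_version": _pkg_version,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": [p.name for p in written],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(manifest_path)

    if plots:
        written += _bias_plots(mean, out)
    return written


def rerun_from_manifest(manifest_path: str | Path) -> DemonstrationResult:
    """Reproduce a demonstration from its manifest (byte-identical outputs)."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_demonstration(ExperimentGrid.from_dict(manifest["grid"]))


def _bias_plots(mean: pd.DataFrame, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for (effect, stat), sub in mean.groupby(["effect", "statistic"], sort=False):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for mech, mech_sub in sub.groupby("mechanism", sort=False):
            ax.plot(mech_sub["loss_rate"], mech_sub["bias_percent"], marker="o", label=mech)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("loss rate")
        ax.set_ylabel("mean bias (%)")
        ax.set_title(f"{effect}: {stat}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = out / f"bias__{effect}__{stat}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
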