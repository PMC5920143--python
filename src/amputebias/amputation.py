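"""Planned amputation: declarative, seeded deletion of complete data.

A :class:`MechanismSpec` describes one loss condition: the mechanism family
(``MCAR`` or stratified ``MAR_STRATA``), the overall loss rate (PdL), and --
for stratified plans -- the conditioning variable, how it is segmented, and
the composition of the lost cases over the ordered strata. ``ampute`` realizes
the plan against a complete :class:`StudyTable` and returns a
:class:`DeletionMask`; applying the mask never mutates the original table.

The five school-study conditions (MCAR, MAR1a, MAR1b and their inverses
MAR2a/MAR2b) and the two prison-study MAR conditions are provided as presets.
Weights such as "(0.80, 0.20) of the lost cases are boys/girls" are the
composition of the deleted set, not per-stratum deletion probabilities: the
realized per-stratum counts equal the integer allocation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSegmentationError,
    InfeasiblePlanError,
    ParameterError,
)
from .table import StudyTable

__all__ = [
    "MechanismSpec",
    "DeletionMask",
    "segment_by_percentiles",
    "allocate_counts",
    "ampute",
    "invert_weights",
    "ampute_study2_mar",
    "apply_mask",
    "school_mechanisms",
    "MCAR",
    "MAR_STRATA",
]

MCAR = "MCAR"
MAR_STRATA = "MAR_STRATA"
STRATUM_LABELS = ("low", "mid", "high")


@dataclass(frozen=True)
class MechanismSpec:
    mechanism_id: str
    loss_rate: float
    stratum_variable: str | None = None
    percentile_cuts: tuple | None = None  # e.g. (0.25, 0.75) -> low/mid/high
    stratum_levels: tuple | None = None   # ordered levels of a categorical variable
    stratum_weights: tuple | None = None  # composition of the lost cases
    group_proportional: bool = False
    group_variable: str = "group"
    label: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.loss_rate < 1.0:
            raise ParameterError("loss_rate must lie in (0, 1)")
        if self.mechanism_id not in (MCAR, MAR_STRATA):
            raise ParameterError(f"unknown mechanism_id {self.mechanism_id!r}")
        if self.mechanism_id == MAR_STRATA:
            if self.stratum_variable is None or self.stratum_weights is None:
                raise ParameterError("MAR_STRATA needs stratum_variable and stratum_weights")
            w = np.asarray(self.stratum_weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ParameterError("stratum_weights must be a simplex")
            if (self.percentile_cuts is None) == (self.stratum_levels is None):
                raise ParameterError(
                    "exactly one of percentile_cuts / stratum_levels must be given"
                )
            n_strata = 3 if self.percentile_cuts else len(self.stratum_levels)
            if len(w) != n_strata:
                raise ParameterError("stratum_weights length must match the strata")

    @property
    def name(self) -> str:
        return self.label or self.mechanism_id


@dataclass(frozen=True)
class DeletionMask:
    deleted_subject_ids: frozenset
    realized_counts_per_stratum: dict
    target_total: int

    def __post_init__(self) -> None:
        if len(self.deleted_subject_ids) != self.target_total:
            raise ParameterError("mask size must equal target_total")
        if sum(self.realized_counts_per_stratum.values()) != self.target_total:
            raise ParameterError("realized counts must sum to target_total")

    def __len__(self) -> int:
        return self.target_total

    def to_csv(self, path: str | Path, strata: dict | None = None) -> Path:
        """Two-column export (subject_id, stratum)."""
        path = Path(path)
        ids = sorted(self.deleted_subject_ids)
        strata = strata or {}
        pd.DataFrame(
            {"subject_id": ids, "stratum": [strata.get(i, "") for i in ids]}
        ).to_csv(path, index=False)
        return path


def segment_by_percentiles(
    values, lower_q: float = 0.25, upper_q: float = 0.75
) -> np.ndarray:
    """Label each value low / mid / high by sample percentiles.

    Uses linear-interpolation sample quantiles (the convention declared once
    for the whole package). ``low`` is value < P_lower, ``high`` is value >
    P_upper; ties at a cutpoint go to ``mid``.
    """
    full = np.asarray(values, dtype=float)
    if np.isnan(full).any():
        raise ParameterError("segmentation requires non-missing values")
    if full.size < 4:
        raise ParameterError("need at least 4 values to segment")
    lo, hi = np.quantile(full, [lower_q, upper_q], method="linear")
    if lo == hi:
        raise DegenerateSegmentationError(
            f"percentiles P{int(lower_q*100)} and P{int(upper_q*100)} coincide ({lo})"
        )
    labels = np.full(full.shape, "mid", dtype=object)
    labels[full < lo] = "low"
    labels[full > hi] = "high"
    return labels


def allocate_counts(
    total: int, weights: Sequence[float], capacities: Sequence[int]
) -> np.ndarray:
    """Integer allocation of ``total`` over strata by largest-remainder rounding.

    Ties in the remainders break by stratum order. If a stratum's allocation
    exceeds its capacity, the overflow is reassigned over the remaining
    strata in proportion to their remaining weights, iterating until feasible.
    """
    w = np.asarray(weights, dtype=float)
    cap = np.asarray(capacities, dtype=int)
    if np.any(w < 0) or w.sum() <= 0:
        raise ParameterError("weights must be nonnegative and sum > 0")
    if total < 0:
        raise ParameterError("total must be nonnegative")
    if total > cap.sum():
        raise InfeasiblePlanError(
            f"cannot place {total} deletions into capacities {cap.tolist()}"
        )
    counts = np.zeros(len(w), dtype=int)
    remaining = total
    open_strata = np.ones(len(w), dtype=bool)
    while remaining > 0:
        w_open = np.where(open_strata, w, 0.0)
        if w_open.sum() == 0:
            # only zero-weight strata remain open: the plan cannot place the rest
            raise InfeasiblePlanError(
                f"strata with positive weight are exhausted; {remaining} deletions "
                f"cannot be placed (capacities {cap.tolist()})"
            )
        shares = remaining * w_open / w_open.sum()
        alloc = np.floor(shares).astype(int)
        short = remaining - alloc.sum()
        if short > 0:
            order = np.argsort(-(shares - alloc), kind="stable")
            order = [i for i in order if open_strata[i]]
            for i in order[:short]:
                alloc[i] += 1
        overflow = np.maximum(counts + alloc - cap, 0)
        alloc -= overflow
        counts += alloc
        full = counts >= cap
        open_strata &= ~full
        remaining = total - counts.sum()
        if remaining > 0 and not open_strata.any():
            raise InfeasiblePlanError("allocation cannot satisfy capacities")
    return counts


def invert_weights(spec: MechanismSpec) -> MechanismSpec:
    """Reverse the stratum-weight composition across the ordered strata.

    This realizes the "inverse" loss conditions (MAR2a/MAR2b mirror
    MAR1a/MAR1b). Involution: ``invert_weights(invert_weights(s)) == s``
    up to the label.
    """
    if spec.mechanism_id != MAR_STRATA:
        raise ParameterError("invert_weights applies to MAR_STRATA specs only")
    return replace(spec, stratum_weights=tuple(reversed(spec.stratum_weights)))


def _target_total(loss_rate: float, n: int) -> int:
    return round(loss_rate * n)  # round-half-to-even, declared convention


def _strata_for(table: StudyTable, spec: MechanismSpec) -> tuple[np.ndarray, list[str]]:
    col = table.data[spec.stratum_variable]
    if spec.percentile_cuts is not None:
        labels = segment_by_percentiles(col.to_numpy(), *spec.percentile_cuts)
        return labels, list(STRATUM_LABELS)
    labels = col.to_numpy().astype(object)
    return labels, list(spec.stratum_levels)


def ampute(table: StudyTable, spec: MechanismSpec, seed=None) -> DeletionMask:
    """Realize a deletion plan against a complete table.

    MCAR draws ``round(loss_rate * n)`` subjects uniformly without
    replacement. MAR_STRATA first fixes the per-stratum deletion counts with
    :func:`allocate_counts` and then draws uniformly within each stratum, so
    the realized composition of the lost cases is exact, not merely expected.
    With ``group_proportional`` the total is first split over the arms of
    ``group_variable`` by their sample shares, then allocated within each arm.
    Deterministic given the seed; the table is never modified.
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    ids = table.subject_ids.to_numpy()
    n = len(ids)
    total = _target_total(spec.loss_rate, n)
    if total == 0:
        return DeletionMask(frozenset(), {"all": 0}, 0)

    if spec.mechanism_id == MCAR:
        chosen = rng.choice(ids, size=total, replace=False)
        return DeletionMask(frozenset(int(i) for i in chosen), {"all": total}, total)

    labels, order = _strata_for(table, spec)

    def _delete_within(pool_ids: np.ndarray, pool_labels: np.ndarray, k: int) -> list[int]:
        caps = np.array([(pool_labels == s).sum() for s in order])
        try:
            counts = allocate_counts(k, spec.stratum_weights, caps)
        except InfeasiblePlanError as err:
            short = [s for s, c in zip(order, caps) if c == 0]
            raise InfeasiblePlanError(
                f"{err} (strata {order}, capacities {caps.tolist()}"
                + (f"; empty strata {short}" if short else "")
                + ")"
            ) from None
        out: list[int] = []
        for s, c in zip(order, counts):
            if c:
                out += list(rng.choice(pool_ids[pool_labels == s], size=c, replace=False))
        return out

    deleted: list[int] = []
    if spec.group_proportional:
        groups = table.data[spec.group_variable].to_numpy()
        g_levels = table.factors[spec.group_variable]
        g_sizes = np.array([(groups == g).sum() for g in g_levels])
        quotas = allocate_counts(total, g_sizes / g_sizes.sum(), g_sizes)
        for g, q in zip(g_levels, quotas):
            if q:
                sel = groups == g
                deleted += _delete_within(ids[sel], labels[sel], int(q))
    else:
        deleted = _delete_within(ids, labels, total)

    label_of = dict(zip(ids.tolist(), labels.tolist()))
    counts_out = {s: sum(1 for i in deleted if label_of[i] == s) for s in order}
    return DeletionMask(frozenset(int(i) for i in deleted), counts_out, total)


def ampute_study2_mar(
    table: StudyTable,
    loss_rate: float,
    seed=None,
    weights_30: Sequence[float] = (0.10, 0.30, 0.60),
) -> DeletionMask:
    """The prison study's dependence-conditioned loss conditions.

    At a 10% loss every deletion comes from the above-P75 stratum of years of
    dependence; at 30% the losses span the whole range with monotone
    increasing weights over (low, mid, high), default (0.10, 0.30, 0.60).
    Both allocate the losses to the arms in proportion to arm size.
    """
    if abs(loss_rate - 0.10) < 1e-9:
        weights = (0.0, 0.0, 1.0)
    elif abs(loss_rate - 0.30) < 1e-9:
        weights = tuple(weights_30)
        if not (weights[0] <= weights[1] <= weights[2]):
            raise ParameterError("30% weights must be monotone over (low, mid, high)")
    else:
        raise ParameterError("the prison demonstration manipulates only 10% and 30% loss")
    spec = MechanismSpec(
        mechanism_id=MAR_STRATA,
        loss_rate=loss_rate,
        stratum_variable="years_dependence",
        percentile_cuts=(0.25, 0.75),
        stratum_weights=weights,
        group_proportional=True,
        label=f"MAR{int(round(loss_rate * 100))}",
    )
    return ampute(table, spec, seed=seed)


def apply_mask(
    table: StudyTable, mask: DeletionMask, occasions: Sequence[str] = ("post", "followup")
) -> StudyTable:
    """Blank the masked subjects' outcome cells on the given occasions.

    Deletion is at the whole-subject level for those occasions (a monotone,
    listwise-deletion unit): baseline values of deleted subjects remain in
    the table and are excluded downstream by listwise analysis.
    """
    out = table.copy()
    cols = [c for occ in occasions for c in table.occasions.get(occ, [])]
    if cols:
        sel = out.data["subject_id"].isin(mask.deleted_subject_ids)
        out.data.loc[sel, cols] = np.nan
    return out


def school_mechanisms(loss_rate: float) -> dict[str, MechanismSpec]:
    """The five loss conditions of the school demonstration at one loss rate."""
    mar1a = MechanismSpec(
        MAR_STRATA,
        loss_rate,
        stratum_variable="sex",
        stratum_levels=("boy", "girl"),
        stratum_weights=(0.80, 0.20),
        label="MAR1a",
    )
    mar1b = MechanismSpec(
        MAR_STRATA,
        loss_rate,
        stratum_variable="pre",
        percentile_cuts=(0.25, 0.75),
        stratum_weights=(0.75, 0.23, 0.02),
        label="MAR1b",
    )
    return {
        "MCAR": MechanismSpec(MCAR, loss_rate, label="MCAR"),
        "MAR1a": mar1a,
        "MAR1b": mar1b,
        "MAR2a": replace(invert_weights(mar1a), label="MAR2a"),
        "MAR2b": replace(invert_weights(mar1b), label="MAR2b"),
    }
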