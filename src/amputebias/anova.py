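"""Fixed-effects factorial ANOVA with Type-III partitioning.

This is the analysis surface of the demonstration: least-squares fits with
sum-to-zero factor coding, Type-III sums of squares (each term tested after
every other term, the convention professional packages apply to unbalanced
data), and for every effect the full block of statistics the demonstration
tracks -- error df, MSe, F, p, partial eta-squared, observed power, and the
estimated marginal mean difference.

Conventions, stated once:

* partial eta-squared is ``SS_effect / (SS_effect + SS_error)``, identically
  ``F * df1 / (F * df1 + df2)``;
* observed power is the exceedance probability of the alpha-critical F under
  a noncentral F with noncentrality ``lambda = F * df1`` (the convention that
  reproduces published post-hoc powers);
* mean differences are differences of model-based marginal means with the
  off-factor levels equally weighted, not raw group means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InestimableTermError, ParameterError
from .table import StudyTable

__all__ = [
    "ModelSpec",
    "EffectRow",
    "AnovaTable",
    "change_scores",
    "fit_anova",
    "partial_eta_squared",
    "observed_power",
    "simple_effects",
    "select_model",
]

Term = tuple[str, ...]


def _as_term(t) -> Term:
    if isinstance(t, str):
        return tuple(p.strip() for p in t.replace("*", ":").split(":"))
    return tuple(t)


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects model: response, ordered factors, and tested terms.

    Terms are tuples of factor names; ``("treatment", "course")`` is the
    interaction. The term list must be hierarchical: an interaction requires
    all its marginal terms.
    """

    response: str
    factors: tuple
    terms: tuple
    alpha: float = 0.05
    ss_type: str = "III"

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "terms", tuple(_as_term(t) for t in self.terms))
        if self.ss_type != "III":
            raise ParameterError("only Type-III partitioning is supported")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        term_set = set(self.terms)
        for t in self.terms:
            if len(set(t)) != len(t):
                raise ParameterError(f"term {t} repeats a factor")
            if not set(t) <= set(self.factors):
                raise ParameterError(f"term {t} uses undeclared factors")
            for k in range(1, len(t)):
                for sub in itertools.combinations(t, k):
                    if sub not in term_set:
                        raise ParameterError(
                            f"non-hierarchical terms: {t} present without {sub}"
                        )

    @staticmethod
    def term_name(t: Term) -> str:
        return ":".join(t)

    def with_terms(self, terms) -> "ModelSpec":
        return ModelSpec(self.response, self.factors, tuple(terms), self.alpha)


@dataclass
class EffectRow:
    term: str
    df_effect: int
    df_error: int
    ss_effect: float
    ms_error: float
    f_value: float
    p_value: float
    partial_eta_sq: float
    observed_power: float
    mean_difference: float | None = None
    md_direction: str | None = None
    marginal_means: dict | None = None


@dataclass
class AnovaTable:
    response: str
    n_used: int
    df_error: int
    ms_error: float
    rows: list

    def __getitem__(self, term: str) -> EffectRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "df_effect": r.df_effect,
                    "df_error": r.df_error,
                    "ms_error": r.ms_error,
                    "f_value": r.f_value,
                    "p_value": r.p_value,
                    "partial_eta_sq": r.partial_eta_sq,
                    "observed_power": r.observed_power,
                    "mean_difference": r.mean_difference,
                    "md_direction": r.md_direction,
                }
                for r in self.rows
            ]
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def change_scores(table: StudyTable, post: str, pre: str) -> pd.Series:
    """Elementwise post - pre; missing whenever either side is missing."""
    return table.data[post] - table.data[pre]


def partial_eta_squared(f_value: float, df_effect: int, df_error: int) -> float:
    """Partial eta-squared from an F statistic and its degrees of freedom."""
    if f_value < 0 or df_effect <= 0 or df_error <= 0:
        raise ParameterError("f_value must be >= 0 and dfs positive")
    if np.isinf(f_value):
        return 1.0
    return f_value * df_effect / (f_value * df_effect + df_error)


def observed_power(
    f_value: float, df_effect: int, df_error: int, alpha: float = 0.05
) -> float:
    """Post-hoc power: P(F' > F_crit) for F' ~ ncF(df1, df2, lambda=F*df1)."""
    if f_value < 0 or df_effect <= 0 or df_error <= 0:
        raise ParameterError("f_value must be >= 0 and dfs positive")
    if np.isinf(f_value):
        return 1.0
    crit = stats.f.isf(alpha, df_effect, df_error)
    lam = f_value * df_effect
    if lam == 0:
        return float(alpha)
    val = float(stats.ncf.sf(crit, df_effect, df_error, lam))
    if np.isnan(val):  # extreme noncentrality overflows the ncf tail computation
        return 1.0
    return val


# ---------------------------------------------------------------------------
# design construction (sum-to-zero / effect coding)
# ---------------------------------------------------------------------------

class _Design:
    def __init__(self, table: StudyTable, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.levels = {f: list(table.factors[f]) for f in spec.factors}
        self.factor_codes: dict[str, np.ndarray] = {}
        n = len(data)
        for f in spec.factors:
            levs = self.levels[f]
            k = len(levs)
            cols = np.zeros((n, k - 1))
            vals = data[f].to_numpy()
            for j, lev in enumerate(levs[:-1]):
                cols[vals == lev, j] = 1.0
            cols[vals == levs[-1], :] = -1.0
            self.factor_codes[f] = cols
        blocks = [np.ones((n, 1))]
        self.slices: dict[Term, slice] = {}
        start = 1
        for t in spec.terms:
            block = self._term_block(t, self.factor_codes)
            self.slices[t] = slice(start, start + block.shape[1])
            blocks.append(block)
            start += block.shape[1]
        self.X = np.hstack(blocks)

    @staticmethod
    def _term_block(term: Term, codes: dict[str, np.ndarray]) -> np.ndarray:
        block = codes[term[0]]
        for f in term[1:]:
            nxt = codes[f]
            block = np.einsum("ni,nj->nij", block, nxt).reshape(len(block), -1)
        return block

    def row_for_cell(self, cell: dict) -> np.ndarray:
        """Design row of a single cell of the factor cross."""
        codes = {}
        for f in self.spec.factors:
            levs = self.levels[f]
            k = len(levs)
            row = np.zeros((1, k - 1))
            if cell[f] == levs[-1]:
                row[:] = -1.0
            else:
                row[0, levs.index(cell[f])] = 1.0
            codes[f] = row
        parts = [np.ones((1, 1))]
        for t in self.spec.terms:
            parts.append(self._term_block(t, codes))
        return np.hstack(parts)[0]


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta, rank


def _snap_zero(sse: float, y: np.ndarray) -> float:
    """Treat numerically-negligible residual SS as an exact zero fit."""
    scale = float(np.sum((y - y.mean()) ** 2))
    return 0.0 if sse <= 1e-12 * max(scale, 1e-300) else sse


def _check_estimable(data: pd.DataFrame, spec: ModelSpec, levels: dict) -> None:
    for t in spec.terms:
        if len(t) < 1:
            continue
        combos = itertools.product(*[levels[f] for f in t])
        present = set(map(tuple, data[list(t)].itertuples(index=False)))
        for combo in combos:
            if combo not in present:
                cell = dict(zip(t, combo))
                raise InestimableTermError(
                    f"term {ModelSpec.term_name(t)} is inestimable: empty cell {cell}",
                    cell=cell,
                )


def _marginal_means(design: _Design, beta: np.ndarray, factor: str) -> dict:
    """Model-based marginal means of one factor, off-factors equally weighted."""
    out = {}
    others = [f for f in design.spec.factors if f != factor]
    for lev in design.levels[factor]:
        rows = []
        for combo in itertools.product(*[design.levels[f] for f in others]):
            cell = {factor: lev, **dict(zip(others, combo))}
            rows.append(design.row_for_cell(cell))
        out[lev] = float(np.mean(rows, axis=0) @ beta)
    return out


def _md_from_means(means: dict) -> tuple[float, str]:
    hi = max(means, key=means.get)
    lo = min(means, key=means.get)
    return means[hi] - means[lo], f"*{hi}-{lo}"


def fit_anova(table: StudyTable, spec: ModelSpec) -> AnovaTable:
    """Type-III factorial ANOVA on the listwise-complete rows.

    Rows with a missing response or factor are dropped (the listwise unit);
    each term's SS is the increase in SSE when its columns are removed from
    the full sum-to-zero-coded design. An empty design cell makes a term
    inestimable and raises :class:`InestimableTermError` naming the cell.
    """
    cols = [spec.response, *spec.factors]
    data = table.data.dropna(subset=cols)
    if data.empty:
        raise ParameterError("no complete rows to analyze")
    design = _Design(table, spec, data)
    _check_estimable(data, spec, design.levels)
    y = data[spec.response].to_numpy(dtype=float)
    X = design.X
    sse_full, beta, rank = _sse(X, y)
    sse_full = _snap_zero(sse_full, y)
    if rank < X.shape[1]:
        raise InestimableTermError("design matrix is rank deficient")
    df_error = len(y) - rank
    if df_error <= 0:
        raise ParameterError("no residual degrees of freedom (need >=2 per cell)")
    mse = sse_full / df_error

    rows = []
    for t in spec.terms:
        sl = design.slices[t]
        keep = np.ones(X.shape[1], dtype=bool)
        keep[sl] = False
        sse_red, _, _ = _sse(X[:, keep], y)
        ss = max(sse_red - sse_full, 0.0)
        df_eff = sl.stop - sl.start
        if mse == 0.0:
            f_val = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f_val = (ss / df_eff) / mse
            p = float(stats.f.sf(f_val, df_eff, df_error))
        eta = partial_eta_squared(f_val, df_eff, df_error)
        power = observed_power(f_val, df_eff, df_error, spec.alpha)
        md = direction = means = None
        if len(t) == 1:
            means = _marginal_means(design, beta, t[0])
            md, direction = _md_from_means(means)
        rows.append(
            EffectRow(
                term=ModelSpec.term_name(t),
                df_effect=df_eff,
                df_error=df_error,
                ss_effect=ss,
                ms_error=mse,
                f_value=float(f_val),
                p_value=p,
                partial_eta_sq=float(eta),
                observed_power=float(power),
                mean_difference=md,
                md_direction=direction,
                marginal_means=means,
            )
        )
    return AnovaTable(spec.response, len(y), df_error, mse, rows)


def simple_effects(
    table: StudyTable, spec: ModelSpec, factor: str, within: str
) -> AnovaTable:
    """Tests of ``factor`` at each level of ``within``, pooled error.

    The F statistics use the pooled MSe and error df of the full model
    (``spec`` must contain the ``factor x within`` interaction); marginal
    means inside each slice weight the remaining factors equally.
    """
    inter = {factor, within}
    if not any(set(t) == inter for t in spec.terms):
        raise ParameterError("simple effects need the factor-by-within interaction in the model")
    cols = [spec.response, *spec.factors]
    data = table.data.dropna(subset=cols)
    design = _Design(table, spec, data)
    _check_estimable(data, spec, design.levels)
    y = data[spec.response].to_numpy(dtype=float)
    X = design.X
    sse_full, beta, rank = _sse(X, y)
    sse_full = _snap_zero(sse_full, y)
    if rank < X.shape[1]:
        raise InestimableTermError("design matrix is rank deficient")
    df_error = len(y) - rank
    mse = sse_full / df_error
    xtx_inv = np.linalg.pinv(X.T @ X)

    others = [f for f in spec.factors if f not in (factor, within)]
    rows = []
    for w in design.levels[within]:
        cvecs = {}
        for lev in design.levels[factor]:
            cell_rows = []
            for combo in itertools.product(*[design.levels[f] for f in others]):
                cell = {factor: lev, within: w, **dict(zip(others, combo))}
                if not ((data[factor] == lev) & (data[within] == w)).any():
                    raise InestimableTermError(
                        f"no observations for {factor}={lev} within {within}={w}",
                        cell={factor: lev, within: w},
                    )
                cell_rows.append(design.row_for_cell(cell))
            cvecs[lev] = np.mean(cell_rows, axis=0)
        levs = design.levels[factor]
        L = np.array([cvecs[l] - cvecs[levs[-1]] for l in levs[:-1]])
        q = L.shape[0]
        est = L @ beta
        cov = L @ xtx_inv @ L.T
        if mse == 0.0:
            f_val = np.inf if np.any(est != 0) else 0.0
            p = 0.0 if np.any(est != 0) else 1.0
        else:
            f_val = float(est @ np.linalg.solve(cov, est)) / (q * mse)
            p = float(stats.f.sf(f_val, q, df_error))
        means = {l: float(cvecs[l] @ beta) for l in levs}
        md, direction = _md_from_means(means)
        rows.append(
            EffectRow(
                term=f"{factor} | {within}={w}",
                df_effect=q,
                df_error=df_error,
                ss_effect=float(f_val * q * mse) if np.isfinite(f_val) else np.inf,
                ms_error=mse,
                f_value=f_val,
                p_value=p,
                partial_eta_sq=partial_eta_squared(f_val, q, df_error),
                observed_power=observed_power(f_val, q, df_error, spec.alpha),
                mean_difference=md,
                md_direction=direction,
                marginal_means=means,
            )
        )
    return AnovaTable(spec.response, len(y), df_error, mse, rows)


def select_model(
    table: StudyTable, candidates: Sequence[ModelSpec], alpha: float | None = None
) -> ModelSpec:
    """Hierarchical model selection over nested-compatible candidates.

    All candidate terms are pooled into one encompassing model; from its
    Type-III tests an interaction enters iff p < alpha, a main effect is
    retained iff p < alpha or required by an included interaction, and the
    candidate whose term set matches the inclusion (nearest by symmetric
    difference on ties, earlier candidate first) is returned.
    """
    if not candidates:
        raise ParameterError("need at least one candidate model")
    base = candidates[0]
    if alpha is None:
        alpha = base.alpha
    all_terms: list[Term] = []
    for cand in candidates:
        if cand.response != base.response:
            raise ParameterError("candidates must share a response")
        for t in cand.terms:
            if t not in all_terms:
                all_terms.append(t)
    full = ModelSpec(base.response, base.factors, tuple(all_terms), alpha)
    fitted = fit_anova(table, full)
    pvals = {t: fitted[ModelSpec.term_name(t)].p_value for t in full.terms}

    included = {t for t in full.terms if pvals[t] < alpha}
    # hierarchy closure: every included interaction drags in its margins
    changed = True
    while changed:
        changed = False
        for t in list(included):
            for k in range(1, len(t)):
                for sub in itertools.combinations(t, k):
                    if sub in full.terms and sub not in included:
                        included.add(sub)
                        changed = True

    best, best_score = None, None
    for i, cand in enumerate(candidates):
        score = (len(set(cand.terms) ^ included), i)
        if best_score is None or score < best_score:
            best, best_score = cand, score
    return best
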