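"""Shared test utilities: random unbalanced fixtures and the reference fit."""

from __future__ import annotations

import numpy as np
import pandas as pd

import amputebias as ab
from amputebias.anova import ModelSpec

FULL_2x2x2_TERMS = (
    ("a",),
    ("b",),
    ("c",),
    ("a", "b"),
    ("a", "c"),
    ("b", "c"),
    ("a", "b", "c"),
)


def random_unbalanced_table(rng: np.random.Generator, n_min=40, n_max=90) -> ab.StudyTable:
    """A 2x2x2 factorial with unbalanced, all-nonempty cells and normal noise."""
    while True:
        n = int(rng.integers(n_min, n_max))
        df = pd.DataFrame(
            {
                "a": rng.choice(["a1", "a2"], n),
                "b": rng.choice(["b1", "b2"], n),
                "c": rng.choice(["c1", "c2"], n),
            }
        )
        sizes = df.groupby(["a", "b", "c"]).size()
        if len(sizes) == 8 and sizes.min() >= 2:
            break
    effects = rng.normal(scale=1.0, size=3)
    df["y"] = (
        effects[0] * (df["a"] == "a2")
        + effects[1] * (df["b"] == "b2")
        + effects[2] * (df["a"] == "a2") * (df["c"] == "c2")
        + rng.standard_normal(n)
    )
    return ab.make_table(
        {"subject_id": np.arange(n), **{k: df[k] for k in df.columns}},
        factors={"a": ["a1", "a2"], "b": ["b1", "b2"], "c": ["c1", "c2"]},
    )


def statsmodels_type3(table: ab.StudyTable, spec: ModelSpec) -> pd.DataFrame:
    """Reference Type-III ANOVA via statsmodels OLS with sum-to-zero contrasts."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    def enc(f: str) -> str:
        return f"C({f}, Sum)"

    rhs = " + ".join(":".join(enc(f) for f in t) for t in spec.terms)
    data = table.data.dropna(subset=[spec.response, *spec.factors])
    fit = smf.ols(f"{spec.response} ~ {rhs}", data=data).fit()
    ref = anova_lm(fit, typ=3)
    ref = ref.rename(
        index={":".join(enc(f) for f in t): ModelSpec.term_name(t) for t in spec.terms}
    )
    return ref
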