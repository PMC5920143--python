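"""Subject-level study tables.

A :class:`StudyTable` is a rectangular subject-by-variable dataset together
with the metadata the rest of the pipeline needs: which columns are factors
(and their ordered level sets), which are numeric covariates, and which are
repeated outcome measurements grouped by occasion (pre / post / follow-up).
Missing outcome cells are represented as NaN; on disk the missing sentinel is
an empty CSV field and the column roles travel in a sidecar JSON schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError

SUBJECT_COL = "subject_id"


@dataclass
class StudyTable:
    data: pd.DataFrame
    factors: dict[str, list[str]]
    covariates: list[str] = field(default_factory=list)
    occasions: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if SUBJECT_COL not in self.data.columns:
            raise ParameterError(f"table must have a {SUBJECT_COL!r} column")
        ids = self.data[SUBJECT_COL]
        if ids.duplicated().any():
            raise ParameterError("subject_ids must be unique")
        for col, levels in self.factors.items():
            if col not in self.data.columns:
                raise ParameterError(f"declared factor {col!r} missing from table")
            observed = set(self.data[col].dropna().unique())
            if not observed <= set(levels):
                raise ParameterError(
                    f"factor {col!r} contains undeclared levels {observed - set(levels)}"
                )
        for col in self.covariates + self.outcome_columns:
            if col not in self.data.columns:
                raise ParameterError(f"declared column {col!r} missing from table")

    # -- accessors ----------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Series:
        return self.data[SUBJECT_COL]

    @property
    def outcome_columns(self) -> list[str]:
        return [c for cols in self.occasions.values() for c in cols]

    def missing_flags(self) -> pd.DataFrame:
        """Boolean missing-cell indicators for the outcome columns."""
        return self.data[self.outcome_columns].isna()

    def is_complete(self) -> bool:
        return not self.missing_flags().to_numpy().any()

    def copy(self) -> "StudyTable":
        return StudyTable(
            self.data.copy(),
            {k: list(v) for k, v in self.factors.items()},
            list(self.covariates),
            {k: list(v) for k, v in self.occasions.items()},
        )

    def listwise(self, columns: Sequence[str] | None = None) -> "StudyTable":
        """Listwise-deletion view: subjects fully observed on ``columns``.

        Defaults to all outcome columns. Returns a new StudyTable; the
        original is never mutated.
        """
        cols = list(columns) if columns is not None else self.outcome_columns
        keep = self.data[cols].notna().all(axis=1)
        return StudyTable(
            self.data.loc[keep].reset_index(drop=True),
            {k: list(v) for k, v in self.factors.items()},
            list(self.covariates),
            {k: list(v) for k, v in self.occasions.items()},
        )

    # -- persistence --------------------------------------------------------
    def schema(self) -> dict:
        return {
            "subject_column": SUBJECT_COL,
            "factors": self.factors,
            "covariates": self.covariates,
            "occasions": self.occasions,
            "missing_sentinel": "",
        }

    def to_csv(self, path: str | Path) -> tuple[Path, Path]:
        """Write the table as CSV plus a sidecar ``<stem>.schema.json``."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        schema_path = path.with_suffix(".schema.json")
        schema_path.write_text(json.dumps(self.schema(), indent=2) + "\n")
        return path, schema_path

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path | None = None) -> "StudyTable":
        path = Path(path)
        if schema_path is None:
            schema_path = path.with_suffix(".schema.json")
        schema = json.loads(Path(schema_path).read_text())
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        for col in schema.get("covariates", []) + [
            c for cols in schema.get("occasions", {}).values() for c in cols
        ]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        return cls(
            df,
            {k: list(v) for k, v in schema["factors"].items()},
            list(schema.get("covariates", [])),
            {k: list(v) for k, v in schema.get("occasions", {}).items()},
        )


def make_table(
    columns: Mapping[str, np.ndarray | Sequence],
    factors: Mapping[str, Sequence[str]],
    covariates: Sequence[str] = (),
    occasions: Mapping[str, Sequence[str]] | None = None,
) -> StudyTable:
    """Convenience constructor from plain column arrays."""
    df = pd.DataFrame(dict(columns))
    return StudyTable(
        df,
        {k: list(v) for k, v in factors.items()},
        list(covariates),
        {k: list(v) for k, v in (occasions or {}).items()},
    )
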