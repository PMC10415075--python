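"""Tertile coding of continuous composites.

Cut-offs are the empirical 1/3 and 2/3 quantiles of the *training* data and
are reused verbatim on held-out or new data; the coding rule is
v <= t1 -> low, v <= t2 -> medium, else high.  Heavily tied Likert data may
leave a category empty (categories merge); the coding stays total and
deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from reguframe.errors import DegenerateVariableError, SchemaError

logger = logging.getLogger(__name__)

TERTILE_LABELS = ["low", "medium", "high"]


def tertile_cutoffs(values) -> tuple[float, float]:
    """Empirical tertile cut-offs (1/3 and 2/3 quantiles).

    Raises ``DegenerateVariableError`` for vectors with fewer than three
    distinct values: such a variable cannot carry three categories and is
    dropped by callers (with a log entry).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(np.unique(v)) < 3:
        raise DegenerateVariableError("fewer than 3 distinct values; cannot tertile-code")
    t1, t2 = np.quantile(v, [1 / 3, 2 / 3])
    return float(t1), float(t2)


def code_tertiles(values, cutoffs: tuple[float, float]) -> np.ndarray:
    t1, t2 = cutoffs
    v = np.asarray(values, dtype=float)
    return np.asarray(TERTILE_LABELS, dtype=object)[
        np.where(v <= t1, 0, np.where(v <= t2, 1, 2))
    ]


@dataclass
class DiscretizationMap:
    """Per-variable tertile cut-offs plus pass-through categorical columns
    (frame, gender, education keep their observed categories)."""

    cutoffs: dict[str, tuple[float, float]] = field(default_factory=dict)
    categorical: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def fit(
        cls,
        table: pd.DataFrame,
        numeric_vars: list[str],
        categorical_vars: list[str] = (),
    ) -> "DiscretizationMap":
        cutoffs = {}
        for v in numeric_vars:
            if v not in table.columns:
                raise SchemaError(f"variable {v!r} not in table")
            try:
                cutoffs[v] = tertile_cutoffs(table[v])
            except DegenerateVariableError:
                logger.warning("dropping degenerate variable %s (<3 distinct values)", v)
        categorical = {
            v: sorted(map(str, pd.unique(table[v].dropna()))) for v in categorical_vars
        }
        return cls(cutoffs=cutoffs, categorical=categorical)

    def states(self) -> dict[str, list[str]]:
        out = {v: list(TERTILE_LABELS) for v in self.cutoffs}
        out.update({v: list(cats) for v, cats in self.categorical.items()})
        return out

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        """Discretize ``table`` (no re-estimation of cut-offs).

        Numeric variables must still be numeric: applying the map to an
        already-coded table is a type error, not a silent no-op.
        """
        out = {}
        for v, cut in self.cutoffs.items():
            if v not in table.columns:
                raise SchemaError(f"variable {v!r} not in table")
            if not pd.api.types.is_numeric_dtype(table[v]):
                raise SchemaError(f"variable {v!r} is not numeric; already coded?")
            out[v] = code_tertiles(table[v], cut)
        for v in self.categorical:
            if v not in table.columns:
                raise SchemaError(f"variable {v!r} not in table")
            out[v] = table[v].astype(str).to_numpy()
        return pd.DataFrame(out, index=table.index)

    def to_json(self) -> str:
        return json.dumps(
            {"cutoffs": {v: list(c) for v, c in self.cutoffs.items()},
             "categorical": self.categorical},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        d = json.loads(text)
        return cls(
            cutoffs={v: tuple(c) for v, c in d["cutoffs"].items()},
            categorical={v: list(c) for v, c in d.get("categorical", {}).items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def discretize_table(table: pd.DataFrame, dmap: DiscretizationMap) -> pd.DataFrame:
    """Functional alias for :meth:`DiscretizationMap.apply`."""
    return dmap.apply(table)
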