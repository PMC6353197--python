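"""Complete-case categorical dataset backed by an integer code matrix."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schema import VariableSchema, schema_by_name


class CategoricalDataset:
    """A rectangular table of category codes, one column per schema variable.

    Invariants: no missing values; every code is a declared level of its
    variable.  Codes are stored as a contiguous ``int32`` matrix for fast
    contingency counting.
    """

    def __init__(self, schema: Sequence[VariableSchema], codes: np.ndarray):
        self.schema = list(schema)
        self._by_name = schema_by_name(self.schema)
        codes = np.ascontiguousarray(codes, dtype=np.int32)
        if codes.ndim != 2 or codes.shape[1] != len(self.schema):
            raise ValueError(
                f"codes must be 2-D with {len(self.schema)} columns, got {codes.shape}"
            )
        for j, var in enumerate(self.schema):
            col = codes[:, j]
            if col.size and (col.min() < 0 or col.max() >= var.cardinality):
                raise ValueError(
                    f"column {var.name!r} contains codes outside 0..{var.cardinality - 1}"
                )
        self.codes = codes
        self._index = {v.name: j for j, v in enumerate(self.schema)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def columns(self) -> list[str]:
        return [v.name for v in self.schema]

    def variable(self, name: str) -> VariableSchema:
        return self._by_name[name]

    def cardinality(self, name: str) -> int:
        return self._by_name[name].cardinality

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self._index[name]]

    def __len__(self) -> int:
        return self.n_rows

    def __contains__(self, name: str) -> bool:
        return name in self._index

    # -- derived datasets ----------------------------------------------------
    def select(self, names: Iterable[str]) -> "CategoricalDataset":
        names = list(names)
        missing = [n for n in names if n not in self._index]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        idx = [self._index[n] for n in names]
        return CategoricalDataset([self._by_name[n] for n in names], self.codes[:, idx])

    def take(self, rows: np.ndarray) -> "CategoricalDataset":
        return CategoricalDataset(self.schema, self.codes[np.asarray(rows)])

    def mask_rows(self, keep: np.ndarray) -> "CategoricalDataset":
        return CategoricalDataset(self.schema, self.codes[np.asarray(keep, dtype=bool)])

    # -- conversions ---------------------------------------------------------
    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: Sequence[VariableSchema]
    ) -> "CategoricalDataset":
        """Build from a DataFrame of level labels (or integer codes)."""
        by_name = schema_by_name(schema)
        cols = []
        for var in schema:
            if var.name not in frame.columns:
                raise KeyError(f"frame is missing column {var.name!r}")
            s = frame[var.name]
            if s.isna().any():
                bad = int(s.isna().to_numpy().argmax())
                raise ValueError(
                    f"missing value in column {var.name!r} at row {bad}; "
                    "apply complete-case filtering first"
                )
            if pd.api.types.is_integer_dtype(s):
                codes = s.to_numpy(dtype=np.int64)
            else:
                mapping = {lab: i for i, lab in enumerate(var.levels)}
                codes = s.astype(str).map(mapping).to_numpy()
                if np.isnan(codes.astype(float)).any():
                    bad_vals = sorted(set(s.astype(str)) - set(var.levels))
                    raise ValueError(
                        f"column {var.name!r} contains undeclared levels {bad_vals}"
                    )
                codes = codes.astype(np.int64)
            cols.append(codes)
        mat = np.column_stack(cols) if cols else np.empty((len(frame), 0), dtype=np.int32)
        ds = cls(list(schema), mat)
        del by_name
        return ds

    def to_frame(self, labels: bool = True) -> pd.DataFrame:
        data = {}
        for j, var in enumerate(self.schema):
            col = self.codes[:, j]
            if labels:
                data[var.name] = pd.Categorical.from_codes(
                    col, categories=list(var.levels)
                )
            else:
                data[var.name] = col.copy()
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
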