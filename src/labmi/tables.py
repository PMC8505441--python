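"""The wide laboratory table shared by every pipeline stage.

A :class:`LabTable` holds one numeric value per (patient, analyte, time
block) cell, where the two blocks are the last observation *before* and the
first observation *after* a patient's index date.  Missing cells are NaN.
Columns are a two-level pandas MultiIndex ``(analyte, block)`` with blocks
drawn from :data:`BLOCKS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Time-block convention used everywhere: 0 = before the index date,
#: 1 = after.  Keeping a single coding prevents sign errors in TIME effects.
BLOCKS = ("pre", "post")

Cell = tuple[object, str, str]  # (patient_id, analyte, block)


@dataclass
class LabTable:
    """Patients x (analyte, block) numeric table with explicit missing cells.

    Parameters
    ----------
    data
        DataFrame indexed by patient id with a two-level column MultiIndex
        ``(analyte, block)``; blocks must be a subset of :data:`BLOCKS`.
    log_transformed
        Analytes whose values are stored on the natural-log scale.  The flag
        applies to both blocks of an analyte.
    """

    data: pd.DataFrame
    log_transformed: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        cols = self.data.columns
        if not isinstance(cols, pd.MultiIndex) or cols.nlevels != 2:
            raise ValueError(
                "LabTable columns must be a 2-level MultiIndex (analyte, block)"
            )
        bad = set(cols.get_level_values(1)) - set(BLOCKS)
        if bad:
            raise ValueError(f"unknown time blocks {sorted(bad)}; expected {BLOCKS}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].tolist()
            raise ValueError(f"duplicate (analyte, block) columns: {dupes}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate patient ids in LabTable index")
        self.log_transformed = frozenset(self.log_transformed)

    # -- basic views ---------------------------------------------------

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    @property
    def analytes(self) -> list:
        """Analyte names in column order (first appearance)."""
        seen: dict = {}
        for a in self.data.columns.get_level_values(0):
            seen.setdefault(a, None)
        return list(seen)

    @property
    def n_patients(self) -> int:
        return len(self.data.index)

    def block(self, which: str) -> pd.DataFrame:
        """Return one time block as a patients x analytes frame."""
        if which not in BLOCKS:
            raise ValueError(f"unknown block {which!r}; expected one of {BLOCKS}")
        out = self.data.xs(which, axis=1, level=1)
        return out.reindex(columns=[a for a in self.analytes if (a, which) in self.data.columns])

    def copy(self) -> "LabTable":
        return LabTable(self.data.copy(), self.log_transformed)

    # -- missingness ---------------------------------------------------

    def missing_fraction(self, block: str | None = None) -> pd.Series:
        """Per-analyte fraction of missing cells (optionally one block)."""
        if block is None:
            sub = self.data
            frac = sub.isna().T.groupby(level=0).mean().mean(axis=1)
            return frac.reindex(self.analytes)
        return self.block(block).isna().mean(axis=0)

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    # -- cell-level access (used by holdout masks) ---------------------

    def get_cells(self, cells: Sequence[Cell]) -> np.ndarray:
        """Gather values at ``(patient, analyte, block)`` cells."""
        ridx = self.data.index.get_indexer([c[0] for c in cells])
        cidx = self.data.columns.get_indexer([(c[1], c[2]) for c in cells])
        if (ridx < 0).any() or (cidx < 0).any():
            raise KeyError("cell reference outside the table")
        return self.data.to_numpy()[ridx, cidx]

    def set_cells(self, cells: Sequence[Cell], values) -> "LabTable":
        """Return a copy with ``values`` written at ``cells``."""
        out = self.data.copy()
        arr = out.to_numpy()
        ridx = out.index.get_indexer([c[0] for c in cells])
        cidx = out.columns.get_indexer([(c[1], c[2]) for c in cells])
        if (ridx < 0).any() or (cidx < 0).any():
            raise KeyError("cell reference outside the table")
        arr[ridx, cidx] = np.asarray(values, dtype=float)
        return LabTable(
            pd.DataFrame(arr, index=out.index, columns=out.columns),
            self.log_transformed,
        )

    def with_data(self, data: pd.DataFrame) -> "LabTable":
        return LabTable(data, self.log_transformed)


def from_blocks(pre: pd.DataFrame, post: pd.DataFrame,
                log_transformed: Iterable = ()) -> LabTable:
    """Assemble a LabTable from two patients x analytes frames."""
    if not pre.index.equals(post.index):
        raise ValueError("pre and post blocks must share the same patients")
    if list(pre.columns) != list(post.columns):
        raise ValueError("pre and post blocks must share the same analytes")
    frames = {}
    for a in pre.columns:
        frames[(a, "pre")] = pre[a].astype(float)
        frames[(a, "post")] = post[a].astype(float)
    data = pd.DataFrame(frames)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return LabTable(data, frozenset(log_transformed))
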