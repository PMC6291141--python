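"""Containers for the two-condition time-series expression design.

The study layout is a factorial grid: two growth conditions (control medium
vs osmotic stress), a shared ordered set of sampling timepoints in hours, and
a fixed number of biological replicates per condition x timepoint. Expression
values are normalized log2 intensities; the matrix here is the
post-normalization object, so no probe-level handling happens anywhere in
this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
STRESS = "stress"

#: Sampling grid of the drought time course, in hours after transfer.
DEFAULT_TIMEPOINTS_H: tuple[int, ...] = (0, 6, 24, 48, 96, 504)

ARRAY_LEVELS = ("condition", "timepoint_h", "replicate")


class IncompleteDesignError(ValueError):
    """The array metadata does not cover the full condition x time grid."""


class MissingContrastError(ValueError):
    """A requested timepoint is absent in one of the two conditions."""


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design of the time-course experiment.

    Parameters
    ----------
    timepoints_h
        Strictly increasing, non-negative sampling times in hours.
    conditions
        Exactly two labels; the first is the reference (control).
    n_replicates
        Biological replicates per condition x timepoint cell.
    shared_time0
        If True, the first timepoint is sampled once before treatment split
        and only control arrays exist at it (22 arrays for the default grid
        instead of 24).
    """

    timepoints_h: tuple[int, ...] = DEFAULT_TIMEPOINTS_H
    conditions: tuple[str, str] = (CONTROL, STRESS)
    n_replicates: int = 2
    shared_time0: bool = False

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints_h)
        object.__setattr__(self, "timepoints_h", tps)
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(self.conditions) != 2:
            raise ValueError("design needs exactly two conditions")
        if len(set(self.conditions)) != 2:
            raise ValueError("condition labels must differ")
        if len(tps) == 0:
            raise ValueError("design needs at least one timepoint")
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be non-negative hours")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")

    @property
    def control(self) -> str:
        return self.conditions[0]

    @property
    def stress(self) -> str:
        return self.conditions[1]

    def arrays(self) -> Iterator[tuple[str, int, int]]:
        """Yield (condition, timepoint_h, replicate) in canonical order."""
        for condition in self.conditions:
            for tp in self.timepoints_h:
                if (
                    self.shared_time0
                    and condition == self.stress
                    and tp == self.timepoints_h[0]
                ):
                    continue
                for rep in range(1, self.n_replicates + 1):
                    yield (condition, tp, rep)

    @property
    def n_arrays(self) -> int:
        return sum(1 for _ in self.arrays())


class ExpressionMatrix:
    """Genes x arrays matrix of normalized log2 intensities.

    Wraps a :class:`pandas.DataFrame` whose index is the unique gene ids and
    whose columns are a 3-level MultiIndex (condition, timepoint_h,
    replicate). Values must be finite; the column metadata must cover a full
    :class:`StudyDesign` grid (optionally with a shared pre-treatment 0 h).
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 3:
            raise ValueError(
                "expression columns must be a (condition, timepoint_h, replicate) MultiIndex"
            )
        data = data.copy()
        data.columns = data.columns.set_names(list(ARRAY_LEVELS))
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {data.index[bad[0]]!r}, "
                f"array {tuple(data.columns[bad[1]])}"
            )
        self.data = data
        self.design = self._infer_design()

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        arrays: Sequence[tuple[str, int, int]],
        values: np.ndarray,
    ) -> "ExpressionMatrix":
        columns = pd.MultiIndex.from_tuples(list(arrays), names=list(ARRAY_LEVELS))
        frame = pd.DataFrame(np.asarray(values, dtype=float),
                             index=list(gene_ids), columns=columns)
        return cls(frame)

    def _infer_design(self) -> StudyDesign:
        cols = self.data.columns
        conditions = list(dict.fromkeys(cols.get_level_values("condition")))
        if len(conditions) != 2:
            raise IncompleteDesignError(
                f"expected exactly two conditions, found {conditions}"
            )
        timepoints = sorted(set(int(t) for t in cols.get_level_values("timepoint_h")))
        cells: dict[tuple[str, int], set[int]] = {}
        for cond, tp, rep in cols:
            cells.setdefault((cond, int(tp)), set()).add(int(rep))
        n_rep = max(len(reps) for reps in cells.values())
        shared_time0 = False
        control, stress = conditions
        for cond in conditions:
            for tp in timepoints:
                reps = cells.get((cond, tp))
                if reps is None:
                    if cond == stress and tp == timepoints[0]:
                        shared_time0 = True
                        continue
                    raise IncompleteDesignError(
                        f"no arrays for condition={cond!r} timepoint={tp}h"
                    )
                if reps != set(range(1, n_rep + 1)):
                    raise IncompleteDesignError(
                        f"condition={cond!r} timepoint={tp}h has replicates "
                        f"{sorted(reps)}, expected 1..{n_rep}"
                    )
        return StudyDesign(
            timepoints_h=tuple(timepoints),
            conditions=(control, stress),
            n_replicates=n_rep,
            shared_time0=shared_time0,
        )

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.data.shape[1]

    @property
    def timepoints_h(self) -> tuple[int, ...]:
        return self.design.timepoints_h

    def replicate_values(self, condition: str, timepoint_h: int) -> np.ndarray:
        """Values for one design cell as a genes x replicates array.

        Raises :class:`MissingContrastError` if the cell is absent.
        """
        key_mask = [
            (c == condition and int(t) == int(timepoint_h))
            for c, t, _ in self.data.columns
        ]
        if not any(key_mask):
            raise MissingContrastError(
                f"no arrays for condition={condition!r} at {timepoint_h}h"
            )
        sub = self.data.loc[:, key_mask]
        order = np.argsort([int(r) for _, _, r in sub.columns], kind="stable")
        return sub.to_numpy()[:, order]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        d = self.design
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_arrays} arrays, "
            f"timepoints={list(d.timepoints_h)}, reps={d.n_replicates})"
        )
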