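"""Binned Pearson chi-squared independence tests and association reports.

Continuous activities in [0, 1] are discretized into equal-width bins
(closed below, top bin closed at 1, matching the activity bins of the
ensemble module); binary variables pass through as two categories.  The
chi-squared statistic is the usual sum of ``(O - E)^2 / E`` with
expected counts from the row/column marginal products; all-zero rows
and columns are dropped before computing the degrees of freedom.  When
fewer than two non-empty rows or columns remain, the test is flagged
inconclusive.  A uniform-expectation goodness-of-fit mode (equal
expected count in every cell) is available for comparison.

When independence is rejected between two ordered variables, the
direction of the association is read off a simple ordinal heuristic:
the mean category index of the first variable, conditional on each
level of the second, must be strictly increasing (positive) or strictly
decreasing (negative); anything else is indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import Attractor
from .ensemble import ControlScan, combined_proliferation_activity

__all__ = [
    "ContingencyTable",
    "IndependenceResult",
    "bin_values",
    "categorize",
    "chi_squared_independence",
    "correlation_direction",
    "association_report",
]

DIRECTION_POSITIVE = "positive"
DIRECTION_NEGATIVE = "negative"
DIRECTION_INDETERMINATE = "indeterminate"
DIRECTION_NA = "not_applicable"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-classifying two categorical variables."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths must match the counts matrix")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("a contingency table needs at least 2 rows and 2 columns")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_matrix(cls, counts) -> "ContingencyTable":
        counts = np.asarray(counts, dtype=np.int64)
        rows = tuple(str(i) for i in range(counts.shape[0]))
        cols = tuple(str(j) for j in range(counts.shape[1]))
        return cls(counts, rows, cols)

    @classmethod
    def from_observations(
        cls,
        x: Sequence[int],
        y: Sequence[int],
        n_x: int | None = None,
        n_y: int | None = None,
        x_labels: Sequence[str] | None = None,
        y_labels: Sequence[str] | None = None,
        weights: Sequence[int] | None = None,
    ) -> "ContingencyTable":
        """Cross-tabulate two integer category vectors.

        ``n_x``/``n_y`` fix the number of category levels (so empty
        levels keep their position and order); integer ``weights`` count
        each observation multiple times.
        """
        x = np.asarray(x, dtype=np.int64)
        y = np.asarray(y, dtype=np.int64)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        n_x = int(x.max()) + 1 if n_x is None else n_x
        n_y = int(y.max()) + 1 if n_y is None else n_y
        w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=np.int64)
        counts = np.zeros((n_x, n_y), dtype=np.int64)
        np.add.at(counts, (x, y), w)
        rows = tuple(x_labels) if x_labels else tuple(str(i) for i in range(n_x))
        cols = tuple(y_labels) if y_labels else tuple(str(j) for j in range(n_y))
        return cls(counts, rows, cols)


@dataclass(frozen=True)
class IndependenceResult:
    """Outcome of one chi-squared independence test."""

    statistic: float
    dof: int
    critical_value: float
    significance: float
    reject: bool
    inconclusive: bool = False
    direction: str = DIRECTION_NA
    table_used: ContingencyTable | None = None


def bin_values(values: Sequence[float], n_bins: int = 4) -> np.ndarray:
    """Equal-width binning of values in [0, 1] into 0-based bin indices.

    Bins are closed below; the top bin is closed at 1.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    arr = np.asarray([float(v) for v in values], dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any():
        bad = arr[(arr < 0) | (arr > 1)][0]
        raise ValueError(f"value {bad!r} outside [0, 1]")
    return np.minimum((arr * n_bins).astype(np.int64), n_bins - 1)


def categorize(values: Sequence[float], n_bins: int = 4) -> tuple[np.ndarray, int]:
    """Category indices plus level count; binary variables pass through."""
    arr = np.asarray([float(v) for v in values], dtype=float)
    if np.isin(arr, (0.0, 1.0)).all():
        return arr.astype(np.int64), 2
    return bin_values(arr, n_bins), n_bins


def _drop_empty(table: ContingencyTable) -> ContingencyTable | None:
    counts = table.counts
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    reduced = counts[np.ix_(keep_r, keep_c)]
    if reduced.shape[0] < 2 or reduced.shape[1] < 2:
        return None
    return ContingencyTable(
        reduced,
        tuple(l for l, k in zip(table.row_labels, keep_r) if k),
        tuple(l for l, k in zip(table.col_labels, keep_c) if k),
    )


def chi_squared_independence(
    table: ContingencyTable,
    significance: float = 0.05,
    uniform_expected: bool = False,
) -> IndependenceResult:
    """Pearson chi-squared test of independence on a contingency table.

    All-zero rows/columns are dropped first.  If fewer than two
    non-empty rows or columns remain the result is flagged
    ``inconclusive`` (and does not reject).  With
    ``uniform_expected=True`` the expected count is the same in every
    cell (a goodness-of-fit variant kept for comparison only).
    """
    if not 0 < significance < 1:
        raise ValueError("significance must lie in (0, 1)")
    reduced = _drop_empty(table)
    if reduced is None:
        return IndependenceResult(
            statistic=0.0,
            dof=0,
            critical_value=float("nan"),
            significance=significance,
            reject=False,
            inconclusive=True,
            table_used=None,
        )
    counts = reduced.counts.astype(float)
    total = counts.sum()
    if uniform_expected:
        expected = np.full_like(counts, total / counts.size)
    else:
        expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    statistic = float(((counts - expected) ** 2 / expected).sum())
    dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    critical = float(sps.chi2.ppf(1 - significance, dof))
    return IndependenceResult(
        statistic=statistic,
        dof=dof,
        critical_value=critical,
        significance=significance,
        reject=statistic > critical,
        inconclusive=False,
        table_used=reduced,
    )


def correlation_direction(
    table: ContingencyTable,
    ordered_rows: bool = True,
    ordered_cols: bool = True,
) -> str:
    """Ordinal direction of an association already found significant.

    Computes the mean row-category index conditional on each column
    level; strictly increasing means positive, strictly decreasing
    negative, anything else indeterminate.  Both variables must carry an
    inherent category order.
    """
    if not (ordered_rows and ordered_cols):
        raise ValueError("direction requires ordered categories on both variables")
    counts = table.counts.astype(float)
    col_totals = counts.sum(axis=0)
    keep = col_totals > 0
    if keep.sum() < 2:
        return DIRECTION_INDETERMINATE
    idx = np.arange(counts.shape[0], dtype=float)
    means = (idx @ counts[:, keep]) / col_totals[keep]
    diffs = np.diff(means)
    if (diffs > 0).all():
        return DIRECTION_POSITIVE
    if (diffs < 0).all():
        return DIRECTION_NEGATIVE
    return DIRECTION_INDETERMINATE


# -- Table-1-style association reports ----------------------------------


def _attractor_combined(attractor: Attractor, reporters, variant: str) -> float:
    return combined_proliferation_activity(
        float(attractor.activity(reporters[0])),
        float(attractor.activity(reporters[1])),
        variant,
    )


def _finals_frame(scan: ControlScan) -> pd.DataFrame:
    """One observation per distinct final state of the whole scan.

    Carries the control values, every node's per-attractor activity,
    and the per-final-state combined reporter activity ``alpha_c``.
    """
    net = scan.net
    records = []
    seen: set[tuple[int, ...]] = set()
    for row, basinlist in zip(scan.rows, scan.basins):
        for b in basinlist:
            if b.attractor.key in seen:
                continue
            seen.add(b.attractor.key)
            rec: dict[str, object] = dict(row.control_state.values)
            for name in net.internal_names:
                rec[name] = float(b.attractor.activity(name))
            rec["alpha_c"] = _attractor_combined(
                b.attractor, scan.reporters, scan.combined_variant
            )
            rec["basin_size"] = b.basin_size
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _controls_frame(scan: ControlScan) -> pd.DataFrame:
    """One observation per control state, with ensemble activities."""
    net = scan.net
    records = []
    for row in scan.rows:
        rec: dict[str, object] = dict(row.control_state.values)
        for name in net.internal_names:
            rec[name] = float(row.avg_activity[name])
        rec["alpha_c"] = row.combined
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _resolve(frame: pd.DataFrame, net, variable: str) -> pd.Series:
    if variable in frame.columns:
        return frame[variable]
    if variable.startswith("alpha_") and variable[len("alpha_"):] in frame.columns:
        return frame[variable[len("alpha_"):]]
    raise KeyError(f"cannot resolve variable {variable!r}")


def association_report(
    scan: ControlScan,
    pairs: Iterable[tuple[str, str, Mapping[str, int] | None]],
    n_bins: int = 4,
    significance: float = 0.05,
    basin_weighted: bool = False,
) -> pd.DataFrame:
    """Chi-squared association tests for variable pairs over a scan.

    Each pair is ``(variable_1, variable_2, conditions)``.  A variable
    is a control-node name, an internal-node name, ``"alpha_<node>"``
    or ``"alpha_c"``.  Pairs in which either variable is a plain
    internal node are observed per distinct final state (activities of
    that final state; ``alpha_c`` is then the combined activity of the
    final state itself); all other pairs are observed per control state
    (ensemble activities).  ``conditions`` filters on control values
    before testing.  With ``basin_weighted=True``, per-final-state
    observations are counted with their basin sizes instead of once
    each.
    """
    net = scan.net
    finals = _finals_frame(scan)
    controls = _controls_frame(scan)
    records = []
    for var1, var2, conditions in pairs:
        conditions = dict(conditions or {})
        per_final = any(
            v in net.internal_names for v in (var1, var2)
        )
        frame = finals if per_final else controls
        for name, value in conditions.items():
            if name not in frame.columns:
                raise KeyError(f"unknown conditioning variable {name!r}")
            frame_f = frame[frame[name] == value]
            frame = frame_f
        if len(frame) == 0:
            raise ValueError(
                f"no observations remain for ({var1}, {var2}) after "
                f"applying conditions {conditions}"
            )
        x_raw = _resolve(frame, net, var1)
        y_raw = _resolve(frame, net, var2)
        x_cat, n_x = categorize(x_raw, n_bins)
        y_cat, n_y = categorize(y_raw, n_bins)
        weights = None
        if basin_weighted and per_final:
            weights = frame["basin_size"].to_numpy()
        table = ContingencyTable.from_observations(
            x_cat, y_cat, n_x=n_x, n_y=n_y, weights=weights
        )
        result = chi_squared_independence(table, significance=significance)
        if result.inconclusive:
            direction = DIRECTION_NA
        elif result.reject:
            direction = correlation_direction(result.table_used)
        else:
            direction = DIRECTION_NA
        records.append(
            {
                "variable_1": var1,
                "variable_2": var2,
                "conditions": ",".join(f"{k}={v}" for k, v in conditions.items()),
                "n_obs": int(len(frame)),
                "chi2": result.statistic,
                "dof": result.dof,
                "reject": result.reject,
                "inconclusive": result.inconclusive,
                "direction": direction,
            }
        )
    return pd.DataFrame.from_records(records)
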