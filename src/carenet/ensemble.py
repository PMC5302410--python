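"""Exhaustive attractor enumeration, basin weights and ensemble averages.

For a fixed control state every one of the ``2^N_int`` initial internal
states is followed to its attractor ``F``.  The basin size ``I(F)`` (the
number of initial conditions reaching ``F``) yields the basin weight

    p(F) = I(F) / 2^N_int,

an exact rational that sums to 1 over the attractors of one control
state; it is the probability of ``F`` under equiprobable initial
conditions.  The ensemble (average) activity of node *i* under control
state *C* is the basin-weighted mean

    avg_alpha_i(C) = sum_k p(F_k) * alpha_i(F_k),

which equals the arithmetic mean of alpha_i over all initial conditions.
The combined proliferation activity couples the two reporter nodes
(WOX4 and HB8 for the bundled cambium network) through a quadratic mean,
and activities are discretized into none/low/medium/high bins.

Two enumeration engines are provided: the default fast engine packs
states into integers, materializes the full transition map once per
control state and resolves attractors by functional-graph traversal
(``carenet._engine``); the ``"naive"`` engine simulates every initial
condition step by step through the high-level dynamics layer and exists
as an independent cross-check for small networks.

When internal nodes are permanently clamped they are excluded from the
enumerated initial-condition bits (their initial value is the clamp
value), and ``N_int`` in the basin-weight denominator is the number of
*free* internal nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .dynamics import (
    Attractor,
    ControlAction,
    ControlState,
    NetworkState,
    all_control_states,
    simulate_to_attractor,
)
from .network import BooleanNetwork, NetworkValidationError

__all__ = [
    "DEFAULT_CAP",
    "BasinSummary",
    "ControlScanRow",
    "ControlScan",
    "StateSpaceCapError",
    "enumerate_attractors_exhaustive",
    "enumerate_attractors_naive",
    "basin_weight",
    "average_activity",
    "combined_proliferation_activity",
    "classify_activity_bin",
    "control_state_scan",
    "count_distinct_final_states",
]

DEFAULT_CAP = 2**28

ACTIVITY_BINS = ("none", "low", "medium", "high")


class StateSpaceCapError(RuntimeError):
    """Raised when an exhaustive run would exceed the state-space cap."""


@dataclass(frozen=True)
class BasinSummary:
    """An attractor with its basin size ``I(F)`` and weight ``p(F)``."""

    attractor: Attractor
    basin_size: int
    weight: Fraction


def basin_weight(basin_size: int, n_internal: int) -> Fraction:
    """Exact basin weight ``I(F) / 2^n_internal``."""
    total = 1 << n_internal
    if not 0 < basin_size <= total:
        raise ValueError(
            f"basin size {basin_size} out of range (0, {total}] for "
            f"{n_internal} internal nodes"
        )
    return Fraction(basin_size, total)


def average_activity(basins: Sequence[BasinSummary], node: str) -> Fraction:
    """Basin-weighted mean activity of ``node`` over a control state's attractors."""
    if not basins:
        raise ValueError("no attractors supplied")
    total = sum((b.weight for b in basins), Fraction(0))
    if total != 1:
        raise ValueError(f"basin weights sum to {total}, expected exactly 1")
    return sum(
        (b.weight * b.attractor.activity(node) for b in basins), Fraction(0)
    )


def combined_proliferation_activity(
    a_wox4: float, a_hb8: float, variant: str = "rms"
) -> float:
    """Combine the two reporter activities into one proliferation proxy.

    The default ``"rms"`` reading is the quadratic mean
    ``sqrt((a^2 + b^2)/2)``, which preserves scale (both reporters at
    ``x`` give ``x``).  The ``"mean-square"`` variant omits the root.
    """
    for value in (a_wox4, a_hb8):
        if not 0 <= value <= 1:
            raise ValueError(f"activity {value!r} outside [0, 1]")
    ms = (float(a_wox4) ** 2 + float(a_hb8) ** 2) / 2.0
    if variant == "rms":
        return math.sqrt(ms)
    if variant == "mean-square":
        return ms
    raise ValueError(f"unknown combined-activity variant {variant!r}")


def classify_activity_bin(a: float) -> str:
    """Discretize an activity into none/low/medium/high.

    Bins are closed below and open above, except the top bin which is
    closed at 1: [0, 0.25), [0.25, 0.5), [0.5, 0.75), [0.75, 1].
    """
    a = float(a)
    if not 0 <= a <= 1:
        raise ValueError(f"activity {a!r} outside [0, 1]")
    return ACTIVITY_BINS[min(int(a * 4), 3)]


# -- enumeration --------------------------------------------------------


def _prepare(
    net: BooleanNetwork,
    controls: ControlState,
    clamps: Iterable[ControlAction],
):
    """Split the network into free/fixed parts for one exhaustive run."""
    clamps = tuple(clamps)
    for action in clamps:
        if action.node not in net:
            raise NetworkValidationError(
                f"clamp references unknown node {action.node!r}"
            )
        if not action.permanent:
            raise ValueError(
                "windowed control actions are not supported in exhaustive "
                "enumeration; attractors are only defined for autonomous dynamics"
            )
    clamp_map = {a.node: a.value for a in clamps}
    eff_controls = {
        name: clamp_map.get(name, controls[name]) for name in net.control_names
    }
    clamped_internal = {
        name: clamp_map[name] for name in net.internal_names if name in clamp_map
    }
    free = [name for name in net.internal_names if name not in clamped_internal]
    return eff_controls, clamped_internal, free


def _full_encoding_base(
    net: BooleanNetwork,
    eff_controls: Mapping[str, int],
    clamped_internal: Mapping[str, int],
) -> int:
    base = 0
    for name, v in clamped_internal.items():
        base |= v << net.internal_bit(name)
    for name in net.control_names:
        base |= eff_controls[name] << (net.n_internal + net.control_bit(name))
    return base


def _expand(free_positions: Sequence[int], enc: int, base: int) -> int:
    full = base
    for k, pos in enumerate(free_positions):
        if (enc >> k) & 1:
            full |= 1 << pos
    return full


def enumerate_attractors_exhaustive(
    net: BooleanNetwork,
    controls: ControlState,
    clamps: Iterable[ControlAction] = (),
    cap: int = DEFAULT_CAP,
    engine: str = "fast",
) -> list[BasinSummary]:
    """Attractors and basins over every initial condition of one control state.

    Every ``2^(#free internal nodes)`` initial assignment is followed to
    its attractor; attractors are deduplicated by canonical form and the
    result is sorted by canonical key, so repeated runs are identical.
    """
    if engine == "naive":
        return enumerate_attractors_naive(net, controls, clamps)
    if engine != "fast":
        raise ValueError(f"unknown engine {engine!r}")
    eff_controls, clamped_internal, free = _prepare(net, controls, clamps)
    n_free = len(free)
    if (1 << n_free) > cap:
        raise StateSpaceCapError(
            f"2^{n_free} initial conditions exceed the cap of {cap} states"
        )

    # pack regulator data for the kernel: per-node fixed contributions and
    # thresholds, plus out-edge lists indexed by free source bit
    free_bit = {name: k for k, name in enumerate(free)}
    consts = np.zeros(n_free, np.int64)
    rhs = np.zeros(n_free, np.int64)
    out_edges: list[list[tuple[int, int]]] = [[] for _ in range(n_free)]
    for i, name in enumerate(free):
        summary = net.regulator_summary(name)
        rhs[i] = summary.n - 2 * summary.m
        for source, sign in summary.regulators:
            if source in free_bit:
                out_edges[free_bit[source]].append((i, sign))
            elif source in clamped_internal:
                consts[i] += sign * clamped_internal[source]
            else:  # control node
                consts[i] += sign * eff_controls[source]
    out_offsets = np.zeros(n_free + 1, np.int64)
    out_targets: list[int] = []
    out_weights: list[int] = []
    for b in range(n_free):
        for target, sign in out_edges[b]:
            out_targets.append(target)
            out_weights.append(sign)
        out_offsets[b + 1] = len(out_targets)

    f = _engine.build_transition_map(
        n_free,
        out_offsets,
        np.asarray(out_targets, np.int64),
        np.asarray(out_weights, np.int64),
        consts,
        rhs,
    )
    comp, on_cycle, n_attr = _engine.label_basins(f)
    sizes = np.bincount(comp, minlength=n_attr)

    free_positions = [net.internal_bit(name) for name in free]
    base = _full_encoding_base(net, eff_controls, clamped_internal)
    cycle_idx = np.nonzero(on_cycle)[0]
    cycle_labels = comp[cycle_idx]

    summaries: list[BasinSummary] = []
    for a in range(n_attr):
        members = cycle_idx[cycle_labels == a]
        start = int(members.min())
        cycle = [start]
        s = int(f[start])
        while s != start:
            cycle.append(s)
            s = int(f[s])
        encodings = [_expand(free_positions, enc, base) for enc in cycle]
        attractor = Attractor(net, encodings)
        summaries.append(
            BasinSummary(
                attractor=attractor,
                basin_size=int(sizes[a]),
                weight=basin_weight(int(sizes[a]), n_free),
            )
        )
    summaries.sort(key=lambda b: b.attractor.key)
    return summaries


def enumerate_attractors_naive(
    net: BooleanNetwork,
    controls: ControlState,
    clamps: Iterable[ControlAction] = (),
) -> list[BasinSummary]:
    """Reference enumeration by per-initial-condition simulation.

    Independent of the fast engine: every initial condition is advanced
    through :func:`carenet.dynamics.simulate_to_attractor`.  Quadratic
    constants make it practical only for small networks; it exists as an
    oracle for the fast engine.
    """
    eff_controls, clamped_internal, free = _prepare(net, controls, clamps)
    n_free = len(free)
    if n_free > 16:
        raise StateSpaceCapError(
            "naive enumeration is limited to 16 free internal nodes"
        )
    counts: dict[tuple[int, ...], int] = {}
    attractors: dict[tuple[int, ...], Attractor] = {}
    for enc in range(1 << n_free):
        values = dict(eff_controls)
        values.update(clamped_internal)
        for k, name in enumerate(free):
            values[name] = (enc >> k) & 1
        initial = NetworkState(net, values)
        attractor, _ = simulate_to_attractor(net, initial, clamps=clamps)
        key = attractor.key
        counts[key] = counts.get(key, 0) + 1
        attractors.setdefault(key, attractor)
    summaries = [
        BasinSummary(
            attractor=attractors[key],
            basin_size=count,
            weight=basin_weight(count, n_free),
        )
        for key, count in counts.items()
    ]
    summaries.sort(key=lambda b: b.attractor.key)
    return summaries


# -- control-state scan -------------------------------------------------


@dataclass
class ControlScanRow:
    """Per-control-state ensemble statistics."""

    control_state: ControlState
    avg_activity: dict[str, Fraction]
    combined: float
    bin_combined: str
    bin_wox4: str
    attractor_count: int


@dataclass
class ControlScan:
    """Result of a full control-state scan.

    ``rows[i]`` holds the ensemble statistics of the *i*-th control
    state (binary counting order) and ``basins[i]`` its full attractor
    list, so downstream statistics can be computed without re-running
    the enumeration.
    """

    net: BooleanNetwork
    rows: list[ControlScanRow]
    basins: list[list[BasinSummary]]
    reporters: tuple[str, str]
    combined_variant: str

    def to_frame(self) -> pd.DataFrame:
        """One row per control state: control bits, K(C), every avg activity,
        the combined activity and its bins."""
        records = []
        for row in self.rows:
            rec: dict[str, object] = dict(row.control_state.values)
            rec["K"] = row.attractor_count
            for name in self.net.internal_names:
                rec[f"alpha_{name}"] = float(row.avg_activity[name])
            rec["alpha_c"] = row.combined
            rec["bin_combined"] = row.bin_combined
            rec[f"bin_{self.reporters[0]}"] = row.bin_wox4
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def attractor_frame(self) -> pd.DataFrame:
        """Attractor catalogue: one row per (control state, attractor)."""
        records = []
        for row, basinlist in zip(self.rows, self.basins):
            label = row.control_state.label()
            for i, b in enumerate(basinlist):
                rec: dict[str, object] = {
                    "control_state": label,
                    "attractor": i,
                    "period": b.attractor.period,
                    "kind": b.attractor.kind,
                    "basin_size": b.basin_size,
                    "weight": float(b.weight),
                }
                for name in self.net.internal_names:
                    rec[f"alpha_{name}"] = float(b.attractor.activity(name))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def summary(self, merge_controls: bool = False) -> tuple[int, int, int]:
        return count_distinct_final_states(self, merge_controls=merge_controls)


def control_state_scan(
    net: BooleanNetwork,
    clamps: Iterable[ControlAction] = (),
    reporters: tuple[str, str] = ("WOX4", "HB8"),
    combined_variant: str = "rms",
    cap: int = DEFAULT_CAP,
    engine: str = "fast",
) -> ControlScan:
    """Exhaustive enumeration for all 2^(#controls) control states."""
    for name in reporters:
        if name not in net:
            raise NetworkValidationError(f"reporter node {name!r} not in network")
    clamps = tuple(clamps)
    rows: list[ControlScanRow] = []
    basins_per_state: list[list[BasinSummary]] = []
    for controls in all_control_states(net):
        basins = enumerate_attractors_exhaustive(
            net, controls, clamps=clamps, cap=cap, engine=engine
        )
        avg = {
            name: average_activity(basins, name)
            for name in net.names
        }
        combined = combined_proliferation_activity(
            float(avg[reporters[0]]), float(avg[reporters[1]]), combined_variant
        )
        rows.append(
            ControlScanRow(
                control_state=controls,
                avg_activity=avg,
                combined=combined,
                bin_combined=classify_activity_bin(combined),
                bin_wox4=classify_activity_bin(float(avg[reporters[0]])),
                attractor_count=len(basins),
            )
        )
        basins_per_state.append(basins)
    return ControlScan(
        net=net,
        rows=rows,
        basins=basins_per_state,
        reporters=tuple(reporters),
        combined_variant=combined_variant,
    )


def count_distinct_final_states(
    scan: ControlScan, merge_controls: bool = False
) -> tuple[int, int, int]:
    """Distinct final states across the whole scan.

    Returns ``(total, limit_cycles, max_period)``.  By default attractors
    are identified by their canonical full-state sequence (control bits
    included), so the same internal cycle reached under two control
    states counts twice; ``merge_controls=True`` deduplicates on the
    internal bits only.
    """
    seen: dict[tuple[int, ...], int] = {}
    for basinlist in scan.basins:
        for b in basinlist:
            key = b.attractor.internal_key if merge_controls else b.attractor.key
            seen[key] = b.attractor.period
    total = len(seen)
    cycles = sum(1 for p in seen.values() if p >= 2)
    max_period = max(seen.values(), default=0)
    return total, cycles, max_period
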