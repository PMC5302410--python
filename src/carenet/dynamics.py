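"""Threshold update rule, synchronous iteration and attractor detection.

The dynamics are deterministic and synchronous: at every time step each
internal node computes the signed sum ``r_i = sum_j s_j * w_ij`` over its
regulators *from the current state* and switches on exactly when ``r_i``
strictly exceeds the midpoint ``n_i/2 - m_i`` of its attainable range
(``n_i`` regulators, ``m_i`` of them inhibitory).  The inequality is
strict so that, e.g., a node with two activators needs both of them on.
Comparisons are carried out in exact integer/rational arithmetic; no
floating point is involved, so even/odd regulator counts are never
ambiguous.

Control nodes keep their value throughout a run.  Control actions
("clamps") may additionally force any node to a fixed value, permanently
or during a step window; they are applied after each synchronous update.

Because the state space is finite and the map deterministic, every
trajectory ends in a *steady state* (period 1) or a *limit cycle*
(period >= 2).  Attractors are put into a canonical rotation (the one
whose encoded-integer sequence is lexicographically minimal) so that they
can be hashed, compared and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .network import (
    ROLE_CONTROL,
    BooleanNetwork,
    NetworkValidationError,
    RegulatorSummary,
)

__all__ = [
    "ControlAction",
    "ControlState",
    "NetworkState",
    "Trajectory",
    "Attractor",
    "threshold_update",
    "synchronous_step",
    "simulate_to_attractor",
    "node_activity",
    "canonicalize_attractor",
    "all_control_states",
]


@dataclass(frozen=True)
class ControlAction:
    """Clamp ``node`` to ``value``; ``window=(start, end)`` limits it in time.

    A clamp without a window is permanent; a windowed clamp is active at
    every step ``start <= t <= end`` (step 0 is the initial state).
    Clamping to 0 emulates a knockout allele, clamping to 1 a
    constitutive one.
    """

    node: str
    value: int
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"clamp value must be 0 or 1, got {self.value!r}")
        if self.window is not None:
            start, end = self.window
            if start > end:
                raise ValueError(f"clamp window start {start} exceeds end {end}")

    @property
    def permanent(self) -> bool:
        return self.window is None

    def active_at(self, step: int) -> bool:
        if self.window is None:
            return True
        start, end = self.window
        return start <= step <= end


def _check_clamps(net: BooleanNetwork, clamps: Iterable[ControlAction]) -> tuple[ControlAction, ...]:
    clamps = tuple(clamps)
    for action in clamps:
        if action.node not in net:
            raise NetworkValidationError(f"clamp references unknown node {action.node!r}")
    return clamps


class ControlState:
    """One 0/1 assignment to every control node of a network."""

    __slots__ = ("net", "_values")

    def __init__(self, net: BooleanNetwork, values: Mapping[str, int]):
        missing = set(net.control_names) - set(values)
        extra = set(values) - set(net.control_names)
        if missing:
            raise NetworkValidationError(
                f"control state missing nodes: {sorted(missing)}"
            )
        if extra:
            raise NetworkValidationError(
                f"control state covers non-control nodes: {sorted(extra)}"
            )
        for name, v in values.items():
            if v not in (0, 1):
                raise NetworkValidationError(
                    f"control {name!r} must be 0 or 1, got {v!r}"
                )
        self.net = net
        self._values = {name: int(values[name]) for name in net.control_names}

    @property
    def values(self) -> dict[str, int]:
        return dict(self._values)

    @property
    def encoding(self) -> int:
        enc = 0
        for j, name in enumerate(self.net.control_names):
            enc |= self._values[name] << j
        return enc

    @classmethod
    def from_encoding(cls, net: BooleanNetwork, encoding: int) -> "ControlState":
        return cls(
            net,
            {name: (encoding >> j) & 1 for j, name in enumerate(net.control_names)},
        )

    def __getitem__(self, name: str) -> int:
        return self._values[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ControlState):
            return NotImplemented
        return self.net is other.net and self._values == other._values

    def __hash__(self) -> int:
        return hash((id(self.net), self.encoding))

    def label(self) -> str:
        return ",".join(f"{k}={v}" for k, v in self._values.items())

    def __repr__(self) -> str:
        return f"ControlState({self.label()})"


def all_control_states(net: BooleanNetwork) -> Iterator[ControlState]:
    """All 2^(#controls) control states, in binary counting order.

    Controls are taken in declaration order with the first-declared
    control most significant, so the scan order is reproducible.
    """
    k = net.n_control
    for i in range(1 << k):
        bits = {
            name: (i >> (k - 1 - pos)) & 1
            for pos, name in enumerate(net.control_names)
        }
        yield ControlState(net, bits)


class NetworkState:
    """A full 0/1 assignment to every node of a network.

    The integer ``encoding`` packs the internal nodes only (bit *k* is
    the *k*-th declared internal node); ``full_encoding`` additionally
    packs the control nodes above the internal bits, giving a unique
    integer per full state.
    """

    __slots__ = ("net", "_bits")

    def __init__(self, net: BooleanNetwork, values: Mapping[str, int]):
        missing = set(net.names) - set(values)
        if missing:
            raise NetworkValidationError(f"state missing nodes: {sorted(missing)}")
        extra = set(values) - set(net.names)
        if extra:
            raise NetworkValidationError(f"state covers unknown nodes: {sorted(extra)}")
        bits = []
        for name in net.names:
            v = values[name]
            if v not in (0, 1):
                raise NetworkValidationError(
                    f"state of {name!r} must be 0 or 1, got {v!r}"
                )
            bits.append(int(v))
        self.net = net
        self._bits = tuple(bits)

    @classmethod
    def _from_bits(cls, net: BooleanNetwork, bits: tuple[int, ...]) -> "NetworkState":
        obj = object.__new__(cls)
        obj.net = net
        obj._bits = bits
        return obj

    @classmethod
    def from_encoding(
        cls,
        net: BooleanNetwork,
        encoding: int,
        controls: "ControlState | Mapping[str, int]",
    ) -> "NetworkState":
        """Build a full state from an internal encoding plus control values."""
        if isinstance(controls, ControlState):
            cvals = controls.values
        else:
            cvals = dict(controls)
        values = dict(cvals)
        for k, name in enumerate(net.internal_names):
            values[name] = (encoding >> k) & 1
        return cls(net, values)

    @classmethod
    def from_full_encoding(cls, net: BooleanNetwork, full: int) -> "NetworkState":
        values = {}
        for k, name in enumerate(net.internal_names):
            values[name] = (full >> k) & 1
        for j, name in enumerate(net.control_names):
            values[name] = (full >> (net.n_internal + j)) & 1
        return cls(net, values)

    @property
    def values(self) -> dict[str, int]:
        return {name: bit for name, bit in zip(self.net.names, self._bits)}

    def __getitem__(self, name: str) -> int:
        idx = self.net._index.get(name)
        if idx is None:
            raise KeyError(name)
        return self._bits[idx]

    @property
    def encoding(self) -> int:
        enc = 0
        index = self.net._index
        bits = self._bits
        for k, name in enumerate(self.net.internal_names):
            enc |= bits[index[name]] << k
        return enc

    @property
    def full_encoding(self) -> int:
        enc = self.encoding
        index = self.net._index
        base = self.net.n_internal
        for j, name in enumerate(self.net.control_names):
            enc |= self._bits[index[name]] << (base + j)
        return enc

    def control_state(self) -> ControlState:
        return ControlState(
            self.net, {name: self[name] for name in self.net.control_names}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkState):
            return NotImplemented
        return self.net is other.net and self._bits == other._bits

    def __hash__(self) -> int:
        return hash((id(self.net), self._bits))

    def __repr__(self) -> str:
        on = [n for n, b in self.values.items() if b]
        return f"<NetworkState on={on}>"


def threshold_update(summary: RegulatorSummary, current: "NetworkState | Mapping[str, int]") -> int:
    """One application of the threshold rule to a single node.

    Returns 1 exactly when ``r = sum_j s_j w_j`` strictly exceeds
    ``n/2 - m``.  The comparison ``r > n/2 - m`` is evaluated as the
    integer inequality ``2 r > n - 2 m``, which is exact.
    """
    r = 0
    for source, sign in summary.regulators:
        try:
            s = current[source]
        except KeyError:
            raise KeyError(f"missing regulator value for {source!r}") from None
        r += s * sign
    return 1 if 2 * r > summary.n - 2 * summary.m else 0


def synchronous_step(
    net: BooleanNetwork,
    state: NetworkState,
    controls: ControlState | None = None,
    clamps: Iterable[ControlAction] = (),
    step: int = 1,
) -> NetworkState:
    """Advance the whole network by one synchronous step.

    Every internal node is updated simultaneously from the *current*
    state; control nodes are copied unchanged.  Clamps active at ``step``
    (the time index of the produced state) are applied afterwards.
    """
    clamps = _check_clamps(net, clamps)
    if controls is not None:
        for name in net.control_names:
            if state[name] != controls[name]:
                raise NetworkValidationError(
                    f"state disagrees with control state on {name!r}"
                )
    values = state.values
    new = dict(values)  # controls keep their value
    for name in net.internal_names:
        new[name] = threshold_update(net.regulator_summary(name), values)
    for action in clamps:
        if action.active_at(step):
            new[action.node] = action.value
    return NetworkState(net, new)


@dataclass
class Trajectory:
    """A recorded synchronous trajectory up to attractor detection."""

    states: list[NetworkState]
    transient_length: int

    def to_frame(self) -> pd.DataFrame:
        """One row per step, one 0/1 column per node, plus a step index."""
        names = self.states[0].net.names
        rows = [[s[name] for name in names] for s in self.states]
        frame = pd.DataFrame(rows, columns=list(names))
        frame.insert(0, "step", range(len(self.states)))
        return frame


class Attractor:
    """A steady state or limit cycle in canonical rotation.

    ``encodings`` are the full-state encodings (internal plus control
    bits) of the successive attractor states, rotated so the sequence is
    lexicographically minimal.  Two attractors compare equal exactly when
    they are the same cycle of full states; attractors reached under
    different control states are therefore distinct.
    """

    __slots__ = ("net", "encodings")

    def __init__(self, net: BooleanNetwork, encodings: Sequence[int]):
        encodings = tuple(int(e) for e in encodings)
        if not encodings:
            raise ValueError("attractor must contain at least one state")
        self.net = net
        self.encodings = _min_rotation(encodings)

    @property
    def period(self) -> int:
        return len(self.encodings)

    @property
    def kind(self) -> str:
        return "steady" if self.period == 1 else "cycle"

    @property
    def states(self) -> list[NetworkState]:
        return [NetworkState.from_full_encoding(self.net, e) for e in self.encodings]

    @property
    def key(self) -> tuple[int, ...]:
        return self.encodings

    @property
    def internal_key(self) -> tuple[int, ...]:
        """Canonical cycle of internal bits only (controls masked off)."""
        mask = (1 << self.net.n_internal) - 1
        return _min_rotation(tuple(e & mask for e in self.encodings))

    def _bit_position(self, node: str) -> int:
        net = self.net
        if node not in net:
            raise NetworkValidationError(f"unknown node {node!r}")
        if net.is_control(node):
            return net.n_internal + net.control_bit(node)
        return net.internal_bit(node)

    def activity(self, node: str) -> Fraction:
        """Fraction of attractor steps with ``node`` on (exact rational)."""
        pos = self._bit_position(node)
        on = sum((e >> pos) & 1 for e in self.encodings)
        return Fraction(on, self.period)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Attractor):
            return NotImplemented
        return self.net is other.net and self.encodings == other.encodings

    def __hash__(self) -> int:
        return hash((id(self.net), self.encodings))

    def __repr__(self) -> str:
        return f"<Attractor kind={self.kind} period={self.period}>"


def _min_rotation(seq: tuple[int, ...]) -> tuple[int, ...]:
    if len(seq) == 1:
        return seq
    best = min(range(len(seq)), key=lambda i: seq[i:] + seq[:i])
    return seq[best:] + seq[:best]


def node_activity(attractor: Attractor, node: str) -> Fraction:
    """Fraction of attractor steps in which ``node`` is on."""
    return attractor.activity(node)


def canonicalize_attractor(
    states: Sequence[NetworkState],
    clamps: Iterable[ControlAction] = (),
    verify: bool = True,
) -> Attractor:
    """Canonicalize a closed state cycle into an :class:`Attractor`.

    With ``verify=True`` (default) the states are checked to form a
    simple closed cycle under one synchronous step (with any permanent
    clamps applied); a :class:`ValueError` is raised otherwise.
    """
    states = list(states)
    if not states:
        raise ValueError("empty state sequence")
    net = states[0].net
    encodings = [s.full_encoding for s in states]
    if len(set(encodings)) != len(encodings):
        raise ValueError("states do not form a simple closed cycle (repeated state)")
    if verify:
        for i, s in enumerate(states):
            nxt = synchronous_step(net, s, clamps=clamps)
            if nxt != states[(i + 1) % len(states)]:
                raise ValueError("states do not form a closed cycle under the update")
    return Attractor(net, encodings)


def simulate_to_attractor(
    net: BooleanNetwork,
    initial: NetworkState,
    controls: ControlState | None = None,
    clamps: Iterable[ControlAction] = (),
) -> tuple[Attractor, Trajectory]:
    """Iterate synchronous steps from ``initial`` until a state recurs.

    Returns the attractor (canonical rotation) and the full recorded
    trajectory with its transient length.  Windowed clamps are honoured;
    recurrence detection only starts once every window has expired, so
    the detected cycle is an attractor of the autonomous (permanently
    clamped) dynamics.
    """
    clamps = _check_clamps(net, clamps)
    horizon = 0
    for action in clamps:
        if action.window is not None:
            horizon = max(horizon, action.window[1] + 1)
    # clamps active at step 0 override the supplied initial state
    init_vals = initial.values
    changed = False
    for action in clamps:
        if action.active_at(0) and init_vals[action.node] != action.value:
            init_vals[action.node] = action.value
            changed = True
    state = NetworkState(net, init_vals) if changed else initial
    if controls is not None:
        for name in net.control_names:
            if state[name] != controls[name]:
                raise NetworkValidationError(
                    f"initial state disagrees with control state on {name!r}"
                )

    seen: dict[int, int] = {}
    states: list[NetworkState] = [state]
    t = 0
    limit = (1 << net.n_internal) + horizon + 1
    while True:
        if t >= horizon:
            enc = states[t].full_encoding
            if enc in seen:
                first = seen[enc]
                cycle = states[first:t]
                attractor = canonicalize_attractor(cycle, clamps=clamps, verify=False)
                return attractor, Trajectory(states=states, transient_length=first)
            seen[enc] = t
        if t > limit:  # pragma: no cover - defensive; cannot happen
            raise RuntimeError("attractor not found within the state-space bound")
        states.append(
            synchronous_step(net, states[t], controls=controls, clamps=clamps, step=t + 1)
        )
        t += 1
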