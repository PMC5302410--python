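"""In-silico genetics: clamping, mutants and hormone-response protocols.

A mutant allele is emulated by a permanent control action: knockouts
clamp a node to 0 at every step, constitutive alleles clamp it to 1.
The hormone-response protocol measures a reporter's ensemble activity
with one hormone (control node) fixed on versus off while the remaining
free control nodes are varied over all of their assignments; the two
arms are averaged with equal weight per free-control assignment.  A
mutant is "insensitive" to a hormone when the on and off arms coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping

import pandas as pd

from .dynamics import ControlAction, ControlState
from .ensemble import (
    DEFAULT_CAP,
    ControlScan,
    average_activity,
    enumerate_attractors_exhaustive,
)
from .network import BooleanNetwork, NetworkValidationError

__all__ = [
    "ControlAction",
    "HormoneEffectProfile",
    "simulate_mutant",
    "hormone_effect_profile",
    "interaction_scan",
    "mutant_response_table",
]


@dataclass(frozen=True)
class HormoneEffectProfile:
    """Mean reporter activity with one hormone on versus off.

    ``avg_on``/``avg_off`` are unweighted means of the reporter's
    ensemble activity over all assignments of the free control nodes,
    with the hormone fixed at 1 and 0 respectively; ``background`` holds
    any control nodes held fixed in both arms.
    """

    hormone: str
    reporter: str
    background: tuple[tuple[str, int], ...]
    avg_on: float
    avg_off: float

    @property
    def response(self) -> float:
        """Signed effect of turning the hormone on."""
        return self.avg_on - self.avg_off


def simulate_mutant(
    net: BooleanNetwork,
    knockouts: Iterable[str] = (),
    constitutive: Iterable[str] = (),
) -> frozenset[ControlAction]:
    """Permanent clamps emulating mutant alleles.

    Knocked-out nodes are held at 0 at every step, constitutive ones at
    1.  The returned clamp set plugs into every dynamics and ensemble
    operation.
    """
    knockouts = set(knockouts)
    constitutive = set(constitutive)
    overlap = knockouts & constitutive
    if overlap:
        raise ValueError(
            f"nodes cannot be both knocked out and constitutive: {sorted(overlap)}"
        )
    for name in knockouts | constitutive:
        if name not in net:
            raise NetworkValidationError(f"unknown node {name!r}")
    actions = {ControlAction(name, 0) for name in knockouts}
    actions |= {ControlAction(name, 1) for name in constitutive}
    return frozenset(actions)


def _reporter_activity(
    net: BooleanNetwork,
    assignment: Mapping[str, int],
    reporter: str,
    clamps: Iterable[ControlAction],
    cap: int,
    engine: str,
) -> float:
    controls = ControlState(net, dict(assignment))
    basins = enumerate_attractors_exhaustive(
        net, controls, clamps=clamps, cap=cap, engine=engine
    )
    return float(average_activity(basins, reporter))


def hormone_effect_profile(
    net: BooleanNetwork,
    hormone: str,
    reporter: str,
    background: Mapping[str, int] | None = None,
    clamps: Iterable[ControlAction] = (),
    scan: ControlScan | None = None,
    cap: int = DEFAULT_CAP,
    engine: str = "fast",
) -> HormoneEffectProfile:
    """Reporter response to one hormone, all other free controls varied.

    ``background`` fixes a subset of the other control nodes in both
    arms.  If a :class:`~carenet.ensemble.ControlScan` computed with the
    same clamps is supplied, per-control-state activities are read from
    it instead of re-running the enumeration.
    """
    background = dict(background or {})
    if not net.is_control(hormone):
        raise NetworkValidationError(f"{hormone!r} is not a control node")
    if hormone in background:
        raise ValueError(f"hormone {hormone!r} must not appear in the background")
    if reporter not in net:
        raise NetworkValidationError(f"unknown reporter node {reporter!r}")
    for name in background:
        if not net.is_control(name):
            raise NetworkValidationError(f"background node {name!r} is not a control")

    clamp_map = {a.node: a.value for a in clamps}
    free = [
        name
        for name in net.control_names
        if name != hormone and name not in background and name not in clamp_map
    ]

    cache: dict[int, float] = {}
    if scan is not None:
        for row in scan.rows:
            cache[row.control_state.encoding] = float(row.avg_activity[reporter])

    def arm(value: int) -> float:
        total = 0.0
        count = 0
        for combo in product((0, 1), repeat=len(free)):
            assignment = dict(background)
            assignment[hormone] = value
            assignment.update(zip(free, combo))
            for name, v in clamp_map.items():
                if name in net.control_names:
                    assignment[name] = v
            controls = ControlState(net, assignment)
            if controls.encoding in cache:
                a = cache[controls.encoding]
            else:
                a = _reporter_activity(net, assignment, reporter, clamps, cap, engine)
            total += a
            count += 1
        return total / count

    return HormoneEffectProfile(
        hormone=hormone,
        reporter=reporter,
        background=tuple(sorted(background.items())),
        avg_on=arm(1),
        avg_off=arm(0),
    )


def interaction_scan(
    net: BooleanNetwork,
    hormones: tuple[str, str],
    background: Mapping[str, int],
    reporter: str,
    clamps: Iterable[ControlAction] = (),
    cap: int = DEFAULT_CAP,
    engine: str = "fast",
) -> pd.DataFrame:
    """2x2 table of reporter activity over the on/off combinations of two hormones.

    ``background`` must fix every other control node, so each cell is a
    single control state.
    """
    h1, h2 = hormones
    if h1 == h2:
        raise ValueError("the two hormones must be distinct")
    for h in (h1, h2):
        if not net.is_control(h):
            raise NetworkValidationError(f"{h!r} is not a control node")
        if h in background:
            raise ValueError(f"hormone {h!r} must not appear in the background")
    clamp_map = {a.node: a.value for a in clamps}
    expected = set(net.control_names) - {h1, h2} - set(clamp_map)
    if set(background) != expected:
        raise ValueError(
            f"background must fix exactly the other controls {sorted(expected)}"
        )
    table = pd.DataFrame(
        0.0,
        index=pd.Index([0, 1], name=h1),
        columns=pd.Index([0, 1], name=h2),
    )
    for v1 in (0, 1):
        for v2 in (0, 1):
            assignment = dict(background)
            assignment[h1] = v1
            assignment[h2] = v2
            for name, v in clamp_map.items():
                if name in net.control_names:
                    assignment[name] = v
            table.loc[v1, v2] = _reporter_activity(
                net, assignment, reporter, clamps, cap, engine
            )
    return table


def mutant_response_table(
    net: BooleanNetwork,
    clamps: Iterable[ControlAction] = (),
    reporter: str = "WOX4",
    scan: ControlScan | None = None,
    cap: int = DEFAULT_CAP,
    engine: str = "fast",
) -> pd.DataFrame:
    """Hormone-effect profiles for every control node under one mutant.

    One row per control node with the on/off arm means and the signed
    response; the mutant is defined by the clamp set (wild type when
    empty).
    """
    records = []
    for hormone in net.control_names:
        profile = hormone_effect_profile(
            net, hormone, reporter, clamps=clamps, scan=scan, cap=cap, engine=engine
        )
        records.append(
            {
                "hormone": hormone,
                "avg_on": profile.avg_on,
                "avg_off": profile.avg_off,
                "response": profile.response,
            }
        )
    return pd.DataFrame.from_records(records)
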