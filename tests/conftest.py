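"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import pytest

from carenet import (
    BooleanNetwork,
    Edge,
    Node,
    load_carenet,
    toy_catalogue,
)


def threshold_oracle(signs: list[int], states: list[int]) -> int:
    """Literal, independent evaluation of the threshold rule.

    ``r = sum_j s_j w_j`` compared against ``n/2 - m`` with exact
    rational arithmetic; strict inequality.  Deliberately mirrors the
    rule's definition rather than the implementation.
    """
    n = len(signs)
    m = sum(1 for w in signs if w == -1)
    r = sum(s * w for s, w in zip(states, signs))
    return 1 if Fraction(r) > Fraction(n, 2) - m else 0


def regulator_net(signs: list[int]) -> BooleanNetwork:
    """One internal target T regulated by control nodes R1..Rk with given signs."""
    nodes = [Node(f"R{i + 1}", "control") for i in range(len(signs))]
    nodes.append(Node("T", "internal"))
    edges = [Edge(f"R{i + 1}", "T", sign) for i, sign in enumerate(signs)]
    return BooleanNetwork(nodes, edges)


@pytest.fixture(scope="session")
def toys():
    return toy_catalogue()

@pytest.fixture(scope="session")
def carenet_net():
    return load_carenet()
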