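"""Random threshold-network generation and deterministic toy networks.

The random generator produces structurally valid signed networks
(controls with in-degree zero, one edge per ordered pair) from a seeded
spec; it backs the property-based tests and oracle comparisons.  The toy
catalogue collects tiny networks whose complete attractor structure is
known by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BooleanNetwork, Edge, Node

__all__ = ["GeneratorSpec", "random_threshold_network", "toy_catalogue"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the random network generator.

    ``mean_in_degree`` is the expected number of regulators per internal
    node (Poisson-distributed, truncated at the number of available
    source nodes); ``inhibition_fraction`` is the probability that an
    edge is inhibitory.
    """

    n_control: int
    n_internal: int
    mean_in_degree: float
    inhibition_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_internal < 1:
            raise ValueError("need at least one internal node")
        if self.n_control < 0:
            raise ValueError("control count must be non-negative")
        if not 0 <= self.inhibition_fraction <= 1:
            raise ValueError("inhibition_fraction must lie in [0, 1]")
        if self.mean_in_degree < 0:
            raise ValueError("mean_in_degree must be non-negative")
        if self.mean_in_degree > self.n_control + self.n_internal:
            raise ValueError(
                "mean_in_degree exceeds the number of available source nodes"
            )


def random_threshold_network(spec: GeneratorSpec) -> BooleanNetwork:
    """A seeded random signed network; equal specs give identical networks."""
    rng = np.random.default_rng(spec.seed)
    controls = [f"C{i + 1}" for i in range(spec.n_control)]
    internals = [f"G{i + 1}" for i in range(spec.n_internal)]
    nodes = [Node(name, "control") for name in controls]
    nodes += [Node(name, "internal") for name in internals]
    sources = controls + internals
    edges: list[Edge] = []
    for target in internals:
        k = min(int(rng.poisson(spec.mean_in_degree)), len(sources))
        chosen = rng.choice(len(sources), size=k, replace=False)
        for idx in sorted(chosen):
            sign = -1 if rng.random() < spec.inhibition_fraction else 1
            edges.append(Edge(sources[idx], target, sign))
    return BooleanNetwork(nodes, edges)


def toy_catalogue() -> dict[str, BooleanNetwork]:
    """Tiny networks with hand-derived attractor structure.

    - ``self_activator``: one internal node activating itself; two
      steady states (0 and 1) with basin weight 1/2 each.
    - ``oscillator``: A activates B, B inhibits A; a single period-4
      limit cycle containing all four states.
    - ``and_gate``: two control inputs both activating one internal
      node; the strict threshold makes the output require *both* inputs
      (one active input sits exactly at the midpoint and yields 0).
    """
    return {
        "self_activator": BooleanNetwork(
            [Node("A", "internal")],
            [Edge("A", "A", 1)],
        ),
        "oscillator": BooleanNetwork(
            [Node("A", "internal"), Node("B", "internal")],
            [Edge("A", "B", 1), Edge("B", "A", -1)],
        ),
        "and_gate": BooleanNetwork(
            [Node("U", "control"), Node("V", "control"), Node("Z", "internal")],
            [Edge("U", "Z", 1), Edge("V", "Z", 1)],
        ),
    }
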