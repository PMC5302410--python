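"""Loader for the bundled CARENET cambium-regulation network."""

from __future__ import annotations

from importlib import resources

from .network import BooleanNetwork, parse_network

__all__ = ["CONTROL_NODES", "REPORTERS", "load_carenet"]

#: External hormonal/peptidic inputs of CARENET.
CONTROL_NODES = ("CK0", "IAA0", "BR", "GA", "TDIF", "ETHL")

#: Proliferation reporter nodes (WOX4 and ATHB8).
REPORTERS = ("WOX4", "HB8")


def load_carenet() -> BooleanNetwork:
    """Load and validate the bundled 30-node CARENET definition."""
    text = (
        resources.files("carenet").joinpath("data/carenet.net").read_text("utf-8")
    )
    net = parse_network(text)
    if net.control_names != CONTROL_NODES or net.n_nodes != 30:
        raise RuntimeError("bundled CARENET definition is corrupt")
    return net
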