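"""Threshold updates, synchronous stepping and attractor detection."""

from fractions import Fraction
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carenet import (
    BooleanNetwork,
    ControlAction,
    ControlState,
    Edge,
    GeneratorSpec,
    NetworkState,
    Node,
    canonicalize_attractor,
    node_activity,
    random_threshold_network,
    simulate_to_attractor,
    synchronous_step,
    threshold_update,
)
from conftest import regulator_net, threshold_oracle


@pytest.mark.parametrize("states", list(product((0, 1), repeat=3)))
def test_two_activators_one_inhibitor_truth_table(states):
    """The worked 3-regulator example: on iff r = s1 + s2 - s3 > 1/2."""
    signs = [1, 1, -1]
    net = regulator_net(signs)
    current = dict(zip(("R1", "R2", "R3"), states))
    expected = threshold_oracle(signs, list(states))
    assert threshold_update(net.regulator_summary("T"), current) == expected
    # spot-check the two configurations worked through by hand
    if states == (1, 0, 0):
        assert expected == 1
    if states == (0, 1, 1):
        assert expected == 0


def test_tie_sits_exactly_at_midpoint_and_yields_zero():
    """Two activators with one active: r equals the midpoint, so output 0."""
    net = regulator_net([1, 1])
    assert threshold_update(net.regulator_summary("T"), {"R1": 1, "R2": 0}) == 0
    assert threshold_update(net.regulator_summary("T"), {"R1": 1, "R2": 1}) == 1


def test_inactive_single_inhibitor_turns_node_on():
    """One inhibitory regulator that is off: r = 0 > -1/2."""
    net = regulator_net([-1])
    assert threshold_update(net.regulator_summary("T"), {"R1": 0}) == 1
    assert threshold_update(net.regulator_summary("T"), {"R1": 1}) == 0


def test_missing_regulator_value_is_reported():
    net = regulator_net([1, 1])
    with pytest.raises(KeyError, match="R2"):
        threshold_update(net.regulator_summary("T"), {"R1": 1})


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    signs=st.lists(st.sampled_from([1, -1]), min_size=0, max_size=5),
    data=st.data(),
)
def test_threshold_update_matches_literal_oracle(signs, data):
    states = data.draw(
        st.lists(
            st.integers(0, 1), min_size=len(signs), max_size=len(signs)
        )
    )
    net = regulator_net(signs)
    current = {f"R{i + 1}": s for i, s in enumerate(states)}
    assert threshold_update(net.regulator_summary("T"), current) == threshold_oracle(
        signs, states
    )


def test_zero_regulator_node_collapses_to_zero():
    """A regulator-free internal node fails the strict comparison (r=0>0)."""
    net = BooleanNetwork([Node("A", "internal")])
    s1 = NetworkState(net, {"A": 1})
    s2 = synchronous_step(net, s1)
    assert s2["A"] == 0
    assert synchronous_step(net, s2)["A"] == 0


def test_oscillator_step_sequence(toys):
    net = toys["oscillator"]
    s = NetworkState(net, {"A": 0, "B": 0})
    seen = []
    for _ in range(5):
        seen.append((s["A"], s["B"]))
        s = synchronous_step(net, s)
    assert seen == [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]


def test_oscillator_limit_cycle_from_any_start(toys):
    net = toys["oscillator"]
    for a, b in product((0, 1), repeat=2):
        attractor, trajectory = simulate_to_attractor(
            net, NetworkState(net, {"A": a, "B": b})
        )
        assert attractor.period == 4
        assert attractor.kind == "cycle"
        assert trajectory.transient_length == 0


def test_self_activator_steady_states(toys):
    net = toys["self_activator"]
    for v in (0, 1):
        attractor, _ = simulate_to_attractor(net, NetworkState(net, {"A": v}))
        assert attractor.kind == "steady"
        assert attractor.period == 1
        assert attractor.states[0]["A"] == v


def test_and_gate_requires_both_inputs(toys):
    net = toys["and_gate"]
    for u, v in product((0, 1), repeat=2):
        state = NetworkState(net, {"U": u, "V": v, "Z": 0})
        attractor, _ = simulate_to_attractor(net, state)
        assert attractor.states[0]["Z"] == (u & v)


def test_steady_state_is_a_fixed_point_of_the_step(toys):
    net = toys["self_activator"]
    s = NetworkState(net, {"A": 1})
    assert synchronous_step(net, s) == s


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 2**31 - 1))
def test_controls_and_clamps_are_conserved_along_trajectories(seed):
    """Control values never change; clamped nodes hold their value at every step."""
    net = random_threshold_network(GeneratorSpec(2, 5, 2.0, 0.3, seed))
    controls = ControlState.from_encoding(net, seed % 4)
    clamp = ControlAction(net.internal_names[seed % net.n_internal], seed % 2)
    initial = NetworkState.from_encoding(net, seed % (1 << net.n_internal), controls)
    _, trajectory = simulate_to_attractor(
        net, initial, controls=controls, clamps=[clamp]
    )
    for state in trajectory.states:
        for name in net.control_names:
            assert state[name] == controls[name]
        assert state[clamp.node] == clamp.value


def test_determinism_bit_identical_reruns(toys):
    net = toys["oscillator"]
    s0 = NetworkState(net, {"A": 1, "B": 0})
    run1 = simulate_to_attractor(net, s0)
    run2 = simulate_to_attractor(net, s0)
    assert [s.full_encoding for s in run1[1].states] == [
        s.full_encoding for s in run2[1].states
    ]
    assert run1[0] == run2[0]


def test_windowed_clamp_forces_then_releases(toys):
    net = toys["oscillator"]
    s0 = NetworkState(net, {"A": 0, "B": 0})
    clamp = ControlAction("B", 1, window=(0, 2))
    _, trajectory = simulate_to_attractor(net, s0, clamps=[clamp])
    values_b = [s["B"] for s in trajectory.states]
    assert values_b[:3] == [1, 1, 1]
    # after release the oscillator resumes; its attractor is still period 4
    attractor, _ = simulate_to_attractor(net, s0, clamps=[clamp])
    assert attractor.period == 4


def test_canonical_rotation_is_rotation_invariant(toys):
    net = toys["oscillator"]
    _, trajectory = simulate_to_attractor(net, NetworkState(net, {"A": 0, "B": 0}))
    cycle = trajectory.states[:4]
    canon = [
        canonicalize_attractor(cycle[k:] + cycle[:k]) for k in range(4)
    ]
    assert all(a == canon[0] for a in canon)
    # idempotence: canonicalizing canonical states changes nothing
    again = canonicalize_attractor(canon[0].states)
    assert again == canon[0]


def test_canonicalize_rejects_non_cycles(toys):
    net = toys["oscillator"]
    s1 = NetworkState(net, {"A": 0, "B": 0})
    s2 = NetworkState(net, {"A": 1, "B": 1})  # not the successor of s1
    with pytest.raises(ValueError, match="closed cycle"):
        canonicalize_attractor([s1, s2])
    with pytest.raises(ValueError, match="closed cycle"):
        canonicalize_attractor([s1, s1])


def test_distinct_steady_states_have_distinct_canonical_forms(toys):
    net = toys["self_activator"]
    a0 = canonicalize_attractor([NetworkState(net, {"A": 0})])
    a1 = canonicalize_attractor([NetworkState(net, {"A": 1})])
    assert a0 != a1
    assert a0.period == a1.period == 1


def test_activity_on_cycles_and_steady_states(toys):
    net = toys["oscillator"]
    attractor, _ = simulate_to_attractor(net, NetworkState(net, {"A": 0, "B": 0}))
    # A is on in 2 of the 4 cycle states
    assert node_activity(attractor, "A") == Fraction(1, 2)
    steady, _ = simulate_to_attractor(
        toys["self_activator"],
        NetworkState(toys["self_activator"], {"A": 1}),
    )
    assert node_activity(steady, "A") == 1


def test_state_encoding_round_trips(carenet_net):
    controls = ControlState.from_encoding(carenet_net, 0b101010)
    state = NetworkState.from_encoding(carenet_net, 123456, controls)
    assert state.encoding == 123456
    rebuilt = NetworkState.from_full_encoding(carenet_net, state.full_encoding)
    assert rebuilt == state
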