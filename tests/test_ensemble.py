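"""Exhaustive enumeration, basin weights, ensemble averages and bins."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carenet import (
    ControlAction,
    ControlState,
    GeneratorSpec,
    StateSpaceCapError,
    average_activity,
    basin_weight,
    classify_activity_bin,
    combined_proliferation_activity,
    control_state_scan,
    count_distinct_final_states,
    enumerate_attractors_exhaustive,
    enumerate_attractors_naive,
    random_threshold_network,
)


def test_self_activator_has_two_equal_basins(toys):
    net = toys["self_activator"]
    basins = enumerate_attractors_exhaustive(net, ControlState(net, {}))
    assert len(basins) == 2
    assert [b.basin_size for b in basins] == [1, 1]
    assert [b.weight for b in basins] == [Fraction(1, 2), Fraction(1, 2)]
    assert all(b.attractor.kind == "steady" for b in basins)


def test_oscillator_single_cycle_owns_full_basin(toys):
    net = toys["oscillator"]
    basins = enumerate_attractors_exhaustive(net, ControlState(net, {}))
    assert len(basins) == 1
    assert basins[0].attractor.period == 4
    assert basins[0].weight == 1


@pytest.mark.parametrize(
    "size, n_int, expected",
    [(2**24, 24, Fraction(1)), (2**23, 24, Fraction(1, 2)), (1, 2, Fraction(1, 4))],
)
def test_basin_weight_examples(size, n_int, expected):
    assert basin_weight(size, n_int) == expected


@pytest.mark.parametrize("bad", [0, -1, 5])
def test_basin_weight_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        basin_weight(bad, 2)


def test_average_activity_weighted_mean(toys):
    net = toys["self_activator"]
    basins = enumerate_attractors_exhaustive(net, ControlState(net, {}))
    # activities 0 and 1 with weights 1/2 each
    assert average_activity(basins, "A") == Fraction(1, 2)


def test_average_activity_requires_unit_weight():
    from carenet import toy_catalogue

    net = toy_catalogue()["self_activator"]
    basins = enumerate_attractors_exhaustive(net, ControlState(net, {}))
    with pytest.raises(ValueError, match="sum"):
        average_activity(basins[:1], "A")


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 2**31 - 1))
def test_weighted_mean_equals_per_initial_condition_mean(seed):
    """The basin-weighted ensemble average equals the brute-force mean of
    per-initial-condition attractor activities."""
    from carenet import NetworkState, simulate_to_attractor

    net = random_threshold_network(GeneratorSpec(1, 4, 2.0, 0.3, seed))
    controls = ControlState.from_encoding(net, seed % 2)
    basins = enumerate_attractors_exhaustive(net, controls)
    for node in net.internal_names:
        direct = Fraction(0)
        for enc in range(16):
            initial = NetworkState.from_encoding(net, enc, controls)
            attractor, _ = simulate_to_attractor(net, initial)
            direct += attractor.activity(node)
        assert average_activity(basins, node) == direct / 16


@pytest.mark.parametrize(
    "inputs, rms, mean_square",
    [
        ((1, 1), 1.0, 1.0),
        ((0, 0), 0.0, 0.0),
        ((1, 0), 0.7071067811865476, 0.5),
    ],
)
def test_combined_activity_both_readings(inputs, rms, mean_square):
    assert combined_proliferation_activity(*inputs) == pytest.approx(rms)
    assert combined_proliferation_activity(
        *inputs, variant="mean-square"
    ) == pytest.approx(mean_square)


def test_combined_activity_rejects_out_of_range():
    with pytest.raises(ValueError):
        combined_proliferation_activity(1.2, 0.0)


@pytest.mark.parametrize(
    "value, expected",
    [
        (0.0, "none"),
        (0.2499, "none"),
        (0.25, "low"),
        (0.49, "low"),
        (0.5, "medium"),
        (0.7, "medium"),
        (0.75, "high"),
        (1.0, "high"),
    ],
)
def test_activity_bins_closed_below_top_closed(value, expected):
    assert classify_activity_bin(value) == expected


def test_activity_bin_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_activity_bin(1.01)


@settings(deadline=None, derandomize=True, max_examples=15)
@given(seed=st.integers(0, 2**31 - 1))
def test_fast_engine_matches_naive_simulation(seed):
    """Functional-graph enumeration and per-state simulation agree exactly."""
    net = random_threshold_network(
        GeneratorSpec(2, 3 + seed % 6, 2.0, 0.4, seed)
    )
    controls = ControlState.from_encoding(net, seed % 4)
    fast = enumerate_attractors_exhaustive(net, controls)
    naive = enumerate_attractors_naive(net, controls)
    assert [(b.attractor.key, b.basin_size) for b in fast] == [
        (b.attractor.key, b.basin_size) for b in naive
    ]
    assert sum((b.weight for b in fast), Fraction(0)) == 1


def test_fast_engine_matches_naive_under_clamps(toys):
    net = toys["and_gate"]
    controls = ControlState(net, {"U": 1, "V": 1})
    clamps = [ControlAction("Z", 0)]
    fast = enumerate_attractors_exhaustive(net, controls, clamps=clamps)
    naive = enumerate_attractors_naive(net, controls, clamps=clamps)
    assert [(b.attractor.key, b.basin_size) for b in fast] == [
        (b.attractor.key, b.basin_size) for b in naive
    ]
    assert fast[0].attractor.states[0]["Z"] == 0
    assert fast[0].weight == 1  # single free-internal-free state space


def test_windowed_clamps_are_rejected_in_enumeration(toys):
    net = toys["self_activator"]
    with pytest.raises(ValueError, match="windowed"):
        enumerate_attractors_exhaustive(
            net, ControlState(net, {}), clamps=[ControlAction("A", 1, (0, 3))]
        )


def test_state_space_cap_guard(toys):
    net = toys["oscillator"]
    with pytest.raises(StateSpaceCapError):
        enumerate_attractors_exhaustive(net, ControlState(net, {}), cap=2)


def test_scan_row_count_and_determinism(toys):
    net = toys["and_gate"]
    scan1 = control_state_scan(net, reporters=("Z", "Z"))
    scan2 = control_state_scan(net, reporters=("Z", "Z"))
    assert len(scan1.rows) == 4  # 2 controls
    assert scan1.to_frame().equals(scan2.to_frame())
    # Z steady state equals U AND V, so its ensemble activity is U*V
    frame = scan1.to_frame()
    assert (frame["alpha_Z"] == frame["U"] * frame["V"]).all()


def test_scan_single_control_two_rows(toys):
    net = toys["self_activator"]
    # graft a control onto the self-activator
    from carenet import BooleanNetwork, Edge, Node

    net2 = BooleanNetwork(
        [Node("C", "control"), Node("A", "internal")],
        [Edge("A", "A", 1)],
    )
    scan = control_state_scan(net2, reporters=("A", "A"))
    assert len(scan.rows) == 2


def test_count_distinct_final_states_toy_catalogue(toys):
    from carenet import BooleanNetwork, Edge, Node

    # control + self-activating internal: 2 controls x 2 steady states
    net = BooleanNetwork(
        [Node("C", "control"), Node("A", "internal")],
        [Edge("A", "A", 1)],
    )
    scan = control_state_scan(net, reporters=("A", "A"))
    assert count_distinct_final_states(scan) == (4, 0, 1)
    # the control bit does not feed back, so merging control states halves it
    assert count_distinct_final_states(scan, merge_controls=True) == (2, 0, 1)

    osc_scan = control_state_scan(toys["oscillator"], reporters=("A", "B"))
    assert count_distinct_final_states(osc_scan) == (1, 1, 4)


def test_clamping_a_reporter_forces_its_average_to_one(toys):
    net = toys["and_gate"]
    scan = control_state_scan(
        net, clamps=[ControlAction("Z", 1)], reporters=("Z", "Z")
    )
    for row in scan.rows:
        assert row.avg_activity["Z"] == 1
        assert row.combined == 1.0


def test_conservation_of_basin_mass_on_scan(toys):
    scan = control_state_scan(toys["oscillator"], reporters=("A", "B"))
    for basins in scan.basins:
        assert sum((b.weight for b in basins), Fraction(0)) == 1
        assert sum(b.basin_size for b in basins) == 4
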