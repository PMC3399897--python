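"""Dynamics, validation and edge accounting of processes and networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from procnet.core import (
    BooleanProcess,
    InteractionNetwork,
    ThresholdConfig,
    edge_count,
    realizes,
    simulate,
    step_boolean,
    step_threshold,
    validate_process,
)


def net_from(n, inhib_edges=(), stim_edges=(), degrade=()):
    ids = tuple(f"n{k + 1}" for k in range(n))
    inhib = np.zeros((n, n), dtype=np.int8)
    stim = np.zeros((n, n), dtype=np.int8)
    deg = np.zeros(n, dtype=np.int8)
    for j, i in inhib_edges:
        inhib[j, i] = 1
    for j, i in stim_edges:
        stim[j, i] = 1
    for i in degrade:
        deg[i] = 1
    return InteractionNetwork(ids, inhib, stim, deg)


class TestValidateProcess:
    def test_identity_construction(self):
        proc = validate_process([[0, 1], [1, 1]], ["g1", "g2"])
        assert (proc.N, proc.T) == (2, 2)
        assert proc.node_ids == ("g1", "g2")
        assert list(proc.transitions(0)) == [(0, 1)]

    def test_non_binary_entry_named(self):
        with pytest.raises(ValueError, match="non-binary entry.*row 0.*col 1"):
            validate_process([[0, 2]])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="T >= 1"):
            validate_process(np.zeros((0, 2), dtype=int))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            validate_process([[0, 1]], ["x", "x"])

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            validate_process([[0, 1], [1]])


class TestStepBoolean:
    def test_self_degradation_without_stimulus(self):
        net = net_from(1, degrade=[0])
        assert step_boolean(net, [1]).tolist() == [0]

    def test_stimulation_overrides_degradation(self):
        net = net_from(2, stim_edges=[(0, 1)], degrade=[0, 1])
        assert step_boolean(net, [1, 1]).tolist() == [0, 1]

    def test_noncanonical_pair_acts_as_pure_inhibition(self):
        both = net_from(2, inhib_edges=[(0, 1)], stim_edges=[(0, 1)])
        pure = net_from(2, inhib_edges=[(0, 1)])
        for state in ([1, 0], [1, 1], [0, 1], [0, 0]):
            assert step_boolean(both, state).tolist() == step_boolean(pure, state).tolist()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            step_boolean(net_from(2), [1])


class TestStepThreshold:
    def test_inhibition_dominates_many_stimulators(self):
        # node 4 receives one active inhibitor and 3 active stimulators
        n = 5
        net = net_from(
            n, inhib_edges=[(0, 4)], stim_edges=[(1, 4), (2, 4), (3, 4)]
        )
        out = step_threshold(net, [1, 1, 1, 1, 0], ThresholdConfig(dominance_weight=n))
        assert out[4] == 0
        assert step_boolean(net, [1, 1, 1, 1, 0])[4] == 0

    def test_zero_input_maintains_without_degradation(self):
        net = net_from(1)
        assert step_threshold(net, [1], ThresholdConfig(1)).tolist() == [1]

    def test_dominance_weight_below_one_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(0.5)


def random_net(rng, n):
    edge = rng.random((n, n)) < 0.5
    np.fill_diagonal(edge, False)
    kind = rng.random((n, n)) < 0.5
    return InteractionNetwork(
        tuple(f"n{k + 1}" for k in range(n)),
        (edge & kind).astype(np.int8),
        (edge & ~kind).astype(np.int8),
        (rng.random(n) < 0.5).astype(np.int8),
    )


def test_dominance_equivalence_exhaustive_states(rng):
    """With R >= N the threshold rule equals the Boolean rule on every state."""
    for n in (2, 3, 4, 5):
        for _ in range(10):
            net = random_net(rng, n)
            cfg = ThresholdConfig(dominance_weight=n)
            for bits in range(2 ** n):
                state = np.array([(bits >> k) & 1 for k in range(n)], dtype=np.int8)
                assert np.array_equal(
                    step_threshold(net, state, cfg), step_boolean(net, state)
                )


def test_canonicalization_leaves_dynamics_unchanged(rng):
    """Dropping the stimulatory half of a doubly-signed pair never changes
    the Boolean dynamics (inhibition dominates)."""
    for _ in range(20):
        n = int(rng.integers(2, 5))
        net = random_net(rng, n)
        # force some non-canonical pairs
        net.stim |= net.inhib
        np.fill_diagonal(net.stim, 0)
        canon = net.canonicalize()
        assert canon.is_canonical and not net.is_canonical or not net.inhib.any()
        for bits in range(2 ** n):
            state = np.array([(bits >> k) & 1 for k in range(n)], dtype=np.int8)
            assert np.array_equal(step_boolean(net, state), step_boolean(canon, state))


class TestSimulateAndRealizes:
    def test_fixed_point_without_edges_or_degradation(self):
        net = net_from(2)
        proc = simulate(net, [1, 0], 3)
        assert proc.states.tolist() == [[1, 0]] * 3

    def test_single_node_decay(self):
        net = net_from(1, degrade=[0])
        proc = simulate(net, [1], 3)
        assert proc.states.tolist() == [[1], [0], [0]]

    def test_simulation_is_realized_by_its_generator(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 6))
            net = random_net(rng, n)
            init = rng.integers(0, 2, size=n, dtype=np.int8)
            proc = simulate(net, init, int(rng.integers(1, 8)))
            assert realizes(net, proc)

    def test_unstimulated_activation_unrealizable(self):
        proc = validate_process([[0], [1]])
        for deg in ([0], [1]):
            assert not realizes(net_from(1, degrade=[0] if deg == [1] else []), proc)

    def test_n_mismatch(self):
        with pytest.raises(ValueError, match="does not match"):
            realizes(net_from(2), validate_process([[0]]))


@given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1), st.integers(0, 7))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_simulation_determinism(inh_bits, stim_bits, deg_bits):
    """simulate is bit-for-bit reproducible from (net, init, T)."""
    n = 3
    inhib = np.zeros((n, n), dtype=np.int8)
    stim = np.zeros((n, n), dtype=np.int8)
    k = 0
    for j in range(n):
        for i in range(n):
            if i == j:
                continue
            inhib[j, i] = (inh_bits >> k) & 1
            stim[j, i] = (stim_bits >> k) & 1
            k += 1
    net = InteractionNetwork(
        ("a", "b", "c"), inhib, stim,
        np.array([(deg_bits >> k) & 1 for k in range(n)], dtype=np.int8),
    )
    p1 = simulate(net, [1, 0, 1], 6)
    p2 = simulate(net, [1, 0, 1], 6)
    assert np.array_equal(p1.states, p2.states)
    assert realizes(net, p1)


class TestEdgeCount:
    def test_empty(self):
        assert edge_count(net_from(3)) == 0

    def test_mixed(self):
        assert edge_count(net_from(2, inhib_edges=[(0, 1)], stim_edges=[(1, 0)])) == 2

    def test_noncanonical_pair_counts_two(self):
        assert edge_count(net_from(2, inhib_edges=[(0, 1)], stim_edges=[(0, 1)])) == 2

    def test_degrade_bits_not_counted(self):
        assert edge_count(net_from(2, degrade=[0, 1])) == 0
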