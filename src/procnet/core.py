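"""Boolean processes, signed interaction networks, and their dynamics.

A *Boolean process* is a T x N matrix of 0/1 molecule states observed over
discrete time.  A *signed interaction network* assigns to every ordered node
pair (j, i) at most one inhibitory edge ``a_ji`` and one stimulatory edge
``b_ji``, plus a per-node self-degradation bit ``r_ii``.  Under the dominant
inhibition assumption the synchronous update rule is purely Boolean: node i is
on at the next step iff no active inhibitor points at it, and either an active
stimulator points at it or it was on and does not self-degrade.

The threshold variant of the rule weighs stimulation +1 and inhibition -R; for
a dominance weight R >= N it coincides with the Boolean rule, which is the
only property downstream code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "BooleanProcess",
    "InteractionNetwork",
    "ThresholdConfig",
    "validate_process",
    "step_boolean",
    "step_threshold",
    "simulate",
    "realizes",
    "edge_count",
]


def _as_bit_matrix(raw, what: str) -> np.ndarray:
    arr = np.asarray(raw)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be a rectangular 2-D array, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class BooleanProcess:
    """A binary time course: ``states[t, i]`` is the state of node i at time t.

    Rows are time steps (0-based), columns are nodes.  Use
    :func:`validate_process` to construct one from untrusted input.
    """

    node_ids: tuple[str, ...]
    states: np.ndarray  # T x N, int8, entries in {0, 1}

    def __post_init__(self):
        states = np.ascontiguousarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "node_ids", tuple(self.node_ids))
        if states.ndim != 2:
            raise ValueError("states must be 2-D (time x nodes)")
        T, N = states.shape
        if T < 1:
            raise ValueError("T >= 1 required")
        if N < 1:
            raise ValueError("N >= 1 required")
        if len(self.node_ids) != N:
            raise ValueError(f"{len(self.node_ids)} node ids for {N} columns")
        if len(set(self.node_ids)) != N:
            raise ValueError("duplicate node ids")
        bad = (states != 0) & (states != 1)
        if bad.any():
            t, i = map(int, np.argwhere(bad)[0])
            raise ValueError(f"non-binary entry at row {t}, col {i}")

    @property
    def N(self) -> int:
        return self.states.shape[1]

    @property
    def T(self) -> int:
        return self.states.shape[0]

    def transitions(self, i: int) -> Iterator[tuple[int, int]]:
        """Yield the T-1 (from, to) bit pairs of node i's column."""
        col = self.states[:, i]
        for t in range(self.T - 1):
            yield int(col[t]), int(col[t + 1])

    def active_others(self, t: int, i: int) -> frozenset[int]:
        """U_i(t): indices of nodes other than i that are on at time t."""
        on = np.flatnonzero(self.states[t]).tolist()
        return frozenset(j for j in on if j != i)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BooleanProcess)
            and self.node_ids == other.node_ids
            and np.array_equal(self.states, other.states)
        )

    def __hash__(self):
        return hash((self.node_ids, self.states.tobytes()))


def default_node_ids(n: int) -> tuple[str, ...]:
    return tuple(f"n{i + 1}" for i in range(n))


def validate_process(raw, node_ids: Sequence[str] | None = None) -> BooleanProcess:
    """Validate a raw integer matrix into a :class:`BooleanProcess`.

    Row order is preserved as time order.  Rejects ragged input, non-binary
    entries (naming row/column) and duplicate node ids.
    """
    arr = _as_bit_matrix(raw, "process")
    if arr.shape[0] < 1:
        raise ValueError("T >= 1 required")
    if arr.shape[1] < 1:
        raise ValueError("N >= 1 required")
    if node_ids is None:
        node_ids = default_node_ids(arr.shape[1])
    return BooleanProcess(tuple(node_ids), arr.astype(np.int8, copy=True))


@dataclass
class InteractionNetwork:
    """Signed network: ``inhib[j, i]`` = a_ji, ``stim[j, i]`` = b_ji, ``degrade[i]`` = r_ii.

    Matrices are indexed [source, target].  Diagonals of ``inhib`` and ``stim``
    are zero by contract (self-influence is carried solely by ``degrade``).  A
    network is *canonical* when no ordered pair is simultaneously inhibitory
    and stimulatory; non-canonical networks are legal (they arise as
    satisfiability witnesses) and produce the same dynamics as their
    canonical form because inhibition dominates.
    """

    node_ids: tuple[str, ...]
    inhib: np.ndarray
    stim: np.ndarray
    degrade: np.ndarray

    def __post_init__(self):
        self.node_ids = tuple(self.node_ids)
        n = len(self.node_ids)
        self.inhib = np.ascontiguousarray(self.inhib, dtype=np.int8)
        self.stim = np.ascontiguousarray(self.stim, dtype=np.int8)
        self.degrade = np.ascontiguousarray(self.degrade, dtype=np.int8)
        for name, m in (("inhib", self.inhib), ("stim", self.stim)):
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if ((m != 0) & (m != 1)).any():
                raise ValueError(f"{name} entries must be 0/1")
            if np.diagonal(m).any():
                raise ValueError(f"{name} diagonal must be zero (no self a/b edges)")
        if self.degrade.shape != (n,):
            raise ValueError(f"degrade must have length {n}")
        if ((self.degrade != 0) & (self.degrade != 1)).any():
            raise ValueError("degrade entries must be 0/1")

    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def is_canonical(self) -> bool:
        return not (self.inhib & self.stim).any()

    def canonicalize(self) -> "InteractionNetwork":
        """Return the canonical form: where a pair is both inhibitory and
        stimulatory, keep the inhibition and drop the stimulation."""
        stim = self.stim & (1 - self.inhib)
        return InteractionNetwork(self.node_ids, self.inhib.copy(), stim, self.degrade.copy())

    @classmethod
    def empty(cls, node_ids: Sequence[str]) -> "InteractionNetwork":
        n = len(node_ids)
        z = np.zeros((n, n), dtype=np.int8)
        return cls(tuple(node_ids), z, z.copy(), np.zeros(n, dtype=np.int8))


@dataclass(frozen=True)
class ThresholdConfig:
    """Dominance weight R >= 1 of inhibition over stimulation."""

    dominance_weight: float = 1.0

    def __post_init__(self):
        if self.dominance_weight < 1:
            raise ValueError("dominance_weight >= 1 required")


def _check_state(net: InteractionNetwork, state) -> np.ndarray:
    s = np.asarray(state, dtype=np.int8).ravel()
    if s.shape != (net.N,):
        raise ValueError(f"state length {s.size} != N={net.N}")
    if ((s != 0) & (s != 1)).any():
        raise ValueError("state entries must be 0/1")
    return s


def step_boolean(net: InteractionNetwork, state) -> np.ndarray:
    """One synchronous update of the dominant-inhibition Boolean rule.

    next[i] = (no j with a_ji=1 active) AND
              ((some j with b_ji=1 active) OR (state[i]=1 AND r_ii=0)).
    """
    s = _check_state(net, state)
    inhibited = (s @ net.inhib) > 0
    stimulated = (s @ net.stim) > 0
    maintain = s.astype(bool) & (net.degrade == 0)
    return (~inhibited & (stimulated | maintain)).astype(np.int8)


def step_threshold(net: InteractionNetwork, state, cfg: ThresholdConfig) -> np.ndarray:
    """One synchronous update of the weighted threshold rule.

    The input to node i is I_i = sum_j (b_ji - R * a_ji) * state[j]; the next
    state is 1 if I_i > 0, 0 if I_i < 0, and on a tie the node keeps its state
    unless it self-degrades.  For R >= N this reduces to :func:`step_boolean`.
    """
    s = _check_state(net, state)
    R = float(cfg.dominance_weight)
    total = s.astype(np.float64) @ (net.stim.astype(np.float64) - R * net.inhib.astype(np.float64))
    hold = s * (1 - net.degrade)
    return np.where(total > 0, 1, np.where(total < 0, 0, hold)).astype(np.int8)


def simulate(net: InteractionNetwork, init, T: int) -> BooleanProcess:
    """Run the Boolean dynamics for T rows starting from ``init`` (row 0)."""
    if T < 1:
        raise ValueError("T >= 1 required")
    s = _check_state(net, init)
    rows = np.empty((T, net.N), dtype=np.int8)
    rows[0] = s
    for t in range(1, T):
        rows[t] = step_boolean(net, rows[t - 1])
    return BooleanProcess(net.node_ids, rows)


def realizes(net: InteractionNetwork, proc: BooleanProcess) -> bool:
    """True iff the network reproduces every transition of the process."""
    if net.N != proc.N:
        raise ValueError(f"network N={net.N} does not match process N={proc.N}")
    if proc.T < 2:
        return True
    S = proc.states
    inhibited = (S @ net.inhib) > 0
    stimulated = (S @ net.stim) > 0
    maintain = S.astype(bool) & (net.degrade == 0)
    predicted = (~inhibited & (stimulated | maintain)).astype(np.int8)
    return bool(np.array_equal(predicted[:-1], S[1:]))


def edge_count(net: InteractionNetwork) -> int:
    """Number of interaction edges: inhibitory plus stimulatory assignments.

    Self-degradation bits are not edges and are never counted.  A
    non-canonical pair (a and b both set) counts as two.
    """
    return int(net.inhib.sum()) + int(net.stim.sum())
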