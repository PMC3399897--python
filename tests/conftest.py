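"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's constraint/Horn/enumeration
machinery: they enumerate whole canonical networks and check realization
through the public dynamics, so they can serve as ground truth for
feasibility, counting, minimality and backbone results.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pytest

from procnet.core import BooleanProcess, InteractionNetwork, realizes


@lru_cache(maxsize=8)
def all_canonical_networks(n: int) -> tuple[InteractionNetwork, ...]:
    """Every canonical network on n nodes: 3 states per ordered pair x 2^n
    degradation vectors.  Only sensible for n <= 3."""
    ids = tuple(f"n{k + 1}" for k in range(n))
    pairs = [(j, i) for j in range(n) for i in range(n) if j != i]
    nets = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        inhib = np.zeros((n, n), dtype=np.int8)
        stim = np.zeros((n, n), dtype=np.int8)
        for (j, i), s in zip(pairs, states):
            if s == 1:
                inhib[j, i] = 1
            elif s == 2:
                stim[j, i] = 1
        for rbits in itertools.product((0, 1), repeat=n):
            nets.append(
                InteractionNetwork(ids, inhib, stim, np.array(rbits, dtype=np.int8))
            )
    return tuple(nets)


def brute_force_solutions(proc: BooleanProcess) -> list[InteractionNetwork]:
    """All canonical networks realizing the process (whole-network check)."""
    return [net for net in all_canonical_networks(proc.N) if realizes(net, proc)]


def brute_force_count(proc: BooleanProcess) -> int:
    return len(brute_force_solutions(proc))


def brute_force_min_edges(proc: BooleanProcess) -> int | None:
    from procnet.core import edge_count

    sols = brute_force_solutions(proc)
    if not sols:
        return None
    return min(edge_count(net) for net in sols)


def all_processes(n: int, t: int):
    """Every 0/1 process matrix of shape t x n."""
    ids = tuple(f"n{k + 1}" for k in range(n))
    for bits in itertools.product((0, 1), repeat=n * t):
        yield BooleanProcess(ids, np.array(bits, dtype=np.int8).reshape(t, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
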