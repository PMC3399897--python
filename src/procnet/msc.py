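"""Minimum set cover, and its encoding as a Boolean-process gadget.

The NP-hardness of minimal-network inference is made executable here: any
coverable MSC instance is compiled into a Boolean process whose collector
node Z turns on after each element's pattern row, so Z's 0->1 constraints
are exactly the cover clauses (one per element, over the set-indicator
stimulatory edges S_k -> Z).  Every exact-minimal network of the gadget
therefore carries a minimum cover in its S -> Z stimulatory edges, and a
cover is read back from any realizing network.

Gadget layout (one concrete realization; tests enforce the semantics, not
the cell values).  For n elements and m sets, nodes are the set nodes
S_1..S_m, the collector Z, odd-row drivers D_2..D_n and even-row relays
E_1..E_n, with T = 2n + 2 rows:

* row 2(e-1): the pattern for element e — S_k on for every set containing e,
  relay E_e on;
* row 2e-1:  Z on; driver D_{e+1} on (it will stimulate pattern e+1);
* row 2n:    all relays on;
* row 2n+1:  everything off.

The relays resolve the activation conflicts a Z-driven layout would create:
E_e (active only at row 2(e-1) and row 2n) stimulates D_{e+1}, and D_{e+1}
(active only at row 2e-1) stimulates the next pattern.  The two tail rows
force b(E_e -> Z) = 0 and b(Z -> S_k) = 0 for every relevant node (the
all-relay row precedes a Z-off row with no available inhibitor), which pins
Z's stimulation clauses to the set nodes alone and keeps every non-cover
column of the gadget cost-constant across minimal solutions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import BooleanProcess, InteractionNetwork, realizes

__all__ = [
    "MSCInstance",
    "greedy_set_cover",
    "exact_set_cover",
    "msc_boolean_encoding",
    "msc_to_process",
    "recover_cover_from_network",
]


@dataclass(frozen=True)
class MSCInstance:
    """Universe {1..n_elements} and an ordered family of subsets."""

    n_elements: int
    sets: tuple[frozenset[int], ...]

    def __post_init__(self):
        object.__setattr__(self, "sets", tuple(frozenset(s) for s in self.sets))
        if self.n_elements < 1:
            raise ValueError("n_elements >= 1 required")
        universe = set(range(1, self.n_elements + 1))
        for k, s in enumerate(self.sets):
            if not s:
                raise ValueError(f"set {k} is empty")
            if not s <= universe:
                raise ValueError(f"set {k} is not a subset of the universe 1..{self.n_elements}")

    @property
    def m(self) -> int:
        return len(self.sets)

    def uncoverable_elements(self) -> list[int]:
        covered = set().union(*self.sets) if self.sets else set()
        return [e for e in range(1, self.n_elements + 1) if e not in covered]


def _require_coverable(inst: MSCInstance) -> None:
    missing = inst.uncoverable_elements()
    if missing:
        raise ValueError(f"element {missing[0]} is not covered by any set")


def greedy_set_cover(inst: MSCInstance) -> list[int]:
    """Classical greedy cover: repeatedly take the set covering the most
    uncovered elements (ties to the lowest index).  Returns 0-based set
    indices in selection order; within (1 + ln n) of optimal."""
    _require_coverable(inst)
    uncovered = set(range(1, inst.n_elements + 1))
    chosen: list[int] = []
    while uncovered:
        k = max(range(inst.m), key=lambda k: (len(inst.sets[k] & uncovered), -k))
        chosen.append(k)
        uncovered -= inst.sets[k]
    return chosen


def exact_set_cover(inst: MSCInstance, max_sets: int = 22) -> tuple[int, list[int]]:
    """Exhaustive minimum cover (size, one optimal cover, lexicographically
    first among minimum covers).  Guarded: refuses families larger than
    ``max_sets``."""
    _require_coverable(inst)
    if inst.m > max_sets:
        raise ValueError(f"{inst.m} sets exceed the enumeration cap ({max_sets})")
    universe = set(range(1, inst.n_elements + 1))
    for size in range(1, inst.m + 1):
        for combo in itertools.combinations(range(inst.m), size):
            covered = set().union(*(inst.sets[k] for k in combo))
            if covered >= universe:
                return size, list(combo)
    raise AssertionError("coverable instance must have a cover")  # pragma: no cover


def msc_boolean_encoding(inst: MSCInstance) -> list[frozenset[int]]:
    """CNF over set-indicator variables x_0..x_{m-1}: one all-positive clause
    per element e, over the sets containing e.  Satisfying assignments are
    exactly the covers."""
    _require_coverable(inst)
    return [
        frozenset(k for k in range(inst.m) if e in inst.sets[k])
        for e in range(1, inst.n_elements + 1)
    ]


def msc_to_process(inst: MSCInstance) -> tuple[BooleanProcess, dict]:
    """Compile a coverable MSC instance into a feasible Boolean process.

    Returns the gadget process and a role map with keys 'sets' (node id ->
    0-based set index), 'collector', 'drivers', 'relays'.
    """
    _require_coverable(inst)
    n, m = inst.n_elements, inst.m
    set_ids = [f"S{k + 1}" for k in range(m)]
    drivers = [f"D{e}" for e in range(2, n + 1)]
    relays = [f"E{e}" for e in range(1, n + 1)]
    node_ids = set_ids + ["Z"] + drivers + relays
    col = {nid: k for k, nid in enumerate(node_ids)}

    T = 2 * n + 2
    S = np.zeros((T, len(node_ids)), dtype=np.int8)
    for e in range(1, n + 1):
        pat = 2 * (e - 1)
        for k in range(m):
            if e in inst.sets[k]:
                S[pat, col[set_ids[k]]] = 1
        S[pat, col[f"E{e}"]] = 1
        odd = 2 * e - 1
        S[odd, col["Z"]] = 1
        if e < n:
            S[odd, col[f"D{e + 1}"]] = 1
    for r in relays:
        S[2 * n, col[r]] = 1
    # final row all zero

    proc = BooleanProcess(tuple(node_ids), S)
    roles = {
        "sets": {sid: k for k, sid in enumerate(set_ids)},
        "collector": "Z",
        "drivers": drivers,
        "relays": relays,
    }
    return proc, roles


def recover_cover_from_network(
    net: InteractionNetwork, roles: dict, proc: BooleanProcess | None = None
) -> list[int]:
    """Read the cover off a realizing network: the 0-based indices of set
    nodes with a stimulatory edge into the collector.  When the network is
    exact-minimal for its gadget, this is a minimum cover."""
    if proc is not None and not realizes(net, proc):
        raise ValueError("network does not realize the gadget process")
    idx = {nid: k for k, nid in enumerate(net.node_ids)}
    z = idx[roles["collector"]]
    chosen = [
        k for sid, k in roles["sets"].items() if net.stim[idx[sid], z] == 1
    ]
    return sorted(chosen)
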