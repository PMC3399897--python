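"""Polynomial-time feasibility of a Boolean process via HORNSAT.

The Horn formula built by :mod:`procnet.constraints` is satisfiable iff some
signed network realizes the process.  Unit propagation computes the unique
*least model* (minimal set of true variables); inverting it through the
polarity map yields a witness network, and probing each variable with both
unit pins classifies the solution-space backbone (edges present in all
solutions, edges absent from all solutions, free edges).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constraints import Clause, HornFormula, build_horn
from .core import BooleanProcess, InteractionNetwork

__all__ = [
    "HornResult",
    "horn_sat",
    "is_feasible",
    "witness_network",
    "forced_assignments",
    "BackboneReport",
]


@dataclass(frozen=True)
class HornResult:
    """Outcome of HORNSAT: satisfiability, the least model (ids of variables
    true in it) and, on failure, the index of a violated clause."""

    satisfiable: bool
    least_model: frozenset[int]
    conflict: int | None = None


def horn_sat(f: HornFormula, extra_units: Sequence[int] = ()) -> HornResult:
    """Decide a Horn formula by unit propagation; linear in total literal count.

    ``extra_units`` are additional single-literal clauses (signed variable
    ids in the formula's own polarity space), used for backbone probing.
    All variables start false; a clause whose negative literals are all
    forced true must fire its head, or the formula is unsatisfiable.
    """
    clauses: list[Clause] = list(f.clauses) + [(l,) for l in extra_units]
    heads: list[int] = []
    remaining: list[int] = []
    watch: dict[int, list[int]] = defaultdict(list)  # var -> clauses with -var
    queue: deque[int] = deque()
    true: set[int] = set()

    for ci, clause in enumerate(clauses):
        pos = [l for l in clause if l > 0]
        neg = [-l for l in clause if l < 0]
        if len(pos) > 1:
            raise ValueError(f"clause {clause} is not Horn")
        if len(pos) + len(neg) != len(clause):
            raise ValueError(f"malformed clause {clause}")
        heads.append(pos[0] if pos else 0)
        remaining.append(len(neg))
        for v in neg:
            watch[v].append(ci)
        if not neg:
            if not pos:
                return HornResult(False, frozenset(), conflict=ci)
            queue.append(pos[0])

    while queue:
        v = queue.popleft()
        if v in true:
            continue
        true.add(v)
        for ci in watch[v]:
            remaining[ci] -= 1
            if remaining[ci] == 0:
                h = heads[ci]
                if h == 0:
                    return HornResult(False, frozenset(true), conflict=ci)
                if h not in true:
                    queue.append(h)

    return HornResult(True, frozenset(true))


def is_feasible(proc: BooleanProcess) -> bool:
    """Can any signed network under dominant inhibition realize the process?

    A process with a single row has no transitions to explain and is feasible
    by definition.
    """
    if proc.T < 2:
        return True
    horn, _ = build_horn(proc)
    return horn_sat(horn).satisfiable


def _network_from_model(
    proc: BooleanProcess, horn: HornFormula, model: frozenset[int]
) -> InteractionNetwork:
    """Invert a (flipped-space) model into a network.

    Free and unmentioned a/b variables default to edge present (their primed
    variables are false in the least model), free r variables to 0.
    """
    n = proc.N
    inhib = np.ones((n, n), dtype=np.int8)
    stim = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(inhib, 0)
    np.fill_diagonal(stim, 0)
    degrade = np.zeros(n, dtype=np.int8)
    for v, (kind, j, i) in enumerate(horn.var_table, start=1):
        value = v in model
        if v in horn.flipped:
            value = not value  # primed -> original
        if kind == "a":
            inhib[j, i] = int(value)
        elif kind == "b":
            stim[j, i] = int(value)
        else:
            degrade[i] = int(value)
    return InteractionNetwork(proc.node_ids, inhib, stim, degrade)


def witness_network(proc: BooleanProcess) -> InteractionNetwork:
    """A network realizing the process, from the Horn least model.

    Deterministic but generally dense and possibly non-canonical: the least
    model pins exactly the forced assignments and everything left free
    defaults to an edge.  Minimality is a separate concern (see
    :mod:`procnet.minimality`).  Raises on an infeasible process.
    """
    if proc.T < 2:
        horn, _ = build_horn_trivial(proc)
        return _network_from_model(proc, horn, frozenset())
    horn, _ = build_horn(proc)
    res = horn_sat(horn)
    if not res.satisfiable:
        raise ValueError("infeasible: no network realizes this process")
    return _network_from_model(proc, horn, res.least_model)


def build_horn_trivial(proc: BooleanProcess):
    """Empty Horn formula for a transition-free (T = 1) process."""
    from .constraints import HornFormula, VarTable

    return HornFormula([], VarTable(), frozenset()), []


_STATUSES = ("forced_true", "forced_false", "free")


@dataclass
class BackboneReport:
    """Forced/free classification of every edge variable, in original
    (unflipped) semantics: ``forced_true`` means present in all solutions."""

    node_ids: tuple[str, ...]
    status: dict[tuple[str, int, int], str]

    def forced_true(self) -> set[tuple[str, int, int]]:
        return {k for k, s in self.status.items() if s == "forced_true"}

    def forced_false(self) -> set[tuple[str, int, int]]:
        return {k for k, s in self.status.items() if s == "forced_false"}

    def to_tsv(self) -> str:
        lines = ["kind\tsource\ttarget\tstatus"]
        for (kind, j, i), s in sorted(self.status.items()):
            lines.append(f"{kind}\t{self.node_ids[j]}\t{self.node_ids[i]}\t{s}")
        return "\n".join(lines) + "\n"


def forced_assignments(proc: BooleanProcess) -> BackboneReport:
    """Classify every variable as forced-true / forced-false / free.

    Probes the Horn formula twice per variable with a unit pin; both pins
    remain Horn under the global polarity flip, so the whole backbone is
    polynomial.  Variables never mentioned by a constraint are free.
    """
    n = proc.N
    all_vars = [("a", j, i) for j in range(n) for i in range(n) if j != i]
    all_vars += [("b", j, i) for j in range(n) for i in range(n) if j != i]
    all_vars += [("r", i, i) for i in range(n)]

    if proc.T < 2:
        return BackboneReport(proc.node_ids, {k: "free" for k in all_vars})

    horn, _ = build_horn(proc)
    base = horn_sat(horn)
    if not base.satisfiable:
        raise ValueError("infeasible: no network realizes this process")

    status: dict[tuple[str, int, int], str] = {}
    for key in all_vars:
        v = horn.var_table.get(*key)
        if v is None:
            status[key] = "free"
            continue
        # pin in flipped space; translate to original semantics afterwards
        sat_flip_true = horn_sat(horn, extra_units=(v,)).satisfiable
        sat_flip_false = horn_sat(horn, extra_units=(-v,)).satisfiable
        if v in horn.flipped:
            # flipped var true  <=> original false
            sat_orig_true, sat_orig_false = sat_flip_false, sat_flip_true
        else:
            sat_orig_true, sat_orig_false = sat_flip_true, sat_flip_false
        if sat_orig_true and sat_orig_false:
            status[key] = "free"
        elif sat_orig_true:
            status[key] = "forced_true"
        else:
            status[key] = "forced_false"
    return BackboneReport(proc.node_ids, status)
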