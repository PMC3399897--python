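"""From a Boolean process to edge-variable constraints, CNF, and a Horn formula.

For a target node i, each observed transition S_i(t) -> S_i(t+1) constrains
the incoming edge variables a_ji (inhibition), b_ji (stimulation) and the
self-degradation bit r_ii.  Writing U(t) for the set of nodes other than i
active at time t, W for the union of U(t) over all t whose successor has i on
(nodes thereby known not to inhibit i), and V(t) = U(t) \\ W:

* 0->1 : at least one b_ji over U(t), and a_ji = 0 for every j in U(t)
* 1->1 : (at least one b_ji over U(t), or r_ii = 0), and a_ji = 0 over U(t)
* 1->0 : some a_ji over V(t), or (r_ii = 1 and b_ji = 0 for every j in U(t))
* 0->0 : some a_ji over V(t), or b_ji = 0 for every j in U(t)

Multiplying the last two out yields CNF clauses, at most |U(t)| + 1 per
transition.  Globally flipping the polarity of every a- and b-variable
(primed variables a' = NOT a, b' = NOT b; r unflipped) renders every clause
Horn (at most one positive literal), so feasibility reduces to HORNSAT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import BooleanProcess

__all__ = [
    "TransitionConstraint",
    "NodeConstraintContext",
    "VarTable",
    "CNFFormula",
    "HornFormula",
    "derive_constraints",
    "to_cnf",
    "to_horn",
    "build_horn",
]

# a clause is a tuple of signed 1-based variable indices; () is the
# unsatisfiable empty clause
Clause = tuple[int, ...]


@dataclass(frozen=True)
class TransitionConstraint:
    """One transition's constraint for a target node.

    ``kind`` is the (from, to) bit pair as a two-character string
    ('01', '11', '10', '00').
    """

    kind: str
    t: int
    U: frozenset[int]
    V: frozenset[int]


@dataclass
class NodeConstraintContext:
    """Per-target-node constraint bookkeeping: the U/W/V sets and the
    structured constraint per transition."""

    target: int
    U: dict[int, frozenset[int]]
    W: frozenset[int]
    V: dict[int, frozenset[int]]
    constraints: list[TransitionConstraint]


class VarTable:
    """Bidirectional map between edge variables and 1-based integer indices.

    A variable is a triple (kind, source, target) with kind 'a' (inhibitory
    edge), 'b' (stimulatory edge) or 'r' (self-degradation, source == target).
    Variables are materialized lazily: pairs never mentioned by a constraint
    get no index and remain free.
    """

    def __init__(self):
        self._index: dict[tuple[str, int, int], int] = {}
        self._vars: list[tuple[str, int, int]] = []

    def index(self, kind: str, j: int, i: int) -> int:
        if kind not in ("a", "b", "r"):
            raise ValueError(f"unknown variable kind {kind!r}")
        if (kind == "r") != (j == i):
            raise ValueError("r variables are diagonal; a/b variables are not")
        key = (kind, j, i)
        v = self._index.get(key)
        if v is None:
            self._vars.append(key)
            v = len(self._vars)
            self._index[key] = v
        return v

    def get(self, kind: str, j: int, i: int) -> int | None:
        return self._index.get((kind, j, i))

    def lookup(self, v: int) -> tuple[str, int, int]:
        return self._vars[abs(v) - 1]

    def __len__(self) -> int:
        return len(self._vars)

    def __iter__(self):
        return iter(self._vars)


@dataclass
class CNFFormula:
    clauses: list[Clause]
    var_table: VarTable

    @property
    def num_vars(self) -> int:
        return len(self.var_table)


@dataclass
class HornFormula:
    """CNF in which every clause has at most one positive literal.

    ``flipped`` holds the variable ids whose sense was globally inverted
    (all a- and b-variables): a literal over a flipped variable speaks about
    the primed variable a' = NOT a / b' = NOT b.
    """

    clauses: list[Clause]
    var_table: VarTable
    flipped: frozenset[int]

    @property
    def num_vars(self) -> int:
        return len(self.var_table)


def derive_constraints(proc: BooleanProcess, i: int) -> NodeConstraintContext:
    """Build the U/W/V sets and per-transition constraints for node i."""
    if proc.T < 2:
        raise ValueError("no transitions: T >= 2 required")
    U = {t: proc.active_others(t, i) for t in range(proc.T - 1)}
    col = proc.states[:, i]
    W = frozenset().union(*(U[t] for t in range(proc.T - 1) if col[t + 1] == 1)) \
        if any(col[t + 1] == 1 for t in range(proc.T - 1)) else frozenset()
    V = {t: U[t] - W for t in U}
    constraints = [
        TransitionConstraint(kind=f"{col[t]}{col[t + 1]}", t=t, U=U[t], V=V[t])
        for t in range(proc.T - 1)
    ]
    return NodeConstraintContext(target=i, U=U, W=W, V=V, constraints=constraints)


def _cnf_for_constraint(c: TransitionConstraint, i: int, vt: VarTable) -> list[Clause]:
    a = lambda j: vt.index("a", j, i)
    b = lambda j: vt.index("b", j, i)
    U = sorted(c.U)
    V = sorted(c.V)
    out: list[Clause] = []
    if c.kind == "01":
        # possibly empty -> explicit false clause
        out.append(tuple(b(j) for j in U))
        out.extend((-a(j),) for j in U)
    elif c.kind == "11":
        out.append(tuple(b(j) for j in U) + (-vt.index("r", i, i),))
        out.extend((-a(j),) for j in U)
    elif c.kind == "10":
        av = tuple(a(j) for j in V)
        out.append(av + (vt.index("r", i, i),))
        out.extend(av + (-b(u),) for u in U)
    elif c.kind == "00":
        av = tuple(a(j) for j in V)
        out.extend(av + (-b(u),) for u in U)
    else:  # pragma: no cover - kinds are exhaustive by construction
        raise ValueError(f"unrecognized constraint kind {c.kind!r}")
    return out


def to_cnf(
    contexts: Iterable[NodeConstraintContext], var_table: VarTable | None = None
) -> CNFFormula:
    """Convert per-node constraints into CNF clauses (deduplicated, ordered)."""
    vt = var_table if var_table is not None else VarTable()
    seen: dict[Clause, None] = {}
    for ctx in contexts:
        for c in ctx.constraints:
            for clause in _cnf_for_constraint(c, ctx.target, vt):
                seen.setdefault(clause, None)
    return CNFFormula(clauses=list(seen), var_table=vt)


def to_horn(cnf: CNFFormula) -> HornFormula:
    """Globally flip every a- and b-variable; verify the result is Horn.

    The flip is consistent per variable across all clauses, so any assignment
    of the Horn formula maps back exactly to an assignment of the CNF (and
    hence of the original transition constraints).
    """
    vt = cnf.var_table
    flipped = frozenset(
        idx for idx, (kind, _, _) in enumerate(vt, start=1) if kind in ("a", "b")
    )
    out: list[Clause] = []
    for clause in cnf.clauses:
        flipped_clause = tuple(-l if abs(l) in flipped else l for l in clause)
        if sum(1 for l in flipped_clause if l > 0) > 1:
            raise ValueError(
                f"clause {clause} is not of a recognized family: "
                "polarity flip did not yield a Horn clause"
            )
        out.append(flipped_clause)
    return HornFormula(clauses=out, var_table=vt, flipped=flipped)


def build_horn(proc: BooleanProcess) -> tuple[HornFormula, list[NodeConstraintContext]]:
    """Full pipeline for a process: constraints for every node, one shared
    variable table, CNF, Horn.  Requires T >= 2."""
    contexts = [derive_constraints(proc, i) for i in range(proc.N)]
    cnf = to_cnf(contexts)
    return to_horn(cnf), contexts
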