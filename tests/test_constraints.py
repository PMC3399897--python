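"""Constraint derivation, CNF conversion and the Horn polarity flip."""

import itertools

import numpy as np
import pytest

from procnet.constraints import (
    HornFormula,
    VarTable,
    build_horn,
    derive_constraints,
    to_cnf,
    to_horn,
)
from procnet.core import validate_process

from conftest import all_processes


class TestDeriveConstraints:
    def test_active_set_excludes_target(self):
        proc = validate_process([[1, 0, 1], [0, 0, 0]])
        ctx = derive_constraints(proc, 1)
        assert ctx.U[0] == {0, 2}

    def test_activation_row_populates_w(self):
        # node 1 goes 0->1 while node 2 is active: node 2 cannot inhibit it
        proc = validate_process([[0, 1], [1, 1]])
        ctx = derive_constraints(proc, 0)
        assert ctx.W == {1}
        cnf = to_cnf([ctx])
        va = cnf.var_table.get("a", 1, 0)
        assert (-va,) in cnf.clauses

    def test_deactivation_context(self):
        # rows (1,1),(0,1), target node 1: W empty, V(0) = {2};
        # constraint: a_21 or (r_11 and not b_21)
        proc = validate_process([[1, 1], [0, 1]])
        ctx = derive_constraints(proc, 0)
        assert ctx.W == frozenset()
        assert ctx.V[0] == {1}
        assert ctx.constraints[0].kind == "10"
        cnf = to_cnf([ctx])
        va = cnf.var_table.get("a", 1, 0)
        vb = cnf.var_table.get("b", 1, 0)
        vr = cnf.var_table.get("r", 0, 0)
        assert (va, vr) in cnf.clauses and (va, -vb) in cnf.clauses

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="no transitions"):
            derive_constraints(validate_process([[0, 1]]), 0)


class TestToCnf:
    def test_deactivation_distribution(self):
        # 1->0 with V = {j1, j2}, U = {u}: (a_j1 | a_j2 | r) and (a_j1 | a_j2 | ~b_u)
        # build: nodes j1=0, j2=1, u=2, target i=3; target on at t=0 only,
        # u active only at t=0 but u also active before an on-row? keep W={}:
        proc = validate_process([[1, 1, 1, 1], [0, 0, 0, 0]])
        ctx = derive_constraints(proc, 3)
        cnf = to_cnf([ctx])
        vt = cnf.var_table
        a0, a1, a2 = (vt.get("a", j, 3) for j in (0, 1, 2))
        r = vt.get("r", 3, 3)
        assert (a0, a1, a2, r) in cnf.clauses
        bs = [vt.get("b", j, 3) for j in (0, 1, 2)]
        for b in bs:
            assert (a0, a1, a2, -b) in cnf.clauses

    def test_activation_clause_plus_units(self):
        # 0->1 with U = {u1, u2}: (b_u1 | b_u2) plus units ~a_u1, ~a_u2
        proc = validate_process([[1, 1, 0], [0, 0, 1]])
        ctx = derive_constraints(proc, 2)
        cnf = to_cnf([ctx])
        vt = cnf.var_table
        b0, b1 = vt.get("b", 0, 2), vt.get("b", 1, 2)
        assert (b0, b1) in cnf.clauses
        assert (-vt.get("a", 0, 2),) in cnf.clauses
        assert (-vt.get("a", 1, 2),) in cnf.clauses

    def test_empty_activation_is_false_clause(self):
        proc = validate_process([[0], [1]])
        cnf = to_cnf([derive_constraints(proc, 0)])
        assert () in cnf.clauses

    def test_clause_count_linear_per_transition(self, rng):
        """Each transition contributes at most |U| + 1 clauses (pre-dedup),
        so totals are O(N^2 T)."""
        for _ in range(20):
            n, t = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            proc = validate_process(rng.integers(0, 2, size=(t, n)))
            bound = 0
            clauses = 0
            for i in range(n):
                ctx = derive_constraints(proc, i)
                for c in ctx.constraints:
                    bound += len(c.U) + 1
                from procnet.constraints import _cnf_for_constraint

                vt = VarTable()
                for c in ctx.constraints:
                    clauses += len(_cnf_for_constraint(c, i, vt))
            assert clauses <= bound


class TestToHorn:
    def test_all_negative_after_flip(self):
        proc = validate_process([[1, 1, 0], [0, 0, 1]])
        cnf = to_cnf([derive_constraints(proc, 2)])
        horn = to_horn(cnf)
        b0 = cnf.var_table.get("b", 0, 2)
        b1 = cnf.var_table.get("b", 1, 2)
        assert (-b0, -b1) in horn.clauses

    def test_every_clause_at_most_one_positive(self, rng):
        for _ in range(30):
            n, t = int(rng.integers(1, 6)), int(rng.integers(2, 6))
            proc = validate_process(rng.integers(0, 2, size=(t, n)))
            horn, _ = build_horn(proc)
            for clause in horn.clauses:
                assert sum(1 for l in clause if l > 0) <= 1

    def test_flip_is_global_per_variable(self, rng):
        proc = validate_process(rng.integers(0, 2, size=(4, 4)))
        horn, _ = build_horn(proc)
        for v, (kind, _, _) in enumerate(horn.var_table, start=1):
            assert (v in horn.flipped) == (kind in ("a", "b"))


def _satisfies_cnf(clauses, assign):
    return all(
        any(assign[abs(l)] == (l > 0) for l in clause) if clause else False
        for clause in clauses
    )


def test_solution_set_preserved_by_polarity_flip():
    """An assignment satisfies the CNF iff its image under the polarity map
    satisfies the Horn formula — exhaustively over all small processes."""
    import itertools as it

    checked = 0
    for proc in all_processes(2, 3):
        cnf = to_cnf([derive_constraints(proc, i) for i in range(proc.N)])
        horn = to_horn(cnf)
        nv = cnf.num_vars
        if nv > 8:
            continue
        for bits in it.product((False, True), repeat=nv):
            assign = {v: bits[v - 1] for v in range(1, nv + 1)}
            image = {
                v: (not val if v in horn.flipped else val) for v, val in assign.items()
            }
            assert _satisfies_cnf(cnf.clauses, assign) == _satisfies_cnf(
                horn.clauses, image
            )
            checked += 1
    assert checked > 0


def test_unit_inhibition_clauses_match_w_sets(rng):
    """Unit ~a clauses exist exactly for pairs (j, i) with j in W_i."""
    for _ in range(20):
        n, t = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        proc = validate_process(rng.integers(0, 2, size=(t, n)))
        for i in range(n):
            ctx = derive_constraints(proc, i)
            cnf = to_cnf([ctx])
            units = {
                cnf.var_table.lookup(-c[0])
                for c in cnf.clauses
                if len(c) == 1 and c[0] < 0 and cnf.var_table.lookup(c[0])[0] == "a"
            }
            assert units == {("a", j, i) for j in ctx.W}


def test_per_node_separability(rng):
    """Clauses for target i mention only variables (., j, i) and r_ii."""
    proc = validate_process(rng.integers(0, 2, size=(5, 4)))
    for i in range(proc.N):
        cnf = to_cnf([derive_constraints(proc, i)])
        for clause in cnf.clauses:
            for lit in clause:
                kind, j, tgt = cnf.var_table.lookup(lit)
                assert tgt == i
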