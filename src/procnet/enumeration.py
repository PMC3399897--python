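"""Exhaustive per-node enumeration of canonical incoming-edge assignments.

Because the transition constraints never couple variables of different
target nodes, everything exhaustive (feasibility oracle, exact minimality,
exact solution counting, attainable pair-states) decomposes into independent
per-node searches over the 2 * 3^(N-1) canonical assignments of node i's
incoming pairs (none / inhibit / stimulate per ordered pair, plus the
self-degradation bit).

Two reductions keep this fast enough for the problem sizes used here:

* pairs (j, i) with j in W_i (j active before some row where i turns or
  stays on) can never be inhibitory, so their radix drops from 3 to 2;
* assignments are filtered transition by transition as numpy bitmask
  vectors, so the candidate set collapses quickly.

Digit convention per pair: 0 = none, 1 = inhibit, 2 = stimulate (radix-3
positions) or 0 = none, 1 = stimulate (radix-2 positions).  Enumeration
order is lexicographic in (r, digits), digits most significant first in
ascending source-node order, which fixes all tie-breaks deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BooleanProcess

__all__ = ["NodeEnumeration", "EnumerationCapError", "DEFAULT_CAP"]

DEFAULT_CAP = 8_000_000  # assignments per node, both r branches combined


class EnumerationCapError(ValueError):
    """Raised when a per-node search space exceeds the configured cap."""


@dataclass(frozen=True)
class NodeAssignment:
    """One canonical per-node assignment decoded to edge sets."""

    target: int
    a_sources: frozenset[int]
    b_sources: frozenset[int]
    r: int

    @property
    def edge_count(self) -> int:
        return len(self.a_sources) + len(self.b_sources)


class NodeEnumeration:
    """All canonical assignments realizing node ``i``'s column of a process.

    Parameters
    ----------
    proc : BooleanProcess
    i : int
        Target node index.
    max_assignments : int
        Guard on 2 * product(radices); exceeding it raises
        :class:`EnumerationCapError` advising the greedy / probing routes.
    """

    def __init__(self, proc: BooleanProcess, i: int, max_assignments: int = DEFAULT_CAP):
        self.proc = proc
        self.target = i
        self.others = [j for j in range(proc.N) if j != i]
        col = proc.states[:, i]
        T = proc.T

        # W: sources active before any on-row of i -> cannot inhibit i
        W: set[int] = set()
        for t in range(T - 1):
            if col[t + 1] == 1:
                W.update(j for j in self.others if proc.states[t, j] == 1)
        self.W = frozenset(W)

        self.radices = np.array(
            [2 if j in W else 3 for j in self.others], dtype=np.int64
        )
        total = 2 * int(np.prod(self.radices)) if self.others else 2
        if total > max_assignments:
            raise EnumerationCapError(
                f"{total} canonical assignments for node {i} exceed the cap "
                f"({max_assignments}); use the greedy heuristic or Horn probing"
            )
        self.total = total

        # weights for mixed-radix digit extraction, position 0 most significant
        P = len(self.others)
        weights = np.ones(P, dtype=np.int64)
        for p in range(P - 2, -1, -1):
            weights[p] = weights[p + 1] * self.radices[p + 1]
        self.weights = weights

        idx = np.arange(total // 2, dtype=np.int64)
        a_mask = np.zeros_like(idx)
        b_mask = np.zeros_like(idx)
        for p in range(P):
            digit = (idx // weights[p]) % self.radices[p]
            if self.radices[p] == 3:
                a_mask |= (digit == 1).astype(np.int64) << p
                b_mask |= (digit == 2).astype(np.int64) << p
            else:
                b_mask |= (digit == 1).astype(np.int64) << p

        # per-transition active-source bitmasks
        self._umasks = []
        self._steps = []
        for t in range(T - 1):
            m = 0
            for p, j in enumerate(self.others):
                if proc.states[t, j] == 1:
                    m |= 1 << p
            self._umasks.append(m)
            self._steps.append((int(col[t]), int(col[t + 1])))

        # filter survivors per r branch, transition by transition
        self.survivors: dict[int, dict[str, np.ndarray]] = {}
        for r in (0, 1):
            a, b, ix = a_mask, b_mask, idx
            for (u, (s_from, s_to)) in zip(self._umasks, self._steps):
                inh = (a & u) != 0
                stim = (b & u) != 0
                nxt = ~inh & (stim | bool(s_from and not r))
                keep = nxt == bool(s_to)
                if not keep.all():
                    a, b, ix = a[keep], b[keep], ix[keep]
                if ix.size == 0:
                    break
            self.survivors[r] = {"a": a, "b": b, "idx": ix}

    # ------------------------------------------------------------------

    def count(self) -> int:
        """Number of canonical assignments realizing the column."""
        return int(self.survivors[0]["idx"].size + self.survivors[1]["idx"].size)

    def _popcounts(self, r: int) -> np.ndarray:
        s = self.survivors[r]
        return np.bitwise_count(s["a"]) + np.bitwise_count(s["b"])

    def min_edges(self) -> tuple[int, int, NodeAssignment] | None:
        """(minimum edge count, number of optima, lexicographically first
        optimal assignment), or None if the column is infeasible.

        Ties between the two r branches go to r = 0.
        """
        best: int | None = None
        for r in (0, 1):
            if self.survivors[r]["idx"].size:
                m = int(self._popcounts(r).min())
                best = m if best is None else min(best, m)
        if best is None:
            return None
        n_opt = 0
        first: NodeAssignment | None = None
        for r in (0, 1):
            s = self.survivors[r]
            if not s["idx"].size:
                continue
            at = self._popcounts(r) == best
            n_opt += int(at.sum())
            if first is None and at.any():
                k = int(np.flatnonzero(at)[0])
                first = self._decode(int(s["a"][k]), int(s["b"][k]), r)
        return best, n_opt, first

    def _decode(self, a_mask: int, b_mask: int, r: int) -> NodeAssignment:
        a = frozenset(self.others[p] for p in range(len(self.others)) if a_mask >> p & 1)
        b = frozenset(self.others[p] for p in range(len(self.others)) if b_mask >> p & 1)
        return NodeAssignment(self.target, a, b, r)

    def attainable_pair_states(self) -> dict[int, set[str]]:
        """For each source j != i, which of {'none', 'inhibit', 'stimulate'}
        occur among realizing assignments."""
        out: dict[int, set[str]] = {j: set() for j in self.others}
        for p, j in enumerate(self.others):
            bit = np.int64(1) << p
            for r in (0, 1):
                s = self.survivors[r]
                if not s["idx"].size:
                    continue
                a_on = (s["a"] & bit) != 0
                b_on = (s["b"] & bit) != 0
                if a_on.any():
                    out[j].add("inhibit")
                if b_on.any():
                    out[j].add("stimulate")
                if (~a_on & ~b_on).any():
                    out[j].add("none")
        return out
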