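# procnet — process-driven inference of Boolean interaction networks

Molecular interaction maps are rarely observed directly; what experiments
deliver are snapshots of which molecules are on or off over time.  Given
such a binarized time course — a **Boolean process**, a T x N matrix of
states S_i(t) — `procnet` answers three questions about the signed networks
(inhibitory edges a_ji, stimulatory edges b_ji, self-degradation bits r_ii)
that could have produced it under the **dominant inhibition** update rule

    S_i(t+1) = [∀j: ¬(a_ji ∧ S_j(t))] ∧ [(∃j: b_ji ∧ S_j(t)) ∨ (S_i(t) ∧ ¬r_ii)]

* **Feasibility** — does *any* network realize the data?  Decided in
  polynomial time: the per-transition constraints become CNF, a global
  polarity flip of the edge variables makes every clause Horn, and unit
  propagation settles satisfiability.  The least model yields a witness
  network and, by probing, the solution-space **backbone** (edges forced in
  or out of every solution).
* **Minimality** — what is the smallest realizing network?  NP-hard (the
  package ships an executable reduction from minimum set cover), so a fast
  two-phase greedy heuristic is provided alongside an exhaustive per-node
  oracle that validates it at small N and counts the distinct minimal
  networks.
* **Designability** — how many canonical networks realize the process?
  Counted exactly by per-node enumeration at small N, and estimated at
  scale by an ordinary least-squares fit of ln D on six cheap
  solution-space features (ln D̂ = c0 + Σ c_k M_k).

The intended users are systems biologists and method developers working
with Boolean models of regulatory or signaling subsystems who need
solution-space structure (existence, cores, multiplicity), not just a
single inferred network.

## Worked example

A three-node cascade: a transient signal activates a middle node, which
activates an output and shuts the signal down, after which everything
decays.

```python
import procnet as pn

proc = pn.validate_process(
    [[1, 0, 0],
     [1, 1, 0],
     [0, 1, 1],
     [0, 0, 1],
     [0, 0, 0]],
    ["sig", "mid", "out"],
)
print("feasible:", pn.is_feasible(proc))
res = pn.exact_minimal_network(proc)
print("minimal edges:", res.total_edges, "| minimal networks:", res.minimal_network_count)
print("designability D =", pn.count_exact(proc))
bb = pn.forced_assignments(proc)
print("backbone forced true:", sorted(bb.forced_true()))
```

prints

```
feasible: True
minimal edges: 3 | minimal networks: 1
designability D = 6
backbone forced true: [('a', 1, 0), ('b', 0, 1), ('b', 1, 2), ('r', 2, 2)]
```

Read: the data are realizable; the unique 3-edge minimal network is
`sig -> mid`, `mid -| sig`, `mid -> out` (with `mid` and `out`
self-degrading); only 6 canonical networks of the 3^6 x 2^3 possible ones
reproduce the trajectory; and every one of them contains the stimulations
`sig -> mid`, `mid -> out`, the inhibition `mid -| sig`, and degradation of
`out` — the backbone, i.e. the mechanism the data force.

The same stack is scriptable from the shell:

```bash
procnet generate-process --n 5 --t 6 --seed 1 --out proc.csv
procnet feasible proc.csv            # exit 0 / 1
procnet minimal proc.csv --method exact
procnet count proc.csv
procnet msc-solve instance.json --method via-network
```

The package also ships the classic budding yeast cell-cycle trajectory
(`procnet.budding_yeast_process()`, 13 steps x 11 regulators, transcribed
from the published cell-cycle Boolean model) as a realistic fixture for the
exact oracles.

## Layout

| path | contents |
| --- | --- |
| `src/procnet/core.py` | processes, networks, Boolean and threshold dynamics |
| `src/procnet/constraints.py` | transition constraints -> CNF -> Horn formula |
| `src/procnet/feasibility.py` | HORNSAT, witness extraction, backbone probing |
| `src/procnet/enumeration.py` | vectorized per-node canonical enumeration |
| `src/procnet/minimality.py` | greedy heuristic, exact oracle, deviation harness |
| `src/procnet/designability.py` | exact counting, features M1..M6, log-linear fit |
| `src/procnet/msc.py` | set-cover solvers and the NP-hardness gadget |
| `src/procnet/generate.py`, `io.py`, `cli.py` | seeded generators, file formats, CLI |
| `docs/methods.md` | model, algorithms, design decisions, limitations |

See `docs/methods.md` for the full account of the model, the Horn
construction, tie-breaking rules, generator conditions and known
limitations.
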