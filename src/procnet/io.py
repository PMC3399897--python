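"""File formats: process CSV, network JSON / SIF, DIMACS CNF export.

Process CSV: an optional header line of node ids, then one comma-separated
0/1 row per time step (rows are time, columns are nodes).

Network JSON: ``{"nodes": [...], "edges": [{"source", "target", "sign"}],
"degrade": {id: 0|1}}`` with sign 'inhibit' or 'stimulate'.

SIF dialect: one edge per line, ``source<TAB>inhibits|activates<TAB>target``.
SIF carries no degradation bits; exporting a network with any set drops them
with a warning.

DIMACS: standard ``p cnf V C`` body plus a sidecar variable map, one line
per variable ``index kind source target flipped`` — enough to reconstruct
the Horn formula exactly on re-import.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path

import numpy as np

from .constraints import HornFormula, VarTable
from .core import BooleanProcess, InteractionNetwork, validate_process

__all__ = [
    "network_to_json_dict",
    "read_process_csv",
    "write_process_csv",
    "read_network_json",
    "write_network_json",
    "read_network_sif",
    "write_network_sif",
    "export_dimacs",
    "import_dimacs",
]


def _parse_bit(tok: str, lineno: int) -> int:
    tok = tok.strip()
    if tok not in ("0", "1"):
        raise ValueError(f"line {lineno}: expected 0/1, got {tok!r}")
    return int(tok)


def read_process_csv(path) -> BooleanProcess:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [row for row in csv.reader(fh) if row and any(c.strip() for c in row)]
    if not rows:
        raise ValueError(f"{path}: line 1: empty process file (T >= 1 required)")
    node_ids = None
    start = 0
    if any(c.strip() not in ("0", "1") for c in rows[0]):
        node_ids = [c.strip() for c in rows[0]]
        start = 1
        if len(rows) == 1:
            raise ValueError(f"{path}: line 2: no data rows (T >= 1 required)")
    data = []
    width = len(rows[start])
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) != width:
            raise ValueError(f"{path}: line {lineno}: ragged row ({len(row)} != {width})")
        data.append([_parse_bit(c, lineno) for c in row])
    return validate_process(np.array(data, dtype=np.int8), node_ids)


def write_process_csv(proc: BooleanProcess, path, header: bool = True) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(proc.node_ids)
        for row in proc.states:
            w.writerow([int(x) for x in row])


def network_to_json_dict(net: InteractionNetwork) -> dict:
    edges = []
    for j in range(net.N):
        for i in range(net.N):
            if net.inhib[j, i]:
                edges.append(
                    {"source": net.node_ids[j], "target": net.node_ids[i], "sign": "inhibit"}
                )
            if net.stim[j, i]:
                edges.append(
                    {"source": net.node_ids[j], "target": net.node_ids[i], "sign": "stimulate"}
                )
    return {
        "nodes": list(net.node_ids),
        "edges": edges,
        "degrade": {nid: int(net.degrade[i]) for i, nid in enumerate(net.node_ids)},
    }


def write_network_json(net: InteractionNetwork, path) -> None:
    Path(path).write_text(json.dumps(network_to_json_dict(net), indent=1) + "\n")


def read_network_json(path) -> InteractionNetwork:
    doc = json.loads(Path(path).read_text())
    nodes = list(doc["nodes"])
    idx = {nid: k for k, nid in enumerate(nodes)}
    n = len(nodes)
    inhib = np.zeros((n, n), dtype=np.int8)
    stim = np.zeros((n, n), dtype=np.int8)
    for e in doc.get("edges", []):
        j, i = idx[e["source"]], idx[e["target"]]
        sign = e["sign"]
        if sign == "inhibit":
            inhib[j, i] = 1
        elif sign == "stimulate":
            stim[j, i] = 1
        else:
            raise ValueError(f"unknown edge sign {sign!r}")
    degrade = np.zeros(n, dtype=np.int8)
    for nid, bit in doc.get("degrade", {}).items():
        degrade[idx[nid]] = int(bit)
    return InteractionNetwork(tuple(nodes), inhib, stim, degrade)


_SIF_RELATION = {"inhibits": "inhibit", "activates": "stimulate"}


def write_network_sif(net: InteractionNetwork, path) -> None:
    if net.degrade.any():
        warnings.warn(
            "SIF carries no self-degradation bits; they are dropped on export",
            stacklevel=2,
        )
    lines = []
    for j in range(net.N):
        for i in range(net.N):
            if net.inhib[j, i]:
                lines.append(f"{net.node_ids[j]}\tinhibits\t{net.node_ids[i]}")
            if net.stim[j, i]:
                lines.append(f"{net.node_ids[j]}\tactivates\t{net.node_ids[i]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_network_sif(path, node_ids=None) -> InteractionNetwork:
    """Parse the SIF dialect.  Node set defaults to the endpoints seen, in
    order of first appearance; pass ``node_ids`` to keep isolated nodes."""
    edges = []
    seen: dict[str, None] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 'source<TAB>relation<TAB>target'")
        src, rel, tgt = (p.strip() for p in parts)
        if rel not in _SIF_RELATION:
            raise ValueError(f"line {lineno}: unknown relation {rel!r}")
        edges.append((src, _SIF_RELATION[rel], tgt))
        seen.setdefault(src)
        seen.setdefault(tgt)
    nodes = list(node_ids) if node_ids is not None else list(seen)
    idx = {nid: k for k, nid in enumerate(nodes)}
    n = len(nodes)
    inhib = np.zeros((n, n), dtype=np.int8)
    stim = np.zeros((n, n), dtype=np.int8)
    for src, sign, tgt in edges:
        (inhib if sign == "inhibit" else stim)[idx[src], idx[tgt]] = 1
    return InteractionNetwork(tuple(nodes), inhib, stim, np.zeros(n, dtype=np.int8))


def export_dimacs(horn: HornFormula, path, map_path, node_ids=None) -> None:
    """Write the Horn formula as DIMACS CNF with a sidecar variable map."""
    lines = [f"p cnf {horn.num_vars} {len(horn.clauses)}"]
    lines += [" ".join(str(l) for l in clause) + " 0" for clause in horn.clauses]
    Path(path).write_text("\n".join(lines) + "\n")

    def name(k):
        return node_ids[k] if node_ids is not None else str(k)

    map_lines = []
    for v, (kind, j, i) in enumerate(horn.var_table, start=1):
        flipped = 1 if v in horn.flipped else 0
        map_lines.append(f"{v} {kind} {name(j)} {name(i)} {flipped}")
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))


def import_dimacs(path, map_path, node_ids=None) -> HornFormula:
    """Reconstruct a Horn formula from a DIMACS file and its sidecar map."""
    clauses = []
    n_vars = n_clauses = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise ValueError(f"line {lineno}: malformed problem line")
            n_vars, n_clauses = int(parts[2]), int(parts[3])
            continue
        lits = [int(tok) for tok in line.split()]
        if not lits or lits[-1] != 0:
            raise ValueError(f"line {lineno}: clause must end with 0")
        clauses.append(tuple(lits[:-1]))
    if n_vars is None:
        raise ValueError("missing 'p cnf' header")
    if len(clauses) != n_clauses:
        raise ValueError(f"header declares {n_clauses} clauses, body has {len(clauses)}")

    index = {nid: k for k, nid in enumerate(node_ids)} if node_ids is not None else None
    vt = VarTable()
    flipped = set()
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"map line {lineno}: expected 'index kind source target flipped'")
        v, kind, src, tgt, flip = parts
        j = index[src] if index is not None else int(src)
        i = index[tgt] if index is not None else int(tgt)
        got = vt.index(kind, j, i)
        if got != int(v):
            raise ValueError(f"map line {lineno}: variable indices must be dense and ordered")
        if flip == "1":
            flipped.add(got)
    if len(vt) != n_vars:
        raise ValueError(f"map lists {len(vt)} variables, header declares {n_vars}")
    return HornFormula(clauses=clauses, var_table=vt, flipped=frozenset(flipped))
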