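"""Literature-derived Boolean trajectories.

The budding yeast cell-cycle trajectory below is transcribed from the
published synchronous Boolean cell-cycle model of Li, Long, Lu, Ouyang and
Tang (PNAS 101:4781-4786, 2004, Table 2): the 13-step path from the START
state (Cln3 on in the stationary G1 state) back to stationary G1, over the
11 regulators of the cycle.  It is the canonical worked example for
process-driven network inference: its exact minimal realizing network and
the number of distinct minimal networks are classic reference quantities.
"""

from __future__ import annotations

import numpy as np

from .core import BooleanProcess

__all__ = ["budding_yeast_process", "BUDDING_YEAST_NODES"]

BUDDING_YEAST_NODES = (
    "Cln3",
    "MBF",
    "SBF",
    "Cln1,2",
    "Cdh1",
    "Swi5",
    "Cdc20&Cdc14",
    "Clb5,6",
    "Sic1",
    "Clb1,2",
    "Mcm1/SFF",
)

# rows are time steps 1..13 of the cell-cycle sequence; columns follow
# BUDDING_YEAST_NODES
_BUDDING_YEAST_STATES = """
1 0 0 0 1 0 0 0 1 0 0
0 1 1 0 1 0 0 0 1 0 0
0 1 1 1 1 0 0 0 1 0 0
0 1 1 1 0 0 0 0 0 0 0
0 1 1 1 0 0 0 1 0 0 0
0 1 1 1 0 0 0 1 0 1 1
0 0 0 1 0 0 1 1 0 1 1
0 0 0 0 0 1 1 0 0 1 1
0 0 0 0 0 1 1 0 1 1 1
0 0 0 0 0 1 1 0 1 0 1
0 0 0 0 1 1 1 0 1 0 0
0 0 0 0 1 1 0 0 1 0 0
0 0 0 0 1 0 0 0 1 0 0
"""


def budding_yeast_process() -> BooleanProcess:
    """The budding yeast cell-cycle Boolean process (13 steps x 11 nodes)."""
    rows = [
        [int(tok) for tok in line.split()]
        for line in _BUDDING_YEAST_STATES.strip().splitlines()
    ]
    return BooleanProcess(BUDDING_YEAST_NODES, np.array(rows, dtype=np.int8))
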