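"""Seeded synthetic data: random signed networks and feasible processes.

Two ensemble modes are provided because how published feasible ensembles
were constructed is not derivable from the method alone:

* ``network`` — simulate a random canonical network from a random initial
  state; feasible by construction (the generating network is a witness);
* ``rejection`` — draw uniform 0/1 matrices and keep the first feasible one
  (bounded retries), i.e. sampling uniformly over feasible processes.

Default ensemble conditions model sparse biological wiring: 30% of ordered
pairs carry an edge, 40% of edges are inhibitory, and half the nodes
self-degrade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BooleanProcess, InteractionNetwork, simulate
from .feasibility import is_feasible

__all__ = ["GeneratorConfig", "random_network", "random_feasible_process"]


@dataclass(frozen=True)
class GeneratorConfig:
    N: int = 5
    T: int = 6
    mode: str = "network"
    edge_density: float = 0.3
    inhib_fraction: float = 0.4
    degrade_prob: float = 0.5
    seed: int = 0
    max_rejection_tries: int = 10_000

    def __post_init__(self):
        for name in ("edge_density", "inhib_fraction", "degrade_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mode not in ("network", "rejection"):
            raise ValueError("mode must be 'network' or 'rejection'")
        if self.N < 1 or self.T < 1:
            raise ValueError("N >= 1 and T >= 1 required")


def _rng(cfg: GeneratorConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(cfg.seed)


def random_network(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> InteractionNetwork:
    """Random canonical network: each ordered pair carries an edge with
    probability ``edge_density``, inhibitory with probability
    ``inhib_fraction`` (stimulatory otherwise)."""
    g = _rng(cfg, rng)
    n = cfg.N
    edge = g.random((n, n)) < cfg.edge_density
    np.fill_diagonal(edge, False)
    inhibitory = g.random((n, n)) < cfg.inhib_fraction
    inhib = (edge & inhibitory).astype(np.int8)
    stim = (edge & ~inhibitory).astype(np.int8)
    degrade = (g.random(n) < cfg.degrade_prob).astype(np.int8)
    from .core import default_node_ids

    return InteractionNetwork(default_node_ids(n), inhib, stim, degrade)


def random_feasible_process(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> BooleanProcess:
    """A feasible T x N process, by simulation or by rejection sampling."""
    g = _rng(cfg, rng)
    if cfg.mode == "network":
        net = random_network(cfg, rng=g)
        init = g.integers(0, 2, size=cfg.N, dtype=np.int8)
        return simulate(net, init, cfg.T)
    for _ in range(cfg.max_rejection_tries):
        states = g.integers(0, 2, size=(cfg.T, cfg.N), dtype=np.int8)
        from .core import default_node_ids

        proc = BooleanProcess(default_node_ids(cfg.N), states)
        if is_feasible(proc):
            return proc
    raise RuntimeError(
        f"no feasible process found in {cfg.max_rejection_tries} rejection draws; "
        "try mode='network'"
    )
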