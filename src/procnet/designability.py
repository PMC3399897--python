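"""Designability: how many canonical networks realize a given process.

Counting decomposes over target nodes (the constraints never couple incoming
edges of different targets), so the exact count is a product of per-node
enumeration counts — exponential in N per node, but exact at small N.  At
scale, a fast estimator regresses log-designability on six cheap solution-
space features, counted over ordered node pairs (j, i), j != i:

M1  forced-inhibitory pairs (inhibition present in every solution)
M2  forced-stimulatory pairs
M3  pairs where inhibition is impossible
M4  pairs where stimulation is impossible
M5  pairs where any connection is impossible (both impossible)
M6  pairs where all three states (inhibit / stimulate / none) remain possible

The estimator is an ordinary least-squares fit of ln D on (1, M1..M6),
presented as a small model/results pair: construct a
:class:`DesignabilityRegression` from an ensemble, call :meth:`fit`, and use
the returned :class:`DesignabilityModel` to predict.  Counting always uses
canonical networks (no pair simultaneously inhibitory and stimulatory).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import BooleanProcess
from .enumeration import DEFAULT_CAP, EnumerationCapError, NodeEnumeration
from .feasibility import horn_sat, is_feasible

__all__ = [
    "FeatureVector",
    "count_exact_node",
    "count_exact",
    "extract_features",
    "DesignabilityRegression",
    "DesignabilityModel",
    "fit_log_linear",
    "estimate_designability",
]

FEATURE_DEFINITIONS_VERSION = "pair-attainability-v1 (M3/M4 include M5 pairs)"


@dataclass(frozen=True)
class FeatureVector:
    m1: int
    m2: int
    m3: int
    m4: int
    m5: int
    m6: int

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.m3, self.m4, self.m5, self.m6], dtype=float)


def count_exact_node(
    proc: BooleanProcess, i: int, max_assignments: int = DEFAULT_CAP
) -> int:
    """Number of canonical per-node assignments realizing node i's column."""
    if proc.T < 2:
        n_others = proc.N - 1
        return 2 * 3 ** n_others
    return NodeEnumeration(proc, i, max_assignments).count()


def count_exact(proc: BooleanProcess, max_assignments: int = DEFAULT_CAP) -> int:
    """Exact designability D: the product of per-node counts.

    Zero iff the process is infeasible.
    """
    total = 1
    for i in range(proc.N):
        c = count_exact_node(proc, i, max_assignments)
        if c == 0:
            return 0
        total *= c
    return total


def _features_by_enumeration(proc: BooleanProcess) -> dict[tuple[int, int], set[str]]:
    attain: dict[tuple[int, int], set[str]] = {}
    for i in range(proc.N):
        enum = NodeEnumeration(proc, i)
        for j, states in enum.attainable_pair_states().items():
            attain[(j, i)] = states
    return attain


def _features_by_probing(proc: BooleanProcess) -> dict[tuple[int, int], set[str]]:
    """Horn-probing route: pin each pair to each of its three canonical
    states and test satisfiability.  A solution with a_ji = 1 always maps to
    a canonical solution with the pair inhibitory (the stimulation bit is
    inert under dominant inhibition), so 'inhibit attainable' needs only the
    a-pin."""
    from .constraints import build_horn

    horn, _ = build_horn(proc)
    vt = horn.var_table

    def pin(kind: str, j: int, i: int, value: bool) -> list[int]:
        v = vt.get(kind, j, i)
        if v is None:
            return []  # unconstrained variable: any value attainable
        flipped_value = (not value) if v in horn.flipped else value
        return [v if flipped_value else -v]

    attain: dict[tuple[int, int], set[str]] = {}
    for i in range(proc.N):
        for j in range(proc.N):
            if j == i:
                continue
            states = set()
            if horn_sat(horn, extra_units=pin("a", j, i, True)).satisfiable:
                states.add("inhibit")
            if horn_sat(
                horn, extra_units=pin("a", j, i, False) + pin("b", j, i, True)
            ).satisfiable:
                states.add("stimulate")
            if horn_sat(
                horn, extra_units=pin("a", j, i, False) + pin("b", j, i, False)
            ).satisfiable:
                states.add("none")
            attain[(j, i)] = states
    return attain


def extract_features(proc: BooleanProcess, method: str = "auto") -> FeatureVector:
    """Count the six pair-attainability features of a feasible process.

    ``method``: 'enumerate' (exhaustive per-node, small N), 'probe'
    (polynomial Horn probing), or 'auto' (enumerate when within the cap).
    A process with T = 1 leaves every pair fully free.
    """
    if not is_feasible(proc):
        raise ValueError("infeasible: features are defined over a nonempty solution space")
    if proc.T < 2:
        n_pairs = proc.N * (proc.N - 1)
        return FeatureVector(0, 0, 0, 0, 0, n_pairs)
    if method == "auto":
        try:
            attain = _features_by_enumeration(proc)
        except EnumerationCapError:
            attain = _features_by_probing(proc)
    elif method == "enumerate":
        attain = _features_by_enumeration(proc)
    elif method == "probe":
        attain = _features_by_probing(proc)
    else:
        raise ValueError(f"unknown method {method!r}")

    m = [0] * 6
    for states in attain.values():
        can_inh = "inhibit" in states
        can_stim = "stimulate" in states
        can_none = "none" in states
        if can_inh and not can_stim and not can_none:
            m[0] += 1
        if can_stim and not can_inh and not can_none:
            m[1] += 1
        if not can_inh:
            m[2] += 1
        if not can_stim:
            m[3] += 1
        if not can_inh and not can_stim:
            m[4] += 1
        if can_inh and can_stim and can_none:
            m[5] += 1
    return FeatureVector(*m)


@dataclass
class DesignabilityModel:
    """Fitted log-linear designability estimator.

    Prediction: L_hat = c0 + sum_k c_k * M_k; D_hat = exp(L_hat) (natural
    log base, recorded so the record is self-describing).
    """

    coefficients: np.ndarray  # c0..c6
    log_base: str = "e"
    feature_definitions: str = FEATURE_DEFINITIONS_VERSION
    n_obs: int = 0
    rank: int = 7
    residual_sd: float = float("nan")
    pearson_r: float = float("nan")
    r_squared: float = float("nan")

    def predict_log(self, features: FeatureVector) -> float:
        x = np.concatenate([[1.0], features.as_array()])
        return float(x @ self.coefficients)

    def predict(self, features: FeatureVector) -> float:
        return math.exp(self.predict_log(features))

    def summary(self) -> str:
        names = ["intercept"] + [f"M{k}" for k in range(1, 7)]
        lines = [
            "Log-linear designability model (ln D ~ 1 + M1..M6)",
            f"  observations: {self.n_obs}   design rank: {self.rank}",
            f"  in-sample Pearson r: {self.pearson_r:.4f}   R^2: {self.r_squared:.4f}",
            f"  residual s.d.: {self.residual_sd:.4f}   log base: {self.log_base}",
            f"  features: {self.feature_definitions}",
            "  coefficients:",
        ]
        lines += [f"    {nm:<10s} {c:+.6f}" for nm, c in zip(names, self.coefficients)]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "log_base": self.log_base,
            "feature_definitions": self.feature_definitions,
            "n_obs": self.n_obs,
            "rank": self.rank,
            "residual_sd": self.residual_sd,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignabilityModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            log_base=d.get("log_base", "e"),
            feature_definitions=d.get("feature_definitions", FEATURE_DEFINITIONS_VERSION),
            n_obs=d.get("n_obs", 0),
            rank=d.get("rank", 7),
            residual_sd=d.get("residual_sd", float("nan")),
            pearson_r=d.get("pearson_r", float("nan")),
            r_squared=d.get("r_squared", float("nan")),
        )


class DesignabilityRegression:
    """OLS of ln D on (1, M1..M6) over an ensemble of feasible processes."""

    def __init__(self, ensemble: list[tuple[FeatureVector, int]]):
        if not ensemble:
            raise ValueError("ensemble must be nonempty")
        if any(d <= 0 for _, d in ensemble):
            raise ValueError("all designabilities must be positive (feasible processes)")
        self.X = np.column_stack(
            [np.ones(len(ensemble))] + [
                np.array([f.as_array()[k] for f, _ in ensemble]) for k in range(6)
            ]
        )
        self.y = np.array([math.log(d) for _, d in ensemble])

    def fit(self) -> DesignabilityModel:
        coef, _, rank, _ = np.linalg.lstsq(self.X, self.y, rcond=None)
        if rank < self.X.shape[1]:
            warnings.warn(
                f"rank-deficient design (rank {rank} < {self.X.shape[1]}); "
                "minimum-norm coefficients returned",
                stacklevel=2,
            )
        pred = self.X @ coef
        resid = self.y - pred
        ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        if pred.std() > 0 and self.y.std() > 0:
            r = float(np.corrcoef(pred, self.y)[0, 1])
        else:
            r = 1.0 if np.allclose(pred, self.y) else 0.0
        return DesignabilityModel(
            coefficients=coef,
            n_obs=len(self.y),
            rank=int(rank),
            residual_sd=float(resid.std()),
            pearson_r=r,
            r_squared=r2,
        )


def fit_log_linear(ensemble: list[tuple[FeatureVector, int]]) -> DesignabilityModel:
    """Functional wrapper: fit the log-linear model on (features, exact D) pairs."""
    return DesignabilityRegression(ensemble).fit()


def estimate_designability(
    model: DesignabilityModel, proc: BooleanProcess, method: str = "auto"
) -> dict:
    """Polynomial-time designability estimate for a process.

    Returns a dict with 'feasible', 'log_estimate' (L_hat) and 'estimate'
    (D_hat).  For an infeasible process the exact designability is zero and
    the estimate is reported alongside that flag.
    """
    feasible = is_feasible(proc)
    if not feasible:
        return {"feasible": False, "log_estimate": None, "estimate": 0.0}
    feats = extract_features(proc, method=method)
    L = model.predict_log(feats)
    return {"feasible": True, "log_estimate": L, "estimate": math.exp(L), "features": feats}
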