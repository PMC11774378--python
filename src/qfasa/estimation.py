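"""Original QFASA model: per-predator diet estimation with fixed CCs.

Each predator's diet is the simplex vector ``pi`` over prey groups that
minimizes the configured distance between the (space-adjusted) predator
signature and the mixture ``sum_k pi_k mu_k`` of (space-adjusted) prey-group
mean signatures:

* prey space: the predator signature is divided by the CCs and
  renormalized, and compared against the raw prey means;
* predator space: each prey mean is multiplied by the CCs and renormalized
  (transform-then-mix), and compared against the raw predator signature.

Minimization uses sequential quadratic programming (SLSQP) under
``pi >= 0, sum pi = 1`` with multiple restarts (uniform, each vertex, and
seeded random interior points); the best objective wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .distances import get_distance
from .signatures import (
    CalibrationVector,
    GroupMeans,
    MethodConfig,
    PreyLibrary,
    SignatureMatrix,
    to_predator_space,
    to_prey_space,
)

__all__ = [
    "DietEstimate",
    "DietTable",
    "model_signature",
    "adjusted_inputs",
    "estimate_from_adjusted",
    "estimate_diet",
    "estimate_all",
    "pool_to_species",
]


@dataclass
class DietEstimate:
    """One predator's estimated diet over prey groups."""

    predator_id: object
    pi: np.ndarray
    objective: float
    converged: bool
    n_restarts_used: int

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a simplex vector")


@dataclass
class DietTable:
    """Diet estimates for a set of predators, in predator order."""

    estimates: list
    group_labels: list
    method: str = ""

    @property
    def n(self) -> int:
        return len(self.estimates)

    @property
    def predator_ids(self) -> list:
        return [e.predator_id for e in self.estimates]

    @property
    def pi_matrix(self) -> np.ndarray:
        if not self.estimates:
            return np.empty((0, len(self.group_labels)))
        return np.vstack([e.pi for e in self.estimates])

    @property
    def objectives(self) -> np.ndarray:
        return np.array([e.objective for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pi_matrix, columns=self.group_labels)
        df.insert(0, "predator_id", self.predator_ids)
        df["objective"] = [e.objective for e in self.estimates]
        df["converged"] = [e.converged for e in self.estimates]
        return df


def model_signature(pi, means: GroupMeans) -> np.ndarray:
    """Modeled predator signature: the pi-weighted average of group means."""
    pi = np.asarray(pi, dtype=float)
    if pi.size != means.G:
        raise ValueError(
            f"pi has {pi.size} components for {means.G} prey groups"
        )
    return pi @ means.means


def adjusted_inputs(
    predator: np.ndarray,
    means: GroupMeans,
    c: CalibrationVector | np.ndarray,
    space: str,
):
    """Place the predator signature and prey means in the estimation space.

    Returns ``(pred_adj, means_adj)`` where ``means_adj`` is a (G, K) array.
    """
    coeff = c.coefficients if isinstance(c, CalibrationVector) else np.asarray(c, float)
    predator = np.asarray(predator, dtype=float)
    if space == "prey":
        return to_prey_space(predator, coeff), np.asarray(means.means, float)
    if space == "predator":
        return predator, to_predator_space(means.means, coeff)
    raise ValueError(f"unknown estimation space {space!r}")


def _restart_points(G: int, n_restarts: int, seed) -> list:
    """Uniform start, the G vertices, then seeded random interior points."""
    pts = [np.full(G, 1.0 / G)]
    pts += [np.eye(G)[k] for k in range(G)]
    rng = np.random.default_rng(seed)
    while len(pts) < max(n_restarts, 1):
        pts.append(rng.dirichlet(np.ones(G)))
    return pts[: max(n_restarts, 1)]


def estimate_from_adjusted(
    predator_id,
    pred_adj: np.ndarray,
    means_adj: np.ndarray,
    distance: str,
    n_restarts: int = 10,
    seed: int = 0,
    x0: np.ndarray | None = None,
    ftol: float = 1e-12,
) -> DietEstimate:
    """Solve the simplex-constrained fit for one already-adjusted predator.

    ``x0``, when given, replaces the multi-start list by a single warm
    start (used by the joint model's inner loop).
    """
    dist = get_distance(distance)
    G = means_adj.shape[0]

    if distance == "aitchison":
        lx = np.log(pred_adj)
        clr_x = lx - lx.mean()

        def objective_grad(pi):
            mix = np.clip(pi, 0.0, None) @ means_adj
            if np.any(mix <= 0):
                return np.inf, np.zeros(G)
            lm = np.log(mix)
            z = clr_x - (lm - lm.mean())
            r = np.sqrt(z @ z)
            gm = -z / (max(r, 1e-30) * mix)
            return r, means_adj @ gm
    else:  # kullback_leibler

        def objective_grad(pi):
            mix = np.clip(pi, 0.0, None) @ means_adj
            if np.any(mix <= 0):
                return np.inf, np.zeros(G)
            lr = np.log(pred_adj / mix)
            val = float(np.sum((pred_adj - mix) * lr))
            gm = 1.0 - lr - pred_adj / mix
            return val, means_adj @ gm

    def objective(pi):
        return objective_grad(pi)[0]

    constraints = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * G
    starts = [np.asarray(x0, float)] if x0 is not None else _restart_points(
        G, n_restarts, seed
    )

    best_pi, best_obj, any_ok = None, np.inf, False
    for start in starts:
        res = minimize(
            objective_grad,
            start,
            jac=True,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"ftol": ftol, "maxiter": 300},
        )
        pi = np.clip(res.x, 0.0, None)
        s = pi.sum()
        if s <= 0:
            continue
        pi = pi / s
        obj = objective(pi)
        any_ok = any_ok or bool(res.success)
        if obj < best_obj:
            best_obj, best_pi = obj, pi
    if best_pi is None:
        raise RuntimeError(
            f"diet optimization failed for predator {predator_id!r}"
        )
    return DietEstimate(
        predator_id, best_pi, float(best_obj), any_ok, len(starts)
    )


def estimate_diet(
    predator: np.ndarray,
    means: GroupMeans,
    c: CalibrationVector | np.ndarray,
    config: MethodConfig,
    predator_id=None,
    n_restarts: int = 10,
    seed: int = 0,
) -> DietEstimate:
    """Estimate one predator's diet under a fixed-CC configuration."""
    if config.model != "fixed_cc":
        raise ValueError("estimate_diet requires config.model == 'fixed_cc'")
    pred_adj, means_adj = adjusted_inputs(predator, means, c, config.space)
    return estimate_from_adjusted(
        predator_id,
        pred_adj,
        means_adj,
        config.distance,
        n_restarts=n_restarts,
        seed=seed,
    )


def estimate_all(
    predators: SignatureMatrix,
    library: PreyLibrary,
    c: CalibrationVector | np.ndarray,
    config: MethodConfig,
    n_restarts: int = 10,
    seed: int = 0,
    means: GroupMeans | None = None,
) -> DietTable:
    """Estimate diets for every predator row; failures are collected.

    ``means`` may be supplied to reuse precomputed group means; otherwise
    they are derived from the library.
    """
    from .signatures import prey_group_means

    if means is None:
        means = prey_group_means(library)
    estimates, failures = [], []
    for i in range(predators.n):
        pid = predators.individual_ids[i]
        try:
            estimates.append(
                estimate_diet(
                    predators.proportions[i],
                    means,
                    c,
                    config,
                    predator_id=pid,
                    n_restarts=n_restarts,
                    seed=seed,
                )
            )
        except Exception as exc:  # keep going; report at the end
            failures.append((pid, str(exc)))
    table = DietTable(estimates, list(means.group_labels), method=config.model)
    if failures:
        table.method += f" ({len(failures)} failures)"
        table.failures = failures  # type: ignore[attr-defined]
    return table


def pool_to_species(diets: DietTable, species_map: dict) -> DietTable:
    """Sum group-level diet proportions to species level."""
    unmapped = [g for g in diets.group_labels if g not in species_map]
    if unmapped:
        raise ValueError(f"prey groups without a species mapping: {unmapped}")
    species: list = []
    for g in diets.group_labels:
        s = species_map[g]
        if s not in species:
            species.append(s)
    idx = {s: i for i, s in enumerate(species)}
    pooled = []
    for est in diets.estimates:
        pi = np.zeros(len(species))
        for g, p in zip(diets.group_labels, est.pi):
            pi[idx[species_map[g]]] += p
        pooled.append(
            DietEstimate(
                est.predator_id, pi, est.objective, est.converged,
                est.n_restarts_used,
            )
        )
    return DietTable(pooled, species, method=diets.method + "+pooled")
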