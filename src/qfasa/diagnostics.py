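"""Diagnostic statistics for prey libraries and fitted diets.

* ``psi`` — the share of the total pairwise distance between prey
  signatures that occurs *within* prey groups.  Small values mean groups
  are internally tight and mutually distinct, the situation in which diet
  estimation can be expected to resolve them.
* ``lopo`` — leave-one-prey-out cross-validation: each prey signature is
  held out, its group mean recomputed without it, and the signature is
  "diet-estimated" against all group means; the attribution matrix reports
  the mean estimated proportion by true group.
* ``out_of_range_proportion`` — the share of predator proportion cells
  lying outside the per-component range of the group means, a direct
  indicator of model assumption violations (a mixture of means can never
  leave that range component-wise).
* ``fit_distances`` / ``compare_methods`` — distances between observed and
  modeled predator signatures, and per-species Pearson correlations
  between two sets of diet estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import distance_matrix, get_distance
from .estimation import (
    DietTable,
    adjusted_inputs,
    estimate_from_adjusted,
    pool_to_species,
)
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
    "PsiResult",
    "LopoResult",
    "psi",
    "lopo",
    "out_of_range_proportion",
    "fit_distances",
    "compare_methods",
]


@dataclass
class PsiResult:
    """Within-group share of total pairwise prey distance."""

    psi: float
    within_sum: float
    between_sum: float
    measure: str


@dataclass
class LopoResult:
    """Leave-one-prey-out attribution matrix (rows: true group)."""

    group_labels: list
    attribution: np.ndarray

    @property
    def correct(self) -> np.ndarray:
        return np.diag(self.attribution)

    @property
    def total(self) -> float:
        return float(np.trace(self.attribution))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.attribution, index=self.group_labels,
            columns=self.group_labels,
        )


def psi(library: PreyLibrary, measure: str) -> PsiResult:
    """Share of the summed pairwise distance occurring within prey groups.

    Every unordered pair of prey signatures contributes its distance once,
    to the numerator if both members belong to the same group; the
    denominator is the total over all pairs.
    """
    sig = library.signatures
    if sig.n < 2:
        raise ValueError("psi needs at least 2 prey signatures")
    dm = distance_matrix(sig, measure).values
    labels = np.asarray(library.group_labels, dtype=object)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(sig.n, k=1)
    within = float(dm[iu][same[iu]].sum())
    between = float(dm[iu][~same[iu]].sum())
    if within + between == 0:
        raise ValueError("all pairwise distances are zero; psi is undefined")
    return PsiResult(within / (within + between), within, between, measure)


def lopo(
    library: PreyLibrary,
    c: CalibrationVector | np.ndarray,
    config: MethodConfig,
    n_restarts: int = 10,
    seed: int = 0,
) -> LopoResult:
    """Leave-one-prey-out attribution under a fixed-CC configuration.

    Only the held-out signature's own group mean is recomputed; the other
    means are untouched.  In the prey space the held-out prey signature is
    used as-is; in the predator space it is first CC-transformed (a prey
    item eaten whole would appear in the predator space).
    """
    if config.model != "fixed_cc":
        raise ValueError("lopo requires a fixed-CC configuration")
    coeff = c.coefficients if isinstance(c, CalibrationVector) else np.asarray(c, float)
    sig = library.signatures
    groups = library.group_names
    sizes = library.group_sizes
    for g in groups:
        if sizes[g] < 2:
            raise ValueError(
                f"prey group {g!r} has fewer than 2 members; cannot hold out"
            )
    group_idx = {g: library.group_rows(g) for g in groups}
    base_means = np.vstack(
        [sig.proportions[group_idx[g]].mean(axis=0) for g in groups]
    )
    G = len(groups)
    attribution = np.zeros((G, G))
    counter = 0
    for gi, g in enumerate(groups):
        rows = group_idx[g]
        for r in rows:
            held = sig.proportions[r]
            n_g = rows.size
            means = base_means.copy()
            means[gi] = (means[gi] * n_g - held) / (n_g - 1)
            if config.space == "prey":
                pred_adj, means_adj = held, means
            else:
                pred_adj = to_predator_space(held, coeff)
                means_adj = to_predator_space(means, coeff)
            est = estimate_from_adjusted(
                sig.individual_ids[r], pred_adj, means_adj, config.distance,
                n_restarts=n_restarts, seed=seed + counter,
            )
            attribution[gi] += est.pi
            counter += 1
        attribution[gi] /= rows.size
    return LopoResult(list(groups), attribution)


def out_of_range_proportion(
    predators: SignatureMatrix,
    means: GroupMeans,
    c: CalibrationVector | np.ndarray,
    config: MethodConfig,
) -> float:
    """Share of predator proportion cells outside the group-mean range.

    Predators and means are placed in the estimation space of ``config``
    before comparison; a cell counts if it is strictly below the minimum or
    strictly above the maximum of the G group-mean values for that
    component.
    """
    if predators.fa_names != means.fa_names:
        raise ValueError("predators and means must share FA columns")
    coeff = c.coefficients if isinstance(c, CalibrationVector) else np.asarray(c, float)
    X = predators.proportions
    if config.space == "prey":
        X = to_prey_space(X, coeff)
        M = np.asarray(means.means, float)
    else:
        M = to_predator_space(means.means, coeff)
    lo = M.min(axis=0)
    hi = M.max(axis=0)
    outside = (X < lo) | (X > hi)
    return float(outside.sum()) / outside.size


def fit_distances(
    predators: SignatureMatrix,
    diets: DietTable,
    means: GroupMeans,
    c: CalibrationVector | np.ndarray,
    config: MethodConfig,
) -> np.ndarray:
    """Distance between each observed (space-adjusted) predator signature
    and its modeled mixture, recomputed from the stored diets."""
    if diets.predator_ids != list(predators.individual_ids):
        raise ValueError("diet table does not match the predator set")
    dist = get_distance(config.distance)
    out = np.empty(predators.n)
    for p in range(predators.n):
        pred_adj, means_adj = adjusted_inputs(
            predators.proportions[p], means, c, config.space
        )
        out[p] = dist(pred_adj, diets.estimates[p].pi @ means_adj)
    return out


def compare_methods(
    a: DietTable,
    b: DietTable,
    species_map: dict | None = None,
    fit_a: np.ndarray | None = None,
    fit_b: np.ndarray | None = None,
):
    """Per-species Pearson correlation between two sets of diet estimates.

    Estimates are pooled to species first when ``species_map`` is given
    (the two tables may then have different group structures, as long as
    they pool to the same species).  Zero-variance species are reported as
    NaN, never coerced to 0.  When per-predator fit distances are supplied
    the fraction of predators with a strictly smaller distance under ``b``
    is returned as well.

    Returns
    -------
    (pandas.Series, float or None)
        Correlations indexed by species, and ``share_smaller``.
    """
    if a.predator_ids != b.predator_ids:
        raise ValueError("diet tables cover different predators")
    if species_map is not None:
        a = pool_to_species(a, species_map)
        b = pool_to_species(b, species_map)
    if set(a.group_labels) != set(b.group_labels):
        raise ValueError("diet tables do not share a species set")
    bi = [b.group_labels.index(s) for s in a.group_labels]
    A = a.pi_matrix
    B = b.pi_matrix[:, bi]
    corr = {}
    for j, s in enumerate(a.group_labels):
        x, y = A[:, j], B[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            corr[s] = np.nan
        else:
            corr[s] = float(np.corrcoef(x, y)[0, 1])
    share_smaller = None
    if fit_a is not None and fit_b is not None:
        share_smaller = float(np.mean(np.asarray(fit_b) < np.asarray(fit_a)))
    return pd.Series(corr, name="pearson_r"), share_smaller
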