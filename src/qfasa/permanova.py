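"""Distance-based one-way permutation ANOVA for prey-group decisions.

Tests equality of group signature distributions directly from a pairwise
distance matrix via the pseudo-F statistic

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_k (1/n_k) * sum_{i<j in group k} d_ij^2
    F = ((SS_total - SS_within) / (g - 1)) / (SS_within / (N - g))

The p-value is obtained by permuting group labels.  When the number of
distinct label assignments (the multinomial coefficient N!/prod n_k!) does
not exceed the replicate cap, *all* assignments are enumerated and the
p-value is exact; otherwise label permutations are sampled uniformly and
the add-one rule p = (1 + #{F_perm >= F_obs}) / (1 + reps) avoids zero
p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .distances import DistanceMatrix

__all__ = [
    "PermanovaResult",
    "pseudo_f",
    "count_unique_assignments",
    "permanova",
    "pairwise_permanova",
]

DEFAULT_MAX_REPS = 100_000


@dataclass
class PermanovaResult:
    f_stat: float
    p_value: float
    replicates_used: int
    exact: bool
    n_unique_assignments: int = 0


def _encode_labels(labels):
    labels = list(labels)
    uniq: dict = {}
    for g in labels:
        uniq.setdefault(g, len(uniq))
    codes = np.array([uniq[g] for g in labels], dtype=int)
    return codes, list(uniq)


def _ss_within_batch(d2: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    """SS_within for each row of a (R, N) label-code matrix."""
    codes = np.atleast_2d(codes)
    R, N = codes.shape
    onehot = np.zeros((R, N, g))
    r = np.repeat(np.arange(R), N)
    onehot[r, np.tile(np.arange(N), R), codes.ravel()] = 1.0
    # quadratic form z_k' D2 z_k per replicate and group
    quad = np.einsum("rng,nm,rmg->rg", onehot, d2, onehot)
    sizes = onehot.sum(axis=1)
    return (quad / (2.0 * sizes)).sum(axis=1)


def pseudo_f(dm: DistanceMatrix, labels) -> float:
    """One-way distance-based pseudo-F for a grouping of the matrix rows.

    Returns ``inf`` when the groups are perfectly separated
    (``SS_within == 0`` with ``SS_total > 0``); raises on a constant
    all-zero matrix.
    """
    codes, names = _encode_labels(labels)
    g = len(names)
    N = dm.n
    if len(codes) != N:
        raise ValueError("one label required per matrix row")
    if g < 2:
        raise ValueError("need at least 2 groups")
    if N - g < 1:
        raise ValueError("need at least one residual degree of freedom")
    d2 = dm.values**2
    ss_total = d2.sum() / (2.0 * N)
    ss_within = float(_ss_within_batch(d2, codes, g)[0])
    if ss_total == 0:
        raise ValueError("constant (all-zero) distance matrix")
    if ss_within == 0:
        return math.inf
    ss_among = ss_total - ss_within
    return (ss_among / (g - 1)) / (ss_within / (N - g))


def count_unique_assignments(group_sizes) -> int:
    """Number of distinct label assignments: N! / prod(n_k!)."""
    sizes = [int(n) for n in group_sizes]
    if any(n < 1 for n in sizes):
        raise ValueError("group sizes must be >= 1")
    total = math.factorial(sum(sizes))
    for n in sizes:
        total //= math.factorial(n)
    return total


def permanova(
    dm: DistanceMatrix,
    labels,
    max_reps: int = DEFAULT_MAX_REPS,
    seed: int = 0,
) -> PermanovaResult:
    """Permutation test of group equality from a distance matrix.

    Exact (full enumeration over distinct assignments) when feasible under
    ``max_reps``, otherwise Monte-Carlo with ``max_reps`` sampled label
    permutations.  Deterministic given ``seed``.
    """
    codes, names = _encode_labels(labels)
    g = len(names)
    N = dm.n
    d2 = dm.values**2
    if d2.sum() == 0:
        raise ValueError(
            "constant (all-zero) distance matrix: pseudo-F is undefined"
        )
    f_obs = pseudo_f(dm, labels)
    sizes = [int(np.sum(codes == k)) for k in range(g)]
    n_unique = count_unique_assignments(sizes)
    ss_total = d2.sum() / (2.0 * N)

    def f_from_ssw(ssw: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return ((ss_total - ssw) / (g - 1)) / (ssw / (N - g))

    chunk = 2000
    if n_unique <= max_reps:
        count_ge = 0
        buf = []
        for assignment in multiset_permutations(sorted(codes)):
            buf.append(assignment)
            if len(buf) == chunk:
                ssw = _ss_within_batch(d2, np.array(buf), g)
                count_ge += int(np.sum(f_from_ssw(ssw) >= f_obs - 1e-12))
                buf = []
        if buf:
            ssw = _ss_within_batch(d2, np.array(buf), g)
            count_ge += int(np.sum(f_from_ssw(ssw) >= f_obs - 1e-12))
        return PermanovaResult(
            f_obs, count_ge / n_unique, n_unique, True, n_unique
        )
    rng = np.random.default_rng(seed)
    count_ge = 0
    done = 0
    while done < max_reps:
        m = min(chunk, max_reps - done)
        perms = np.array([rng.permutation(codes) for _ in range(m)])
        ssw = _ss_within_batch(d2, perms, g)
        count_ge += int(np.sum(f_from_ssw(ssw) >= f_obs - 1e-12))
        done += m
    p = (1 + count_ge) / (1 + max_reps)
    return PermanovaResult(f_obs, p, max_reps, False, n_unique)


def pairwise_permanova(
    dm: DistanceMatrix,
    labels,
    max_reps: int = DEFAULT_MAX_REPS,
    seed: int = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """Run :func:`permanova` for every pair of groups.

    Raw p-values are reported by default; ``holm=True`` adds a
    Holm-adjusted column.
    """
    labels = list(labels)
    codes, names = _encode_labels(labels)
    rows = []
    for a, b in combinations(names, 2):
        idx = [i for i, lab in enumerate(labels) if lab in (a, b)]
        sub = DistanceMatrix(
            [dm.ids[i] for i in idx],
            dm.values[np.ix_(idx, idx)],
            dm.measure,
        )
        res = permanova(
            sub, [labels[i] for i in idx], max_reps=max_reps, seed=seed
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "replicates": res.replicates_used,
                "unique_assignments": res.n_unique_assignments,
                "TS": res.f_stat,
                "p_value": res.p_value,
                "exact": res.exact,
            }
        )
    out = pd.DataFrame(rows)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[i])
            adj[i] = min(1.0, running)
        out["p_holm"] = adj
    return out
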