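"""Synthetic prey libraries, calibration vectors, and pseudo-predators.

The generator realizes the data-generating model the estimators assume:
prey-group mean signatures on the simplex, individual prey as
logistic-normal perturbations of their group mean (log-space Gaussian
noise followed by renormalization, which preserves the relative-difference
geometry the Aitchison distance measures), a positive calibration vector
with mean coefficient 1, and predators built as diet-weighted mixtures of
prey means, distorted into the predator space by the calibration vector,
with optional logistic-normal observation noise.  True diets and CCs are
recorded so every pipeline stage can be checked against known truth.

Everything is deterministic given ``SimulationSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import DietTable
from .signatures import (
    CalibrationVector,
    GroupMeans,
    PreyLibrary,
    SignatureMatrix,
    prey_group_means,
    to_predator_space,
)

__all__ = [
    "SimulationSpec",
    "SyntheticTruth",
    "simulate_prey_library",
    "simulate_cc",
    "simulate_predators",
    "recovery_report",
]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of a marine-mammal prey library:
    6 prey groups, 32 signature components (31 dietary FAs plus an
    augmented pool), 20 prey per group, 50 predators, moderate within-group
    spread, clear between-group separation, calibration coefficients
    scattered around 1, and small predator observation noise.
    """

    G: int = 6
    K: int = 32
    n_per_group: int = 20
    n_predators: int = 50
    within_spread: float = 0.15
    separation: float = 0.6
    cc_spread: float = 0.2
    noise_spread: float = 0.01
    diet_concentration: float = 1.0
    censor_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.G < 2 or self.K < 3:
            raise ValueError("need G >= 2 groups and K >= 3 components")
        for name in ("within_spread", "separation", "cc_spread",
                     "noise_spread", "censor_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.diet_concentration <= 0:
            raise ValueError("diet_concentration must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside simulated predators."""

    true_diets: np.ndarray
    true_cc: CalibrationVector
    group_means: GroupMeans
    group_labels: list


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator stage
    return np.random.default_rng([stream, spec.seed])


def _logistic_normal(rng, base: np.ndarray, scale: float, n: int) -> np.ndarray:
    """n perturbations of ``base``: exp(log base + N(0, scale)) renormalized."""
    z = rng.normal(0.0, scale, size=(n, base.size)) if scale > 0 else np.zeros(
        (n, base.size)
    )
    y = np.exp(np.log(base) + z)
    return y / y.sum(axis=1, keepdims=True)


def _fa_names(K: int) -> list:
    return [f"fa_{j + 1:02d}" for j in range(K)]


def simulate_prey_library(spec: SimulationSpec) -> PreyLibrary:
    """Multi-group prey library of strictly positive compositions.

    Group base means are logistic-normal displacements (scale
    ``separation``) of a shared baseline composition; members are
    logistic-normal perturbations (scale ``within_spread``) of their group
    mean.  ``censor_threshold > 0`` zeroes cells below the threshold to
    create realistic missing FAs for zero-replacement testing.
    """
    rng = _rng(spec, 1)
    baseline = np.exp(rng.normal(0.0, 1.0, size=spec.K))
    baseline /= baseline.sum()
    group_means = _logistic_normal(rng, baseline, spec.separation, spec.G)
    rows, labels, ids = [], [], []
    for g in range(spec.G):
        members = _logistic_normal(
            rng, group_means[g], spec.within_spread, spec.n_per_group
        )
        rows.append(members)
        labels += [f"group_{g + 1}"] * spec.n_per_group
        ids += [f"prey_{g + 1}_{m + 1}" for m in range(spec.n_per_group)]
    values = np.vstack(rows)
    completed = True
    if spec.censor_threshold > 0:
        values = values.copy()
        values[values < spec.censor_threshold] = 0.0
        completed = False
    sig = SignatureMatrix(ids, _fa_names(spec.K), values, completed=completed)
    species_map = {f"group_{g + 1}": f"species_{g // 2 + 1}"
                   for g in range(spec.G)}
    return PreyLibrary(sig, labels, species_map)


def simulate_cc(spec: SimulationSpec) -> CalibrationVector:
    """Log-normal calibration coefficients rescaled to sum(c) = K."""
    rng = _rng(spec, 2)
    if spec.cc_spread == 0:
        c = np.ones(spec.K)
    else:
        c = np.exp(rng.normal(0.0, spec.cc_spread, size=spec.K))
        c = c * spec.K / c.sum()
    return CalibrationVector(_fa_names(spec.K), c)


def simulate_predators(
    library: PreyLibrary,
    c: CalibrationVector,
    spec: SimulationSpec,
    mixture_space: str = "prey",
):
    """Pseudo-predators with known diets.

    For each predator a diet is drawn from a symmetric Dirichlet
    (``diet_concentration``); the noiseless signature is the diet-weighted
    mixture of the library's empirical group means — formed in the prey
    space and then CC-transformed (``mixture_space='prey'``, the generative
    reading of the model) or formed directly from CC-transformed means
    (``mixture_space='predator'``, an exact mixture in the estimation
    space) — and logistic-normal noise of scale ``noise_spread`` is
    applied.

    Returns
    -------
    (SignatureMatrix, SyntheticTruth)
    """
    if mixture_space not in ("prey", "predator"):
        raise ValueError("mixture_space must be 'prey' or 'predator'")
    means = prey_group_means(library)
    if list(means.fa_names) != list(c.fa_names):
        raise ValueError("library and calibration vector are not aligned")
    rng = _rng(spec, 3)
    G = means.G
    Pi = rng.dirichlet(
        np.full(G, spec.diet_concentration), size=spec.n_predators
    )
    if mixture_space == "prey":
        clean = to_predator_space(Pi @ means.means, c)
    else:
        clean = Pi @ to_predator_space(means.means, c)
    if spec.noise_spread > 0:
        noisy = np.exp(
            np.log(clean)
            + rng.normal(0.0, spec.noise_spread, size=clean.shape)
        )
        noisy /= noisy.sum(axis=1, keepdims=True)
    else:
        noisy = clean
    ids = [f"pred_{p + 1}" for p in range(spec.n_predators)]
    sig = SignatureMatrix(ids, list(means.fa_names), noisy, completed=True)
    truth = SyntheticTruth(Pi, c, means, list(means.group_labels))
    return sig, truth


def recovery_report(
    truth: SyntheticTruth,
    estimated: DietTable,
    cc_hat: CalibrationVector | None = None,
) -> dict:
    """Machine-readable accuracy summary of estimates against truth.

    Diet errors are computed group-wise (bias, RMSE) and predator-wise
    (per-predator RMSE across groups); CC errors are relative, after both
    vectors are rescaled to sum(c) = K.
    """
    Pi_true = np.asarray(truth.true_diets, float)
    Pi_hat = estimated.pi_matrix
    if Pi_hat.shape != Pi_true.shape:
        raise ValueError("estimated diets do not match truth shape")
    err = Pi_hat - Pi_true
    per_pred_rmse = np.sqrt(np.mean(err**2, axis=1))
    report = {
        "n_predators": int(Pi_true.shape[0]),
        "n_groups": int(Pi_true.shape[1]),
        "group_bias": {
            g: float(b)
            for g, b in zip(truth.group_labels, err.mean(axis=0))
        },
        "group_rmse": {
            g: float(r)
            for g, r in zip(
                truth.group_labels, np.sqrt(np.mean(err**2, axis=0))
            )
        },
        "max_abs_error": float(np.max(np.abs(err))) if err.size else 0.0,
        "mean_predator_rmse": float(per_pred_rmse.mean()) if err.size else 0.0,
        "max_predator_rmse": float(per_pred_rmse.max()) if err.size else 0.0,
    }
    if cc_hat is not None:
        K = truth.true_cc.coefficients.size
        c_true = truth.true_cc.coefficients * K / truth.true_cc.coefficients.sum()
        c_est = cc_hat.aligned_to(truth.true_cc.fa_names)
        c_est = c_est * K / c_est.sum()
        rel = np.abs(c_est - c_true) / c_true
        report["cc_max_relative_error"] = float(rel.max())
        report["cc_mean_relative_error"] = float(rel.mean())
        report["cc_within_5pct_fraction"] = float(np.mean(rel < 0.05))
    return report
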