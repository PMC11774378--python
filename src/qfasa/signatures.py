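"""Compositional fatty-acid signature data model and preprocessing.

A fatty acid signature (FAS) is a compositional vector of proportions, one
per fatty acid (FA), summing to 1.  Diet estimation works on a *subset* of
the measured FAs (the dietary FAs), which must be re-completed to sum to 1
either by multiplicative normalization or by augmentation with a single
pseudo-component holding the excluded mass.  Predator metabolism is modelled
by per-FA multiplicative calibration coefficients (CCs) that map signatures
between the "prey space" and the "predator space".

This module holds the data containers and every preprocessing operation:
zero replacement, normalization, augmentation, group means, and the two
calibration-space transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignatureMatrix",
    "PreyLibrary",
    "GroupMeans",
    "CalibrationVector",
    "MethodConfig",
    "AUGMENTED_NAME",
    "load_signatures",
    "load_calibration",
    "replace_zeros",
    "normalize_multiplicative",
    "augment",
    "prey_group_means",
    "to_prey_space",
    "to_predator_space",
    "augmented_cc",
    "subset_cc",
]

#: Column name given to the pseudo-component created by :func:`augment`.
AUGMENTED_NAME = "augmented"

_SUM_TOL = 1e-9


@dataclass
class SignatureMatrix:
    """A set of compositional FA signatures: one row per individual.

    Parameters
    ----------
    individual_ids
        Opaque identifiers, one per row.
    fa_names
        Ordered, unique fatty-acid labels (e.g. ``"20:1n-11"``), one per
        column.
    proportions
        Non-negative array of shape ``(n_individuals, n_fas)``.
    completed
        If True, every row sums to 1 (checked to 1e-9).
    """

    individual_ids: list
    fa_names: list
    proportions: np.ndarray
    completed: bool = False

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.ndim != 2:
            raise ValueError("proportions must be a 2-D array")
        n, k = self.proportions.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} ids for {n} signature rows"
            )
        if len(self.fa_names) != k:
            raise ValueError(f"{len(self.fa_names)} FA names for {k} columns")
        if len(set(self.fa_names)) != len(self.fa_names):
            raise ValueError("fa_names must be unique")
        if np.any(self.proportions < 0):
            i, j = np.argwhere(self.proportions < 0)[0]
            raise ValueError(
                f"negative proportion at row {self.individual_ids[i]!r}, "
                f"column {self.fa_names[j]!r}"
            )
        if self.completed:
            sums = self.proportions.sum(axis=1)
            bad = np.abs(sums - 1.0) > _SUM_TOL
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"row {self.individual_ids[i]!r} sums to {sums[i]:.12g}, "
                    "not 1, but completed=True"
                )

    @property
    def n(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_fa(self) -> int:
        return self.proportions.shape[1]

    def column_indices(self, names) -> np.ndarray:
        """Indices of ``names`` in column order, matching by name."""
        pos = {f: i for i, f in enumerate(self.fa_names)}
        missing = [f for f in names if f not in pos]
        if missing:
            raise KeyError(f"FA columns not present: {missing}")
        return np.array([pos[f] for f in names], dtype=int)

    def select(self, rows) -> "SignatureMatrix":
        rows = np.asarray(rows)
        return SignatureMatrix(
            [self.individual_ids[i] for i in np.atleast_1d(rows)],
            list(self.fa_names),
            self.proportions[rows],
            completed=self.completed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.proportions, columns=self.fa_names)
        df.insert(0, "id", self.individual_ids)
        return df


@dataclass
class PreyLibrary:
    """Prey signatures with group structure.

    ``group_labels`` assigns each row to exactly one prey group; groups map
    to species via ``species_map`` (several groups may share a species, e.g.
    age classes or collection sources within ringed seal).
    """

    signatures: SignatureMatrix
    group_labels: list
    species_map: dict = field(default_factory=dict)

    def __post_init__(self):
        self.group_labels = list(self.group_labels)
        if len(self.group_labels) != self.signatures.n:
            raise ValueError("one group label required per signature row")
        if self.G < 1:
            raise ValueError("library must contain at least one group")

    @property
    def group_names(self) -> list:
        """Distinct groups in order of first appearance."""
        seen: dict = {}
        for g in self.group_labels:
            seen.setdefault(g, None)
        return list(seen)

    @property
    def G(self) -> int:
        return len(self.group_names)

    @property
    def group_sizes(self) -> dict:
        sizes: dict = {g: 0 for g in self.group_names}
        for g in self.group_labels:
            sizes[g] += 1
        return sizes

    def group_rows(self, group) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.group_labels) if g == group],
            dtype=int,
        )


@dataclass
class GroupMeans:
    """Per-group arithmetic mean signatures (symbol mu)."""

    group_labels: list
    fa_names: list
    means: np.ndarray
    sizes: list

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        if self.means.shape != (len(self.group_labels), len(self.fa_names)):
            raise ValueError("means shape does not match labels/fa_names")

    @property
    def G(self) -> int:
        return len(self.group_labels)


@dataclass
class CalibrationVector:
    """Strictly positive per-FA multipliers (symbol c)."""

    fa_names: list
    coefficients: np.ndarray
    includes_augmented: bool = False

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 1:
            raise ValueError("coefficients must be 1-D")
        if len(self.fa_names) != self.coefficients.size:
            raise ValueError("one coefficient required per FA name")
        if np.any(self.coefficients <= 0):
            j = int(np.argmax(self.coefficients <= 0))
            raise ValueError(
                f"non-positive calibration coefficient for {self.fa_names[j]!r}"
            )

    def aligned_to(self, fa_names) -> np.ndarray:
        """Coefficients reordered to match ``fa_names`` (match by name)."""
        pos = {f: i for i, f in enumerate(self.fa_names)}
        missing = [f for f in fa_names if f not in pos]
        if missing:
            raise KeyError(f"calibration coefficients missing for: {missing}")
        return self.coefficients[[pos[f] for f in fa_names]]


_MODELS = ("fixed_cc", "joint")
_SPACES = ("prey", "predator")
_DISTANCES = ("kullback_leibler", "aitchison")
_COMPLETIONS = ("normalize", "augment")


@dataclass
class MethodConfig:
    """One estimation configuration: model, space, distance, completion, FAs."""

    model: str
    space: str
    distance: str
    completion: str
    fa_subset: list
    zero_floor_fraction: float = 0.9

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.space not in _SPACES:
            raise ValueError(f"space must be one of {_SPACES}")
        if self.distance not in _DISTANCES:
            raise ValueError(f"distance must be one of {_DISTANCES}")
        if self.completion not in _COMPLETIONS:
            raise ValueError(f"completion must be one of {_COMPLETIONS}")
        if not self.fa_subset:
            raise ValueError("fa_subset must be non-empty")
        if self.model == "joint" and self.space != "predator":
            raise ValueError("the joint model estimates in the predator space")
        if not 0.0 < self.zero_floor_fraction < 1.0:
            raise ValueError("zero_floor_fraction must lie in (0, 1)")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ("group", "species", "source", "age_class")


def load_signatures(path, label_columns=_LABEL_COLUMNS):
    """Read a signature CSV into a :class:`SignatureMatrix` plus labels.

    The file must have an ``id`` column; any of ``label_columns`` that are
    present are split off into a label frame; every remaining column is
    treated as an FA proportion.  Files in the percent dialect (every row
    sum within 95-105) are divided by 100; files whose row sums are neither
    all near 1 nor all near 100 are rejected as ambiguous.

    Returns
    -------
    (SignatureMatrix, pandas.DataFrame)
        The signatures and the label frame (indexed like the input rows;
        may have zero columns).
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing required 'id' column")
    ids = df["id"].tolist()
    present = [c for c in label_columns if c in df.columns]
    labels = df[present].copy()
    fa_cols = [c for c in df.columns if c != "id" and c not in present]
    if not fa_cols:
        raise ValueError(f"{path}: no FA columns found")
    try:
        values = df[fa_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        for c in fa_cols:
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any() and not df[c].isna().any():
                row = ids[int(coerced.isna().idxmax())]
                raise ValueError(
                    f"{path}: non-numeric value in column {c!r}, row {row!r}"
                ) from exc
        raise
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative proportion at row {ids[i]!r}, "
            f"column {fa_cols[j]!r}"
        )
    sums = values.sum(axis=1)
    if np.all((sums >= 95) & (sums <= 105)):
        values = values / 100.0
        sums = sums / 100.0
    elif not np.all((sums > 0) & (sums <= 1.5)):
        raise ValueError(
            f"{path}: row sums neither all near 1 nor all near 100 "
            "(ambiguous proportion/percent dialect)"
        )
    completed = bool(np.all(np.abs(sums - 1.0) <= _SUM_TOL))
    return SignatureMatrix(ids, fa_cols, values, completed=completed), labels


def load_calibration(path) -> CalibrationVector:
    """Read a CC CSV with columns ``fa_name``, ``coefficient``."""
    df = pd.read_csv(path)
    for col in ("fa_name", "coefficient"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    names = df["fa_name"].tolist()
    return CalibrationVector(
        names,
        df["coefficient"].astype(float).to_numpy(),
        includes_augmented=AUGMENTED_NAME in names,
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def replace_zeros(
    data: SignatureMatrix,
    reference: SignatureMatrix,
    floor_fraction: float = 0.9,
) -> SignatureMatrix:
    """Replace zero proportions with a small floor derived from prey data.

    The floor is ``floor_fraction`` times the smallest non-zero proportion
    found anywhere in ``reference`` (the prey library).  Rows in which a
    replacement was made are re-scaled multiplicatively to sum to 1; rows
    without zeros are returned bit-identical.
    """
    if not 0.0 < floor_fraction < 1.0:
        raise ValueError("floor_fraction must lie in (0, 1)")
    ref = reference.proportions
    nonzero = ref[ref > 0]
    if nonzero.size == 0:
        raise ValueError("reference matrix contains no non-zero proportions")
    floor = floor_fraction * nonzero.min()

    out = data.proportions.copy()
    row_sums = out.sum(axis=1)
    all_zero = row_sums == 0
    if np.any(all_zero):
        i = int(np.argmax(all_zero))
        raise ValueError(
            f"row {data.individual_ids[i]!r} is entirely zero and cannot "
            "be rescaled"
        )
    had_zero = (out == 0).any(axis=1)
    if np.any(had_zero):
        rows = np.where(had_zero)[0]
        block = out[rows]
        block[block == 0] = floor
        block /= block.sum(axis=1, keepdims=True)
        out[rows] = block
    completed = bool(np.all(np.abs(out.sum(axis=1) - 1.0) <= _SUM_TOL))
    return SignatureMatrix(
        list(data.individual_ids),
        list(data.fa_names),
        out,
        completed=completed,
    )


def normalize_multiplicative(
    data: SignatureMatrix, fa_subset
) -> SignatureMatrix:
    """Keep only ``fa_subset`` columns and rescale each row to sum to 1."""
    cols = data.column_indices(fa_subset)
    sub = data.proportions[:, cols]
    sums = sub.sum(axis=1)
    if np.any(sums <= 0):
        i = int(np.argmax(sums <= 0))
        raise ValueError(
            f"row {data.individual_ids[i]!r}: selected FA subset sums to 0"
        )
    return SignatureMatrix(
        list(data.individual_ids),
        list(fa_subset),
        sub / sums[:, None],
        completed=True,
    )


def augment(data: SignatureMatrix, fa_subset) -> SignatureMatrix:
    """Complete ``fa_subset`` with one pseudo-component holding excess mass.

    The appended ``"augmented"`` component equals 1 minus the subset sum, so
    rows stay compositional while every ratio among the retained FAs is
    preserved exactly (no rescaling is applied).  Input rows must already
    sum to 1.
    """
    if not data.completed:
        raise ValueError("augment requires completed signatures (rows sum 1)")
    if AUGMENTED_NAME in fa_subset:
        raise ValueError(f"fa_subset already contains {AUGMENTED_NAME!r}")
    cols = data.column_indices(fa_subset)
    sub = data.proportions[:, cols]
    rest = 1.0 - sub.sum(axis=1)
    if np.any(rest < -1e-9):
        i = int(np.argmax(rest < -1e-9))
        raise ValueError(
            f"row {data.individual_ids[i]!r}: subset proportions sum to more "
            "than 1"
        )
    rest = np.clip(rest, 0.0, None)
    return SignatureMatrix(
        list(data.individual_ids),
        list(fa_subset) + [AUGMENTED_NAME],
        np.column_stack([sub, rest]),
        completed=True,
    )


def prey_group_means(library: PreyLibrary) -> GroupMeans:
    """Arithmetic mean signature of each prey group."""
    sig = library.signatures
    names = library.group_names
    means = np.empty((len(names), sig.n_fa))
    sizes = []
    for gi, g in enumerate(names):
        rows = library.group_rows(g)
        if rows.size == 0:
            raise ValueError(f"prey group {g!r} is empty")
        means[gi] = sig.proportions[rows].mean(axis=0)
        sizes.append(int(rows.size))
    return GroupMeans(names, list(sig.fa_names), means, sizes)


# ---------------------------------------------------------------------------
# Calibration-space transforms
# ---------------------------------------------------------------------------


def _check_positive(x: np.ndarray, what: str):
    if np.any(x <= 0):
        raise ValueError(f"{what} must be strictly positive")


def to_prey_space(predator: np.ndarray, c) -> np.ndarray:
    """Invert predator metabolism: divide by the CCs and renormalize.

    Accepts a single signature or a matrix of signatures; ``c`` may be a
    :class:`CalibrationVector` (its name order must already match) or a bare
    array.  The output is invariant to uniform rescaling of ``c``.
    """
    coeff = c.coefficients if isinstance(c, CalibrationVector) else np.asarray(c, float)
    x = np.asarray(predator, dtype=float)
    _check_positive(x, "predator proportions")
    _check_positive(coeff, "calibration coefficients")
    y = x / coeff
    return y / y.sum(axis=-1, keepdims=True)


def to_predator_space(prey: np.ndarray, c) -> np.ndarray:
    """Apply predator metabolism: multiply by the CCs and renormalize."""
    coeff = c.coefficients if isinstance(c, CalibrationVector) else np.asarray(c, float)
    x = np.asarray(prey, dtype=float)
    _check_positive(x, "prey proportions")
    _check_positive(coeff, "calibration coefficients")
    y = x * coeff
    return y / y.sum(axis=-1, keepdims=True)


def augmented_cc(
    full_cc: CalibrationVector, full_mean: np.ndarray, fa_subset
) -> float:
    """CC for the augmented component under a fixed-CC analysis.

    The augmented proportion is a pooled mixture of the excluded FAs, so its
    coefficient is taken as the mean of the excluded FAs' coefficients
    weighted by their proportions in ``full_mean`` (the overall prey mean
    signature over all measured FAs).
    """
    full_mean = np.asarray(full_mean, dtype=float)
    if full_mean.size != len(full_cc.fa_names):
        raise ValueError("full_mean length must match full_cc")
    excluded = [f for f in full_cc.fa_names if f not in set(fa_subset)]
    if not excluded:
        raise ValueError("no excluded FAs: augmented CC is undefined")
    pos = {f: i for i, f in enumerate(full_cc.fa_names)}
    idx = [pos[f] for f in excluded]
    w = full_mean[idx]
    if w.sum() <= 0:
        raise ValueError("excluded FAs have zero total mean proportion")
    return float(np.average(full_cc.coefficients[idx], weights=w))


def subset_cc(
    full_cc: CalibrationVector,
    fa_subset,
    full_mean: np.ndarray | None = None,
    augmented: bool = False,
) -> CalibrationVector:
    """Restrict a CC vector to ``fa_subset``, optionally adding the
    augmented component's coefficient (requires ``full_mean``)."""
    coeff = full_cc.aligned_to(fa_subset)
    names = list(fa_subset)
    if augmented:
        if full_mean is None:
            raise ValueError("full_mean required to derive the augmented CC")
        names = names + [AUGMENTED_NAME]
        coeff = np.append(coeff, augmented_cc(full_cc, full_mean, fa_subset))
    return CalibrationVector(names, coeff, includes_augmented=augmented)
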