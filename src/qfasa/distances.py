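"""Distance measures between compositional signatures.

Two measures are supported:

* the symmetrized Kullback-Leibler distance,
  ``sum_i (x_i - y_i) * ln(x_i / y_i)``, which weighs both absolute and
  relative differences between proportions, and
* the Aitchison distance, the Euclidean distance between centered
  log-ratio (clr) transforms, which depends only on relative differences
  and is invariant to positive rescaling of either argument.

Both require strictly positive inputs; zero handling belongs to the
preprocessing step (see :func:`qfasa.signatures.replace_zeros`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import SignatureMatrix

__all__ = [
    "DistanceMatrix",
    "kl_distance",
    "aitchison_distance",
    "clr",
    "distance_matrix",
    "get_distance",
]

_MEASURES = ("kullback_leibler", "aitchison")


def _as_positive(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            f"{name} must be strictly positive (zero-replace first)"
        )
    return x


def kl_distance(x, y) -> float:
    """Symmetrized Kullback-Leibler distance between two positive rows."""
    x = _as_positive(x, "x")
    y = _as_positive(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return float(np.sum((x - y) * np.log(x / y)))


def clr(x) -> np.ndarray:
    """Centered log-ratio transform (rows of a matrix or a single vector)."""
    x = _as_positive(x, "composition")
    lx = np.log(x)
    return lx - lx.mean(axis=-1, keepdims=True)


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean distance between clr transforms.

    A metric on the simplex; scale-invariant, so the arguments need not be
    normalized.
    """
    x = _as_positive(x, "x")
    y = _as_positive(y, "y")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 components")
    return float(np.linalg.norm(clr(x) - clr(y)))


def get_distance(measure: str):
    """Return the scalar distance function for a measure name."""
    if measure == "kullback_leibler":
        return kl_distance
    if measure == "aitchison":
        return aitchison_distance
    raise ValueError(f"unknown distance measure {measure!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with ids and the measure used."""

    ids: list
    values: np.ndarray
    measure: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path):
        self.to_frame().to_csv(path, index_label="id")


def distance_matrix(data: SignatureMatrix, measure: str) -> DistanceMatrix:
    """All pairwise distances between the rows of ``data``."""
    x = data.proportions
    if np.any(x <= 0):
        i = int(np.argmax((x <= 0).any(axis=1)))
        raise ValueError(
            f"row {data.individual_ids[i]!r} has a non-positive proportion; "
            "zero-replace before computing distances"
        )
    n = x.shape[0]
    if measure == "aitchison":
        z = clr(x)
        sq = np.sum(z * z, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (z @ z.T)
        values = np.sqrt(np.clip(d2, 0.0, None))
    elif measure == "kullback_leibler":
        lx = np.log(x)
        # sum_k (x_ik - x_jk)(log x_ik - log x_jk) expanded into dot products
        values = (
            np.einsum("ik,ik->i", x, lx)[:, None]
            + np.einsum("jk,jk->j", x, lx)[None, :]
            - x @ lx.T
            - lx @ x.T
        )
        values = np.clip(values, 0.0, None)
    else:
        raise ValueError(f"unknown distance measure {measure!r}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(data.individual_ids), values, measure)
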