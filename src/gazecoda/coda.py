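"""Aitchison-geometry kernel for compositional dwell-time data.

A composition is a vector of strictly positive parts (e.g. total fixation
durations per Area of Interest, in ms) whose information content is the set
of *ratios* between parts: two proportional vectors are the same composition.
This module provides the vector-space operations of the simplex (closure,
perturbation, powering), the centred (clr) and isometric pivot (ilr)
log-ratio transforms that map compositions into ordinary Euclidean
coordinates, the Aitchison distance, and the descriptive statistics of a
compositional sample (geometric mean, variation matrix, total variance).

All logarithms are natural. Exact log-ratio identities are enforced at
``ATOL_EXACT`` (1e-10); round-trip reconstructions at ``ATOL_ROUNDTRIP``
(1e-9). Variances use the unbiased divisor ``n - 1`` by default; pass
``ddof=0`` for the maximum-likelihood divisor ``n`` (published totals from
other software may differ by the factor ``(n-1)/n``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ATOL_EXACT = 1e-10
ATOL_ROUNDTRIP = 1e-9

__all__ = [
    "ATOL_EXACT",
    "ATOL_ROUNDTRIP",
    "CompositionMatrix",
    "VariationMatrix",
    "aitchison_distance",
    "close",
    "clr_inverse",
    "clr_transform",
    "compositional_mean",
    "ilr_inverse",
    "ilr_pivot",
    "perturb",
    "pivot_basis",
    "power_scale",
    "replace_zeros",
    "total_variance",
    "variation_matrix",
]


def _as_float_array(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim not in (1, 2):
        raise ValueError(f"{name} must be a vector or a matrix, got ndim={arr.ndim}")
    return arr


def _check_positive(arr: np.ndarray, parts: Sequence[str] | None = None) -> None:
    if np.all(arr > 0):
        return
    bad = np.argwhere(~(arr > 0))
    j = int(bad[0][-1])
    label = parts[j] if parts is not None else f"index {j}"
    raise ValueError(
        f"composition has a nonpositive entry in part {label!r}; "
        "resolve zeros first (replace_zeros) or merge sparsely visited AOIs"
    )


def close(x, kappa: float = 1.0, parts: Sequence[str] | None = None) -> np.ndarray:
    """Rescale each composition so its parts sum to ``kappa``.

    Closure is a compositional no-op: ratios between parts are unchanged.
    Works on a single vector or row-wise on a matrix.
    """
    if not np.isfinite(kappa) or kappa <= 0:
        raise ValueError(f"closure constant kappa must be positive, got {kappa}")
    arr = _as_float_array(x)
    _check_positive(arr, parts)
    total = arr.sum(axis=-1, keepdims=True)
    return arr / total * kappa


def perturb(x, p, kappa: float | None = None) -> np.ndarray:
    """Aitchison perturbation: component-wise product, then closure.

    The group operation of the simplex; the uniform composition is the
    neutral element. If ``kappa`` is None the result is closed to the sum
    of ``x`` (so perturbing by the uniform vector returns ``close(x)``).
    """
    xa = _as_float_array(x)
    pa = _as_float_array(p, "p")
    if xa.shape[-1] != pa.shape[-1]:
        raise ValueError(
            f"perturbation length mismatch: {xa.shape[-1]} vs {pa.shape[-1]} parts"
        )
    _check_positive(xa)
    _check_positive(pa)
    if kappa is None:
        kappa = float(np.atleast_2d(xa).sum(axis=-1)[0])
    return close(xa * pa, kappa)


def power_scale(x, a: float, kappa: float = 1.0) -> np.ndarray:
    """Aitchison powering: component-wise ``a``-th power, closed to ``kappa``.

    ``a=0`` gives the uniform composition; ``a=1`` is closure.
    """
    xa = _as_float_array(x)
    _check_positive(xa)
    return close(xa ** float(a), kappa)


def clr_transform(x) -> np.ndarray:
    """Centred log-ratio transform ``y_j = ln(x_j / g(x))``.

    ``g(x)`` is the row geometric mean, so each clr row sums to zero and the
    transform is invariant to rescaling of the row. Positive coordinates mark
    parts above the average relative dominance, negative ones below.
    """
    arr = _as_float_array(x)
    _check_positive(arr)
    logx = np.log(arr)
    return logx - logx.mean(axis=-1, keepdims=True)


def clr_inverse(y, kappa: float = 1.0) -> np.ndarray:
    """Map clr coordinates back to the simplex: ``close(exp(y), kappa)``.

    Rows must satisfy the clr zero-sum constraint (checked at 1e-8, which is
    loose enough for accumulated float error on long rows).
    """
    arr = _as_float_array(y, "y")
    sums = np.abs(arr.sum(axis=-1))
    if np.any(sums > 1e-8):
        raise ValueError(
            f"clr rows must sum to 0 (max |sum| = {sums.max():.3g}); "
            "not a valid clr image"
        )
    return close(np.exp(arr), kappa)


def pivot_basis(D: int) -> np.ndarray:
    """Contrast matrix of the pivot (ilr) coordinates, shape (D-1, D).

    Row j (0-based) encodes the balance of part j against the geometric mean
    of all later parts. Rows are orthonormal and each sums to zero, so
    ``ilr = clr @ basis.T`` and ``clr = ilr @ basis``.
    """
    if D < 2:
        raise ValueError("need at least 2 parts")
    basis = np.zeros((D - 1, D))
    for j in range(D - 1):
        r = D - j - 1  # parts remaining after j
        coef = np.sqrt(r / (r + 1))
        basis[j, j] = coef
        basis[j, j + 1:] = -coef / r
    return basis


def _permutation_indices(parts: Sequence[str] | int, order) -> np.ndarray:
    if isinstance(parts, int):
        D = parts
        labels = list(range(D))
    else:
        labels = list(parts)
        D = len(labels)
    if order is None:
        return np.arange(D)
    order = list(order)
    if sorted(order) != sorted(labels):
        raise ValueError(f"order {order!r} is not a permutation of the part list {labels!r}")
    return np.array([labels.index(o) for o in order])


def ilr_pivot(x, order=None, parts: Sequence[str] | None = None) -> np.ndarray:
    """Isometric log-ratio pivot coordinates (D-1 balances).

    ``z_j = sqrt((D-j)/(D-j+1)) ln( x_j / gmean(x_{j+1..D}) )`` after
    permuting the parts by ``order`` (labels if ``parts`` given, else
    column indices). The map is an isometry: ``||z|| = ||clr(x)||`` and
    Aitchison distances become plain Euclidean ones.
    """
    arr = _as_float_array(x)
    D = arr.shape[-1]
    idx = _permutation_indices(parts if parts is not None else D, order)
    return clr_transform(arr[..., idx]) @ pivot_basis(D).T


def ilr_inverse(z, kappa: float = 1.0, order=None, parts: Sequence[str] | None = None) -> np.ndarray:
    """Invert :func:`ilr_pivot`; returns compositions closed to ``kappa``."""
    arr = _as_float_array(z, "z")
    D = arr.shape[-1] + 1
    idx = _permutation_indices(parts if parts is not None else D, order)
    y = arr @ pivot_basis(D)
    x_perm = close(np.exp(y), kappa)
    out = np.empty_like(x_perm)
    out[..., idx] = x_perm
    return out


def aitchison_distance(x, z) -> float | np.ndarray:
    """Aitchison distance: Euclidean distance between clr images.

    Invariant to rescaling of either argument and to common perturbation;
    the natural metric when only relative structure matters.
    """
    xa = _as_float_array(x)
    za = _as_float_array(z, "z")
    if xa.shape[-1] != za.shape[-1]:
        raise ValueError("part lists differ in length")
    diff = clr_transform(xa) - clr_transform(za)
    return np.linalg.norm(diff, axis=-1)


@dataclass
class CompositionMatrix:
    """n compositions over one shared part list, with row design metadata.

    ``values`` must be strictly positive (route tables with zeros through
    :func:`replace_zeros` or AOI aggregation first). ``row_meta`` carries one
    row per observation, typically with ``participant`` and ``task`` columns.
    """

    values: np.ndarray
    parts: list[str]
    row_meta: pd.DataFrame | None = None
    kappa: float | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.parts = list(self.parts)
        if self.values.shape[1] != len(self.parts):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.parts)} part labels"
            )
        if len(self.parts) < 2:
            raise ValueError("a composition needs at least 2 parts")
        _check_positive(self.values, self.parts)
        if self.row_meta is not None:
            self.row_meta = self.row_meta.reset_index(drop=True)
            if len(self.row_meta) != self.values.shape[0]:
                raise ValueError("row_meta length does not match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]

    def closed(self, kappa: float = 1.0) -> "CompositionMatrix":
        return CompositionMatrix(close(self.values, kappa), self.parts, self.row_meta, kappa)

    def clr(self) -> np.ndarray:
        return clr_transform(self.values)

    def ilr(self, order=None) -> np.ndarray:
        return ilr_pivot(self.values, order=order, parts=self.parts)

    def subset(self, mask) -> "CompositionMatrix":
        mask = np.asarray(mask)
        meta = self.row_meta.loc[mask].reset_index(drop=True) if self.row_meta is not None else None
        return CompositionMatrix(self.values[mask], self.parts, meta, self.kappa)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.parts)
        if self.row_meta is not None:
            df = pd.concat([self.row_meta.reset_index(drop=True), df], axis=1)
        return df


@dataclass
class VariationMatrix:
    """Pairwise log-ratio variances t_jk and the scalar total variance.

    Entries near zero flag part pairs that stay (nearly) proportional across
    the sample; large entries flag unstable relative dominance. The total
    variance is (1/2D) sum_jk t_jk, identically the sum of clr column
    variances (same divisor).
    """

    t: np.ndarray
    totvar: float
    n_used: int
    parts: list[str] = field(default_factory=list)
    ddof: int = 1

    def to_frame(self) -> pd.DataFrame:
        labels = self.parts or list(range(self.t.shape[0]))
        return pd.DataFrame(self.t, index=labels, columns=labels)


def _matrix_values(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, CompositionMatrix):
        return X.values, X.parts
    arr = np.atleast_2d(_as_float_array(X, "X"))
    return arr, None


def compositional_mean(X, kappa: float = 1.0) -> np.ndarray:
    """Closed vector of column-wise geometric means — the centre of the sample.

    Equivariant under perturbation: the mean of {p (+) x_i} is p (+) mean.
    """
    arr, parts = _matrix_values(X)
    if arr.shape[0] < 1:
        raise ValueError("need at least one observation")
    _check_positive(arr, parts)
    g = np.exp(np.log(arr).mean(axis=0))
    return close(g, kappa)


def variation_matrix(X, ddof: int = 1) -> VariationMatrix:
    """Sample variances of all pairwise log-ratios ln(x_.j / x_.k)."""
    arr, parts = _matrix_values(X)
    n, D = arr.shape
    if n < 2:
        raise ValueError(f"variation matrix needs n >= 2 observations, got {n}")
    _check_positive(arr, parts)
    logx = np.log(arr)
    # var(l_j - l_k) expanded through the covariance of log columns
    cov = np.cov(logx, rowvar=False, ddof=ddof)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum(t, 0.0)
    np.fill_diagonal(t, 0.0)
    totvar = float(t.sum() / (2 * D))
    return VariationMatrix(t, totvar, n, list(parts) if parts else [], ddof)


def total_variance(X, ddof: int = 1) -> float:
    """Total compositional variance: (1/2D) double sum of the variation matrix."""
    return variation_matrix(X, ddof=ddof).totvar


def replace_zeros(X, fraction: float = 0.65, parts: Sequence[str] | None = None):
    """Replace each zero by ``fraction`` x the column's minimum positive value.

    A simple multiplicative-style imputation for dwell-time tables where an
    AOI was never fixated. Positive entries are untouched. Returns the
    imputed array and a replacement log (row, column, imputed value).

    Raises if a column has no positive entry (merge or drop that AOI — an
    area nobody visited carries no ratio information) or if ``fraction`` is
    not in (0, 1].
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"replacement fraction must be in (0, 1], got {fraction}")
    if isinstance(X, CompositionMatrix):
        raise TypeError("CompositionMatrix is already strictly positive; pass the raw table")
    arr = np.atleast_2d(_as_float_array(X, "X")).copy()
    if np.any(arr < 0):
        raise ValueError("negative entries are not valid dwell times")
    log: list[tuple[int, int, float]] = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        pos = col[col > 0]
        if pos.size == 0:
            label = parts[j] if parts is not None else f"column {j}"
            raise ValueError(
                f"AOI {label!r} is zero for every observation; merge it with a "
                "neighbouring AOI or drop it before compositional analysis"
            )
        repl = fraction * pos.min()
        for i in np.nonzero(col == 0)[0]:
            arr[i, j] = repl
            log.append((int(i), int(j), float(repl)))
    return arr, log
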