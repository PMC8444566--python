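"""Simplex geometry for 24-h time-use compositions.

A day is split into four behaviors — sleep, sedentary behavior (SB), light
physical activity (LPA) and moderate-to-vigorous physical activity (MVPA) —
whose durations carry only relative information: they are a *composition*.
This module provides closure (rescaling to a constant such as 100% or
1440 min), the compositional (geometric) mean, the variation matrix of
pairwise log-ratio variances, isometric log-ratio (ilr) pivot coordinates
and their inverse, the family of pivot bases used to report one coefficient
per behavior, and barycentric density grids for ternary heat maps.

Pivot coordinates for a D-part composition taken in a given part order are

    z_k = sqrt((D-k)/(D-k+1)) * ln( x_k / gmean(x_{k+1}, ..., x_D) )

for k = 1..D-1, so the first coordinate contrasts the leading part against
the geometric mean of everything else.  Rotating each part into the lead
position yields D bases spanning the same subspace (they differ by an
orthogonal rotation), which is what lets a regression report a
per-behavior coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_LABELS",
    "MINUTES_PER_DAY",
    "Composition",
    "IlrBasis",
    "close",
    "compositional_mean",
    "variation_matrix",
    "ilr_transform",
    "ilr_inverse",
    "pivot_bases",
    "canonical_basis",
    "ternary_density",
    "aitchison_distance",
    "replace_zeros",
]

DEFAULT_LABELS: tuple[str, ...] = ("Sleep", "SB", "LPA", "MVPA")
MINUTES_PER_DAY: float = 1440.0

_CLOSURE_RTOL = 1e-9


def _as_2d(parts: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(parts, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError(f"expected a 1-D or 2-D array of parts, got ndim={arr.ndim}")


def _check_positive(arr: np.ndarray, labels: Sequence[str]) -> None:
    if np.all(arr > 0):
        return
    rows, cols = np.nonzero(~(arr > 0))
    r, c = int(rows[0]), int(cols[0])
    name = labels[c] if c < len(labels) else f"part {c}"
    raise ValueError(
        f"composition parts must be strictly positive: part '{name}'"
        f" has value {arr[r, c]!r} (row {r}); zeros/negatives are not"
        " representable in log-ratio space (use replace_zeros for"
        " below-detection values)"
    )


@dataclass(frozen=True)
class Composition:
    """A strictly positive composition closed to a fixed total.

    ``parts`` are stored already closed: they sum to ``total`` within
    1e-9 relative tolerance.  Default labels and total describe daily
    minutes in the four time-use behaviors.
    """

    parts: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS
    total: float = MINUTES_PER_DAY

    def __post_init__(self) -> None:
        arr = np.asarray(self.parts, dtype=float)
        if arr.ndim != 1:
            raise ValueError("Composition holds a single 1-D part vector")
        if len(self.labels) != arr.size:
            raise ValueError(
                f"{len(self.labels)} labels for {arr.size} parts"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"labels must be unique, got {self.labels}")
        if self.total <= 0:
            raise ValueError("closure total must be positive")
        _check_positive(arr[None, :], self.labels)
        s = arr.sum()
        if not np.isclose(s, self.total, rtol=_CLOSURE_RTOL, atol=0.0):
            raise ValueError(
                f"parts sum to {s!r}, not the closure total {self.total!r};"
                " build compositions with close()"
            )
        object.__setattr__(self, "parts", arr)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def D(self) -> int:
        return self.parts.size

    def __getitem__(self, label: str) -> float:
        return float(self.parts[self.labels.index(label)])

    def reclose(self, total: float) -> "Composition":
        return close(self.parts, total=total, labels=self.labels)

    def as_series(self) -> pd.Series:
        return pd.Series(self.parts, index=list(self.labels))


def close(
    parts: Iterable[float] | np.ndarray,
    total: float = MINUTES_PER_DAY,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> Composition:
    """Rescale strictly positive parts so they sum to ``total``.

    Raises ``ValueError`` naming the offending part if any entry is
    zero or negative.
    """
    arr = np.asarray(list(parts) if not isinstance(parts, np.ndarray) else parts,
                     dtype=float)
    if total <= 0:
        raise ValueError("closure total must be positive")
    _check_positive(arr[None, :], labels)
    s = arr.sum()
    # already closed (to within accumulated rounding): keep bits unchanged,
    # which makes closure exactly idempotent
    if np.isclose(s, total, rtol=1e-12, atol=0.0):
        closed = arr
    else:
        closed = arr * (total / s)
    return Composition(closed, tuple(labels), float(total))


def _closure_array(arr: np.ndarray, total: float = 1.0) -> np.ndarray:
    return arr * (total / arr.sum(axis=-1, keepdims=True))


def _to_matrix(
    compositions: Iterable[Composition] | np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Coerce a collection of compositions to an (n, D) array plus labels."""
    if isinstance(compositions, pd.DataFrame):
        cols = list(labels) if labels is not None else list(compositions.columns)
        return compositions[cols].to_numpy(dtype=float), tuple(cols)
    if isinstance(compositions, np.ndarray):
        arr, _ = _as_2d(compositions)
        lab = tuple(labels) if labels is not None else DEFAULT_LABELS[: arr.shape[1]]
        if len(lab) != arr.shape[1]:
            lab = tuple(f"part{i + 1}" for i in range(arr.shape[1]))
        return arr, lab
    comps = list(compositions)
    if not comps:
        raise ValueError("empty composition set")
    if isinstance(comps[0], Composition):
        lab = comps[0].labels
        for c in comps:
            if c.labels != lab:
                raise ValueError("compositions carry inconsistent labels")
        return np.vstack([c.parts for c in comps]), lab
    return _to_matrix(np.asarray(comps, dtype=float), labels)


def compositional_mean(
    compositions: Iterable[Composition] | np.ndarray | pd.DataFrame,
    total: float = MINUTES_PER_DAY,
    labels: Sequence[str] | None = None,
) -> Composition:
    """Center of a compositional sample: part-wise geometric means, re-closed.

    The geometric mean is the natural center under Aitchison geometry; the
    result does not depend on the closure constant of the inputs.
    """
    arr, lab = _to_matrix(compositions, labels)
    if arr.shape[0] < 1:
        raise ValueError("compositional_mean needs at least one composition")
    _check_positive(arr, lab)
    gm = np.exp(np.log(arr).mean(axis=0))
    return close(gm, total=total, labels=lab)


def variation_matrix(
    compositions: Iterable[Composition] | np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Matrix of pairwise log-ratio variances var(ln(x_i / x_j)).

    Entries close to zero mean the two parts move proportionally (highly
    co-dependent); large entries mean the ratio varies a lot.  Symmetric
    with a zero diagonal, and invariant to the closure constant.
    """
    arr, lab = _to_matrix(compositions, labels)
    n, D = arr.shape
    if n < 2:
        raise ValueError("variation_matrix needs at least 2 compositions")
    _check_positive(arr, lab)
    logx = np.log(arr)
    T = np.zeros((D, D))
    for i in range(D):
        for j in range(i + 1, D):
            v = np.var(logx[:, i] - logx[:, j], ddof=1)
            T[i, j] = T[j, i] = v
    return pd.DataFrame(T, index=list(lab), columns=list(lab))


@dataclass(frozen=True)
class IlrBasis:
    """Sequential-binary-partition (pivot) ilr basis for a set of part labels.

    ``part_order`` is a permutation of the labels; the first entry is the
    pivot whose first coordinate contrasts it against all remaining parts.
    """

    part_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.part_order)) != len(self.part_order):
            raise ValueError(f"duplicate labels in part order {self.part_order}")
        if len(self.part_order) < 2:
            raise ValueError("an ilr basis needs at least 2 parts")
        object.__setattr__(self, "part_order", tuple(self.part_order))

    @property
    def D(self) -> int:
        return len(self.part_order)

    @property
    def dimension(self) -> int:
        return self.D - 1

    @property
    def pivot(self) -> str:
        return self.part_order[0]

    def contrast_matrix(self) -> np.ndarray:
        """Orthonormal D x (D-1) matrix V with z = clr(x_ordered) @ V."""
        D = self.D
        V = np.zeros((D, D - 1))
        for k in range(D - 1):
            r = D - k - 1  # number of parts after the pivot of coordinate k
            coef = np.sqrt(r / (r + 1))
            V[k, k] = coef
            V[k + 1 :, k] = -coef / r
        return V

    def permutation(self, labels: Sequence[str]) -> np.ndarray:
        """Index array mapping columns in ``labels`` order to basis order."""
        if set(labels) != set(self.part_order):
            raise ValueError(
                f"basis parts {self.part_order} do not match labels {tuple(labels)}"
            )
        lookup = {lab: i for i, lab in enumerate(labels)}
        return np.array([lookup[lab] for lab in self.part_order])

    def coordinate_names(self) -> list[str]:
        return [f"z{k + 1}" for k in range(self.dimension)]


def canonical_basis(labels: Sequence[str] = DEFAULT_LABELS) -> IlrBasis:
    """The basis in the published part order (Sleep, SB, LPA, MVPA by default)."""
    return IlrBasis(tuple(labels))


def pivot_bases(labels: Sequence[str] = DEFAULT_LABELS) -> list[IlrBasis]:
    """One pivot basis per part.

    Basis *i* moves part *i* to the front and keeps the remaining parts in
    canonical order, so the first coordinate of basis *i* is "part i
    relative to all the others".  All D bases span the same subspace.
    """
    labels = tuple(labels)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels {labels}")
    if len(labels) < 2:
        raise ValueError("need at least 2 parts")
    bases = []
    for i, lab in enumerate(labels):
        order = (lab,) + labels[:i] + labels[i + 1 :]
        bases.append(IlrBasis(order))
    return bases


def ilr_transform(
    composition: Composition | np.ndarray | pd.DataFrame,
    basis: IlrBasis | None = None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Map composition(s) to pivot ilr coordinates under ``basis``.

    Accepts a single Composition, an (n, D) array/DataFrame, or a 1-D part
    vector.  The result is invariant to the closure constant.  Returns a
    vector of length D-1 for single inputs, an (n, D-1) array otherwise.
    """
    if isinstance(composition, Composition):
        arr, single = composition.parts[None, :], True
        lab: tuple[str, ...] = composition.labels
    else:
        mat, lab = _to_matrix(composition, labels)
        arr, single = mat, (np.asarray(composition).ndim == 1)
    if basis is None:
        basis = canonical_basis(lab)
    _check_positive(arr, lab)
    perm = basis.permutation(lab)
    z = np.log(arr[:, perm]) @ basis.contrast_matrix()
    return z[0] if single else z


def ilr_inverse(
    coordinates: np.ndarray,
    basis: IlrBasis | None = None,
    total: float = MINUTES_PER_DAY,
    labels: Sequence[str] | None = None,
) -> Composition | np.ndarray:
    """Inverse pivot-ilr map; round-trips with :func:`ilr_transform`.

    A single coordinate vector returns a :class:`Composition` (in ``labels``
    order, closed to ``total``); an (n, D-1) array returns an (n, D) array
    of closed part matrices.  ``labels`` defaults to the canonical four
    behaviors, or to the basis part order for other bases.
    """
    z = np.asarray(coordinates, dtype=float)
    single = z.ndim == 1
    z2 = z[None, :] if single else z
    if not np.all(np.isfinite(z2)):
        raise ValueError("ilr coordinates must be finite")
    if labels is None:
        if basis is None:
            labels = DEFAULT_LABELS[: z2.shape[1] + 1]
            if len(labels) != z2.shape[1] + 1:
                raise ValueError("pass labels or a basis for non-4-part data")
        else:
            labels = (
                DEFAULT_LABELS
                if set(basis.part_order) == set(DEFAULT_LABELS)
                else basis.part_order
            )
    labels = tuple(labels)
    if basis is None:
        basis = canonical_basis(labels)
    if z2.shape[1] != basis.dimension:
        raise ValueError(
            f"{z2.shape[1]} coordinates for a {basis.D}-part basis"
        )
    clr = z2 @ basis.contrast_matrix().T  # in basis order
    x_ordered = np.exp(clr)
    # undo the basis permutation back to `labels` order
    perm = basis.permutation(labels)
    x = np.empty_like(x_ordered)
    x[:, perm] = x_ordered
    x = _closure_array(x, total)
    if single:
        return Composition(x[0], labels, float(total))
    return x


def aitchison_distance(a: Composition | np.ndarray, b: Composition | np.ndarray) -> float:
    """Aitchison distance: Euclidean distance between clr (or ilr) images."""
    pa = a.parts if isinstance(a, Composition) else np.asarray(a, dtype=float)
    pb = b.parts if isinstance(b, Composition) else np.asarray(b, dtype=float)
    la, lb = np.log(pa), np.log(pb)
    ca = la - la.mean()
    cb = lb - lb.mean()
    return float(np.linalg.norm(ca - cb))


def replace_zeros(
    parts: np.ndarray,
    detection_limit: float,
    fraction: float = 0.65,
) -> np.ndarray:
    """Multiplicative replacement of zero parts by ``fraction * detection_limit``.

    Off by default throughout the package: daily time-use data from
    full-day accelerometry has no structural zeros, so zeros are treated
    as errors unless the caller opts into this replacement (e.g. for
    reuse on short-epoch or diary data with below-detection values).
    """
    arr = np.asarray(parts, dtype=float).copy()
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    single = arr.ndim == 1
    mat = arr[None, :] if single else arr
    repl = fraction * detection_limit
    for row in mat:
        zero = row <= 0
        if zero.any():
            added = repl * zero.sum()
            row[~zero] *= 1.0 - added / row.sum()
            row[zero] = repl
    return mat[0] if single else mat


def ternary_density(
    compositions: Iterable[Composition] | np.ndarray | pd.DataFrame,
    triple: Sequence[str],
    resolution: int = 50,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Barycentric density grid over a 3-part subcomposition.

    Each composition is projected onto the chosen ``triple`` of parts and
    re-closed to 1; the unit triangle is divided into ``resolution**2``
    equal-area triangular cells (``resolution`` bins per edge, alternating
    upward/downward triangles) and points are counted per cell.  Returns a
    long-format frame with the cell centroid's barycentric coordinates
    (b1, b2, b3 for the three chosen parts), an up/down orientation flag,
    the count and the frequency; frequencies sum to 1 and empty cells are
    kept as zeros.  This is plot-ready data for a ternary heat map.
    """
    arr, lab = _to_matrix(compositions, labels)
    triple = tuple(triple)
    if len(triple) != 3:
        raise ValueError("ternary_density needs exactly 3 part labels")
    missing = [t for t in triple if t not in lab]
    if missing:
        raise ValueError(f"labels {missing} not among composition parts {lab}")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    idx = [lab.index(t) for t in triple]
    sub = _closure_array(arr[:, idx], 1.0)
    _check_positive(sub, triple)

    R = resolution
    u = sub[:, 0] * R
    v = sub[:, 1] * R
    i = np.clip(np.floor(u).astype(int), 0, R - 1)
    j = np.clip(np.floor(v).astype(int), 0, R - 1)
    # points with i + j = R sit on the far edge; pull them into range
    over = i + j > R - 1
    fu, fv = u - i, v - j
    shrink = np.where(fu >= fv, 0, 1)
    i = np.where(over & (shrink == 0), i - 1, i)
    j = np.where(over & (shrink == 1), j - 1, j)
    down = ((u - i) + (v - j)) > 1.0  # downward-pointing subtriangle
    down &= i + j < R - 1  # cells on the hypotenuse row are upward only

    cells: dict[tuple[int, int, int], int] = {}
    for ii in range(R):
        for jj in range(R - ii):
            cells[(ii, jj, 0)] = 0
            if ii + jj < R - 1:
                cells[(ii, jj, 1)] = 0
    for ii, jj, dd in zip(i, j, down.astype(int)):
        cells[(int(ii), int(jj), int(dd))] += 1

    rows = []
    n = arr.shape[0]
    for (ii, jj, dd), count in sorted(cells.items()):
        if dd == 0:  # upward: vertices (i,j), (i+1,j), (i,j+1)
            b1 = (3 * ii + 1) / (3 * R)
            b2 = (3 * jj + 1) / (3 * R)
        else:  # downward: vertices (i+1,j), (i,j+1), (i+1,j+1)
            b1 = (3 * ii + 2) / (3 * R)
            b2 = (3 * jj + 2) / (3 * R)
        rows.append(
            {
                "b1": b1,
                "b2": b2,
                "b3": 1.0 - b1 - b2,
                "orientation": "down" if dd else "up",
                "count": count,
                "frequency": count / n,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["parts"] = triple
    out.attrs["resolution"] = R
    return out
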