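"""Polynomial control-point registration.

Aligns a source frame (the LiDAR orthomosaic / point cloud) to a
reference frame (the multispectral orthomosaic) via a bivariate
polynomial fitted by least squares on manually picked control-point
pairs, with RMSE-driven order selection and iterative rejection of the
worst-fitting pair.

Monomial basis convention: terms are ordered by total degree, and within
a degree by descending x power, e.g. order 2 -> [1, x, y, x^2, x*y, y^2].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def n_coefficients(order: int) -> int:
    """Number of monomials of a bivariate polynomial of the given order."""
    return (order + 1) * (order + 2) // 2


def _design_matrix(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    cols = []
    for degree in range(order + 1):
        for xp in range(degree, -1, -1):
            cols.append(x**xp * y ** (degree - xp))
    return np.column_stack(cols)


@dataclass
class ControlPointSet:
    """Paired (source, reference) planar coordinates with labels."""

    source: np.ndarray  # (n, 2)
    reference: np.ndarray  # (n, 2)
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.source.shape != self.reference.shape or self.source.shape[1] != 2:
            raise ValueError("source and reference must be matching (n, 2) arrays")
        if not self.ids:
            self.ids = [f"cp{i + 1}" for i in range(len(self.source))]
        uniq = {tuple(p) for p in np.round(self.reference, 9)}
        if len(uniq) != len(self.reference):
            raise ValueError("duplicate reference coordinates in control point set")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ControlPointSet":
        return cls(
            source=df[["src_x", "src_y"]].to_numpy(),
            reference=df[["ref_x", "ref_y"]].to_numpy(),
            ids=[str(i) for i in df["id"]],
        )

    def drop(self, index: int) -> "ControlPointSet":
        keep = np.ones(len(self), dtype=bool)
        keep[index] = False
        return ControlPointSet(self.source[keep], self.reference[keep], [i for k, i in zip(keep, self.ids) if k])


@dataclass
class PolynomialTransform:
    """Fitted source->reference polynomial map.

    ``rmse`` is the root-mean-square residual distance (m) at the
    control points used for the fit; ``converged`` records whether the
    requested RMSE threshold was met during refinement.
    """

    order: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    rmse: float
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        expected = n_coefficients(self.order)
        if len(self.coeffs_x) != expected or len(self.coeffs_y) != expected:
            raise ValueError(f"order-{self.order} transform needs {expected} coefficients per axis")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "order": self.order,
            "coeffs_x": self.coeffs_x.tolist(),
            "coeffs_y": self.coeffs_y.tolist(),
            "rmse": self.rmse,
            "converged": self.converged,
            "n_points": self.n_points,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PolynomialTransform":
        d = json.loads(Path(path).read_text())
        return cls(
            order=d["order"],
            coeffs_x=np.array(d["coeffs_x"]),
            coeffs_y=np.array(d["coeffs_y"]),
            rmse=d["rmse"],
            converged=d.get("converged", True),
            n_points=d.get("n_points", 0),
        )


def fit_polynomial_transform(points: ControlPointSet, order: int) -> PolynomialTransform:
    """Least-squares fit of a bivariate polynomial mapping source->reference.

    Raises ``ValueError`` when there are fewer pairs than coefficients
    (underdetermined) or when the control points are collinear enough to
    make the design matrix rank deficient.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3; got {order}")
    need = n_coefficients(order)
    if len(points) < need:
        raise ValueError(
            f"order-{order} transform needs at least {need} control point pairs; got {len(points)}"
        )
    A = _design_matrix(points.source[:, 0], points.source[:, 1], order)
    rank = np.linalg.matrix_rank(A)
    if rank < need:
        raise ValueError(
            f"control point geometry is rank deficient (rank {rank} < {need}); points may be collinear"
        )
    cx, *_ = np.linalg.lstsq(A, points.reference[:, 0], rcond=None)
    cy, *_ = np.linalg.lstsq(A, points.reference[:, 1], rcond=None)
    pred = np.column_stack([A @ cx, A @ cy])
    resid = np.linalg.norm(pred - points.reference, axis=1)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return PolynomialTransform(order=order, coeffs_x=cx, coeffs_y=cy, rmse=rmse, n_points=len(points))


def apply_transform(transform: PolynomialTransform, coords: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at (n, 2) planar coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    A = _design_matrix(coords[:, 0], coords[:, 1], transform.order)
    return np.column_stack([A @ transform.coeffs_x, A @ transform.coeffs_y])


def residual_distances(transform: PolynomialTransform, points: ControlPointSet) -> np.ndarray:
    pred = apply_transform(transform, points.source)
    return np.linalg.norm(pred - points.reference, axis=1)


def refine_and_select_order(
    points: ControlPointSet,
    rmse_threshold: float,
    orders: Sequence[int] = (1, 2, 3),
    max_dropped: int | None = None,
) -> PolynomialTransform:
    """RMSE-driven order selection with bounded worst-point rejection.

    Candidate orders are tried lowest first (lower-order models are
    preferred when the distortion is limited).  For each feasible order
    the transform is fitted; while the RMSE exceeds the threshold and
    the drop budget allows, the single worst-residual pair is removed
    and the fit repeated.  The first (lowest-order) transform meeting
    the threshold is returned.  If no candidate meets it, the transform
    with the smallest RMSE is returned flagged ``converged=False``.

    ``max_dropped`` defaults to ``len(points) // 5`` (at least 1), so at
    most ~20% of pairs can be discarded.
    """
    if len(points) < 6:
        raise ValueError(f"refinement needs at least 6 control point pairs; got {len(points)}")
    if rmse_threshold <= 0:
        raise ValueError("rmse_threshold must be positive")
    budget = max(1, len(points) // 5) if max_dropped is None else max_dropped

    best: PolynomialTransform | None = None
    for order in sorted(orders):
        if len(points) < n_coefficients(order):
            continue  # e.g. 7 pairs cannot determine an order-3 (10-coefficient) model
        working = points
        dropped = 0
        while True:
            try:
                t = fit_polynomial_transform(working, order)
            except ValueError:
                break
            if best is None or t.rmse < best.rmse:
                best = t
            if t.rmse <= rmse_threshold:
                t.converged = True
                return t
            if dropped >= budget or len(working) - 1 < n_coefficients(order):
                break
            worst = int(np.argmax(residual_distances(t, working)))
            working = working.drop(worst)
            dropped += 1
    if best is None:
        raise ValueError("no candidate order is determined by the available control points")
    best.converged = False
    return best
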