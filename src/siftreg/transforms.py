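"""Geometric transforms estimated from point correspondences.

Three estimators used by the registration pipeline:

* least-squares affine fit (the model inside RANSAC),
* affine RANSAC with an adaptive iteration schedule and a physical-distance
  inlier threshold in mm,
* thin-plate-spline (TPS) interpolation with the 3D biharmonic kernel
  U(r) = r, giving 3N + 12 parameters for N control points (12 of them a
  global affine block).

All transforms map CBCT physical points into CT physical space in the
registration pipeline, but the estimators themselves are symmetric in
their arguments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AffineTransform3D",
    "TPSTransform3D",
    "RansacResult",
    "fit_affine_lsq",
    "ransac_affine",
    "fit_tps",
    "apply_transform",
    "invert_affine",
    "tps_parameter_count",
    "invert_map_points",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]


class DegenerateGeometryError(ValueError):
    """Source points are coplanar/rank-deficient or duplicated."""


class SingularTransformError(ValueError):
    pass


@dataclass(frozen=True)
class AffineTransform3D:
    """p' = linear @ p + translation (physical mm on both sides)."""

    linear: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        linear = np.asarray(self.linear, dtype=float)
        translation = np.asarray(self.translation, dtype=float)
        if linear.shape != (3, 3) or translation.shape != (3,):
            raise ValueError("affine needs a 3x3 linear part and a 3-vector translation")
        if abs(np.linalg.det(linear)) < 1e-12:
            raise SingularTransformError("affine linear part is singular")
        object.__setattr__(self, "linear", linear)
        object.__setattr__(self, "translation", translation)

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def transform_points(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.linear.T + self.translation

    def __call__(self, points):
        return self.transform_points(points)


@dataclass(frozen=True)
class TPSTransform3D:
    """Thin-plate spline: affine part plus radial terms at N control points.

    T(p) = linear @ p + translation + sum_i w_i * U(||p - c_i||),
    with the 3D biharmonic kernel U(r) = r.  The side conditions
    sum_i w_i = 0 and sum_i w_i c_i^T = 0 make the radial part purely
    nonlinear, so affinely related correspondences yield zero weights.
    """

    control_points: np.ndarray  # (N, 3)
    weights: np.ndarray  # (N, 3)
    linear: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        for name, shape in (
            ("control_points", (-1, 3)),
            ("weights", (-1, 3)),
            ("linear", (3, 3)),
            ("translation", (3,)),
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.control_points.shape != self.weights.shape:
            raise ValueError("control_points and weights must be index-aligned (N, 3)")

    @property
    def n_parameters(self) -> int:
        return tps_parameter_count(len(self.control_points))

    def transform_points(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        out = pts @ self.linear.T + self.translation
        if len(self.control_points):
            U = cdist(pts, self.control_points)  # U(r) = r
            out = out + U @ self.weights
        return out[0] if single else out

    def __call__(self, points):
        return self.transform_points(points)


@dataclass
class RansacResult:
    transform: AffineTransform3D | None
    inlier_mask: np.ndarray
    n_iterations: int
    threshold: float
    success: bool

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())


def fit_affine_lsq(points_a, points_b) -> AffineTransform3D:
    """Least-squares affine minimizing sum ||A p_i + t - q_i||^2.

    Requires >= 4 non-coplanar source points.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    if pa.shape != pb.shape or pa.ndim != 2 or pa.shape[1] != 3:
        raise ValueError("point arrays must both be (N, 3)")
    if len(pa) < 4:
        raise ValueError(f"need >= 4 point pairs, got {len(pa)}")
    if _coplanar(pa):
        raise DegenerateGeometryError("source points are coplanar: affine is underdetermined")
    X = np.hstack([pa, np.ones((len(pa), 1))])
    sol, *_ = np.linalg.lstsq(X, pb, rcond=None)
    return AffineTransform3D(sol[:3].T, sol[3])


def _coplanar(points: np.ndarray, tol: float = 1e-8) -> bool:
    c = points - points.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    scale = max(sv[0], 1.0)
    return sv[-1] <= tol * scale


def ransac_affine(
    points_a,
    points_b,
    threshold: float,
    confidence: float = 0.99,
    max_iterations: int = 10000,
    seed: int = 0,
) -> RansacResult:
    """Affine RANSAC: minimal samples of 4, consensus by residual <= threshold (mm).

    The iteration count adapts to the best observed inlier ratio at the
    requested confidence, capped at ``max_iterations``; near-coplanar
    minimal samples are rejected and redrawn.  The consensus-maximal model
    is refit by least squares on all its inliers and the inlier mask is
    recomputed against the refit.  Identical seeds give identical results.

    When more than 4 matches are available, a consensus consisting of the
    minimal sample alone (4 inliers, which any 4 matches produce trivially)
    is not accepted as success: at least one supporting match beyond the
    sample is required.  With exactly 4 matches an exact fit succeeds.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    n = len(pa)
    if n < 4:
        raise ValueError(f"RANSAC needs >= 4 matches, got {n}")
    if threshold <= 0:
        raise ValueError("threshold must be positive (mm)")
    rng = np.random.default_rng(seed)

    best_mask = None
    best_count = 0
    best_err = np.inf
    needed = max_iterations
    it = 0
    while it < min(needed, max_iterations):
        it += 1
        idx = rng.choice(n, size=4, replace=False)
        sample = pa[idx]
        if _coplanar(sample, tol=1e-6):
            continue
        X = np.hstack([sample, np.ones((4, 1))])
        try:
            sol = np.linalg.solve(X, pb[idx])
        except np.linalg.LinAlgError:
            continue
        resid = np.linalg.norm(pa @ sol[:3] + sol[3] - pb, axis=1)
        mask = resid <= threshold
        count = int(mask.sum())
        err = float(resid[mask].sum())
        if count > best_count or (count == best_count and err < best_err):
            best_count, best_mask, best_err = count, mask, err
            ratio = count / n
            if ratio > 0:
                denom = np.log(max(1.0 - ratio**4, 1e-12))
                needed = int(np.ceil(np.log(max(1.0 - confidence, 1e-12)) / denom))

    min_consensus = 4 if n == 4 else 5
    if best_mask is None or best_count < min_consensus:
        return RansacResult(None, np.zeros(n, dtype=bool), it, threshold, False)

    try:
        refit = fit_affine_lsq(pa[best_mask], pb[best_mask])
    except DegenerateGeometryError:
        return RansacResult(None, np.zeros(n, dtype=bool), it, threshold, False)
    resid = np.linalg.norm(refit.transform_points(pa) - pb, axis=1)
    mask = resid <= threshold
    if mask.sum() < 4:
        return RansacResult(None, np.zeros(n, dtype=bool), it, threshold, False)
    return RansacResult(refit, mask, it, threshold, True)


def fit_tps(source_points, target_points, regularization: float = 0.0) -> TPSTransform3D:
    """Fit a 3D thin-plate spline through N >= 4 correspondences.

    Solves the standard TPS linear system

        [K + lambda*I  P] [W]   [Q]
        [P^T           0] [A] = [0]

    with K_ij = ||c_i - c_j||, P = [1 | c].  With ``regularization`` = 0
    the map interpolates the targets exactly; lambda > 0 trades
    interpolation for smoothness.
    """
    src = np.asarray(source_points, dtype=float)
    tgt = np.asarray(target_points, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("point arrays must both be (N, 3)")
    n = len(src)
    if n < 4:
        raise ValueError(f"TPS needs >= 4 correspondences, got {n}")
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    K = cdist(src, src)
    offdiag = K.copy()
    np.fill_diagonal(offdiag, np.inf)
    if offdiag.min() < 1e-6:
        raise DegenerateGeometryError("duplicate source points (within 1e-6 mm)")
    if _coplanar(src):
        raise DegenerateGeometryError("coplanar source points: TPS system is rank-deficient")

    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + 4, n + 4))
    # U(r) = r is conditionally *negative* definite on the side-condition
    # subspace, so the smoothing perturbation enters with a minus sign
    # (the lambda -> infinity limit is then the least-squares affine).
    L[:n, :n] = K - regularization * np.eye(n)
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"TPS system is singular: {exc}") from exc
    W = sol[:n]
    A = sol[n:]  # rows: [translation; linear^T]
    return TPSTransform3D(src, W, A[1:].T, A[0])


def apply_transform(transform, points) -> np.ndarray:
    """Apply an affine or TPS transform (or any callable) to (N, 3) points."""
    if hasattr(transform, "transform_points"):
        return transform.transform_points(points)
    return transform(np.asarray(points, dtype=float))


def invert_affine(transform: AffineTransform3D) -> AffineTransform3D:
    if abs(np.linalg.det(transform.linear)) < 1e-12:
        raise SingularTransformError("cannot invert a singular affine")
    inv = np.linalg.inv(transform.linear)
    return AffineTransform3D(inv, -inv @ transform.translation)


def tps_parameter_count(n_points: int) -> int:
    """3N + 12: twelve global affine parameters plus 3 per control point."""
    n_points = int(n_points)
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    return 3 * n_points + 12


def invert_map_points(
    transform,
    targets,
    initializer: AffineTransform3D | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
):
    """Numerically invert a smooth forward map at the given target points.

    Finds p with T(p) = q by quasi-Newton fixed-point iteration
    p <- p - J^{-1} (T(p) - q), using the linear part of ``initializer``
    (or of the transform itself) as a constant Jacobian approximation.
    Returns ``(points, converged_mask)``.
    """
    q = np.atleast_2d(np.asarray(targets, dtype=float))
    if initializer is not None:
        Jinv = np.linalg.inv(initializer.linear)
        p = (q - initializer.translation) @ Jinv.T
    elif hasattr(transform, "linear"):
        Jinv = np.linalg.inv(transform.linear)
        p = (q - np.asarray(transform.translation)) @ Jinv.T
    else:
        Jinv = np.eye(3)
        p = q.copy()
    converged = np.zeros(len(q), dtype=bool)
    active = np.arange(len(q))
    for _ in range(max_iter):
        err = apply_transform(transform, p[active]) - q[active]
        norm = np.linalg.norm(err, axis=1)
        done = norm <= tol
        converged[active[done]] = True
        active = active[~done]
        if len(active) == 0:
            break
        p[active] -= (err[~done]) @ Jinv.T
    return p, converged


# ---------------------------------------------------------------------------
# Serialization: JSON with an explicit direction-convention field.

def transform_to_dict(transform, convention: str = "cbct_to_ct") -> dict:
    if isinstance(transform, AffineTransform3D):
        return {
            "type": "affine",
            "convention": convention,
            "linear": transform.linear.ravel().tolist(),
            "translation": transform.translation.tolist(),
        }
    if isinstance(transform, TPSTransform3D):
        return {
            "type": "tps",
            "convention": convention,
            "linear": transform.linear.ravel().tolist(),
            "translation": transform.translation.tolist(),
            "control_points": transform.control_points.tolist(),
            "weights": transform.weights.tolist(),
        }
    raise TypeError(f"cannot serialize {type(transform).__name__}")


def transform_from_dict(d: dict):
    if d["type"] == "affine":
        return AffineTransform3D(np.asarray(d["linear"]).reshape(3, 3), np.asarray(d["translation"]))
    if d["type"] == "tps":
        return TPSTransform3D(
            np.asarray(d["control_points"]),
            np.asarray(d["weights"]),
            np.asarray(d["linear"]).reshape(3, 3),
            np.asarray(d["translation"]),
        )
    raise ValueError(f"unknown transform type {d['type']!r}")


def save_transform(transform, path, convention: str = "cbct_to_ct") -> None:
    with open(path, "w") as fh:
        json.dump(transform_to_dict(transform, convention), fh, indent=1)


def load_transform(path):
    with open(path) as fh:
        return transform_from_dict(json.load(fh))
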