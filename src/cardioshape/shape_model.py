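"""Statistical point-distribution model of 3D landmark shapes.

A shape is an ordered set of n corresponded 3D landmarks, flattened as
``x = (x1, y1, z1, ..., xn, yn, zn)``.  A training set is brought into a
common frame by generalized Procrustes analysis (GPA): each shape is mapped
by the similarity transform ``T_i`` minimizing ``G = sum_i |m - T_i(x_i)|^2``
against the evolving mean ``m``, which is re-centred and rescaled to unit
norm after every pass.  Principal component analysis of the aligned cloud
then gives the linear generative model ``x = xbar + Phi b`` whose mode
variances are the eigenvalues ``lambda_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LandmarkShape",
    "SimilarityTransform",
    "AlignmentResult",
    "ShapeModel",
    "procrustes_similarity",
    "align_shapes",
    "build_model",
    "generate_shape",
    "project_shape",
]


class CorrespondenceError(ValueError):
    """Landmark counts differ where point-to-point correspondence is required."""


class DegenerateShapeError(ValueError):
    """A shape has no spatial spread (all landmarks coincide)."""


@dataclass(frozen=True)
class LandmarkShape:
    """Ordered set of corresponded 3D landmarks.

    Parameters
    ----------
    points : (n, 3) array of landmark coordinates, in mm.  Index i refers to
        the same anatomical location in every shape of a training set.
    grid_dims : optional (rows, cols); set when the landmarks form a
        parametric grid with ``rows`` longitudinal stations of ``cols``
        circumferential samples each, stored row-major.
    """

    points: np.ndarray
    grid_dims: tuple[int, int] | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 4:
            raise ValueError("a 3D landmark shape needs at least 4 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        if self.grid_dims is not None:
            r, c = self.grid_dims
            if r * c != pts.shape[0]:
                raise ValueError(
                    f"grid_dims {self.grid_dims} inconsistent with n={pts.shape[0]}"
                )
        object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Flattened ``(x1, y1, z1, ..., xn, yn, zn)`` view."""
        return self.points.reshape(-1)

    @classmethod
    def from_vector(cls, vec: np.ndarray, grid_dims=None) -> "LandmarkShape":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 3:
            raise ValueError("flattened shape vector length must be a multiple of 3")
        return cls(vec.reshape(-1, 3), grid_dims=grid_dims)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def spread(self) -> float:
        """Root-mean-square distance of landmarks from their centroid."""
        return float(np.sqrt(((self.points - self.centroid()) ** 2).sum(1).mean()))


@dataclass(frozen=True)
class SimilarityTransform:
    """Scale + proper rotation + translation: ``p -> scale * R @ p + t``."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be 3x3 orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1), no reflections")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "scale", float(self.scale))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (np.asarray(points) @ self.rotation.T) + self.translation

    def apply_shape(self, shape: LandmarkShape) -> LandmarkShape:
        return LandmarkShape(self.apply(shape.points), grid_dims=shape.grid_dims)

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        s = 1.0 / self.scale
        return SimilarityTransform(s, Rinv, -s * (Rinv @ self.translation))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self ∘ other`` (apply `other` first)."""
        return SimilarityTransform(
            self.scale * other.scale,
            self.rotation @ other.rotation,
            self.scale * (self.rotation @ other.translation) + self.translation,
        )


@dataclass
class AlignmentResult:
    """Output of generalized Procrustes alignment."""

    aligned_shapes: list[LandmarkShape]
    transforms: list[SimilarityTransform]
    mean_shape: LandmarkShape
    residual_G: float
    residual_history: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


@dataclass
class ShapeModel:
    """Linear point-distribution model ``x = mean + modes @ b``.

    ``modes`` is a (3n, t) matrix of orthonormal columns (principal axes of
    the aligned training cloud); ``eigenvalues`` are the corresponding mode
    variances, sorted descending.
    """

    mean: LandmarkShape
    modes: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        self.modes = np.asarray(self.modes, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.modes.shape[0] != 3 * self.mean.n:
            raise ValueError("modes row count must be 3 * n_landmarks")
        if self.modes.shape[1] != self.eigenvalues.size:
            raise ValueError("one eigenvalue per mode required")
        if np.any(self.eigenvalues < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_landmarks(self) -> int:
        return self.mean.n

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]


def procrustes_similarity(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Closed-form similarity transform minimizing ``|target - T(source)|^2``.

    Umeyama's solution: SVD of the cross-covariance with determinant
    correction so the rotation is always proper (no reflections).
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise CorrespondenceError("source and target must have the same landmarks")
    mu_s, mu_t = src.mean(0), tgt.mean(0)
    sc, tc = src - mu_s, tgt - mu_t
    var_s = (sc ** 2).sum() / len(src)
    if var_s < 1e-30:
        raise DegenerateShapeError("source shape has zero spread")
    cov = tc.T @ sc / len(src)
    U, d, Vt = np.linalg.svd(cov)
    sgn = np.ones(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        sgn[-1] = -1.0
    R = U @ np.diag(sgn) @ Vt
    scale = float((d * sgn).sum() / var_s)
    if scale <= 0:
        # pathological anti-correlated clouds; fall back to pure rotation fit
        scale = np.finfo(float).eps
    t = mu_t - scale * R @ mu_s
    return SimilarityTransform(scale, R, t)


def _check_training_set(shapes: Sequence[LandmarkShape]) -> int:
    if len(shapes) < 2:
        raise ValueError("need at least 2 shapes")
    n = shapes[0].n
    for i, s in enumerate(shapes):
        if s.n != n:
            raise CorrespondenceError(
                f"shape {i} has {s.n} landmarks, expected {n}"
            )
        if s.spread() < 1e-12:
            raise DegenerateShapeError(f"shape {i} has zero spread")
    return n


def align_shapes(
    shapes: Sequence[LandmarkShape],
    tol: float = 1e-7,
    max_iter: int = 100,
) -> AlignmentResult:
    """Generalized Procrustes alignment of a corresponded training set.

    Iteratively maps every shape onto the current mean by the optimal
    similarity transform, recomputes the mean, re-centres it and rescales it
    to unit norm (the ``|m| = 1`` constraint), until the mean moves by less
    than `tol` or `max_iter` passes are exhausted.  The summed squared
    distance to the mean is non-increasing across iterations.
    """
    _check_training_set(shapes)
    grid = shapes[0].grid_dims

    def _normalize(vec: np.ndarray) -> np.ndarray:
        pts = vec.reshape(-1, 3)
        pts = pts - pts.mean(0)
        return (pts / np.linalg.norm(pts)).reshape(-1)

    mean_vec = _normalize(shapes[0].vector)
    history: list[float] = []
    converged = False
    it = 0
    aligned = [s.points for s in shapes]
    for it in range(1, max_iter + 1):
        mean_pts = mean_vec.reshape(-1, 3)
        transforms = [procrustes_similarity(s.points, mean_pts) for s in shapes]
        aligned = [T.apply(s.points) for T, s in zip(transforms, shapes)]
        G = float(sum(((a - mean_pts) ** 2).sum() for a in aligned))
        history.append(G)
        new_mean = _normalize(np.mean([a.reshape(-1) for a in aligned], axis=0))
        delta = np.linalg.norm(new_mean - mean_vec)
        mean_vec = new_mean
        if delta < tol:
            converged = True
            break

    # final re-alignment against the converged mean
    mean_pts = mean_vec.reshape(-1, 3)
    transforms = [procrustes_similarity(s.points, mean_pts) for s in shapes]
    aligned = [T.apply(s.points) for T, s in zip(transforms, shapes)]
    G = float(sum(((a - mean_pts) ** 2).sum() for a in aligned))
    history.append(G)

    return AlignmentResult(
        aligned_shapes=[LandmarkShape(a, grid_dims=grid) for a in aligned],
        transforms=transforms,
        mean_shape=LandmarkShape(mean_pts, grid_dims=grid),
        residual_G=G,
        residual_history=history,
        n_iterations=it,
        converged=converged,
    )


def build_model(
    alignment: AlignmentResult,
    mode_policy: int | float = 50,
    policy_kind: Literal["count", "variance_fraction"] = "count",
) -> ShapeModel:
    """PCA of the aligned cloud about its arithmetic mean.

    `mode_policy` is either a fixed mode count (default 50, clamped to the
    available rank) or, with ``policy_kind='variance_fraction'``, the fraction
    of total variance the retained modes must explain.  Sample covariance
    uses the N-1 divisor.  Eigenvector signs are fixed by making each mode's
    largest-magnitude component positive.
    """
    shapes = alignment.aligned_shapes
    if len(shapes) < 2:
        raise ValueError("need at least 2 aligned shapes")
    X = np.stack([s.vector for s in shapes])  # (N, 3n)
    xbar = X.mean(axis=0)
    Xc = X - xbar
    # thin SVD: eigenvalues of cov = s^2 / (N-1), modes = rows of Vt
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = svals ** 2 / (len(shapes) - 1)
    available = min(3 * shapes[0].n, len(shapes) - 1)

    if policy_kind == "variance_fraction":
        if not 0 < mode_policy <= 1:
            raise ValueError("variance fraction must be in (0, 1]")
        cum = np.cumsum(eigvals[:available])
        total = cum[-1] if cum.size else 0.0
        t = int(np.searchsorted(cum, mode_policy * total - 1e-12) + 1) if total > 0 else 0
        t = max(t, 1)
    elif policy_kind == "count":
        t = int(mode_policy)
        if t > available:
            warnings.warn(
                f"requested {t} modes but only {available} available; clamping",
                stacklevel=2,
            )
            t = available
        if t < 1:
            raise ValueError("mode count must be >= 1")
    else:
        raise ValueError(f"unknown policy kind {policy_kind!r}")

    modes = Vt[:t].T.copy()
    # deterministic sign convention
    for j in range(modes.shape[1]):
        k = np.argmax(np.abs(modes[:, j]))
        if modes[k, j] < 0:
            modes[:, j] = -modes[:, j]

    return ShapeModel(
        mean=LandmarkShape(xbar.reshape(-1, 3), grid_dims=shapes[0].grid_dims),
        modes=modes,
        eigenvalues=eigvals[:t],
    )


def clamp_parameters(model: ShapeModel, b: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Limit each shape parameter to ``|b_j| <= n_sigma * sqrt(lambda_j)``."""
    lim = n_sigma * np.sqrt(np.maximum(model.eigenvalues, 0.0))
    return np.clip(b, -lim, lim)


def generate_shape(model: ShapeModel, b: np.ndarray, clamp: bool = False) -> LandmarkShape:
    """Synthesize ``x = mean + modes @ b`` (optionally clamping b to 3 sigma)."""
    b = np.asarray(b, dtype=float).reshape(-1)
    if b.size != model.n_modes:
        raise ValueError(f"b has length {b.size}, model has {model.n_modes} modes")
    if clamp:
        b = clamp_parameters(model, b)
    vec = model.mean.vector + model.modes @ b
    return LandmarkShape.from_vector(vec, grid_dims=model.mean.grid_dims)


def project_shape(model: ShapeModel, shape: LandmarkShape) -> np.ndarray:
    """Least-squares shape parameters ``b = modes^T (x - mean)``.

    ``generate(project(x))`` is the orthogonal projection of x onto the
    model subspace.
    """
    if shape.n != model.n_landmarks:
        raise ValueError(
            f"shape has {shape.n} landmarks, model expects {model.n_landmarks}"
        )
    return model.modes.T @ (shape.vector - model.mean.vector)
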