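"""Active-shape-model fitting of the statistical model to a 3D image volume.

The match minimizes ``f = |X - T(xbar + Phi b)|^2`` where X are candidate
boundary points found in the image, T a similarity pose and b the shape
parameters.  Fitting alternates two steps until convergence: (1) for every
landmark, search along the surface normal for the best match to a trained
gradient-profile model (minimum Mahalanobis distance); (2) update pose and
shape parameters to best fit the found candidates (closed-form similarity
alignment alternated with linear projection of b, clamped to 3 sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .shape_model import (
    LandmarkShape,
    ShapeModel,
    SimilarityTransform,
    clamp_parameters,
    procrustes_similarity,
)

__all__ = [
    "ImageVolume",
    "ProfileModel",
    "FitResult",
    "grid_normals",
    "build_profile_models",
    "search_profile",
    "update_pose_and_shape",
    "initialize_pose",
    "fit",
]


@dataclass
class ImageVolume:
    """3D scalar image on a regular grid.

    ``intensities[i, j, k]`` sits at world position ``origin + (i,j,k)*spacing``.
    """

    intensities: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world points (border values clamped)."""
        idx = self.world_to_index(points)
        return map_coordinates(self.intensities, idx.T, order=1, mode="nearest")

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=-1)


@dataclass
class ProfileModel:
    """Per-landmark statistics of normalized gradient profiles.

    For each landmark, the mean of normalized image-gradient profiles of
    length 2k+1 sampled along the outward normal across the training images,
    and the (ridge-regularized) covariance inverse used for Mahalanobis
    matching.
    """

    mean_profiles: np.ndarray  # (L, 2k+1)
    cov_inv: np.ndarray  # (L, 2k+1, 2k+1)
    half_length: int
    step: float  # sample spacing along the normal, mm


@dataclass
class FitResult:
    pose: SimilarityTransform
    b: np.ndarray
    residual_f: float
    iterations: int
    converged: bool
    landmarks: LandmarkShape | None = None
    landmark_error: float | None = None
    residual_history: list[float] = field(default_factory=list)


def grid_normals(shape: LandmarkShape) -> np.ndarray:
    """Outward unit normals of a (rows x cols) landmark grid.

    Tangents come from circumferential (wrapped) and longitudinal (one-sided
    at the ends) central differences; orientation is fixed to point away from
    the shape centroid.
    """
    if shape.grid_dims is None:
        raise ValueError("grid_dims required to compute surface normals")
    rows, cols = shape.grid_dims
    P = shape.points.reshape(rows, cols, 3)
    tu = np.roll(P, -1, axis=1) - np.roll(P, 1, axis=1)
    tv = np.empty_like(P)
    tv[1:-1] = P[2:] - P[:-2]
    tv[0] = P[1] - P[0]
    tv[-1] = P[-1] - P[-2]
    n = np.cross(tu, tv)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    # degenerate (e.g. collapsed) grid cells: fall back to the radial direction
    centroid = shape.centroid()
    radial = P - centroid
    bad = norm[..., 0] < 1e-12
    n[bad] = radial[bad]
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    n = n / np.maximum(norm, 1e-300)
    flip = np.einsum("rjc,rjc->rj", n, radial) < 0
    n[flip] = -n[flip]
    return n.reshape(-1, 3)


def _normalize_profile(g: np.ndarray) -> np.ndarray:
    return g / (np.abs(g).sum(axis=-1, keepdims=True) + 1e-12)


def _sample_gradient_profiles(
    image: ImageVolume, points: np.ndarray, normals: np.ndarray,
    half: int, step: float,
) -> np.ndarray:
    """Normalized derivative profiles of length 2*half+1 along each normal."""
    offsets = np.arange(-(half + 1), half + 2) * step  # 2*half+3 samples
    pos = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = image.sample(pos.reshape(-1, 3)).reshape(len(points), -1)
    grad = (vals[:, 2:] - vals[:, :-2]) / (2.0 * step)
    return _normalize_profile(grad)


def build_profile_models(
    training_images: Sequence[ImageVolume],
    training_landmarks: Sequence[LandmarkShape],
    k: int = 5,
    step: float | None = None,
    ridge: float = 1e-3,
) -> ProfileModel:
    """Train per-landmark gradient-profile statistics across images.

    ``step`` defaults to the smallest voxel spacing of the first image.
    Profiles whose landmark falls outside its image are excluded (warned);
    if every sample of a landmark is excluded an error is raised.
    """
    if len(training_images) != len(training_landmarks):
        raise ValueError("paired images and landmark sets required")
    if len(training_images) == 0:
        raise ValueError("at least one training image required")
    if step is None:
        step = float(training_images[0].spacing.min())
    L = training_landmarks[0].n
    samples: list[list[np.ndarray]] = [[] for _ in range(L)]
    for img, lms in zip(training_images, training_landmarks):
        normals = grid_normals(lms)
        inb = img.contains(lms.points)
        if not inb.all():
            warnings.warn(
                f"{int((~inb).sum())} landmarks outside image bounds excluded",
                stacklevel=2,
            )
        prof = _sample_gradient_profiles(img, lms.points, normals, k, step)
        for i in np.flatnonzero(inb):
            samples[i].append(prof[i])
    width = 2 * k + 1
    mean = np.empty((L, width))
    cov_inv = np.empty((L, width, width))
    for i in range(L):
        if not samples[i]:
            raise ValueError(f"landmark {i} excluded from every training image")
        S = np.stack(samples[i])
        mean[i] = S.mean(axis=0)
        if len(S) > 1:
            cov = np.cov(S.T, ddof=1).reshape(width, width)
        else:
            cov = np.zeros((width, width))
        lam = ridge * (np.trace(cov) / width) + 1e-8
        cov_inv[i] = np.linalg.inv(cov + lam * np.eye(width))
    return ProfileModel(mean_profiles=mean, cov_inv=cov_inv, half_length=k, step=step)


def search_profile(
    image: ImageVolume,
    point: np.ndarray,
    normal: np.ndarray,
    mean_profile: np.ndarray,
    cov_inv: np.ndarray,
    m: int,
    step: float,
) -> tuple[np.ndarray, int]:
    """Best boundary candidate along one normal by Mahalanobis profile match.

    Offsets from -(m-k) to +(m-k) voxels along the normal are scored; ties
    break toward the smaller absolute offset (then the negative one), so the
    result is deterministic.  Returns the candidate point and the offset.
    """
    k = (mean_profile.size - 1) // 2
    if m < k:
        raise ValueError("search half-length m must be >= profile half-length k")
    g = _sample_long_gradient(image, point, normal, m, step)
    best_d, best_off = np.inf, 0
    for off in sorted(range(-(m - k), m - k + 1), key=lambda o: (abs(o), o)):
        w = _normalize_profile(g[off + m - k : off + m + k + 1])
        r = w - mean_profile
        d = float(r @ cov_inv @ r)
        if d < best_d - 1e-15:
            best_d, best_off = d, off
    return point + best_off * step * normal, best_off


def _sample_long_gradient(image, point, normal, m, step):
    offsets = np.arange(-(m + 1), m + 2) * step
    pos = point[None, :] + offsets[:, None] * normal[None, :]
    vals = image.sample(pos)
    return (vals[2:] - vals[:-2]) / (2.0 * step)


def _search_all(image, points, normals, profiles: ProfileModel, m: int):
    """Vectorized profile search over all landmarks."""
    k = profiles.half_length
    step = profiles.step
    offsets = np.arange(-(m + 1), m + 2) * step
    pos = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = image.sample(pos.reshape(-1, 3)).reshape(len(points), -1)
    grad = (vals[:, 2:] - vals[:, :-2]) / (2.0 * step)  # (L, 2m+1)
    span = m - k
    cand_offsets = sorted(range(-span, span + 1), key=lambda o: (abs(o), o))
    best_d = np.full(len(points), np.inf)
    best_off = np.zeros(len(points), dtype=int)
    for off in cand_offsets:
        w = _normalize_profile(grad[:, off + m - k : off + m + k + 1])
        r = w - profiles.mean_profiles
        d = np.einsum("li,lij,lj->l", r, profiles.cov_inv, r)
        better = d < best_d - 1e-15
        best_d[better] = d[better]
        best_off[better] = off
    return points + best_off[:, None] * step * normals, best_off


def update_pose_and_shape(
    model: ShapeModel,
    candidates: LandmarkShape,
    clamp: bool = True,
    tol: float = 1e-14,
    max_alternations: int = 200,
) -> tuple[SimilarityTransform, np.ndarray, float]:
    """Minimize ``|X - T(xbar + Phi b)|^2`` by coordinate descent.

    Alternates the closed-form similarity alignment of the current model
    instance onto the candidates with the linear projection of the
    back-transformed candidates onto the mode subspace (b clamped to 3 sigma
    when requested).  The residual is non-increasing across alternations.
    """
    if candidates.n != model.n_landmarks:
        raise ValueError("candidate landmark count does not match the model")
    if candidates.spread() < 1e-12:
        raise ValueError("degenerate candidates: no spatial spread")
    X = candidates.points
    xbar = model.mean.vector
    b = np.zeros(model.n_modes)
    prev = np.inf
    pose = SimilarityTransform()
    residual = np.inf
    for _ in range(max_alternations):
        y = (xbar + model.modes @ b).reshape(-1, 3)
        pose = procrustes_similarity(y, X)
        residual = float(((X - pose.apply(y)) ** 2).sum())
        yt = pose.inverse().apply(X).reshape(-1)
        b = model.modes.T @ (yt - xbar)
        if clamp:
            b = clamp_parameters(model, b)
        if prev - residual < tol:
            break
        prev = residual
    y = (xbar + model.modes @ b).reshape(-1, 3)
    pose = procrustes_similarity(y, X)
    residual = float(((X - pose.apply(y)) ** 2).sum())
    return pose, b, residual


def _otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(centers[int(np.argmax(sigma_b))])


def initialize_pose(image: ImageVolume, model: ShapeModel | None = None) -> SimilarityTransform:
    """Coarse pose from intensity moments.

    Translation is the centroid of above-Otsu intensity mass; scale matches
    the object's RMS radius to the model mean's.  Identity rotation.  This is
    a moment-based stand-in for anatomical-knowledge placement of the model
    in the chest (the heart's location relative to pericardium and great
    vessels is qualitative prior knowledge, not computable from the image
    alone).
    """
    I = image.intensities
    if float(I.max() - I.min()) < 1e-12:
        raise ValueError("uniform image: no structure to initialize from")
    thr = _otsu_threshold(I.reshape(-1))
    w = np.clip(I - thr, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("no voxels above threshold; cannot initialize pose")
    idx = np.indices(I.shape, dtype=float)
    centroid_idx = np.array([(idx[a] * w).sum() / total for a in range(3)])
    centroid = image.origin + centroid_idx * image.spacing
    coords = np.stack([idx[a].reshape(-1) * image.spacing[a] + image.origin[a]
                       for a in range(3)], axis=1)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    rms = float(np.sqrt((d2 * w.reshape(-1)).sum() / total))
    model_rms = model.mean.spread() if model is not None else 1.0
    return SimilarityTransform(scale=max(rms / model_rms, np.finfo(float).tiny),
                               rotation=np.eye(3), translation=centroid)


def fit(
    model: ShapeModel,
    profiles: ProfileModel,
    image: ImageVolume,
    init: SimilarityTransform,
    max_iter: int = 50,
    tol: float | None = None,
    m: int = 8,
    clamp: bool = True,
    ground_truth: LandmarkShape | None = None,
) -> FitResult:
    """Two-step iterative model-to-image matching.

    Each outer iteration searches the best profile match along every
    landmark normal, then updates pose and shape to fit the candidates.
    Stops when the mean landmark displacement drops below `tol` (default
    0.1 voxel) or after `max_iter` iterations; a divergence guard stops after
    three consecutive residual increases and reports ``converged=False``.
    """
    if tol is None:
        tol = 0.1 * float(image.spacing.min())
    pose = init
    b = np.zeros(model.n_modes)
    grid = model.mean.grid_dims
    current = pose.apply(model.mean.points)
    history: list[float] = []
    converged = False
    rising = 0
    it = 0
    residual = np.inf
    for it in range(1, max_iter + 1):
        lshape = LandmarkShape(current, grid_dims=grid)
        normals = grid_normals(lshape)
        cand_pts, _ = _search_all(image, current, normals, profiles, m)
        pose, b, residual = update_pose_and_shape(
            model, LandmarkShape(cand_pts, grid_dims=grid), clamp=clamp
        )
        new = pose.apply((model.mean.vector + model.modes @ b).reshape(-1, 3))
        move = float(np.linalg.norm(new - current, axis=1).mean())
        current = new
        if history and residual > history[-1] + 1e-12:
            rising += 1
        else:
            rising = 0
        history.append(residual)
        if move < tol:
            converged = True
            break
        if rising >= 3:
            converged = False
            break
    landmarks = LandmarkShape(current, grid_dims=grid)
    err = None
    if ground_truth is not None:
        err = float(np.linalg.norm(current - ground_truth.points, axis=1).mean())
    return FitResult(
        pose=pose, b=b,
        residual_f=residual if max_iter > 0 else np.inf,
        iterations=it if max_iter > 0 else 0,
        converged=converged,
        landmarks=landmarks,
        landmark_error=err,
        residual_history=history,
    )
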