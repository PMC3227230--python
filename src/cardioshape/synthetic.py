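"""Synthetic ventricle phantoms with analytic ground truth.

The phantom family is a truncated prolate ellipsoid — the classic idealized
ventricle — closed by a flat basal cap, sampled as a corresponded landmark
grid (rows = longitudinal stations from apex to basal-cap centre, columns =
circumferential samples).  Its cavity volume is available in closed form,
so every downstream computation (spline fitting, polynomial integration,
ejection fraction) can be validated against analytic truth.

Shape variability is planted as a few named linear deformation modes
(long-axis stretch, circumferential bulge, apical twist).  The mode
displacement fields are orthonormalized against the similarity-transform
tangent space (translations, rotations, isotropic scaling) so that
Procrustes alignment cannot absorb planted variance; mode amplitudes are
then recoverable as PCA eigenvalues up to the unit-norm scaling of the
aligned frame.

Image volumes are rendered as a three-class piecewise-constant intensity
model (blood pool / myocardium / background) with Gaussian blur and noise —
the simplest model that gives gradient-profile matching realistic structure.
Cardiac cycles modulate the transverse radii by a smooth contraction curve
scaled to a prescribed ejection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .fitting import ImageVolume
from .meshing import mesh_from_landmark_grid, voxelize_mesh
from .shape_model import LandmarkShape, SimilarityTransform

__all__ = [
    "PhantomSpec",
    "TrainingSet",
    "unit_cube_surface",
    "sphere_landmark_grid",
    "make_ventricle_shape",
    "make_training_set",
    "make_image_volume",
    "make_cardiac_cycle",
    "mode_fields",
    "mode_gains",
    "analytic_endo_volume",
    "contraction_factor",
]

#: fraction of the long semi-axis at which the ellipsoid is truncated
TRUNCATION = 0.5

#: intensity classes of rendered volumes; contrasts mimic cine bSSFP MR,
#: where the bright blood pool dominates and the epicardial edge is weaker
INTENSITY_BACKGROUND = 55.0
INTENSITY_MYOCARDIUM = 100.0
INTENSITY_BLOOD = 210.0

MODE_NAMES = ("stretch", "bulge", "twist")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, variability and imaging parameters of the phantom family.

    Lengths in mm.  ``grid_dims`` is (circumferential, longitudinal) landmark
    counts; ``mode_amplitudes`` maps named deformation modes to standard
    deviations (mm, in the unit-field convention); ``contraction_amplitude``
    is the peak-systole fractional shrink of the transverse radii (the
    default 0.3 gives ejection fraction 1 - 0.7^2 = 0.51, a normal value).
    """

    long_axis: float = 70.0
    endo_radii: tuple[float, float] = (25.0, 25.0)
    wall_thickness: float = 10.0
    grid_dims: tuple[int, int] = (16, 12)
    mode_amplitudes: tuple[tuple[str, float], ...] = (
        ("stretch", 2.0),
        ("bulge", 1.0),
        ("twist", 0.5),
    )
    contraction_amplitude: float = 0.3
    noise_sigma: float = 5.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.long_axis <= 0 or min(self.endo_radii) <= 0:
            raise ValueError("phantom lengths must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if self.grid_dims[0] < 8 or self.grid_dims[1] < 6:
            raise ValueError("grid_dims must be at least (8, 6)")
        if not 0.0 <= self.contraction_amplitude < 1.0:
            raise ValueError("contraction_amplitude must be in [0, 1)")
        for name, _ in self.mode_amplitudes:
            if name not in MODE_NAMES:
                raise ValueError(f"unknown mode {name!r}; known: {MODE_NAMES}")


def contraction_factor(phase: float, amplitude: float) -> float:
    """Smooth transverse contraction: 1 at phase 0, (1 - amplitude) at 0.5."""
    return 1.0 - amplitude * float(np.sin(np.pi * phase) ** 2)


def _ellipsoid_grid(a: float, b: float, c: float, z_cut: float,
                    n_circ: int, n_long: int) -> np.ndarray:
    """Landmark grid of a truncated ellipsoid closed by a flat basal cap.

    Returns (n_long, n_circ, 3): wall rows from near-apex to the basal rim,
    then cap rows spiralling inward on the plane z = z_cut.
    """
    theta_t = np.arccos(z_cut / c)
    n_cap = max(2, n_long // 4)
    n_wall = n_long - n_cap
    u = 2.0 * np.pi * np.arange(n_circ) / n_circ
    rows = []
    for j in range(n_wall):
        theta = np.pi - (np.pi - theta_t) * (j + 1.0) / n_wall
        rows.append(np.stack([
            a * np.sin(theta) * np.cos(u),
            b * np.sin(theta) * np.sin(u),
            np.full(n_circ, c * np.cos(theta)),
        ], axis=1))
    r_rim = np.sin(theta_t)
    for i in range(n_cap):
        g = (n_cap - i) / (n_cap + 1.0)
        rows.append(np.stack([
            a * r_rim * g * np.cos(u),
            b * r_rim * g * np.sin(u),
            np.full(n_circ, z_cut),
        ], axis=1))
    return np.stack(rows)


def _base_geometry(spec: PhantomSpec, phase: float = 0.0,
                   amplitude: float | None = None):
    """Semi-axes and cut planes of endo/epi at a cycle phase."""
    if amplitude is None:
        amplitude = spec.contraction_amplitude
    c = spec.long_axis / (1.0 + TRUNCATION)
    g = contraction_factor(phase, amplitude)
    a, b = spec.endo_radii[0] * g, spec.endo_radii[1] * g
    z_cut = TRUNCATION * c
    wt = spec.wall_thickness
    return (a, b, c, z_cut), (a + wt, b + wt, c + wt, z_cut + wt)


def _similarity_tangent_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3n, 7) of the similarity-transform tangent space."""
    n = len(points)
    centered = points - points.mean(axis=0)
    cols = []
    for ax in range(3):  # translations
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        cols.append(t.reshape(-1))
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ]
    for G in gens:  # infinitesimal rotations
        cols.append((centered @ G.T).reshape(-1))
    cols.append(centered.reshape(-1))  # isotropic scaling
    Q, _ = np.linalg.qr(np.stack(cols, axis=1))
    return Q


def _raw_mode_field(points: np.ndarray, name: str) -> np.ndarray:
    z = points[:, 2]
    zmin, zmax = z.min(), z.max()
    span = max(zmax - zmin, 1e-12)
    d = np.zeros_like(points)
    if name == "stretch":
        d[:, 2] = z - z.mean()
    elif name == "bulge":
        s = np.sin(np.pi * (z - zmin) / span)
        d[:, 0] = points[:, 0] * s
        d[:, 1] = points[:, 1] * s
    elif name == "twist":
        omega = (zmax - z) / span  # max twist at the apex
        d[:, 0] = -points[:, 1] * omega
        d[:, 1] = points[:, 0] * omega
    else:
        raise ValueError(f"unknown mode {name!r}")
    return d.reshape(-1)


def mode_fields(spec: PhantomSpec, which: str = "endo") -> tuple[list[str], np.ndarray]:
    """Orthonormal mode displacement fields (3n, K) for the phase-0 grid.

    Raw analytic fields are projected out of the similarity tangent space and
    Gram-Schmidt orthonormalized in the declared order, so planted mode
    variance cannot leak into (or be removed by) Procrustes alignment.
    """
    endo_geo, epi_geo = _base_geometry(spec, 0.0)
    geo = endo_geo if which == "endo" else epi_geo
    n_circ, n_long = spec.grid_dims
    pts = _ellipsoid_grid(*geo, n_circ, n_long).reshape(-1, 3)
    Qsim = _similarity_tangent_basis(pts)
    names = [name for name, _ in spec.mode_amplitudes]
    fields = []
    for name in names:
        f = _raw_mode_field(pts, name)
        f = f - Qsim @ (Qsim.T @ f)
        for prev in fields:
            f = f - prev * (prev @ f)
        nrm = np.linalg.norm(f)
        if nrm < 1e-10:
            raise ValueError(f"mode {name!r} degenerate after orthogonalization")
        fields.append(f / nrm)
    return names, np.stack(fields, axis=1)


def mode_gains(spec: PhantomSpec) -> dict[str, float]:
    """Long-axis-extent derivative of each orthonormalized endo mode field.

    ``extent(b) - extent(0) = b * gain`` exactly, for amplitudes small enough
    not to reorder the extremal landmarks.
    """
    endo_geo, _ = _base_geometry(spec, 0.0)
    n_circ, n_long = spec.grid_dims
    pts = _ellipsoid_grid(*endo_geo, n_circ, n_long).reshape(-1, 3)
    names, U = mode_fields(spec, "endo")
    imax, imin = int(np.argmax(pts[:, 2])), int(np.argmin(pts[:, 2]))
    gains = {}
    for j, name in enumerate(names):
        fz = U[:, j].reshape(-1, 3)[:, 2]
        gains[name] = float(fz[imax] - fz[imin])
    return gains


def make_ventricle_shape(
    spec: PhantomSpec,
    b_true: np.ndarray | None = None,
    phase: float = 0.0,
) -> tuple[LandmarkShape, LandmarkShape]:
    """Corresponded endo/epi landmark grids at a cycle phase.

    `b_true` are amplitudes for the spec's named modes (default zero).  The
    endo and epi grids share the parametric sampling, so landmark index i
    corresponds across every shape drawn from the same spec.
    """
    n_circ, n_long = spec.grid_dims
    endo_geo, epi_geo = _base_geometry(spec, phase)
    grids = []
    for which, geo in (("endo", endo_geo), ("epi", epi_geo)):
        pts = _ellipsoid_grid(*geo, n_circ, n_long).reshape(-1, 3)
        if b_true is not None:
            b = np.asarray(b_true, dtype=float).reshape(-1)
            names, U = mode_fields(spec, which)
            if b.size != len(names):
                raise ValueError(f"b_true must have {len(names)} amplitudes")
            pts = pts + (U @ b).reshape(-1, 3)
        grids.append(LandmarkShape(pts, grid_dims=(n_long, n_circ)))
    endo, epi = grids
    if endo.spread() >= epi.spread():
        raise ValueError("wall collapse: epicardium not outside endocardium")
    return endo, epi


@dataclass
class TrainingSet:
    """Synthetic corresponded training population with recorded ground truth."""

    shapes: list[LandmarkShape]
    b_true: np.ndarray  # (N, K) planted amplitudes
    mode_names: list[str]
    fields: np.ndarray  # (3n, K) orthonormal planted mode fields
    template: LandmarkShape  # phase-0, b=0 endo grid
    sigmas: np.ndarray  # planted per-mode standard deviations

    @property
    def template_scale(self) -> float:
        """Norm of the centred template — converts aligned-frame units to mm."""
        pts = self.template.points - self.template.centroid()
        return float(np.linalg.norm(pts))


def make_training_set(
    spec: PhantomSpec,
    n_shapes: int,
    random_pose: bool = False,
    seed: int | None = None,
) -> TrainingSet:
    """Draw a population of endocardial grids with normal mode amplitudes.

    With `random_pose`, each shape additionally receives a random similarity
    transform (rotation up to ~0.2 rad, log-normal scale sigma 0.1,
    translation sigma 10 mm) so Procrustes alignment is exercised.
    Deterministic per seed (defaults to ``spec.seed``).
    """
    if n_shapes < 2:
        raise ValueError("need at least 2 shapes")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names, U = mode_fields(spec, "endo")
    sigmas = np.array([s for _, s in spec.mode_amplitudes], dtype=float)
    endo0, _ = make_ventricle_shape(spec)
    base = endo0.vector
    B = rng.normal(0.0, 1.0, (n_shapes, len(names))) * sigmas
    shapes = []
    for i in range(n_shapes):
        vec = base + U @ B[i]
        shape = LandmarkShape.from_vector(vec, grid_dims=endo0.grid_dims)
        if random_pose:
            ax = rng.normal(size=3)
            ax /= np.linalg.norm(ax)
            ang = rng.normal(0.0, 0.2)
            K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
            R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
            T = SimilarityTransform(
                scale=float(np.exp(rng.normal(0.0, 0.1))),
                rotation=R,
                translation=rng.normal(0.0, 10.0, 3),
            )
            shape = T.apply_shape(shape)
        shapes.append(shape)
    return TrainingSet(
        shapes=shapes, b_true=B, mode_names=list(names), fields=U,
        template=endo0, sigmas=sigmas,
    )


def analytic_endo_volume(spec: PhantomSpec, phase: float = 0.0,
                         amplitude: float | None = None) -> float:
    """Closed-form cavity volume of the (b = 0) truncated-ellipsoid endocardium.

    Integral of the elliptical cross-section from apex to the basal cap:
    ``pi a b c * (tau - tau^3/3 + 2/3)`` with tau the truncation fraction.
    """
    (a, b, c, z_cut), _ = _base_geometry(spec, phase, amplitude)
    tau = z_cut / c
    return float(np.pi * a * b * c * (tau - tau ** 3 / 3.0 + 2.0 / 3.0))


def make_image_volume(
    endo: LandmarkShape,
    epi: LandmarkShape,
    resolution: int = 48,
    noise_sigma: float = 5.0,
    blur_sigma: float = 1.0,
    seed: int = 0,
    margin: float = 0.15,
) -> tuple[ImageVolume, LandmarkShape]:
    """Render a three-class image volume from closed endo/epi surfaces.

    Cubic field of view covering the epicardium with a relative `margin`;
    piecewise-constant intensities (blood pool inside the endocardium,
    myocardium between the surfaces, background outside), Gaussian blur of
    `blur_sigma` mm, additive Gaussian noise.  Returns the volume and the
    ground-truth endocardial landmarks (which lie on the rendered boundary).
    """
    epi_mesh = mesh_from_landmark_grid(epi)
    endo_mesh = mesh_from_landmark_grid(endo)
    if not (epi_mesh.watertight and endo_mesh.watertight):
        raise ValueError("surfaces must mesh watertight for rendering")
    lo = epi_mesh.vertices.min(axis=0)
    hi = epi_mesh.vertices.max(axis=0)
    center = 0.5 * (lo + hi)
    extent = float((hi - lo).max()) * (1.0 + 2.0 * margin)
    spacing = np.full(3, extent / resolution)
    origin = center - (resolution - 1) / 2.0 * spacing
    shape = (resolution, resolution, resolution)
    if np.any(lo < origin) or np.any(hi > origin + (resolution - 1) * spacing):
        raise ValueError("shapes exceed the field of view")

    inside_epi = voxelize_mesh(epi_mesh, shape, spacing, origin)
    inside_endo = voxelize_mesh(endo_mesh, shape, spacing, origin)
    img = np.full(shape, INTENSITY_BACKGROUND)
    img[inside_epi] = INTENSITY_MYOCARDIUM
    img[inside_endo] = INTENSITY_BLOOD
    if blur_sigma > 0:
        img = gaussian_filter(img, sigma=blur_sigma / spacing[0])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, shape)
    return ImageVolume(img, spacing=spacing, origin=origin), endo


def unit_cube_surface():
    """The axis-aligned unit cube as a closed bilinear B-spline surface.

    Four circumferential control columns (the square cross-section), one
    collapsed pole slice at each face centre; with linear orders every span
    is exactly a face of the cube, so the polynomial volume integral is
    exactly 1.  Canonical fixture for the exact volumetry.
    """
    from .bspline import BSplineSurface

    ring0 = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    nv = 4  # bottom pole, bottom ring, top ring, top pole
    net = np.empty((5, nv, 3))
    for i in range(5):
        x, y = ring0[i % 4]
        net[i, 0] = (0.5, 0.5, 0.0)
        net[i, 1] = (x, y, 0.0)
        net[i, 2] = (x, y, 1.0)
        net[i, 3] = (0.5, 0.5, 1.0)
    return BSplineSurface(net, order_u=1, order_v=1, closed_u=True, pole_caps=True)


def sphere_landmark_grid(radius: float = 1.0, n_circ: int = 48,
                         n_long: int = 36, center=(0.0, 0.0, 0.0)) -> LandmarkShape:
    """Dense landmark grid sampling a sphere (fixture for volume validation).

    Latitude rows exclude the exact poles (the spline fitter closes them with
    pole caps); rows run from near the south pole to near the north pole.
    """
    u = 2.0 * np.pi * np.arange(n_circ) / n_circ
    thetas = np.pi - np.pi * (np.arange(n_long) + 1.0) / (n_long + 1.0)
    rows = []
    for th in thetas:
        rows.append(np.stack([
            radius * np.sin(th) * np.cos(u),
            radius * np.sin(th) * np.sin(u),
            np.full(n_circ, radius * np.cos(th)),
        ], axis=1))
    pts = np.stack(rows).reshape(-1, 3) + np.asarray(center, dtype=float)
    return LandmarkShape(pts, grid_dims=(n_long, n_circ))


def make_cardiac_cycle(
    spec: PhantomSpec,
    n_phases: int,
    ef_target: float,
) -> list[tuple[float, LandmarkShape, LandmarkShape]]:
    """Time-ordered (time_ms, endo, epi) phases with a prescribed EF.

    The transverse radii follow ``1 - A sin^2(pi t / T)`` over a 1000 ms
    cycle; since the cavity volume scales with the transverse radii squared,
    ``A = 1 - sqrt(1 - EF)`` makes the analytic volume curve's ejection
    fraction exactly `ef_target`.  With ``n_phases = 2`` the samples are
    exactly end-diastole (t = 0) and end-systole (t = 500 ms).
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if not 0.0 < ef_target < 1.0:
        raise ValueError("ef_target must be in (0, 1)")
    amplitude = 1.0 - np.sqrt(1.0 - ef_target)
    if amplitude >= 1.0 - 1e-9:
        raise ValueError("ef_target infeasible for this geometry")
    cycle_spec = replace(spec, contraction_amplitude=float(amplitude))
    out = []
    for i in range(n_phases):
        t = 1000.0 * i / n_phases
        endo, epi = make_ventricle_shape(cycle_spec, phase=t / 1000.0)
        out.append((t, endo, epi))
    return out
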