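"""File formats: landmark CSV, manifests, model/surface/profile files, images, meshes.

Landmark files are plain-text CSV, one ``x,y,z`` row per landmark (mm), with
``#``-prefixed header lines carrying the landmark count and optional grid
dimensions.  Model, surface and profile files are versioned NumPy archives
whose write-read round trip is bit-exact.  Image volumes are NIfTI (via
nibabel) or a raw little-endian float32 block with a JSON sidecar header.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .bspline import BSplineSurface
from .fitting import ImageVolume, ProfileModel
from .meshing import TriangleMesh
from .shape_model import LandmarkShape, ShapeModel

__all__ = [
    "read_landmark_file",
    "write_landmark_file",
    "read_manifest",
    "write_manifest",
    "save_model",
    "load_model",
    "save_surface",
    "load_surface",
    "save_profiles",
    "load_profiles",
    "save_image",
    "load_image",
    "export_mesh",
]

FORMAT_VERSION = "cardioshape-1"


def write_landmark_file(path, shape: LandmarkShape) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {FORMAT_VERSION} landmarks\n")
        fh.write(f"# n={shape.n}\n")
        if shape.grid_dims is not None:
            fh.write(f"# grid_dims={shape.grid_dims[0]},{shape.grid_dims[1]}\n")
        fh.write("# columns: x,y,z (mm)\n")
        for p in shape.points:
            fh.write(f"{p[0]:.17g},{p[1]:.17g},{p[2]:.17g}\n")


def read_landmark_file(path) -> LandmarkShape:
    path = Path(path)
    n_expected = None
    grid_dims = None
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("n="):
                    n_expected = int(body[2:])
                elif body.startswith("grid_dims="):
                    r, c = body.split("=", 1)[1].split(",")
                    grid_dims = (int(r), int(c))
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 comma-separated values")
            try:
                xyz = [float(v) for v in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number") from exc
            if not all(np.isfinite(v) for v in xyz):
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            rows.append(xyz)
    if n_expected is not None and len(rows) != n_expected:
        raise ValueError(f"{path}: header says n={n_expected} but {len(rows)} rows found")
    if grid_dims is not None and grid_dims[0] * grid_dims[1] != len(rows):
        raise ValueError(
            f"{path}: grid_dims {grid_dims} inconsistent with {len(rows)} rows"
        )
    return LandmarkShape(np.asarray(rows, dtype=float), grid_dims=grid_dims)


def write_manifest(path, files) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {FORMAT_VERSION} manifest\n")
        for f in files:
            fh.write(os.path.relpath(Path(f), path.parent) + "\n")


def read_manifest(path) -> list[Path]:
    path = Path(path)
    out = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append((path.parent / line).resolve())
    return out


def save_model(path, model: ShapeModel) -> None:
    grid = np.asarray(model.mean.grid_dims if model.mean.grid_dims else (-1, -1))
    np.savez(
        path,
        version=FORMAT_VERSION,
        mean=model.mean.points,
        grid_dims=grid,
        modes=model.modes,
        eigenvalues=model.eigenvalues,
    )


def _check_version(data, path):
    if str(data["version"]) != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported format version {data['version']}")


def load_model(path) -> ShapeModel:
    with np.load(path, allow_pickle=False) as data:
        _check_version(data, path)
        grid = tuple(int(v) for v in data["grid_dims"])
        mean = LandmarkShape(data["mean"], grid_dims=None if grid[0] < 0 else grid)
        return ShapeModel(mean=mean, modes=data["modes"],
                          eigenvalues=data["eigenvalues"])


def save_surface(path, surface: BSplineSurface) -> None:
    np.savez(
        path,
        version=FORMAT_VERSION,
        control_net=surface.control_net,
        orders=np.array([surface.order_u, surface.order_v]),
        flags=np.array([surface.closed_u, surface.closed_v, surface.pole_caps]),
    )


def load_surface(path) -> BSplineSurface:
    with np.load(path, allow_pickle=False) as data:
        _check_version(data, path)
        ou, ov = (int(v) for v in data["orders"])
        cu, cv, pc = (bool(v) for v in data["flags"])
        return BSplineSurface(data["control_net"], order_u=ou, order_v=ov,
                              closed_u=cu, closed_v=cv, pole_caps=pc)


def save_profiles(path, profiles: ProfileModel) -> None:
    np.savez(
        path,
        version=FORMAT_VERSION,
        mean_profiles=profiles.mean_profiles,
        cov_inv=profiles.cov_inv,
        half_length=np.array(profiles.half_length),
        step=np.array(profiles.step),
    )


def load_profiles(path) -> ProfileModel:
    with np.load(path, allow_pickle=False) as data:
        _check_version(data, path)
        return ProfileModel(
            mean_profiles=data["mean_profiles"],
            cov_inv=data["cov_inv"],
            half_length=int(data["half_length"]),
            step=float(data["step"]),
        )


def save_image(path, image: ImageVolume) -> None:
    """Write NIfTI (.nii / .nii.gz) or raw float32 + JSON header (.raw)."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(image.spacing)
        affine[:3, 3] = image.origin
        nib.save(nib.Nifti1Image(image.intensities.astype(np.float32), affine), str(path))
    elif path.suffix == ".raw":
        image.intensities.astype("<f4").tofile(path)
        header = {
            "version": FORMAT_VERSION,
            "shape": list(image.shape),
            "spacing": list(map(float, image.spacing)),
            "origin": list(map(float, image.origin)),
            "dtype": "float32",
            "byte_order": "little",
            "order": "C",
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r} (use .nii or .raw)")


def load_image(path) -> ImageVolume:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        origin = affine[:3, 3]
        return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)
    if path.suffix == ".raw":
        header = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path, dtype="<f4").reshape(header["shape"])
        return ImageVolume(data.astype(float), np.asarray(header["spacing"]),
                           np.asarray(header["origin"]))
    raise ValueError(f"unsupported image extension {path.suffix!r}")


def export_mesh(path, mesh: TriangleMesh) -> None:
    """ASCII PLY or OBJ export, chosen by extension."""
    path = Path(path)
    tm = mesh.as_trimesh()
    if path.suffix == ".ply":
        data = tm.export(file_type="ply", encoding="ascii")
    elif path.suffix == ".obj":
        data = tm.export(file_type="obj")
    else:
        raise ValueError(f"unsupported mesh extension {path.suffix!r} (use .ply or .obj)")
    if isinstance(data, bytes):
        path.write_bytes(data)
    else:
        path.write_text(data)
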