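"""Synthetic diffusion-tensor phantoms with embedded fiber tubes and lesions.

A phantom is a regular 3-D grid of symmetric diffusion tensors (units mm^2/s)
plus an integer parcellation volume whose nonzero labels mark the end caps of
each fiber tube.  Tubes have hard-edged (binary) cross-sections so that
analytic expectations about FA, MD and tract length are exact.

Coordinate convention (used everywhere in the package): voxel indices are
0-based and half-open; the center of voxel (i, j, k) sits at world position
``affine @ (i + 0.5, j + 0.5, k + 0.5, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TensorVolume",
    "Parcellation",
    "TractSpec",
    "LesionSpec",
    "StraightCenterline",
    "ArcCenterline",
    "make_tensor_phantom",
    "add_lesions",
]


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------

class StraightCenterline:
    """Straight segment from ``start`` to ``end`` (world mm)."""

    def __init__(self, start, end):
        self.start = np.asarray(start, dtype=float)
        self.end = np.asarray(end, dtype=float)
        d = self.end - self.start
        self.length_mm = float(np.linalg.norm(d))
        if self.length_mm <= 0:
            raise ValueError("degenerate segment: start == end")
        self._u = d / self.length_mm

    def point(self, s):
        s = np.asarray(s, dtype=float)
        return self.start + s[..., None] * self._u

    def tangent(self, s):
        s = np.asarray(s, dtype=float)
        return np.broadcast_to(self._u, s.shape + (3,)).copy()

    def nearest(self, points):
        """Arc-length parameter (clamped) and distance for each query point."""
        points = np.atleast_2d(points)
        s = (points - self.start) @ self._u
        s = np.clip(s, 0.0, self.length_mm)
        dist = np.linalg.norm(points - self.point(s), axis=-1)
        return s, dist


class ArcCenterline:
    """Circular arc: ``center + R*(cos(s/R)*u + sin(s/R)*v)`` for s in [0, R*angle].

    ``u`` and ``v`` must be orthonormal; ``angle_rad`` is the subtended angle.
    """

    def __init__(self, center, arc_radius_mm, u, v, angle_rad):
        self.center = np.asarray(center, dtype=float)
        self.R = float(arc_radius_mm)
        self.u = np.asarray(u, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.angle = float(angle_rad)
        if self.R <= 0 or not (0 < self.angle <= 2 * np.pi):
            raise ValueError("need arc_radius_mm > 0 and 0 < angle_rad <= 2*pi")
        for a, b in ((self.u, self.u), (self.v, self.v)):
            if abs(np.dot(a, b) - 1) > 1e-8:
                raise ValueError("u, v must be unit vectors")
        if abs(np.dot(self.u, self.v)) > 1e-8:
            raise ValueError("u, v must be orthogonal")
        self.length_mm = self.R * self.angle

    def point(self, s):
        s = np.asarray(s, dtype=float)
        th = s / self.R
        return (self.center
                + self.R * (np.cos(th)[..., None] * self.u
                            + np.sin(th)[..., None] * self.v))

    def tangent(self, s):
        s = np.asarray(s, dtype=float)
        th = s / self.R
        return -np.sin(th)[..., None] * self.u + np.cos(th)[..., None] * self.v

    def nearest(self, points):
        points = np.atleast_2d(points)
        rel = points - self.center
        x = rel @ self.u
        y = rel @ self.v
        th = np.arctan2(y, x)  # in (-pi, pi]
        # the angle is periodic: clamp both unwrappings into [0, angle] and
        # keep whichever candidate is closer (handles points just past s = 0)
        s_a = np.clip(th, 0.0, self.angle) * self.R
        s_b = np.clip(th + 2 * np.pi, 0.0, self.angle) * self.R
        d_a = np.linalg.norm(points - self.point(s_a), axis=-1)
        d_b = np.linalg.norm(points - self.point(s_b), axis=-1)
        pick_b = d_b < d_a
        return np.where(pick_b, s_b, s_a), np.where(pick_b, d_b, d_a)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class TractSpec:
    """A fiber tube: centerline + radius + axially symmetric diffusivities."""

    centerline: StraightCenterline | ArcCenterline
    radius_mm: float
    eigenvalue_along: float
    eigenvalue_perp: float
    endpoint_region_ids: tuple[int, int]

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if not (self.eigenvalue_along > self.eigenvalue_perp > 0):
            raise ValueError("need eigenvalue_along > eigenvalue_perp > 0")
        a, b = self.endpoint_region_ids
        if a <= 0 or b <= 0:
            raise ValueError("endpoint region ids must be positive")


@dataclass
class LesionSpec:
    """Spherical lesion: MD inflated by ``md_scale``, anisotropy shrunk by ``fa_scale``.

    ``fa_scale`` in (0, 1] multiplies the eigenvalue deviations from their
    mean (1 leaves FA unchanged, values near 0 make the voxel isotropic);
    ``md_scale`` >= 1 multiplies all eigenvalues, inflating MD.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    fa_scale: float = 1.0
    md_scale: float = 1.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if not (0 < self.fa_scale <= 1):
            raise ValueError("fa_scale must be in (0, 1]")
        if self.md_scale < 1:
            raise ValueError("md_scale must be >= 1")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

@dataclass
class TensorVolume:
    """3-D grid of symmetric diffusion tensors (mm^2/s) with voxel geometry."""

    tensors: np.ndarray          # (X, Y, Z, 3, 3)
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray           # 4x4 voxel->world (applied to index + 0.5)
    tube_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (X, Y, Z, 3, 3)")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (X, Y, Z, 3)."""
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in self.shape],
                                   indexing="ij"), axis=-1) + 0.5
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.tensors)

    def fa_map(self) -> np.ndarray:
        lam = self.eigenvalues()
        return _fa_from_eigenvalues(lam)

    def md_map(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=-2, axis2=-1) / 3.0

    # ---- NIfTI I/O ------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        """Lower-triangular 6-component tensor image (xx, xy, yy, xz, yz, zz)."""
        t = self.tensors
        comp = np.stack([t[..., 0, 0], t[..., 0, 1], t[..., 1, 1],
                         t[..., 0, 2], t[..., 1, 2], t[..., 2, 2]], axis=-1)
        return nib.Nifti1Image(comp.astype(np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, voxel_size_mm=None) -> "TensorVolume":
        img = nib.load(str(img_or_path)) if not isinstance(img_or_path, nib.Nifti1Image) else img_or_path
        comp = np.asarray(img.dataobj, dtype=float)
        if comp.ndim != 4 or comp.shape[-1] != 6:
            raise ValueError("expected a 4-D image with 6 tensor components")
        xx, xy, yy, xz, yz, zz = np.moveaxis(comp, -1, 0)
        t = np.empty(comp.shape[:3] + (3, 3))
        t[..., 0, 0] = xx
        t[..., 1, 1] = yy
        t[..., 2, 2] = zz
        t[..., 0, 1] = t[..., 1, 0] = xy
        t[..., 0, 2] = t[..., 2, 0] = xz
        t[..., 1, 2] = t[..., 2, 1] = yz
        if voxel_size_mm is None:
            voxel_size_mm = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(t, voxel_size_mm, img.affine)


@dataclass
class Parcellation:
    """Integer label volume sharing the geometry of its TensorVolume; 0 = background."""

    labels: np.ndarray           # (X, Y, Z) int
    region_ids: list[int]
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(self.region_ids):
            raise ValueError(f"labels {present - set(self.region_ids)} not in region_ids")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.labels.shape

    def label_at_world(self, points: np.ndarray, dilation_voxels: int = 0) -> np.ndarray:
        """Nearest-voxel label lookup for world-mm points; -1 outside the volume.

        With ``dilation_voxels > 0`` a point landing in background takes the
        label of the nearest labelled voxel within that cube radius (a
        robustness option; phantom end caps make it unnecessary by default).
        """
        points = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine)
        idx = points @ inv[:3, :3].T + inv[:3, 3]
        vox = np.floor(idx).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(self.shape)), axis=-1)
        out = np.full(len(points), -1, dtype=int)
        v = vox[inside]
        out[inside] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        if dilation_voxels > 0:
            r = dilation_voxels
            offsets = sorted(
                ((dx, dy, dz) for dx in range(-r, r + 1)
                 for dy in range(-r, r + 1) for dz in range(-r, r + 1)
                 if (dx, dy, dz) != (0, 0, 0)),
                key=lambda o: o[0] ** 2 + o[1] ** 2 + o[2] ** 2)
            shape = np.array(self.shape)
            for i in np.flatnonzero(inside & (out == 0)):
                for off in offsets:
                    nb = vox[i] + off
                    if np.all(nb >= 0) and np.all(nb < shape):
                        lab = self.labels[nb[0], nb[1], nb[2]]
                        if lab > 0:
                            out[i] = lab
                            break
        return out

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int32), self.affine), str(path))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _fa_from_eigenvalues(lam: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||, 0 where the tensor is zero."""
    lam = np.asarray(lam, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def _axisymmetric_tensor(tangents: np.ndarray, lam_along: float, lam_perp: float) -> np.ndarray:
    """D = lam_perp * I + (lam_along - lam_perp) * t t^T for unit tangents (N, 3)."""
    t = tangents / np.linalg.norm(tangents, axis=-1, keepdims=True)
    outer = t[..., :, None] * t[..., None, :]
    return lam_perp * np.eye(3) + (lam_along - lam_perp) * outer


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_tensor_phantom(
    tracts: list[TractSpec],
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float | tuple[float, float, float] = 2.5,
    background_diffusivity: float = 0.8e-3,
    cap_length_mm: float = 5.0,
    n_regions: int = 90,
    blend: str | None = None,
) -> tuple[TensorVolume, Parcellation]:
    """Build a tensor phantom with fiber tubes and an end-cap parcellation.

    Background voxels hold the isotropic tensor ``background_diffusivity * I``
    (FA exactly 0).  Voxels within ``radius_mm`` of a tract centerline hold an
    axially symmetric tensor whose principal eigenvector is the local
    centerline tangent.  The final ``cap_length_mm`` of each tube end is
    labelled with the tract's endpoint region ids; everything else is 0.

    Overlapping tubes whose local tangents disagree by more than 1 degree
    raise an error unless ``blend="average"`` is requested, in which case the
    overlapping tensors are averaged component-wise.
    """
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    shape = tuple(int(n) for n in shape)
    affine = np.diag(list(voxel_size_mm) + [1.0])

    tensors = np.broadcast_to(background_diffusivity * np.eye(3),
                              shape + (3, 3)).copy()
    labels = np.zeros(shape, dtype=np.int32)
    tube_mask = np.zeros(shape, dtype=bool)
    claimed_tangent = np.full(shape + (3,), np.nan)

    centers = (np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                                    indexing="ij"), axis=-1) + 0.5) * np.array(voxel_size_mm)
    flat_centers = centers.reshape(-1, 3)

    region_ids: set[int] = set()
    for tract in tracts:
        cl = tract.centerline
        s, dist = cl.nearest(flat_centers)
        inside = dist <= tract.radius_mm
        if not inside.any():
            raise ValueError("tract tube contains no voxel centers; enlarge radius or volume")
        # bounds check: all in-tube voxels must be strictly inside the grid
        idx = np.flatnonzero(inside)
        tangents = cl.tangent(s[idx])
        new_t = _axisymmetric_tensor(tangents, tract.eigenvalue_along, tract.eigenvalue_perp)

        ijk = np.unravel_index(idx, shape)
        prev = claimed_tangent[ijk]
        overlap = ~np.isnan(prev[:, 0])
        if overlap.any():
            cosang = np.abs(np.sum(prev[overlap] * tangents[overlap], axis=-1))
            if blend is None and np.any(cosang < np.cos(np.deg2rad(1.0))):
                raise ValueError(
                    "overlapping tubes with conflicting tangents; "
                    "pass blend='average' to combine them")
            if blend == "average":
                new_t[overlap] = 0.5 * (new_t[overlap]
                                        + tensors[ijk[0][overlap], ijk[1][overlap], ijk[2][overlap]])
        tensors[ijk] = new_t
        claimed_tangent[ijk] = tangents
        tube_mask[ijk] = True

        # end caps
        lo, hi = tract.endpoint_region_ids
        cap_lo = idx[s[idx] <= cap_length_mm]
        cap_hi = idx[s[idx] >= cl.length_mm - cap_length_mm]
        labels[np.unravel_index(cap_lo, shape)] = lo
        labels[np.unravel_index(cap_hi, shape)] = hi
        region_ids |= {lo, hi}

    volume = TensorVolume(tensors, voxel_size_mm, affine, tube_mask=tube_mask)
    parcellation = Parcellation(labels, sorted(set(range(1, n_regions + 1)) | region_ids), affine)
    return volume, parcellation


def add_lesions(volume: TensorVolume, lesions: list[LesionSpec]) -> TensorVolume:
    """Return a new TensorVolume with spherical lesions applied.

    Inside each sphere the tensor becomes
    ``md_scale * (fa_scale * D + (1 - fa_scale) * MD * I)`` so that MD is
    multiplied by exactly ``md_scale`` and the eigenvalue deviations from
    their mean shrink by ``fa_scale``.  Voxels outside all spheres are
    bit-identical to the input.
    """
    centers = volume.voxel_centers_world().reshape(-1, 3)
    tensors = volume.tensors.copy()
    flat = tensors.reshape(-1, 3, 3)
    extent = np.array(volume.shape) * np.array(volume.voxel_size_mm)
    for lesion in lesions:
        c = np.asarray(lesion.center_mm, dtype=float)
        if np.any(c < 0) or np.any(c > extent):
            raise ValueError(f"lesion center {c} outside volume bounds {extent}")
        inside = np.linalg.norm(centers - c, axis=-1) <= lesion.radius_mm
        d = flat[inside]
        md = np.trace(d, axis1=-2, axis2=-1)[:, None, None] / 3.0
        flat[inside] = lesion.md_scale * (lesion.fa_scale * d
                                          + (1 - lesion.fa_scale) * md * np.eye(3))
    mask = None if volume.tube_mask is None else volume.tube_mask.copy()
    return TensorVolume(flat.reshape(volume.tensors.shape), volume.voxel_size_mm,
                        volume.affine.copy(), tube_mask=mask)


# ---------------------------------------------------------------------------
# JSON phantom specs (CLI support)
# ---------------------------------------------------------------------------

def phantom_from_json(spec: dict | str | Path) -> tuple[TensorVolume, Parcellation]:
    """Build a phantom from a JSON spec (dict, JSON string, or path)."""
    if isinstance(spec, (str, Path)) and Path(str(spec)).exists():
        spec = json.loads(Path(spec).read_text())
    elif isinstance(spec, str):
        spec = json.loads(spec)
    tracts = []
    for t in spec["tracts"]:
        c = t["centerline"]
        if c["type"] == "straight":
            cl = StraightCenterline(c["start"], c["end"])
        elif c["type"] == "arc":
            cl = ArcCenterline(c["center"], c["arc_radius_mm"], c["u"], c["v"],
                               np.deg2rad(c["angle_deg"]))
        else:
            raise ValueError(f"unknown centerline type {c['type']!r}")
        tracts.append(TractSpec(cl, t["radius_mm"], t["eigenvalue_along"],
                                t["eigenvalue_perp"], tuple(t["endpoint_region_ids"])))
    kwargs = {k: spec[k] for k in ("shape", "voxel_size_mm", "background_diffusivity",
                                   "cap_length_mm", "n_regions") if k in spec}
    if "shape" in kwargs:
        kwargs["shape"] = tuple(kwargs["shape"])
    volume, parc = make_tensor_phantom(tracts, **kwargs)
    if spec.get("lesions"):
        volume = add_lesions(volume, [LesionSpec(tuple(l["center_mm"]), l["radius_mm"],
                                                 l.get("fa_scale", 1.0), l.get("md_scale", 1.0))
                                      for l in spec["lesions"]])
    return volume, parc
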