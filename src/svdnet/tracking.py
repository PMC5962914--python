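"""Deterministic tensorline tractography.

Streamlines are integrated with fixed-step Euler steps along the principal
eigenvector of the component-wise trilinearly interpolated diffusion tensor.
Seeding is on a regular super-resolution grid (default 0.5 mm, i.e. 5x5x5
sub-seeds per 2.5 mm voxel) restricted to locations with interpolated
FA >= 0.2.  A branch terminates when interpolated FA drops below the stop
threshold, the turn between consecutive steps exceeds the angle limit, or the
position leaves the volume.  The two branches started in opposite directions
from the seed are concatenated through the seed point.  No randomness is
involved: the same volume and parameters always give the same streamlines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from svdnet.phantom import TensorVolume, _fa_from_eigenvalues

__all__ = [
    "Streamline",
    "StreamlineSet",
    "TrackingParams",
    "SeedRejected",
    "tensor_invariants",
    "track_streamline",
    "whole_volume_tractography",
]

logger = logging.getLogger(__name__)


class SeedRejected(ValueError):
    """Raised when a seed point does not meet the FA seeding threshold."""


@dataclass
class TrackingParams:
    """Tractography parameters (defaults follow the study protocol)."""

    fa_seed_threshold: float = 0.2
    fa_stop_threshold: float = 0.2
    step_mm: float = 0.5
    max_angle_deg: float = 45.0
    min_length_mm: float = 20.0
    max_length_mm: float = 250.0
    seed_grid_mm: float = 0.5
    integrator: str = "euler"  # "euler" (contract default) or "rk2" (midpoint)

    def __post_init__(self):
        vals = (self.fa_seed_threshold, self.fa_stop_threshold, self.step_mm,
                self.max_angle_deg, self.min_length_mm, self.max_length_mm,
                self.seed_grid_mm)
        if any(v <= 0 for v in vals):
            raise ValueError("all tracking parameters must be positive")
        if not self.min_length_mm < self.max_length_mm:
            raise ValueError("min_length_mm must be < max_length_mm")
        if not 0 < self.max_angle_deg <= 90:
            raise ValueError("max_angle_deg must be in (0, 90]")
        if self.integrator not in ("euler", "rk2"):
            raise ValueError("integrator must be 'euler' or 'rk2'")


@dataclass
class Streamline:
    """Ordered polyline in world-mm coordinates."""

    points: np.ndarray  # (M, 3)
    length_mm: float = field(default=None)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must have shape (M, 3)")
        recomputed = float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())
        if self.length_mm is None:
            self.length_mm = recomputed
        elif abs(self.length_mm - recomputed) > 1e-6 * max(1.0, recomputed):
            raise ValueError("stored length_mm disagrees with polyline length")

    def __len__(self):
        return len(self.points)


class StreamlineSet:
    """A collection of streamlines, with TRK/TCK I/O in world-mm coordinates."""

    def __init__(self, streamlines: list[Streamline]):
        self.streamlines = list(streamlines)

    def __len__(self):
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    @property
    def lengths_mm(self) -> np.ndarray:
        return np.array([s.length_mm for s in self.streamlines])

    def filter_length(self, min_length_mm: float, max_length_mm: float) -> "StreamlineSet":
        return StreamlineSet([s for s in self.streamlines
                              if min_length_mm <= s.length_mm <= max_length_mm])

    def save(self, path: str) -> None:
        """Write TRK or TCK (by extension) with an identity voxel-to-world affine,
        so stored coordinates are world mm."""
        path = str(path)
        tractogram = nib.streamlines.Tractogram(
            [s.points for s in self.streamlines], affine_to_rasmm=np.eye(4))
        if path.endswith(".trk"):
            nib.streamlines.save(tractogram, path)
        elif path.endswith(".tck"):
            nib.streamlines.save(tractogram, path)
        else:
            raise ValueError("unsupported streamline format: use .trk or .tck")

    @classmethod
    def load(cls, path: str) -> "StreamlineSet":
        tf = nib.streamlines.load(str(path))
        return cls([Streamline(np.asarray(s)) for s in tf.tractogram.streamlines])


# ---------------------------------------------------------------------------
# tensor invariants
# ---------------------------------------------------------------------------

def tensor_invariants(tensor: np.ndarray) -> tuple[float, float, np.ndarray]:
    """FA, MD and principal axis of one symmetric tensor.

    Raises ``ValueError`` for the zero tensor (FA undefined) and for
    asymmetric or negative-definite input.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-10):
        raise ValueError("tensor must be symmetric 3x3")
    lam, vec = np.linalg.eigh(tensor)
    if lam[0] < -1e-12 * max(1.0, abs(lam[2])):
        raise ValueError("tensor has negative eigenvalues")
    lam = np.clip(lam, 0, None)
    if lam[2] == 0:
        raise ValueError("zero tensor: FA undefined")
    fa = float(_fa_from_eigenvalues(lam))
    md = float(lam.mean())
    axis = vec[:, 2] / np.linalg.norm(vec[:, 2])
    return fa, md, axis


def _batch_invariants(tensors: np.ndarray):
    """Vectorized FA / MD / principal axis for (N, 3, 3) tensors.

    Zero tensors get FA 0 and an arbitrary axis; callers treat FA below the
    stop threshold as termination, so the axis is never used there.
    """
    lam, vec = np.linalg.eigh(tensors)
    lam = np.clip(lam, 0, None)
    fa = _fa_from_eigenvalues(lam)
    md = lam.mean(axis=-1)
    axes = vec[..., 2]
    return fa, md, axes


# ---------------------------------------------------------------------------
# interpolated tensor field
# ---------------------------------------------------------------------------

class _TensorField:
    """Trilinear component-wise interpolation of a TensorVolume."""

    _COMPONENTS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

    def __init__(self, volume: TensorVolume):
        self.volume = volume
        self.inv_affine = np.linalg.inv(volume.affine)
        self.shape = np.array(volume.shape)
        t = volume.tensors
        self.comps = np.stack([t[..., i, j] for i, j in self._COMPONENTS])

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates; voxel centers map to integers + 0.5 - 0.5."""
        return points @ self.inv_affine[:3, :3].T + self.inv_affine[:3, 3]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """(N, 3, 3) interpolated tensors; zero tensor outside the volume."""
        idx = self.world_to_index(np.atleast_2d(points)) - 0.5  # center convention
        coords = idx.T
        vals = np.stack([map_coordinates(c, coords, order=1, mode="constant", cval=0.0)
                         for c in self.comps], axis=-1)
        n = len(idx)
        t = np.empty((n, 3, 3))
        for k, (i, j) in enumerate(self._COMPONENTS):
            t[:, i, j] = vals[:, k]
            t[:, j, i] = vals[:, k]
        return t

    def inside(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(np.atleast_2d(points))
        return np.all((idx >= 0) & (idx <= self.shape), axis=-1)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _integrate_branch(field: _TensorField, seeds: np.ndarray, dirs: np.ndarray,
                      params: TrackingParams) -> list[np.ndarray]:
    """Euler-integrate one branch for a batch of seeds.

    Returns, per seed, the array of points *after* the seed (possibly empty).
    """
    n = len(seeds)
    max_steps = int(np.ceil(params.max_length_mm / params.step_mm)) + 1
    cos_limit = np.cos(np.deg2rad(params.max_angle_deg))

    pos = seeds.copy()
    direction = dirs.copy()
    active = np.ones(n, dtype=bool)
    trail = np.full((n, max_steps, 3), np.nan)
    counts = np.zeros(n, dtype=int)

    for step in range(max_steps):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        if params.integrator == "rk2":
            # midpoint method: step along the principal axis sampled at the
            # half-step position, sign-aligned with the current direction
            mid = pos[ai] + 0.5 * params.step_mm * direction[ai]
            _, _, mid_axes = _batch_invariants(field.interpolate(mid))
            mid_dots = np.sum(mid_axes * direction[ai], axis=-1)
            mid_axes = np.where(mid_dots[:, None] < 0, -mid_axes, mid_axes)
            cand = pos[ai] + params.step_mm * mid_axes
        else:
            cand = pos[ai] + params.step_mm * direction[ai]
        ok_inside = field.inside(cand)
        tensors = field.interpolate(cand)
        fa, _, axes = _batch_invariants(tensors)
        # sign continuity with the previous step direction
        dots = np.sum(axes * direction[ai], axis=-1)
        axes = np.where(dots[:, None] < 0, -axes, axes)
        cos_turn = np.abs(dots)
        ok = ok_inside & (fa >= params.fa_stop_threshold) & (cos_turn >= cos_limit)
        good = ai[ok]
        trail[good, step] = cand[ok]
        counts[good] += 1
        pos[good] = cand[ok]
        direction[good] = axes[ok]
        active[ai[~ok]] = False

    return [trail[i, :counts[i]] for i in range(n)]


def _track_batch(field: _TensorField, seeds: np.ndarray,
                 params: TrackingParams) -> list[Streamline]:
    """Track a batch of eligible seeds bidirectionally; no length filter."""
    tensors = field.interpolate(seeds)
    _, _, axes = _batch_invariants(tensors)
    forward = _integrate_branch(field, seeds, axes, params)
    backward = _integrate_branch(field, seeds, -axes, params)
    out = []
    for i, seed in enumerate(seeds):
        pts = np.vstack([backward[i][::-1], seed[None, :], forward[i]])
        out.append(Streamline(pts))
    return out


def track_streamline(volume: TensorVolume, seed, params: TrackingParams | None = None) -> Streamline:
    """Track a single streamline from ``seed`` (world mm).

    Raises :class:`SeedRejected` if the interpolated FA at the seed is below
    ``params.fa_seed_threshold`` or the seed lies outside the volume.
    """
    params = params or TrackingParams()
    field = _TensorField(volume)
    seed = np.asarray(seed, dtype=float).reshape(1, 3)
    if not field.inside(seed)[0]:
        raise SeedRejected(f"seed {seed[0]} outside volume")
    fa, _, _ = _batch_invariants(field.interpolate(seed))
    if fa[0] < params.fa_seed_threshold:
        raise SeedRejected(
            f"seed FA {fa[0]:.3f} below threshold {params.fa_seed_threshold}")
    return _track_batch(field, seed, params)[0]


def _seed_grid(volume: TensorVolume, params: TrackingParams) -> np.ndarray:
    """Regular super-resolution seed grid in world coordinates."""
    factors = [max(1, int(round(v / params.seed_grid_mm))) for v in volume.voxel_size_mm]
    axes = []
    for n, f in zip(volume.shape, factors):
        axes.append((np.arange(n * f) + 0.5) / f)  # continuous index coords
    idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]


def eligible_seeds(volume: TensorVolume, params: TrackingParams | None = None) -> np.ndarray:
    """World coordinates of all super-resolution grid points with FA >= threshold."""
    params = params or TrackingParams()
    field = _TensorField(volume)
    grid = _seed_grid(volume, params)
    keep = np.zeros(len(grid), dtype=bool)
    for lo in range(0, len(grid), 100_000):
        chunk = grid[lo:lo + 100_000]
        fa, _, _ = _batch_invariants(field.interpolate(chunk))
        keep[lo:lo + 100_000] = fa >= params.fa_seed_threshold
    return grid[keep]


def whole_volume_tractography(volume: TensorVolume,
                              params: TrackingParams | None = None,
                              chunk_size: int = 4096) -> StreamlineSet:
    """Seed every eligible super-resolution grid point and length-filter.

    Deterministic: the result depends only on the volume and parameters.
    """
    params = params or TrackingParams()
    field = _TensorField(volume)
    seeds = eligible_seeds(volume, params)
    if len(seeds) == 0:
        warnings.warn("no eligible seeds (all FA below threshold); empty tractogram")
        return StreamlineSet([])
    streamlines: list[Streamline] = []
    for lo in range(0, len(seeds), chunk_size):
        streamlines.extend(_track_batch(field, seeds[lo:lo + chunk_size], params))
    kept = [s for s in streamlines
            if params.min_length_mm <= s.length_mm <= params.max_length_mm]
    logger.info("tracked %d seeds, kept %d streamlines after length gate",
                len(seeds), len(kept))
    return StreamlineSet(kept)
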