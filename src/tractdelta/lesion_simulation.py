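"""Synthetic phantoms: a tubular fiber bundle in an FA volume, plus small
spherical lesions with a multiplicative FA reduction.

The phantom stands in for repeat scans of a healthy subject: a smooth
centerline is surrounded by jittered fiber copies inside a tube; the FA
volume is a static spatial field (elevated inside the tube, lower outside,
optional per-voxel texture) to which each time-point adds an independent
acquisition-noise draw.  Lesions multiply the FA of every voxel within a
sphere by a reduction coefficient alpha (alpha = 1: no change; alpha = 0:
total loss); the construction order is field -> noise -> lesion, so the
ratio of post- to pre-lesion FA inside the sphere is exactly alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .bundle_io import RawBundle, ScalarVolume

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "ValidationCase",
    "generate_phantom",
    "make_followup",
    "insert_lesions",
    "build_validation_set",
]


@dataclass(frozen=True)
class LesionSpec:
    """A spherical FA reduction: voxels within ``radius`` (voxel units,
    inclusive, voxel-center distance) of ``center`` are multiplied by
    ``alpha``."""

    center: tuple[int, int, int]
    radius: float = 2.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise of the synthetic bundle phantom.

    Defaults mimic a 2 mm isotropic acquisition with a ~100 mm arched
    bundle: FA 0.55 +/- 0.05 inside the bundle against a 0.30 +/- 0.05
    background, and 0.02 acquisition noise per time-point.  ``tube_radius``
    is the radius of the fiber-occupied tube (5.5 mm, in the range of major
    projection/association tracts and wider than the default 2-voxel lesion
    radius, so a single lesion never spans a whole cross-section); FA is
    elevated out to ``tube_radius + fa_halo`` so that nearest-voxel lookup
    from any fiber point (up to half a voxel diagonal away) always lands on
    bundle-level FA.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    voxel_size: float = 2.0
    n_fibers: int = 100
    tube_radius: float = 5.5           # mm, radius of the fiber-occupied tube
    fa_halo: float = 2.0               # mm, partial-volume rim of bundle FA
    bundle_fa: float = 0.55
    bundle_fa_sd: float = 0.05
    background_fa: float = 0.30
    background_fa_sd: float = 0.05
    noise_sd: float = 0.02
    points_per_fiber: int = 60
    arc_height: float = 20.0           # mm, bow of the quadratic centerline
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass
class ValidationCase:
    """One simulated follow-up: baseline W1, lesioned follow-up W2, the
    planted lesion, its voxel mask and the bundle geometry."""

    w1: ScalarVolume
    w2: ScalarVolume
    lesion: LesionSpec
    mask: np.ndarray
    bundle: RawBundle


def _centerline(spec: PhantomSpec, n_samples: int = 500) -> np.ndarray:
    """Quadratic-arc centerline in world mm, margin-safe inside the grid."""
    extent = (np.array(spec.shape) - 1) * spec.voxel_size
    margin = spec.tube_radius + spec.fa_halo + 2 * spec.voxel_size
    t = np.linspace(0.0, 1.0, n_samples)
    x = margin + (extent[0] - 2 * margin) * t
    y0 = extent[1] * 0.38
    y = y0 + spec.arc_height * 4 * t * (1 - t)
    z = np.full_like(t, extent[2] / 2)
    line = np.column_stack([x, y, z])
    if ((line < margin - spec.tube_radius).any()
            or (line > extent - (margin - spec.tube_radius)).any()):
        raise ValueError("tube exits the volume; enlarge the grid or shrink "
                         "the tube")
    return line


def generate_phantom(spec: PhantomSpec) -> tuple[RawBundle, ScalarVolume]:
    """Build the bundle and the baseline (W1) FA volume.

    Fibers are jittered copies of the centerline: each fiber carries a
    constant random offset inside a disc of radius ``tube_radius - 0.5`` mm
    plus small per-point jitter (clamped to 0.5 mm), so every fiber point
    stays within ``tube_radius`` of the centerline.  The W1 volume is the
    static noise-free field plus one acquisition-noise draw; the field, the
    bundle-FA mask (``tube_mask``) and the fiber-occupied core mask
    (``core_mask``, the admissible lesion sites) ride along in ``meta`` for
    follow-up construction.
    """
    rng = np.random.default_rng(spec.seed)
    line = _centerline(spec)

    # fibers: constant in-disc offset (y-z plane) + clamped per-point jitter
    n_pts = spec.points_per_fiber
    idx = np.linspace(0, len(line) - 1, n_pts).round().astype(int)
    base = line[idx]
    r_off = max(spec.tube_radius - 0.5, 0.0)
    theta = rng.uniform(0, 2 * np.pi, spec.n_fibers)
    rho = r_off * np.sqrt(rng.uniform(0, 1, spec.n_fibers))
    offsets = np.zeros((spec.n_fibers, 3))
    offsets[:, 1] = rho * np.cos(theta)
    offsets[:, 2] = rho * np.sin(theta)
    # smooth per-point wobble: iid noise low-passed along the fiber so the
    # polyline stays streamline-like (no corner-cutting on resampling)
    raw = rng.normal(0.0, 0.4, size=(spec.n_fibers, n_pts + 8, 3))
    kernel = np.ones(9) / 9.0
    jitter = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), 1, raw)
    jitter = np.clip(jitter, -0.5, 0.5)
    fibers = base[None, :, :] + offsets[:, None, :] + jitter
    bundle = RawBundle(fibers=list(fibers))

    # static FA field: background / tube contrast with optional texture
    grid_idx = np.indices(spec.shape).reshape(3, -1).T
    centers = grid_idx * spec.voxel_size
    tree = cKDTree(line)
    dist, _ = tree.query(centers, workers=-1)
    tube_mask = (dist <= spec.tube_radius + spec.fa_halo).reshape(spec.shape)
    core_mask = (dist <= spec.tube_radius).reshape(spec.shape)
    field = rng.normal(spec.background_fa, spec.background_fa_sd,
                       size=spec.shape) if spec.background_fa_sd > 0 else \
        np.full(spec.shape, spec.background_fa)
    tube_vals = (rng.normal(spec.bundle_fa, spec.bundle_fa_sd,
                            size=int(tube_mask.sum()))
                 if spec.bundle_fa_sd > 0
                 else np.full(int(tube_mask.sum()), spec.bundle_fa))
    field[tube_mask] = tube_vals
    field = np.clip(field, 0.0, 1.0)

    w1_data = field + (rng.normal(0.0, spec.noise_sd, size=spec.shape)
                       if spec.noise_sd > 0 else 0.0)
    w1 = ScalarVolume(data=np.clip(w1_data, 0.0, 1.0), affine=spec.affine)
    w1.meta.update(noise_free=field, tube_mask=tube_mask,
                   core_mask=core_mask, centerline=line, spec=spec)
    return bundle, w1


def make_followup(volume_w1: ScalarVolume, noise_sd: float,
                  seed: int) -> ScalarVolume:
    """Fresh acquisition of the same subject: noise-free field + new noise.

    Never reuses W1's noise realization; requires the noise-free field kept
    in ``volume_w1.meta`` by :func:`generate_phantom`.
    """
    if "noise_free" not in volume_w1.meta:
        raise ValueError("volume has no noise-free field; it was not built "
                         "by generate_phantom")
    field = volume_w1.meta["noise_free"]
    rng = np.random.default_rng(seed)
    data = field + (rng.normal(0.0, noise_sd, size=field.shape)
                    if noise_sd > 0 else 0.0)
    w2 = ScalarVolume(data=np.clip(data, 0.0, 1.0),
                      affine=volume_w1.affine.copy())
    w2.meta.update({k: v for k, v in volume_w1.meta.items()})
    return w2


def _sphere_voxels(center: Sequence[int], radius: float,
                   shape: Sequence[int]) -> np.ndarray:
    """Integer voxel indices with center distance <= radius (inclusive)."""
    c = np.asarray(center)
    r = int(np.ceil(radius))
    lo = c - r
    hi = c + r
    if (lo < 0).any() or (hi >= np.asarray(shape)).any():
        raise ValueError(f"sphere at {tuple(c)} radius {radius} exceeds "
                         f"volume bounds {tuple(shape)}")
    offs = np.indices((2 * r + 1,) * 3).reshape(3, -1).T - r
    keep = (offs ** 2).sum(axis=1) <= radius ** 2 + 1e-12
    return c + offs[keep]


def insert_lesions(volume: ScalarVolume, lesions: Sequence[LesionSpec]
                   ) -> tuple[ScalarVolume, np.ndarray]:
    """Apply multiplicative spherical lesions; returns (volume, label mask).

    The mask labels each lesion's voxels with its 1-based index.  Voxels
    outside every sphere are bit-preserved.  Overlapping or out-of-bounds
    spheres raise.
    """
    for a, la in enumerate(lesions):
        for lb in lesions[a + 1:]:
            d = np.linalg.norm(np.asarray(la.center, float)
                               - np.asarray(lb.center, float))
            if d <= la.radius + lb.radius:
                raise ValueError(f"lesions at {la.center} and {lb.center} "
                                 "overlap")
    data = volume.data.copy()
    mask = np.zeros(volume.shape, dtype=np.int32)
    for lid, lesion in enumerate(lesions, start=1):
        vox = _sphere_voxels(lesion.center, lesion.radius, volume.shape)
        data[vox[:, 0], vox[:, 1], vox[:, 2]] *= lesion.alpha
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = lid
    out = ScalarVolume(data=data, affine=volume.affine.copy())
    out.meta.update({k: v for k, v in volume.meta.items()})
    return out, mask


def build_validation_set(n_lesions: int, alphas: Sequence[float],
                         spec: PhantomSpec, seed: int,
                         radius: float = 2.0,
                         max_attempts: int = 20000
                         ) -> list[ValidationCase]:
    """Simulate ``n_lesions`` follow-up pairs, one planted lesion each.

    Lesion centers are sampled uniformly from in-tube voxels, pairwise at
    least ``2 * radius`` apart, at least ``radius`` (in voxels, converted to
    mm) from the tube ends, with the sphere fully inside the grid.  The
    alpha values are assigned in balanced proportions (counts differ by at
    most one).  Every follow-up volume carries an independent noise draw.
    """
    rng = np.random.default_rng(seed)
    bundle, w1 = generate_phantom(spec)
    core_mask = w1.meta["core_mask"]
    line = w1.meta["centerline"]

    candidates = np.argwhere(core_mask)
    centers_mm = candidates * spec.voxel_size
    end_clear = radius * spec.voxel_size
    d_start = np.linalg.norm(centers_mm - line[0], axis=1)
    d_end = np.linalg.norm(centers_mm - line[-1], axis=1)
    r_ceil = int(np.ceil(radius))
    in_bounds = ((candidates - r_ceil >= 0).all(axis=1)
                 & (candidates + r_ceil < np.asarray(spec.shape)).all(axis=1))
    candidates = candidates[(d_start > end_clear) & (d_end > end_clear)
                            & in_bounds]
    if len(candidates) == 0:
        raise ValueError("no admissible lesion centers inside the tube")

    order = rng.permutation(len(candidates))
    accepted: list[np.ndarray] = []
    attempts = 0
    for i in order:
        attempts += 1
        if attempts > max_attempts:
            break
        c = candidates[i]
        if all(np.linalg.norm((c - a).astype(float)) > 2 * radius
               for a in accepted):
            accepted.append(c)
        if len(accepted) == n_lesions:
            break
    if len(accepted) < n_lesions:
        raise ValueError(
            f"could not place {n_lesions} non-overlapping lesions "
            f"(placed {len(accepted)}); shrink n_lesions or enlarge the tube")

    reps = int(np.ceil(n_lesions / len(alphas)))
    alpha_assign = np.tile(np.asarray(alphas, dtype=float), reps)[:n_lesions]
    rng.shuffle(alpha_assign)

    cases: list[ValidationCase] = []
    for k, (center, alpha) in enumerate(zip(accepted, alpha_assign)):
        lesion = LesionSpec(center=tuple(int(v) for v in center),
                            radius=radius, alpha=float(alpha))
        w2 = make_followup(w1, spec.noise_sd,
                           seed=int(rng.integers(0, 2**31 - 1)))
        w2_lesioned, mask = insert_lesions(w2, [lesion])
        cases.append(ValidationCase(w1=w1, w2=w2_lesioned, lesion=lesion,
                                    mask=mask, bundle=bundle))
    return cases
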