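"""Synthetic porous carbonate-block phantoms with exact ground truth.

A phantom emulates a scanned coral-skeleton block: a porous cuboid of
bright (CaCO3-like) voxels inside dark air, to which known bioerosion
(capsule-shaped borings and shallow grazing scars) and known secondary
accretion (surface crust patches) are applied.  The "post-deployment scan"
is rendered under a known rigid misalignment with additive Gaussian noise,
so every downstream stage — thresholding, registration, differencing,
rate conversion — can be checked against exact truth.

Porosity is produced by thresholding a Gaussian-smoothed white-noise field
at the quantile matching the target solid fraction; this is a texture
proxy, not a model of real coral microstructure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from coralct.registration import RigidTransform, resample
from coralct.volume_io import BinaryVolume, VolumeGrid

__all__ = [
    "ErosionSpec",
    "AccretionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_block",
    "apply_bioerosion",
    "apply_accretion",
    "render_post_scan",
    "make_phantom_pair",
]


@dataclass
class ErosionSpec:
    """Borings (capsules from the surface inward) and grazing scars."""

    n_tunnels: int = 6
    radius_range: tuple = (2.0, 3.0)      # voxels
    length_range: tuple = (15.0, 30.0)    # voxels
    n_graze_patches: int = 2
    patch_depth: float = 2.0              # voxels
    patch_radius: float = 10.0            # voxels


@dataclass
class AccretionSpec:
    """Crust patches grown on the solid surface by constrained dilation."""

    n_patches: int = 3
    thickness_range: tuple = (1, 2)       # voxels (integer dilation steps)
    patch_radius: float = 14.0            # voxels


@dataclass
class PhantomSpec:
    """Full description of a synthetic pre/post scan pair.

    Defaults mirror a desk-scale version of the reference protocol: a
    porous block in an air margin, ~2% of solid removed by borings and
    grazing, ~1% added as crusts, a modest rigid misalignment between
    scans, and noise at 5% of the solid-air contrast.
    """

    dims: tuple = (64, 128, 128)          # (nz, ny, nx)
    voxel_edge: float = 100.0             # um
    solid_fraction: float = 0.5
    correlation_length: float = 300.0     # um
    margin: int = 16                      # air margin: must absorb the misalignment sweep
    # the 200-unit global threshold sits at half this contrast, making the
    # binarization the median-unbiased voxelization after interpolation
    intensity_solid: float = 400.0
    intensity_air: float = 0.0
    noise_sd: float = 20.0                # 5% of the 400-unit contrast
    erosion: ErosionSpec = field(default_factory=ErosionSpec)
    accretion: AccretionSpec = field(default_factory=AccretionSpec)
    transform_truth: RigidTransform | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.solid_fraction <= 1.0:
            raise ValueError("solid_fraction must be in (0, 1]")
        if any(d - 2 * self.margin < 4 for d in self.dims):
            raise ValueError(f"dims {self.dims} leave no room for margin {self.margin}")


@dataclass
class PhantomTruth:
    """Exact ground truth for one phantom pair (all masks in the pre frame)."""

    pre_mask: BinaryVolume
    post_mask: BinaryVolume
    eroded_mask: BinaryVolume
    accreted_mask: BinaryVolume
    transform_truth: RigidTransform

    @property
    def vol_eroded_m3(self) -> float:
        return self.eroded_mask.count() * (self.eroded_mask.voxel_edge * 1e-6) ** 3

    @property
    def vol_accreted_m3(self) -> float:
        return self.accreted_mask.count() * (self.accreted_mask.voxel_edge * 1e-6) ** 3


def _block_slices(spec: PhantomSpec) -> tuple:
    return tuple(slice(spec.margin, d - spec.margin) for d in spec.dims)


def generate_block(spec: PhantomSpec, rng: np.random.Generator | None = None):
    """Generate the pre-deployment scan and its exact solid mask.

    Returns ``(VolumeGrid, BinaryVolume)``.  The solid fraction inside the
    block extent matches the target by construction (quantile threshold of
    a smoothed random field).
    """
    rng = rng or np.random.default_rng(spec.seed)
    mask = np.zeros(spec.dims, dtype=bool)
    sl = _block_slices(spec)
    extent = tuple(s.stop - s.start for s in sl)
    if spec.solid_fraction >= 1.0:
        mask[sl] = True
    else:
        sigma_vox = spec.correlation_length / spec.voxel_edge
        fld = rng.standard_normal(extent)
        if sigma_vox > 0:
            fld = ndimage.gaussian_filter(fld, sigma_vox)
        thr = np.quantile(fld, 1.0 - spec.solid_fraction)
        mask[sl] = fld >= thr
    vol = _render_intensity(mask, spec, rng)
    return vol, BinaryVolume(mask, spec.voxel_edge)


def _render_intensity(mask: np.ndarray, spec: PhantomSpec,
                      rng: np.random.Generator) -> VolumeGrid:
    data = np.where(mask, spec.intensity_solid, spec.intensity_air).astype(float)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=mask.shape)
    return VolumeGrid(data, spec.voxel_edge)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Solid voxels face-adjacent to air (outer solid shell)."""
    interior = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1),
                                      border_value=0)
    return mask & ~interior


def _envelope(mask: np.ndarray, closing_radius: int = 4) -> np.ndarray:
    """The block's outer envelope: morphological closing that seals pores.

    For a solid cuboid this is the cuboid itself.  It distinguishes the
    outer block surface (where organisms act) from interior pore walls.
    """
    struct = ndimage.generate_binary_structure(3, 3)
    return ndimage.binary_closing(mask, struct, iterations=closing_radius)


def _ball_dist(shape, center) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    c = np.asarray(center, dtype=float)
    return np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)


def _capsule_mask(shape, start, direction, length, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment start -> start + length*direction."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1) - np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    proj = np.clip(p @ d, 0.0, length)
    closest = proj[..., None] * d
    return np.linalg.norm(p - closest, axis=-1) <= radius


def apply_bioerosion(mask: BinaryVolume, spec: ErosionSpec,
                     rng: np.random.Generator):
    """Carve borings and grazing scars; returns ``(new_mask, eroded_mask)``.

    Borings are capsules starting on the solid surface and pointing inward
    (towards the block's centre of mass, jittered); grazing scars are
    spherical caps removing a shallow shell around a surface point.  Only
    solid voxels flip, so ``eroded`` is always a subset of the input mask.
    """
    m = mask.mask.copy()
    eroded = np.zeros_like(m)
    if (spec.n_tunnels == 0 and spec.n_graze_patches == 0) or not m.any():
        return BinaryVolume(m, mask.voxel_edge), BinaryVolume(eroded, mask.voxel_edge)
    env = _envelope(mask.mask)
    outer_surf = np.argwhere(_surface_voxels(env) & mask.mask)
    if len(outer_surf) == 0:
        outer_surf = np.argwhere(_surface_voxels(mask.mask))
    com = np.argwhere(m).mean(axis=0)
    for _ in range(spec.n_tunnels):
        start = outer_surf[rng.integers(len(outer_surf))]
        direction = com - start + rng.normal(0.0, 2.0, size=3)
        if np.linalg.norm(direction) < 1e-9:
            direction = rng.standard_normal(3)
        radius = rng.uniform(*spec.radius_range)
        length = rng.uniform(*spec.length_range)
        cap = _capsule_mask(m.shape, start, direction, length, radius)
        eroded |= cap & m
        m &= ~cap
    depth = max(1, int(round(spec.patch_depth)))
    env_core = ndimage.binary_erosion(env, ndimage.generate_binary_structure(3, 1),
                                      iterations=depth, border_value=0)
    for _ in range(spec.n_graze_patches):
        center = outer_surf[rng.integers(len(outer_surf))]
        # shallow spherical-cap scar: solid within patch_depth of the
        # envelope surface, limited to a ball around the chosen point
        bite = m & ~env_core & (_ball_dist(m.shape, center) <= spec.patch_radius)
        eroded |= bite
        m &= ~bite
    return BinaryVolume(m, mask.voxel_edge), BinaryVolume(eroded, mask.voxel_edge)


def apply_accretion(mask: BinaryVolume, spec: AccretionSpec,
                    rng: np.random.Generator):
    """Grow crust patches on the surface; returns ``(new_mask, accreted_mask)``.

    Each patch is a constrained dilation: air voxels within ``thickness``
    dilation steps (26-connected structuring element) of the solid, limited
    to a ball around a random surface point.  Accreted voxels are air
    before and solid after, all 26-connected to the pre-existing surface.
    """
    m = mask.mask.copy()
    accreted = np.zeros_like(m)
    if spec.n_patches == 0 or not m.any():
        return BinaryVolume(m, mask.voxel_edge), BinaryVolume(accreted, mask.voxel_edge)
    struct = ndimage.generate_binary_structure(3, 3)  # 26-connectivity
    env = _envelope(mask.mask)
    outer_air = ~env  # crusts grow on the outer surface, not into pores
    outer_surf = np.argwhere(_surface_voxels(env) & mask.mask)
    if len(outer_surf) == 0:
        outer_surf = np.argwhere(_surface_voxels(mask.mask))
    lo, hi = spec.thickness_range
    grown_by = {th: ndimage.binary_dilation(mask.mask, struct, iterations=th)
                for th in range(int(lo), int(hi) + 1)}
    for _ in range(spec.n_patches):
        center = outer_surf[rng.integers(len(outer_surf))]
        thickness = int(rng.integers(lo, hi + 1))
        new = grown_by[thickness] & ~mask.mask & outer_air
        patch = new & (_ball_dist(m.shape, center) <= spec.patch_radius)
        accreted |= patch
        m |= patch
    return BinaryVolume(m, mask.voxel_edge), BinaryVolume(accreted, mask.voxel_edge)


def full_crust(mask: BinaryVolume, thickness: int = 1):
    """Grow a uniform crust over the whole surface (26-connected dilation)."""
    struct = ndimage.generate_binary_structure(3, 3)
    grown = ndimage.binary_dilation(mask.mask, struct, iterations=thickness)
    accreted = grown & ~mask.mask
    return BinaryVolume(grown, mask.voxel_edge), BinaryVolume(accreted, mask.voxel_edge)


def render_post_scan(post_mask: BinaryVolume, truth: RigidTransform,
                     intensity_solid: float, intensity_air: float,
                     noise_sd: float, rng: np.random.Generator) -> VolumeGrid:
    """Render the misaligned, noisy post-deployment scan.

    ``truth`` maps pre-frame points to post-scan points, so the scan is the
    mask resampled under the *inverse* transform; registering the result
    back onto the pre scan should recover ``truth``.  Linear interpolation
    is used at resampling; an identity transform with zero noise therefore
    reproduces a binarizable image exactly.

    Raises if the transform clips the block at the grid boundary.
    """
    ideal = VolumeGrid(
        np.where(post_mask.mask, float(intensity_solid), float(intensity_air)),
        post_mask.voxel_edge)
    ideal_t = replace_center(truth, ideal.center_um())
    scan = resample(ideal, ideal_t.inverse(), interpolation="linear",
                    cval=float(intensity_air))
    mid = (intensity_solid + intensity_air) / 2.0
    shell = np.zeros(scan.shape, dtype=bool)
    shell[[0, -1], :, :] = shell[:, [0, -1], :] = shell[:, :, [0, -1]] = True
    if (scan.data[shell] >= mid).any():
        raise ValueError("transform clips the block at the grid boundary")
    if noise_sd > 0:
        scan = VolumeGrid(scan.data + rng.normal(0.0, noise_sd, size=scan.shape),
                          scan.voxel_edge)
    return scan


def replace_center(t: RigidTransform, center_um) -> RigidTransform:
    """Re-express a rigid transform about a different rotation centre."""
    c_new = np.asarray(center_um, dtype=float)
    R = t.matrix
    # y = R(x - c) + c + t  ==  R(x - c') + c' + t'  with
    # t' = R(c' - c) + c + t - c'
    t_new = R @ (c_new - t.center) + t.center + t.translation - c_new
    return RigidTransform(c_new, t.euler_zyx_deg, t_new)


def make_phantom_pair(spec: PhantomSpec):
    """Generate a full pre/post scan pair with truth.

    Returns ``(pre_scan, post_scan, truth)`` where both scans are intensity
    volumes at ``spec.voxel_edge`` and ``truth`` is a :class:`PhantomTruth`
    whose masks live in the pre frame.  A single seeded RNG drives every
    stage in fixed order, so identical specs give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    pre_scan, pre_mask = generate_block(spec, rng)
    m1, _ = apply_bioerosion(pre_mask, spec.erosion, rng)
    post_mask, _ = apply_accretion(m1, spec.accretion, rng)
    # net truth masks: exactly what differencing of the aligned pair sees
    eroded = BinaryVolume(pre_mask.mask & ~post_mask.mask, spec.voxel_edge)
    accreted = BinaryVolume(post_mask.mask & ~pre_mask.mask, spec.voxel_edge)
    t = spec.transform_truth or RigidTransform.identity(pre_scan.center_um())
    t = replace_center(t, pre_scan.center_um())
    post_scan = render_post_scan(post_mask, t, spec.intensity_solid,
                                 spec.intensity_air, spec.noise_sd, rng)
    truth = PhantomTruth(pre_mask, post_mask, eroded, accreted, t)
    return pre_scan, post_scan, truth
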