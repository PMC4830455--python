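"""Rigid registration of the post-deployment scan onto the pre-deployment scan.

The similarity metric is mutual information of the joint intensity histogram
(Mattes-style fixed binning over each image's range, linear interpolation of
the moving image) and the optimizer is a (1+1) evolution strategy: a single
parent parameter vector is perturbed isotropically; improving offspring are
accepted and grow the search radius, failures shrink it.  Optimization runs
coarse-to-fine over a mean-downsampling pyramid, each level seeded with the
previous solution.

Conventions
-----------
Grids are indexed (z, y, x); the transform maps *fixed-frame* physical
points to *moving-frame* points:

    y = R (x - c) + c + t

with ``R`` the Euler z-y-x rotation (degrees), ``c`` the rotation centre
(default: the fixed volume's geometric centre) and ``t`` a translation in
micrometres.  Resampling evaluates the moving image at ``y``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from coralct.preprocess import downsample_mean
from coralct.volume_io import VolumeGrid

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "RegistrationResult",
    "mattes_mi",
    "register",
    "resample",
]


def _rot_matrix(euler_zyx_deg) -> np.ndarray:
    """Rotation matrix acting on (z, y, x) coordinate vectors, R = Rz @ Ry @ Rx.

    "Rotation about x" rotates the (z, y) plane, etc.; angles in degrees.
    """
    a, b, g = np.deg2rad(np.asarray(euler_zyx_deg, dtype=float))
    ca, sa, cb, sb, cg, sg = np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(g), np.sin(g)
    rx = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])
    rz = np.array([[1.0, 0.0, 0.0], [0.0, ca, -sa], [0.0, sa, ca]])
    return rz @ ry @ rx


def _euler_from_matrix(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_rot_matrix` (z-y-x order, degrees)."""
    b = np.arcsin(np.clip(R[0, 2], -1.0, 1.0))
    a = np.arctan2(-R[1, 2], R[2, 2])
    g = np.arctan2(-R[0, 1], R[0, 0])
    return np.rad2deg(np.array([a, b, g]))


@dataclass
class RigidTransform:
    """6-parameter rigid transform: Euler z-y-x rotation about ``center`` plus translation.

    ``center`` and ``translation`` are (z, y, x) vectors in micrometres.
    """

    center: np.ndarray
    euler_zyx_deg: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.euler_zyx_deg = np.asarray(self.euler_zyx_deg, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        for v in (self.center, self.euler_zyx_deg, self.translation):
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError("transform parameters must be finite 3-vectors")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.asarray(center, float), np.zeros(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        return _rot_matrix(self.euler_zyx_deg)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Map fixed-frame physical points (..., 3) to moving-frame points."""
        p = np.asarray(points_um, dtype=float)
        return (p - self.center) @ self.matrix.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        R = self.matrix
        return RigidTransform(self.center, _euler_from_matrix(R.T), -R.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``.

        Both must share a centre; the composition keeps it.
        """
        if not np.allclose(self.center, other.center):
            raise ValueError("can only compose transforms about the same centre")
        R = self.matrix @ other.matrix
        t = self.matrix @ other.translation + self.translation
        return RigidTransform(self.center, _euler_from_matrix(R), t)

    def to_dict(self) -> dict:
        return {
            "center_um": self.center.tolist(),
            "euler_zyx_deg": self.euler_zyx_deg.tolist(),
            "translation_um": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["center_um"]), np.asarray(d["euler_zyx_deg"]),
                   np.asarray(d["translation_um"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class OptimizerConfig:
    """(1+1) evolution strategy settings (per pyramid level)."""

    initial_radius: float = 6.25e-3
    epsilon: float = 1.5e-6
    growth_factor: float = 1.05
    shrink_factor: float = 0.98
    max_iterations: int = 200


@dataclass
class RegistrationConfig:
    metric_bins: int = 50
    sampling_fraction: float = 1.0
    pyramid_levels: int = 3          # downsample x4, x2, x1
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    seed: int = 42
    center_of_mass_init: bool = False
    # deterministic local polish (Powell) of the metric after the
    # evolutionary search at the finest level; off to mimic the bare ES
    refine: bool = True
    refine_maxfev: int = 150
    # Gaussian pre-smoothing (voxels) of both volumes for the metric only;
    # suppresses the interpolation artifact that biases MI toward
    # fractional-voxel offsets on noisy images
    metric_smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.metric_bins < 8:
            raise ValueError("metric_bins must be >= 8")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in (0, 1]")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    final_metric: float
    iterations_used: list
    converged: bool


def resample(moving: VolumeGrid, t: RigidTransform, interpolation: str = "linear",
             out_shape: tuple | None = None, cval: float = 0.0) -> VolumeGrid:
    """Map the moving volume into the fixed frame under ``t``.

    Output voxel at fixed-frame physical point x takes the moving image's
    value at ``t(x)``; out-of-field voxels are filled with ``cval`` (air).
    """
    order = {"linear": 1, "nearest": 0}[interpolation]
    shape = out_shape or moving.shape
    edge = moving.voxel_edge
    R = t.matrix
    c_vox = t.center / edge
    t_vox = t.translation / edge
    offset = c_vox + t_vox - R @ c_vox
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float), R, offset=offset,
        output_shape=shape, order=order, mode="constant", cval=cval)
    return VolumeGrid(out, edge, moving.intensity_units)


def _mi_from_joint(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _joint_hist(fixed: np.ndarray, moved: np.ndarray, inside: np.ndarray,
                bins: int, f_range, m_range) -> np.ndarray:
    f = fixed[inside]
    m = moved[inside]
    joint, _, _ = np.histogram2d(f, m, bins=bins, range=[f_range, m_range])
    return joint


def mattes_mi(fixed: VolumeGrid, moving: VolumeGrid, t: RigidTransform,
              cfg: RegistrationConfig | None = None) -> float:
    """Mutual information (nats) of the joint intensity histogram under ``t``.

    The moving image is resampled into the fixed frame with linear
    interpolation; intensities are binned linearly over each image's own
    range.  Higher values indicate better alignment.
    """
    cfg = cfg or RegistrationConfig()
    moved, inside = _resample_with_mask(fixed, moving, t)
    if not inside.any():
        raise ValueError("fixed and moving volumes do not overlap under the transform")
    rng = np.random.default_rng(cfg.seed)
    return _mi_value(fixed, moved, inside, cfg, rng)


def _resample_with_mask(fixed: VolumeGrid, moving: VolumeGrid, t: RigidTransform):
    """Resample moving onto the fixed grid; also return the in-field mask."""
    edge = fixed.voxel_edge
    R = t.matrix
    c_vox = t.center / edge
    offset = c_vox + t.translation / edge - R @ c_vox
    data = np.asarray(moving.data, dtype=float)
    moved = ndimage.affine_transform(data, R, offset=offset, output_shape=fixed.shape,
                                     order=1, mode="constant", cval=np.nan)
    inside = ~np.isnan(moved)
    moved[~inside] = 0.0
    return VolumeGrid(moved, edge), inside


def _mi_value(fixed: VolumeGrid, moved: VolumeGrid, inside: np.ndarray,
              cfg: RegistrationConfig, rng) -> float:
    f = np.asarray(fixed.data, dtype=float)
    m = moved.data
    f_range = (float(f.min()), float(f.max()))
    m_range = (float(m[inside].min()), float(m[inside].max()))
    if f_range[0] == f_range[1] or m_range[0] == m_range[1]:
        return 0.0  # a constant marginal carries no information
    sel = inside
    if cfg.sampling_fraction < 1.0:
        keep = rng.random(sel.shape) < cfg.sampling_fraction
        sel = sel & keep
        if not sel.any():
            sel = inside
    joint = _joint_hist(f, m, sel, cfg.metric_bins, f_range, m_range)
    return _mi_from_joint(joint)


def _center_of_mass_um(vol: VolumeGrid) -> np.ndarray:
    w = np.asarray(vol.data, dtype=float)
    w = w - w.min()
    com = np.asarray(ndimage.center_of_mass(w))
    return com * vol.voxel_edge


def register(fixed: VolumeGrid, moving: VolumeGrid,
             cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Runs the (1+1) evolution strategy on the 6 transform parameters,
    coarse-to-fine over a block-averaging pyramid.  Rotation (degrees) and
    translation (micrometres) are balanced by a scale vector equating 1 deg
    with the arc it sweeps at the block's half-diagonal.
    """
    cfg = cfg or RegistrationConfig()
    if abs(fixed.voxel_edge - moving.voxel_edge) > 1e-9 * fixed.voxel_edge:
        raise ValueError("fixed and moving volumes must share voxel_edge")
    rng = np.random.default_rng(cfg.seed)

    center = fixed.center_um()
    half_diag_um = float(np.linalg.norm(np.asarray(fixed.shape) * fixed.voxel_edge)) / 2.0
    # normalized parameter space: 1 unit of angle = 1 radian; 1 unit of
    # translation = the half-diagonal => comparable physical displacement
    scale = np.array([np.rad2deg(1.0)] * 3 + [half_diag_um] * 3)

    params = np.zeros(6)
    if cfg.center_of_mass_init:
        shift = _center_of_mass_um(moving) - _center_of_mass_um(fixed)
        params[3:] = shift / half_diag_um

    fixed = VolumeGrid(np.asarray(fixed.data, dtype=float), fixed.voxel_edge)
    moving = VolumeGrid(np.asarray(moving.data, dtype=float), moving.voxel_edge)
    if cfg.metric_smoothing_sigma > 0:
        fixed = VolumeGrid(ndimage.gaussian_filter(fixed.data, cfg.metric_smoothing_sigma),
                           fixed.voxel_edge)
        moving = VolumeGrid(ndimage.gaussian_filter(moving.data, cfg.metric_smoothing_sigma),
                            moving.voxel_edge)
    factors = [2 ** (cfg.pyramid_levels - 1 - i) for i in range(cfg.pyramid_levels)]
    iters_used = []
    converged = True
    best_val = -np.inf
    for factor in factors:
        if factor > 1:
            f_lvl = downsample_mean(fixed, factor)
            m_lvl = downsample_mean(moving, factor)
        else:
            f_lvl, m_lvl = fixed, moving
        params, val, n_it, conv = _one_plus_one(
            f_lvl, m_lvl, params, scale, center, cfg, rng)
        iters_used.append(n_it)
        converged = converged and conv
        best_val = val

    if cfg.refine:
        params, best_val = _polish(fixed, moving, params, scale, center, cfg, rng)

    t = _params_to_transform(params, scale, center)
    return RegistrationResult(t, best_val, iters_used, converged)


def _polish(fixed, moving, params, scale, center, cfg, rng):
    """Deterministic Powell refinement of the MI metric around the ES solution."""
    from scipy import optimize

    def neg_metric(p):
        t = _params_to_transform(p, scale, center)
        moved, inside = _resample_with_mask(fixed, moving, t)
        if not inside.any():
            return np.inf
        return -_mi_value(fixed, moved, inside, cfg, rng)

    f0 = neg_metric(params)
    res = optimize.minimize(neg_metric, params, method="Powell",
                            options={"maxfev": cfg.refine_maxfev,
                                     "xtol": 1e-5, "ftol": 1e-9})
    if res.fun < f0:  # strict: keep the ES solution on ties
        return np.asarray(res.x), float(-res.fun)
    return params, float(-f0)


def _params_to_transform(params: np.ndarray, scale: np.ndarray,
                         center: np.ndarray) -> RigidTransform:
    phys = params * scale
    return RigidTransform(center, phys[:3], phys[3:])


def _one_plus_one(fixed: VolumeGrid, moving: VolumeGrid, params: np.ndarray,
                  scale: np.ndarray, center: np.ndarray,
                  cfg: RegistrationConfig, rng) -> tuple:
    opt = cfg.optimizer

    def metric(p: np.ndarray) -> float:
        t = _params_to_transform(p, scale, center)
        moved, inside = _resample_with_mask(fixed, moving, t)
        if not inside.any():
            return -np.inf
        return _mi_value(fixed, moved, inside, cfg, rng)

    parent = params.copy()
    f_parent = metric(parent)
    radius = opt.initial_radius
    it = 0
    last_accept = 0
    while it < opt.max_iterations and radius > opt.epsilon:
        it += 1
        child = parent + radius * rng.standard_normal(6)
        f_child = metric(child)
        if f_child > f_parent:
            parent, f_parent = child, f_child
            radius *= opt.growth_factor
            last_accept = it
        else:
            radius *= opt.shrink_factor
    # converged = the search settled: radius collapsed, or no accepted
    # improvement over the final quarter of the iteration budget
    settled = radius <= opt.epsilon or (it - last_accept) >= max(1, opt.max_iterations // 4)
    return parent, f_parent, it, settled
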