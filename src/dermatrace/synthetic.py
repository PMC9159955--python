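"""Ground-truthed synthetic hind-paw-digit imaging data.

Emulates the statistics and geometry the analysis pipeline assumes: branching
tubular fiber forests of two caliber classes (thin nociceptor-like fibers
that send free endings into the epidermis, thick Aβ-like fibers ending in
coiled corpuscle-like terminals below it), an epidermal autofluorescence band
with hair-like appendage clutter, a linear surface-to-depth excitation ramp,
Poisson + Gaussian detection noise, four-quadrant tile acquisition, and
inter-session rigid + smooth non-rigid tissue deformation with
denervation/regrowth timelines.

Every stochastic operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .core import (CALIBER_THICK, CALIBER_THIN, ConfigurationError,
                   DEFAULT_VOXEL_SIZE, EPIDERMAL_AF, APPENDAGE, FIBER,
                   GeometryError, ImageStack, Skeleton)

__all__ = [
    "SimulationConfig", "BranchingParams", "NoiseParams", "ChangeSpec",
    "Deformation", "SceneTimepoint", "TileSet",
    "generate_fiber_forest", "render_stack", "make_quadrant_tiles",
    "make_baseline_scene", "apply_longitudinal_change", "deformed_skeleton",
]


@dataclass
class BranchingParams:
    mean_branches: float = 3.0      # expected side branches per tree
    angle_spread_deg: float = 35.0  # branch take-off angle s.d.
    tortuosity: float = 0.35        # directional jitter per growth step
    step_um: float = 1.5            # centerline sampling step
    up_bias: float = 0.35           # drift toward the surface per step


@dataclass
class NoiseParams:
    poisson_scale: float = 1.0  # photons per intensity unit; 0 disables shot noise
    gauss_sigma: float = 1.0    # additive read noise (photon units); 0 disables

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.gauss_sigma > 0


@dataclass
class SimulationConfig:
    """Scene parameters for one simulated digit volume.

    Distances in µm unless stated; intensities in expected photon counts.
    """

    volume_dims: tuple[int, int, int] = (256, 256, 64)   # (nx, ny, nz) voxels
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    n_trees_thin: int = 4
    n_trees_thick: int = 3
    branching: BranchingParams = field(default_factory=BranchingParams)
    radius_thin: tuple[float, float] = (0.25, 0.45)
    radius_thick: tuple[float, float] = (1.2, 1.8)
    epidermal_band: tuple[float, float] = (0.0, 15.0)    # depth interval of the AF band
    af_intensity: float = 20.0
    af_gap_fraction: float = 0.25    # fraction of the band carved out as signal gaps
    appendage_density: float = 150.0  # hair-like structures per mm²
    appendage_intensity: float = 55.0
    fiber_intensity: float = 45.0
    background_intensity: float = 3.0
    depth_gain: float = 3.0          # bottom/surface excitation ratio (5%→15% ramp)
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.3, 1.0)  # (x, y, z)
    noise: NoiseParams = field(default_factory=NoiseParams)
    dn_per_photon: float = 250.0     # 16-bit digitizer gain
    seed: int = 0

    def __post_init__(self):
        if any(int(d) <= 0 for d in self.volume_dims):
            raise ConfigurationError("volume_dims must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be positive")
        if self.n_trees_thin < 0 or self.n_trees_thick < 0:
            raise ConfigurationError("tree counts must be non-negative")
        if not (self.radius_thin[1] < self.radius_thick[0]):
            raise ConfigurationError("thin radius range must lie strictly below thick range")
        b0, b1 = self.epidermal_band
        if not (0 <= b0 <= b1 <= self.extent_um[2]):
            raise ConfigurationError("epidermal band must lie within the z extent")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(d * v for d, v in zip(self.volume_dims, self.voxel_size))

    @property
    def epidermal_boundary_um(self) -> float:
        return self.epidermal_band[1]


def paper_geometry_config(nz: int = 8, seed: int = 0, **overrides) -> SimulationConfig:
    """Acquisition-scale preset: 2,000 × 2,000 px lateral canvas (854 µm at
    427 nm pixels) with a thin z extent, used for stitching validation."""
    defaults = dict(
        volume_dims=(2000, 2000, nz),
        n_trees_thin=70, n_trees_thick=40,
        branching=BranchingParams(mean_branches=2.0, up_bias=0.04, step_um=2.0),
        epidermal_band=(0.0, min(2.0, nz * 1.0)),
        af_intensity=0.0, appendage_density=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# Fiber forest growth
# ---------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, -1.0])


def _rotate_away(d, angle_rad, rng):
    """Rotate d by angle_rad around a random axis perpendicular to d."""
    d = _unit(d)
    perp = np.cross(d, rng.normal(size=3))
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(d, [1.0, 0.0, 0.0])
    perp = _unit(perp)
    return _unit(d * math.cos(angle_rad) + perp * math.sin(angle_rad))


def generate_fiber_forest(config: SimulationConfig, seed: int | None = None) -> Skeleton:
    """Grow a forest of branching tubular centerlines spanning the dermis.

    Thin-class trees terminate in short filopodia-like endings above the
    epidermal boundary; thick-class trees terminate in coiled
    Meissner-corpuscle-like loops just below it.  Deterministic given seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    ext = np.array(config.extent_um)
    boundary = config.epidermal_boundary_um
    bp = config.branching
    rows = []
    next_id = [0]

    max_steps = max(30, int(1.2 * max(ext) / bp.step_um))

    def grow(tree_id, caliber, radius):
        margin = min(4.0, 0.1 * min(ext[0], ext[1]))
        z_lo = min(boundary + 4.0, 0.7 * ext[2])
        root = np.array([
            rng.uniform(margin, ext[0] - margin),
            rng.uniform(margin, ext[1] - margin),
            rng.uniform(max(z_lo, 0.6 * ext[2]), 0.95 * ext[2] - 0.2),
        ])
        d0 = _unit(np.array([rng.normal(0, 0.4), rng.normal(0, 0.4), -1.0]))
        rid = next_id[0]
        next_id[0] += 1
        rows.append((rid, -1, *root, radius, tree_id, caliber))
        p_branch = bp.mean_branches / max_steps
        # (pos, dir, parent_id, level, steps_left)
        stack = [(root.copy(), d0, rid, 0, max_steps)]
        while stack:
            pos, d, parent, level, budget = stack.pop()
            if caliber == CALIBER_THIN:
                stop_z = rng.uniform(0.3, 0.75) * boundary if boundary > 0 else 0.3
            else:
                stop_z = boundary + rng.uniform(1.5, 5.0)
            taper = 1.0
            for _ in range(budget):
                d = _unit(d + bp.tortuosity * rng.normal(size=3)
                          + np.array([0.0, 0.0, -bp.up_bias]))
                pos = pos + bp.step_um * d
                # steer back from lateral walls
                for ax in (0, 1):
                    if pos[ax] < 2.0:
                        pos[ax] = 2.0 + (2.0 - pos[ax]); d[ax] = abs(d[ax])
                    elif pos[ax] > ext[ax] - 2.0:
                        pos[ax] = 2 * (ext[ax] - 2.0) - pos[ax]; d[ax] = -abs(d[ax])
                pos[2] = np.clip(pos[2], 0.3, ext[2] - 0.3)
                pos[0] = np.clip(pos[0], 0.2, ext[0] - 0.2)
                pos[1] = np.clip(pos[1], 0.2, ext[1] - 0.2)
                nid = next_id[0]
                next_id[0] += 1
                taper = max(0.6, taper * 0.998)
                rows.append((nid, parent, *pos, radius * taper, tree_id, caliber))
                parent = nid
                if pos[2] <= stop_z:
                    break
                if level < 2 and rng.random() < p_branch:
                    bd = _rotate_away(d, math.radians(abs(rng.normal(0, bp.angle_spread_deg))), rng)
                    stack.append((pos.copy(), bd, parent, level + 1, budget // 2))
            if caliber == CALIBER_THICK and boundary > 0:
                parent = _add_coil(rows, next_id, pos, radius, parent, tree_id, rng,
                                   boundary, ext)

    def _add_coil(rows, next_id, pos, radius, parent, tree_id, rng, boundary, ext):
        """Coiled corpuscle-like terminal below the epidermal boundary."""
        r_coil = 2.5
        z0 = max(boundary + 1.0, min(pos[2], ext[2] - 2.0))
        phi0 = rng.uniform(0, 2 * math.pi)
        for k in range(1, 13):
            phi = phi0 + k * (3.0 * math.pi / 12)
            p = np.array([pos[0] + r_coil * math.cos(phi),
                          pos[1] + r_coil * math.sin(phi),
                          z0 + 0.8 * math.sin(k / 3.0)])
            p[0] = np.clip(p[0], 0.2, ext[0] - 0.2)
            p[1] = np.clip(p[1], 0.2, ext[1] - 0.2)
            p[2] = np.clip(p[2], boundary + 0.5, ext[2] - 0.3)
            nid = next_id[0]
            next_id[0] += 1
            rows.append((nid, parent, *p, radius * 0.8, tree_id, CALIBER_THICK))
            parent = nid
        return parent

    tree_id = 0
    for _ in range(config.n_trees_thin):
        grow(tree_id, CALIBER_THIN, rng.uniform(*config.radius_thin))
        tree_id += 1
    for _ in range(config.n_trees_thick):
        grow(tree_id, CALIBER_THICK, rng.uniform(*config.radius_thick))
        tree_id += 1

    df = pd.DataFrame(rows, columns=["id", "parent", "x", "y", "z",
                                     "radius", "tree_id", "caliber"])
    return Skeleton(df, boundary)


# ---------------------------------------------------------------------------
# Rasterization and rendering
# ---------------------------------------------------------------------------

def rasterize_fiber_mask(skeleton: Skeleton, config: SimulationConfig,
                         coverage: bool = False):
    """Exact tube occupancy: a voxel is fiber iff its center lies within the
    (linearly interpolated) radius of some centerline segment.

    With ``coverage=True`` additionally returns an anti-aliased partial-volume
    map (the fraction of each voxel inside the tube, approximated from the
    center distance), which is what a microscope integrating over the voxel
    actually records."""
    nz, ny, nx = config.volume_dims[2], config.volume_dims[1], config.volume_dims[0]
    dx, dy, dz = config.voxel_size
    mask = np.zeros((nz, ny, nx), dtype=bool)
    cov = np.zeros((nz, ny, nx), dtype=np.float32) if coverage else None
    delta = (dx + dy + dz) / 3.0  # effective voxel width for partial volume
    df = skeleton.nodes
    if df.empty:
        return (mask, cov) if coverage else mask
    pos = df.set_index("id")
    ext = config.extent_um
    pts = df[["x", "y", "z"]].to_numpy(float)
    if (pts < -1e-6).any() or (pts > np.array(ext) + 1e-6).any():
        raise GeometryError("skeleton extends outside the simulated volume")
    child = df[df["parent"] >= 0]
    a = pos.loc[child["parent"], ["x", "y", "z"]].to_numpy(float)
    b = child[["x", "y", "z"]].to_numpy(float)
    ra = pos.loc[child["parent"], "radius"].to_numpy(float)
    rb = child["radius"].to_numpy(float)
    vs = np.array([dx, dy, dz])
    for (p0, p1, r0, r1) in zip(a, b, ra, rb):
        rmax = max(r0, r1)
        lo = np.minimum(p0, p1) - rmax - vs
        hi = np.maximum(p0, p1) + rmax + vs
        i0 = np.maximum(np.floor(lo / vs), 0).astype(int)
        i1 = np.minimum(np.ceil(hi / vs), [nx - 1, ny - 1, nz - 1]).astype(int)
        if np.any(i1 < i0):
            continue
        xs = np.arange(i0[0], i1[0] + 1) * dx
        ys = np.arange(i0[1], i1[1] + 1) * dy
        zs = np.arange(i0[2], i1[2] + 1) * dz
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        v = p1 - p0
        vv = float(v @ v)
        if vv == 0:
            t = np.zeros_like(X)
        else:
            t = ((X - p0[0]) * v[0] + (Y - p0[1]) * v[1] + (Z - p0[2]) * v[2]) / vv
            t = np.clip(t, 0.0, 1.0)
        cx = p0[0] + t * v[0]
        cy = p0[1] + t * v[1]
        cz = p0[2] + t * v[2]
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        rloc = r0 + t * (r1 - r0)
        sub = d2 <= rloc ** 2
        sl = (slice(i0[2], i1[2] + 1), slice(i0[1], i1[1] + 1), slice(i0[0], i1[0] + 1))
        mask[sl] |= sub
        if coverage:
            frac = np.clip((rloc - np.sqrt(d2)) / delta + 0.5, 0.0, 1.0)
            np.maximum(cov[sl], frac.astype(np.float32), out=cov[sl])
    return (mask, cov) if coverage else mask


def _smooth_noise_field(shape, rng, coarse=8, sigma=2.0):
    nz, ny, nx = shape
    coarse_shape = (max(2, nz // 2), max(2, ny // coarse), max(2, nx // coarse))
    g = rng.normal(size=coarse_shape)
    g = ndi.zoom(g, [s / c for s, c in zip(shape, coarse_shape)], order=1)
    g = g[:nz, :ny, :nx]
    pad = [(0, max(0, s - gs)) for s, gs in zip(shape, g.shape)]
    if any(p[1] for p in pad):
        g = np.pad(g, pad, mode="edge")
    g = ndi.gaussian_filter(g, sigma)
    g -= g.mean()
    s = g.std()
    return g / s if s > 0 else g


def render_stack(skeleton: Skeleton, config: SimulationConfig,
                 seed: int | None = None) -> tuple[ImageStack, np.ndarray]:
    """Render a 16-bit stack plus its ground-truth label volume.

    Tubes are drawn as hard disks of the local radius convolved with an
    anisotropic Gaussian PSF; the epidermal autofluorescence band (with
    signal gaps) and hair-like appendages are added; a linear
    surface-to-depth excitation ramp scales the expected signal; Poisson shot
    noise and Gaussian read noise are applied last.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    nx, ny, nz = config.volume_dims
    shape = (nz, ny, nx)
    dx, dy, dz = config.voxel_size

    fiber_mask, fiber_cov = rasterize_fiber_mask(skeleton, config, coverage=True)
    labels = np.zeros(shape, dtype=np.uint8)

    expected = np.full(shape, float(config.background_intensity), dtype=np.float32)
    fiber_img = (config.fiber_intensity * fiber_cov).astype(np.float32)
    sig_vox = (config.psf_sigma_um[2] / dz, config.psf_sigma_um[1] / dy,
               config.psf_sigma_um[0] / dx)
    if any(s > 0 for s in sig_vox):
        fiber_img = ndi.gaussian_filter(fiber_img, sig_vox)
    expected += fiber_img

    # epidermal autofluorescence band with gaps
    b0, b1 = config.epidermal_band
    zcoords = (np.arange(nz) * dz)[:, None, None]
    if config.af_intensity > 0 and b1 > b0:
        tex = _smooth_noise_field(shape, rng)
        thr = np.quantile(tex, config.af_gap_fraction)
        in_band = (zcoords >= b0) & (zcoords < b1)
        af_mask = in_band & (tex > thr)
        t01 = (tex - tex.min()) / max(float(np.ptp(tex)), 1e-9)
        af_img = np.where(af_mask, config.af_intensity * (0.6 + 0.4 * t01), 0.0)
        af_img = ndi.gaussian_filter(af_img.astype(np.float32), (0.8, 1.2, 1.2))
        expected += af_img
        labels[af_mask & ~fiber_mask] = EPIDERMAL_AF

    # hair-like appendages: bright tilted cylinders from the surface down
    area_mm2 = (nx * dx / 1000.0) * (ny * dy / 1000.0)
    n_app = rng.poisson(config.appendage_density * area_mm2) if config.appendage_density > 0 else 0
    if n_app:
        Z, Y, X = np.meshgrid(np.arange(nz) * dz, np.arange(ny) * dy,
                              np.arange(nx) * dx, indexing="ij")
        app_mask = np.zeros(shape, dtype=bool)
        for _ in range(n_app):
            cx0 = rng.uniform(5, nx * dx - 5)
            cy0 = rng.uniform(5, ny * dy - 5)
            r_app = rng.uniform(1.5, 3.0)
            d_lo = min(b1 + 5.0, nz * dz)
            d_hi = max(d_lo, min(b1 + 18.0, nz * dz))
            depth = rng.uniform(d_lo, d_hi)
            tilt = rng.normal(0, 0.15, size=2)
            axx = cx0 + tilt[0] * Z
            axy = cy0 + tilt[1] * Z
            app_mask |= ((X - axx) ** 2 + (Y - axy) ** 2 <= r_app ** 2) & (Z <= depth)
        app_img = np.where(app_mask, config.appendage_intensity, 0.0).astype(np.float32)
        app_img = ndi.gaussian_filter(app_img, sig_vox)
        expected += app_img
        labels[app_mask & ~fiber_mask] = APPENDAGE

    labels[fiber_mask] = FIBER

    # linear excitation ramp, surface (z=0) → bottom
    ramp = 1.0 + (config.depth_gain - 1.0) * (np.arange(nz) / max(nz - 1, 1))
    expected *= ramp[:, None, None].astype(np.float32)

    noisy = expected
    if config.noise.poisson_scale > 0:
        noisy = rng.poisson(expected * config.noise.poisson_scale).astype(np.float32) \
            / config.noise.poisson_scale
    if config.noise.gauss_sigma > 0:
        noisy = noisy + rng.normal(0, config.noise.gauss_sigma, size=shape).astype(np.float32)

    dn = np.clip(noisy * config.dn_per_photon, 0, 65535).astype(np.uint16)
    stack = ImageStack(dn, config.voxel_size,
                       meta={"seed": int(seed), "depth_gain": config.depth_gain,
                             "epidermal_boundary_um": config.epidermal_boundary_um})
    return stack, labels


# ---------------------------------------------------------------------------
# Quadrant tiles
# ---------------------------------------------------------------------------

@dataclass
class TileSet:
    """Four quadrant tiles in a 2×2 grid with ground-truth offsets.

    Tiles are row-major: (top-left, top-right, bottom-left, bottom-right).
    ``true_offsets`` are (ox, oy) pixel positions of each tile's origin in the
    parent stack.
    """
    tiles: list
    true_offsets: list
    overlap_px: int
    parent_shape: tuple


def make_quadrant_tiles(stack: ImageStack, overlap_px: int) -> TileSet:
    """Cut a stack into four overlapping quadrant tiles (2×2 grid).

    Adjacent tiles share ``overlap_px`` columns/rows copied from the parent,
    mirroring sequential stage-scanned acquisition with ~10 % overlap.
    """
    nz, ny, nx = stack.shape
    if (nx + overlap_px) % 2 or (ny + overlap_px) % 2:
        raise GeometryError(
            f"lateral dims ({nx}, {ny}) must equal 2*W - overlap for integer tile width")
    wx = (nx + overlap_px) // 2
    wy = (ny + overlap_px) // 2
    if overlap_px < 0 or wx <= overlap_px or wy <= overlap_px:
        raise GeometryError("invalid overlap for these dimensions")
    origins = [(0, 0), (nx - wx, 0), (0, ny - wy), (nx - wx, ny - wy)]
    tiles = []
    for k, (ox, oy) in enumerate(origins):
        sub = stack.data[:, oy:oy + wy, ox:ox + wx].copy()
        tiles.append(ImageStack(sub, stack.voxel_size, stack.session,
                                {**stack.meta, "tile_grid": (k // 2, k % 2),
                                 "tile_origin_px": (ox, oy)}))
    return TileSet(tiles, origins, overlap_px, stack.shape)


# ---------------------------------------------------------------------------
# Inter-session deformation and longitudinal change
# ---------------------------------------------------------------------------

@dataclass
class Deformation:
    """Rigid motion plus a smooth sinusoidal displacement field (µm).

    Maps anatomical coordinates into the session's imaging frame:
    ``p' = R p + t + u(p)`` with ``u`` a sum of low-frequency sinusoids whose
    total slope is kept below 1, so the map is invertible on the volume.
    """
    rotation: np.ndarray          # (3, 3)
    translation: np.ndarray       # (3,)
    wave_amps: np.ndarray         # (k, 3) µm
    wave_vectors: np.ndarray      # (k, 3) rad/µm
    wave_phases: np.ndarray       # (k, 3)

    @classmethod
    def identity(cls):
        return cls(np.eye(3), np.zeros(3), np.zeros((0, 3)),
                   np.zeros((0, 3)), np.zeros((0, 3)))

    @classmethod
    def random(cls, rng, extent_um, amplitude_um=2.0, rot_deg=2.0, trans_um=4.0):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = math.radians(rng.uniform(-rot_deg, rot_deg))
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        t = rng.uniform(-trans_um, trans_um, size=3)
        k = 2
        L = max(extent_um) / 1.3
        amps = rng.uniform(0.3, 1.0, size=(k, 3)) * (amplitude_um / k)
        kvecs = rng.normal(size=(k, 3))
        kvecs = (2 * math.pi / L) * kvecs / np.linalg.norm(kvecs, axis=1, keepdims=True)
        # keep the field a contraction-free perturbation: |∇u| < 1
        slope = (np.abs(amps) * np.linalg.norm(kvecs, axis=1, keepdims=True)).sum()
        if slope > 0.8:
            amps *= 0.8 / slope
        phases = rng.uniform(0, 2 * math.pi, size=(k, 3))
        return cls(R, t, amps, kvecs, phases)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        u = np.zeros_like(points, dtype=float)
        for a, kv, ph in zip(self.wave_amps, self.wave_vectors, self.wave_phases):
            phase = points @ kv
            u += a * np.sin(phase[:, None] + ph)
        return u

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        return points @ self.rotation.T + self.translation + self.displacement(points)


@dataclass
class ChangeSpec:
    """SNI-style longitudinal change relative to the baseline forest."""
    remove_frac_thin: float = 0.0
    remove_frac_thick: float = 0.0
    regrow_frac_thin: float = 0.0
    regrow_frac_thick: float = 0.0
    epidermal_entry: bool = True
    jitter_um: float = 0.5
    deformation_amplitude_um: float = 2.0
    rigid_rot_deg: float = 2.0
    rigid_trans_um: float = 4.0

    def __post_init__(self):
        for f in (self.remove_frac_thin, self.remove_frac_thick,
                  self.regrow_frac_thin, self.regrow_frac_thick):
            if not (0.0 <= f <= 1.0):
                raise ConfigurationError("change fractions must lie in [0, 1]")


@dataclass
class SceneTimepoint:
    """One session of a longitudinal scene, in anatomical coordinates.

    ``skeleton`` holds the session's fiber forest *before* tissue deformation;
    ``deformation`` maps it into the session's imaging frame (use
    :func:`deformed_skeleton` to obtain the frame actually rendered).
    """
    skeleton: Skeleton
    baseline: Skeleton
    deformation: Deformation
    session_label: int
    change_record: dict


def make_baseline_scene(config: SimulationConfig, seed: int | None = None) -> SceneTimepoint:
    skel = generate_fiber_forest(config, seed)
    return SceneTimepoint(skel, skel, Deformation.identity(), 0,
                          {"removed": [], "regrown": [], "epidermal_entry": True})


def _truncate_below_boundary(skel: Skeleton, boundary: float, margin: float = 2.0) -> Skeleton:
    """Cut every subtree at its first node shallower than boundary+margin,
    so no retained node (nor any of its ancestors) enters the epidermis."""
    df = skel.nodes
    if df.empty:
        return skel
    ok = dict()
    parent = dict(zip(df["id"], df["parent"]))
    zs = dict(zip(df["id"], df["z"]))
    order = df["id"].tolist()  # generation order: parents precede children
    for i in order:
        deep_enough = zs[i] >= boundary + margin
        p = parent[i]
        ok[i] = deep_enough and (p < 0 or ok.get(p, False))
    keep = df["id"].map(ok)
    return Skeleton(df[keep].reset_index(drop=True), skel.epidermal_boundary_um)


def apply_longitudinal_change(scene: SceneTimepoint, change: ChangeSpec,
                              seed: int, session_label: int | None = None) -> SceneTimepoint:
    """Produce a later-session scene from the baseline.

    Removes the stated per-caliber fraction of trees; regrown trees reuse their
    stored baseline centerlines (with smooth sub-µm jitter) so sprouting
    retraces the original trajectories; with ``epidermal_entry=False`` regrown
    thin-class trees are truncated below the epidermal boundary; a fresh
    smooth rigid+non-rigid deformation is composed onto the scene.
    """
    rng = np.random.default_rng(seed)
    base = scene.baseline
    calibers = base.caliber_of_tree()
    thin_ids = sorted(t for t, c in calibers.items() if c == CALIBER_THIN)
    thick_ids = sorted(t for t, c in calibers.items() if c == CALIBER_THICK)

    def pick(ids, frac, tag):
        # nested in the fraction: a larger removal/regrowth fraction always
        # extends the smaller one (regrowth is cumulative)
        k = int(round(frac * len(ids)))
        perm = np.random.default_rng([seed, tag]).permutation(sorted(ids))
        return [int(t) for t in perm[:k]]

    removed = pick(thin_ids, change.remove_frac_thin, 0) \
        + pick(thick_ids, change.remove_frac_thick, 1)
    removed_thin = [t for t in removed if calibers[t] == CALIBER_THIN]
    removed_thick = [t for t in removed if calibers[t] == CALIBER_THICK]
    regrown = pick(sorted(removed_thin), change.regrow_frac_thin, 2) \
        + pick(sorted(removed_thick), change.regrow_frac_thick, 3)

    surviving = [t for t in calibers if t not in set(removed)]
    parts = [base.subset_trees(surviving).nodes]
    for t in sorted(regrown):
        sub = base.subset_trees([t]).nodes.copy()
        if len(sub):
            offset = rng.normal(0, change.jitter_um * 0.5, size=3)
            wobble = rng.normal(0, change.jitter_um * 0.25, size=(len(sub), 3))
            wobble = ndi.gaussian_filter1d(wobble, 4, axis=0)
            sub[["x", "y", "z"]] = sub[["x", "y", "z"]].to_numpy() + offset + wobble
        parts.append(sub)
    nodes = pd.concat(parts, ignore_index=True) if parts else base.nodes.iloc[0:0]
    new_skel = Skeleton(nodes, base.epidermal_boundary_um)
    if not change.epidermal_entry:
        regrown_thin = [t for t in regrown if calibers[t] == CALIBER_THIN]
        kept = new_skel.nodes[~new_skel.nodes["tree_id"].isin(regrown_thin)]
        cut = _truncate_below_boundary(
            Skeleton(new_skel.nodes[new_skel.nodes["tree_id"].isin(regrown_thin)]
                     .reset_index(drop=True), base.epidermal_boundary_um),
            base.epidermal_boundary_um)
        new_skel = Skeleton(pd.concat([kept, cut.nodes], ignore_index=True),
                            base.epidermal_boundary_um)

    label = scene.session_label + 1 if session_label is None else session_label
    record = {"removed": sorted(int(t) for t in removed),
              "regrown": sorted(int(t) for t in regrown),
              "epidermal_entry": bool(change.epidermal_entry)}
    return SceneTimepoint(new_skel, base, _make_deformation(rng, base, change),
                          label, record)


def _make_deformation(rng, base: Skeleton, change: ChangeSpec) -> Deformation:
    if base.nodes.empty:
        extent = (100.0, 100.0, 60.0)
    else:
        extent = tuple(base.nodes[c].max() + 1 for c in ("x", "y", "z"))
    return Deformation.random(rng, extent,
                              amplitude_um=change.deformation_amplitude_um,
                              rot_deg=change.rigid_rot_deg,
                              trans_um=change.rigid_trans_um)


def deformed_skeleton(scene: SceneTimepoint, config: SimulationConfig) -> Skeleton:
    """Skeleton in the session's imaging frame, clipped into the volume."""
    df = scene.skeleton.nodes.copy()
    if len(df):
        pts = scene.deformation.apply(df[["x", "y", "z"]].to_numpy(float))
        ext = config.extent_um
        for j, (c, e) in enumerate(zip(("x", "y", "z"), ext)):
            df[c] = np.clip(pts[:, j], 0.2, e - 0.2)
    return Skeleton(df, scene.skeleton.epidermal_boundary_um)
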