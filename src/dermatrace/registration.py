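"""4D registration: rigid ICP on fiber point clouds + thin-plate-spline refinement.

Sessions acquired months apart are aligned by extracting 3D point clouds of
suprathreshold fiber voxels, estimating a rigid transform with trimmed
iterative-closest-point (robust to partial overlap after denervation), and
refining with a thin-plate-spline warp fitted to mutually-nearest
correspondences.  All sessions are registered to the baseline session and can
be cropped/resampled to the largest common physical volume.

The ICP objective is the trimmed sum of correspondence residuals
``J = Σ_P ‖T(P) − Ψ(P)‖`` over the best-matching fraction of source points,
with Ψ the nearest-neighbour correspondence into the target cloud.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .core import GeometryError, ImageStack, PipelineError

__all__ = ["PointCloud", "RigidTransform", "ICPResult", "TPSTransform",
           "CompositeTransform", "extract_point_cloud", "icp_rigid", "tps_fit",
           "register_point_clouds", "crop_common_volume", "DegenerateGeometryWarning"]


class DegenerateGeometryWarning(UserWarning):
    pass


@dataclass
class PointCloud:
    points: np.ndarray                 # (n, 3) µm
    session: str | None = None
    weights: np.ndarray | None = None
    empty_flag: bool = False

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.empty_flag = self.empty_flag or len(self.points) == 0

    def __len__(self):
        return len(self.points)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p ↦ R p + t`` (µm)."""
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must have determinant +1")

    @classmethod
    def identity(cls):
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg, translation=(0, 0, 0)):
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        a = math.radians(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, points):
        return np.atleast_2d(np.asarray(points, float)) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1) / 2
        return math.degrees(math.acos(np.clip(c, -1, 1)))

    def to_dict(self):
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}


@dataclass
class ICPResult:
    transform: RigidTransform
    correspondence: np.ndarray          # target index of each source point (-1 trimmed)
    residual: float                     # J at convergence (µm)
    residual_history: list
    iterations: int
    trimmed_fraction: float


@dataclass
class TPSTransform:
    """3D thin-plate spline: ``f(p) = A p + b + Σ w_i U(‖p − c_i‖)``,
    kernel ``U(r) = r``; λ = 0 interpolates the landmarks."""
    src_landmarks: np.ndarray
    dst_landmarks: np.ndarray
    weights: np.ndarray                 # (n, 3)
    affine: np.ndarray                  # (4, 3): rows constant + x + y + z
    regularization: float

    def apply(self, points):
        points = np.atleast_2d(np.asarray(points, float))
        d = np.linalg.norm(points[:, None, :] - self.src_landmarks[None, :, :], axis=2)
        P = np.hstack([np.ones((len(points), 1)), points])
        return P @ self.affine + d @ self.weights


@dataclass
class CompositeTransform:
    """Rigid pre-alignment followed by an optional TPS refinement."""
    rigid: RigidTransform
    tps: TPSTransform | None = None

    def apply(self, points):
        out = self.rigid.apply(points)
        if self.tps is not None:
            out = self.tps.apply(out)
        return out

    def approximate_inverse(self) -> "CompositeTransform":
        inv_rigid = self.rigid.inverse()
        if self.tps is None:
            return CompositeTransform(inv_rigid)
        # inverse warp approximated by swapping landmark roles, composed with
        # the exact rigid inverse
        inv_tps = tps_fit(self.tps.dst_landmarks, self.tps.src_landmarks,
                          self.tps.regularization)
        return CompositeTransform(RigidTransform.identity(),
                                  _TPSRigidChain(inv_tps, inv_rigid))


@dataclass
class _TPSRigidChain:
    """TPS followed by a rigid map (used for approximate inverses)."""
    tps: TPSTransform
    rigid: RigidTransform

    def apply(self, points):
        return self.rigid.apply(self.tps.apply(points))


# ---------------------------------------------------------------------------
# Point-cloud extraction
# ---------------------------------------------------------------------------

def extract_point_cloud(stack8: ImageStack, threshold: float | None = None,
                        max_points: int = 20000, seed: int = 0) -> PointCloud:
    """Suprathreshold voxels → physical (x, y, z) µm points, subsampled.

    With ``threshold=None`` an Otsu threshold over nonzero voxels is used.
    An empty result is returned flagged, not raised.
    """
    data = stack8.data
    if threshold is None:
        from skimage.filters import threshold_otsu
        nz = data[data > 0]
        threshold = threshold_otsu(nz) if nz.size > 16 else np.inf
    zz, yy, xx = np.nonzero(data > threshold)
    if len(zz) == 0:
        return PointCloud(np.zeros((0, 3)), stack8.session, empty_flag=True)
    dx, dy, dz = stack8.voxel_size
    pts = np.column_stack([xx * dx, yy * dy, zz * dz])
    w = data[zz, yy, xx].astype(float)
    if len(pts) > max_points:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(pts), size=max_points, replace=False)
        sel.sort()
        pts, w = pts[sel], w[sel]
    return PointCloud(pts, stack8.session, w)


# ---------------------------------------------------------------------------
# Trimmed rigid ICP
# ---------------------------------------------------------------------------

def _kabsch(src, dst):
    """Least-squares rigid transform mapping src onto dst."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def icp_rigid(source: PointCloud, target: PointCloud, max_iterations: int = 60,
              tolerance: float = 1e-6, trim_fraction: float = 0.7,
              coarse_points: int = 1500,
              init: RigidTransform | None = None) -> ICPResult:
    """Trimmed rigid ICP minimizing ``J = Σ‖T(P) − Ψ(P)‖``.

    Alternates nearest-neighbour correspondence and a closed-form rigid
    update on the best ``trim_fraction`` of correspondences.  Runs a coarse
    subsampled pass for initialization, then refines on the full clouds.  The
    recorded residual history is non-increasing (iterations that fail to
    improve J terminate the loop).
    """
    if len(source) == 0 or len(target) == 0:
        raise GeometryError("both point clouds must be non-empty")
    src_all = source.points
    tgt = target.points
    if _rank_deficient(src_all) or _rank_deficient(tgt):
        warnings.warn("degenerate (collinear) point cloud: translation-only fit",
                      DegenerateGeometryWarning)
        t = tgt.mean(axis=0) - src_all.mean(axis=0)
        tf = RigidTransform(np.eye(3), t)
        resid = _trimmed_residual(tf.apply(src_all), tgt, trim_fraction)
        return ICPResult(tf, np.full(len(src_all), -1), resid, [resid], 0, trim_fraction)

    transform = init or RigidTransform.identity()
    tree = cKDTree(tgt)
    history: list[float] = []
    it_count = 0
    for stage_pts in _stages(src_all, coarse_points):
        n_keep = max(3, int(round(trim_fraction * len(stage_pts))))
        prev_J = np.inf
        history = []  # J is a sum over stage points; record the final stage only
        for _ in range(max_iterations):
            moved = transform.apply(stage_pts)
            dist, nn = tree.query(moved, workers=-1)
            keep = np.argsort(dist)[:n_keep]
            cand = _kabsch(stage_pts[keep], tgt[nn[keep]])
            moved2 = cand.apply(stage_pts)
            dist2, _ = tree.query(moved2, workers=-1)
            J = float(np.sort(dist2)[:n_keep].sum())
            it_count += 1
            if J >= prev_J - tolerance:
                if J < prev_J:
                    transform = cand
                    history.append(J)
                break
            transform = cand
            prev_J = J
            history.append(J)

    moved = transform.apply(src_all)
    dist, nn = tree.query(moved, workers=-1)
    n_keep = max(3, int(round(trim_fraction * len(src_all))))
    keep = set(np.argsort(dist)[:n_keep].tolist())
    corr = np.array([nn[i] if i in keep else -1 for i in range(len(src_all))])
    J = float(np.sort(dist)[:n_keep].sum())
    if not history:
        history = [J]
    history = _monotone(history + [min(J, history[-1])])
    return ICPResult(transform, corr, history[-1], history, it_count, trim_fraction)


def _stages(points, coarse_points):
    if len(points) > 2 * coarse_points:
        step = len(points) // coarse_points
        yield points[::step]
    yield points


def _monotone(hist):
    out = []
    cur = np.inf
    for h in hist:
        cur = min(cur, h)
        out.append(cur)
    return out


def _rank_deficient(pts):
    if len(pts) < 3:
        return True
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1.0)


def _trimmed_residual(moved, tgt, trim_fraction):
    tree = cKDTree(tgt)
    dist, _ = tree.query(moved, workers=-1)
    n_keep = max(1, int(round(trim_fraction * len(moved))))
    return float(np.sort(dist)[:n_keep].sum())


# ---------------------------------------------------------------------------
# Thin-plate splines
# ---------------------------------------------------------------------------

def tps_fit(src_landmarks: np.ndarray, dst_landmarks: np.ndarray,
            regularization: float = 0.0) -> TPSTransform:
    """Fit a 3D TPS mapping src landmarks to dst landmarks.

    Solves the standard augmented linear system with bending-energy
    regularization λ on the kernel block.  λ = 0 interpolates; λ → ∞
    approaches the least-squares affine fit.  Raises on coplanar landmarks.
    """
    src = np.asarray(src_landmarks, float).reshape(-1, 3)
    dst = np.asarray(dst_landmarks, float).reshape(-1, 3)
    n = len(src)
    if n < 4 or len(dst) != n:
        raise GeometryError("need >= 4 matching landmark pairs")
    P = np.hstack([np.ones((n, 1)), src])
    if np.linalg.matrix_rank(P, tol=1e-9 * max(1.0, np.abs(src).max())) < 4:
        raise GeometryError("landmarks are coplanar: TPS system is rank-deficient")
    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K + regularization * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 4, 3))
    b[:n] = dst
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return TPSTransform(src, dst, sol[:n], sol[n:], regularization)


def mutual_nearest_landmarks(source: PointCloud, target: PointCloud,
                             rigid: RigidTransform, max_landmarks: int = 200,
                             max_dist: float | None = None):
    """Mutually-nearest correspondences after rigid alignment, subsampled.

    Returns (src_points_in_target_frame, dst_points) suitable for TPS fitting.
    """
    moved = rigid.apply(source.points)
    t_tree = cKDTree(target.points)
    s_tree = cKDTree(moved)
    d_st, nn_st = t_tree.query(moved, workers=-1)
    _, nn_ts = s_tree.query(target.points, workers=-1)
    mutual = nn_ts[nn_st] == np.arange(len(moved))
    if max_dist is not None:
        mutual &= d_st <= max_dist
    idx = np.nonzero(mutual)[0]
    if len(idx) > max_landmarks:
        sel = np.linspace(0, len(idx) - 1, max_landmarks).astype(int)
        idx = idx[sel]
    return moved[idx], target.points[nn_st[idx]]


def register_point_clouds(source: PointCloud, target: PointCloud,
                          trim_fraction: float = 0.7, tps_regularization: float = 10.0,
                          max_landmarks: int = 200, landmark_max_dist: float = 5.0,
                          max_tps_displacement: float = 6.0,
                          min_landmarks: int = 25,
                          use_tps: bool = True) -> tuple[CompositeTransform, ICPResult]:
    """Full registration: coarse→fine trimmed ICP, then TPS refinement on
    mutually-nearest correspondences.

    The TPS stage is a small non-rigid correction: correspondences farther
    apart than ``landmark_max_dist`` µm are discarded, at least
    ``min_landmarks`` well-spread pairs are required, and a warp whose
    95th-percentile displacement over the source cloud exceeds
    ``max_tps_displacement`` µm is rejected in favour of the rigid fit.
    """
    icp = icp_rigid(source, target, trim_fraction=trim_fraction)
    tps = None
    if use_tps:
        src_lm, dst_lm = mutual_nearest_landmarks(source, target, icp.transform,
                                                  max_landmarks, landmark_max_dist)
        if len(src_lm) >= min_landmarks:
            try:
                tps = tps_fit(src_lm, dst_lm, tps_regularization)
            except GeometryError:
                tps = None
        if tps is not None:
            moved = icp.transform.apply(source.points)
            disp = np.linalg.norm(tps.apply(moved) - moved, axis=1)
            if np.quantile(disp, 0.95) > max_tps_displacement:
                tps = None
    return CompositeTransform(icp.transform, tps), icp


# ---------------------------------------------------------------------------
# Common-volume cropping
# ---------------------------------------------------------------------------

def _transformed_bounds(stack: ImageStack, transform) -> tuple[np.ndarray, np.ndarray]:
    ex, ey, ez = stack.extent_um
    g = np.linspace(0, 1, 4)
    pts = np.array([[a * ex, b * ey, c * ez] for a in g for b in g for c in g])
    out = transform.apply(pts)
    return out.min(axis=0), out.max(axis=0)


def crop_common_volume(stacks: list[ImageStack], transforms: list,
                       order: int = 1) -> tuple[list[ImageStack], tuple]:
    """Resample all sessions into the largest common physical volume.

    ``transforms[i]`` maps stack *i*'s coordinates into the shared reference
    frame.  Returns the aligned, identically-shaped stacks and the common box
    ``(lo_xyz_um, hi_xyz_um)``.  Use ``order=0`` for label volumes.
    """
    if len(stacks) != len(transforms):
        raise GeometryError("one transform per stack required")
    los, his = [], []
    for st, tf in zip(stacks, transforms):
        lo, hi = _transformed_bounds(st, tf)
        los.append(lo)
        his.append(hi)
    lo = np.max(los, axis=0)
    hi = np.min(his, axis=0)
    if np.any(hi <= lo):
        worst = int(np.argmax([np.max(l - hi) for l in los]))
        raise GeometryError(
            f"no common volume: session {stacks[worst].session or worst} does not intersect")
    vs = stacks[0].voxel_size
    dims = np.maximum(np.floor((hi - lo) / np.asarray(vs)).astype(int), 1)
    nx, ny, nz = int(dims[0]), int(dims[1]), int(dims[2])
    xs = lo[0] + np.arange(nx) * vs[0]
    ys = lo[1] + np.arange(ny) * vs[1]
    zs = lo[2] + np.arange(nz) * vs[2]
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    ref_pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    out = []
    for st, tf in zip(stacks, transforms):
        inv = tf.inverse() if isinstance(tf, RigidTransform) else tf.approximate_inverse()
        src = inv.apply(ref_pts)
        coords = np.stack([src[:, 2] / st.voxel_size[2],
                           src[:, 1] / st.voxel_size[1],
                           src[:, 0] / st.voxel_size[0]])
        res = ndi.map_coordinates(st.data.astype(np.float32), coords, order=order,
                                  mode="constant", cval=0.0)
        res = res.reshape(nz, ny, nx)
        if np.issubdtype(st.dtype, np.integer):
            info = np.iinfo(st.dtype)
            res = np.clip(np.rint(res), info.min, info.max).astype(st.dtype)
        out.append(ImageStack(res, vs, st.session,
                              {**st.meta, "common_box_um": [lo.tolist(), hi.tolist()]}))
    return out, (lo, hi)
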