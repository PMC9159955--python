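"""Quadrant-tile stitching by feature matching on maximum-intensity projections.

Four tiles acquired sequentially in a 2×2 grid with ~10 % nominal overlap are
merged into one seamless superstack.  Offsets between neighbouring tiles are
estimated from scale-invariant features detected on the z-MIPs of the overlap
regions (plus a search margin), with a robust translation consensus; a
normalized cross-correlation search over the nominal overlap ±25 % serves as a
deterministic fallback on feature-poor scenes.  The mosaic topology is fixed
at 2×2 (stage-scanned acquisition, translation-only seams).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors

from .core import GeometryError, ImageStack, PipelineError
from .synthetic import TileSet

__all__ = ["TileOffset", "Superstack", "InsufficientFeaturesError",
           "StitchingError", "estimate_tile_offset", "stitch_quadrants"]

MIN_INLIERS = 5


class InsufficientFeaturesError(PipelineError):
    """Raised when too few matched features support a seam offset."""


class StitchingError(PipelineError):
    pass


@dataclass
class TileOffset:
    """Estimated displacement of tile B's origin relative to tile A's origin."""
    displacement: tuple[float, float]   # (dx, dy) px
    n_inliers: int
    score: float                        # robust residual of inlier matches (px)
    method: str = "sift"

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("score must be non-negative")


@dataclass
class Superstack:
    stack: ImageStack
    offsets: list          # per-tile (ox, oy) integer origins in output px
    blend_ramp_px: int
    seam_offsets: dict     # per-seam TileOffset provenance


def _mip(tile: ImageStack) -> np.ndarray:
    return tile.data.max(axis=0).astype(np.float32)


def _detect(img: np.ndarray):
    det = SIFT()
    det.detect_and_extract(img)
    return det.keypoints, det.descriptors


def estimate_tile_offset(tile_a: ImageStack, tile_b: ImageStack, orientation: str,
                         nominal_overlap_frac: float = 0.10,
                         search_margin_frac: float = 0.5,
                         min_inliers: int = MIN_INLIERS) -> TileOffset:
    """Estimate the translation between two neighbouring tiles.

    ``orientation`` is ``"horizontal"`` (B right of A) or ``"vertical"``
    (B below A).  Works on z-MIPs restricted to the overlap-facing strips
    (nominal overlap plus a search margin); features are matched and a single
    translation is estimated by inlier consensus.  Raises
    :class:`InsufficientFeaturesError` when fewer than ``min_inliers`` matches
    agree (the caller may fall back to cross-correlation).
    """
    if tile_a.shape != tile_b.shape:
        raise GeometryError("tiles must share dimensions")
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mip_a, mip_b = _mip(tile_a), _mip(tile_b)
    if orientation == "vertical":
        # transpose so the seam is always along columns
        mip_a, mip_b = mip_a.T, mip_b.T
    h, w = mip_a.shape
    strip = int(round(min(1.0, nominal_overlap_frac + search_margin_frac) * w))
    strip = max(strip, 32) if w >= 32 else w
    a_off = w - strip
    sa = mip_a[:, a_off:]
    sb = mip_b[:, :strip]
    if sa.std() == 0 or sb.std() == 0:
        raise InsufficientFeaturesError("constant-intensity overlap strips")
    try:
        kp_a, des_a = _detect(sa)
        kp_b, des_b = _detect(sb)
    except (RuntimeError, ValueError) as exc:
        raise InsufficientFeaturesError(f"feature detection failed: {exc}") from exc
    if len(kp_a) == 0 or len(kp_b) == 0:
        raise InsufficientFeaturesError("no features detected in overlap strips")
    matches = match_descriptors(des_a, des_b, cross_check=True, max_ratio=0.9)
    if len(matches) < min_inliers:
        raise InsufficientFeaturesError(f"only {len(matches)} descriptor matches")
    # displacement of B's origin in A's frame: origin_B = pt_A - pt_B
    pa = kp_a[matches[:, 0]].astype(float)
    pa[:, 1] += a_off
    pb = kp_b[matches[:, 1]].astype(float)
    disp = pa - pb                      # (row, col) candidates
    med = np.median(disp, axis=0)
    resid = np.linalg.norm(disp - med, axis=1)
    inl = resid < 2.0
    if inl.sum() < min_inliers:
        raise InsufficientFeaturesError(
            f"only {int(inl.sum())} matches agree on a translation")
    est = disp[inl].mean(axis=0)        # (drow, dcol)
    score = float(np.median(np.linalg.norm(disp[inl] - est, axis=1)))
    if orientation == "horizontal":
        dx, dy = est[1], est[0]
    else:
        dx, dy = est[0], est[1]
    return TileOffset((float(dx), float(dy)), int(inl.sum()), score, "sift")


def _ncc_offset(tile_a: ImageStack, tile_b: ImageStack, orientation: str,
                nominal_overlap_frac: float = 0.10) -> TileOffset:
    """Deterministic fallback: exhaustive NCC over nominal overlap ±25 %."""
    mip_a, mip_b = _mip(tile_a), _mip(tile_b)
    if orientation == "vertical":
        mip_a, mip_b = mip_a.T, mip_b.T
    h, w = mip_a.shape
    o_nom = nominal_overlap_frac * w
    best = (-2.0, None)
    for o in range(max(2, int(0.75 * o_nom)), min(w - 1, int(np.ceil(1.25 * o_nom))) + 1):
        for drow in range(-4, 5):
            a = mip_a[:, w - o:]
            b = mip_b[:, :o]
            if drow > 0:
                a, b = a[drow:], b[:b.shape[0] - drow]
            elif drow < 0:
                a, b = a[:h + drow], b[-drow:]
            a = a - a.mean(); b = b - b.mean()
            denom = np.sqrt((a * a).sum() * (b * b).sum())
            if denom == 0:
                continue
            ncc = float((a * b).sum() / denom)
            if ncc > best[0]:
                best = (ncc, (w - o, drow))
    if best[1] is None:
        raise InsufficientFeaturesError("cross-correlation fallback failed (flat strips)")
    dcol, drow = best[1]
    if orientation == "horizontal":
        dx, dy = dcol, drow
    else:
        dx, dy = drow, dcol
    return TileOffset((float(dx), float(dy)), 0, float(1.0 - best[0]), "ncc")


def _seam(tile_a, tile_b, orientation, nominal):
    try:
        return estimate_tile_offset(tile_a, tile_b, orientation, nominal)
    except InsufficientFeaturesError:
        return _ncc_offset(tile_a, tile_b, orientation, nominal)


def stitch_quadrants(tiles: TileSet | list, offsets: list | None = None,
                     nominal_overlap_frac: float = 0.10) -> Superstack:
    """Stitch four quadrant tiles into a seamless superstack.

    Seam offsets are estimated (left–right pairs first, then top–bottom)
    unless given explicitly.  Sub-pixel estimates are rounded to integers
    before copying; overlap strips are blended with a linear ramp whose width
    equals the estimated overlap, so voxels outside overlaps are copied
    bit-exactly from their unique source tile.
    """
    if isinstance(tiles, TileSet):
        tile_list = tiles.tiles
    else:
        tile_list = list(tiles)
    if len(tile_list) != 4:
        raise GeometryError("expected exactly four tiles (2×2 grid)")
    shapes = {t.shape for t in tile_list}
    if len(shapes) != 1:
        raise GeometryError("tiles must share dimensions")
    nz, wy, wx = tile_list[0].shape
    t00, t01, t10, t11 = tile_list

    seams = {}
    if offsets is None:
        for name, (a, b, orient) in {
            "top_lr": (t00, t01, "horizontal"),
            "bottom_lr": (t10, t11, "horizontal"),
            "left_tb": (t00, t10, "vertical"),
            "right_tb": (t01, t11, "vertical"),
        }.items():
            try:
                seams[name] = _seam(a, b, orient, nominal_overlap_frac)
            except InsufficientFeaturesError as exc:
                raise StitchingError(f"offset estimation failed on seam {name}: {exc}")
        dx_top = seams["top_lr"].displacement[0]
        dx_bot = seams["bottom_lr"].displacement[0]
        dy_left = seams["left_tb"].displacement[1]
        dy_right = seams["right_tb"].displacement[1]
        sh_top = seams["top_lr"].displacement[1]
        sh_left = seams["left_tb"].displacement[0]
        # bottom-right origin: average the two consistent routes (via the
        # right seam and via the bottom seam); exact on consistent estimates
        via_right = (dx_top + seams["right_tb"].displacement[0],
                     sh_top + seams["right_tb"].displacement[1])
        via_bottom = (sh_left + dx_bot, dy_left + seams["bottom_lr"].displacement[1])
        origins = [
            (0, 0),
            (int(round(dx_top)), int(round(sh_top))),
            (int(round(sh_left)), int(round(dy_left))),
            (int(round((via_right[0] + via_bottom[0]) / 2)),
             int(round((via_right[1] + via_bottom[1]) / 2))),
        ]
    else:
        origins = [(int(round(ox)), int(round(oy))) for ox, oy in offsets]
        if origins[0] != (0, 0):
            shift = origins[0]
            origins = [(ox - shift[0], oy - shift[1]) for ox, oy in origins]

    min_x = min(o[0] for o in origins)
    min_y = min(o[1] for o in origins)
    origins = [(ox - min_x, oy - min_y) for ox, oy in origins]
    out_w = max(o[0] for o in origins) + wx
    out_h = max(o[1] for o in origins) + wy

    overlap_x = max(1, 2 * wx - out_w)
    overlap_y = max(1, 2 * wy - out_h)

    acc = np.zeros((nz, out_h, out_w), dtype=np.float64)
    wsum = np.zeros((out_h, out_w), dtype=np.float64)
    for (ox, oy), tile, (gx, gy) in zip(origins, tile_list,
                                        [(0, 0), (1, 0), (0, 1), (1, 1)]):
        w2 = _feather_weights(wy, wx, overlap_y, overlap_x,
                              left=gx == 1, right=gx == 0,
                              top=gy == 1, bottom=gy == 0)
        acc[:, oy:oy + wy, ox:ox + wx] += tile.data.astype(np.float64) * w2
        wsum[oy:oy + wy, ox:ox + wx] += w2
    wsum[wsum == 0] = 1.0
    merged = acc / wsum
    dtype = tile_list[0].dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        merged = np.clip(np.rint(merged), info.min, info.max).astype(dtype)
    else:
        merged = merged.astype(dtype)
    stack = ImageStack(merged, tile_list[0].voxel_size, tile_list[0].session,
                       {"tile_origins_px": origins,
                        "seam_methods": {k: v.method for k, v in seams.items()}})
    return Superstack(stack, origins, int(max(overlap_x, overlap_y)), seams)


def _feather_weights(h, w, overlap_y, overlap_x, left, right, top, bottom):
    """Per-tile blend weights: linear ramps of the overlap width on the sides
    that face a neighbouring tile, weight 1 elsewhere."""
    wx = np.ones(w)
    if left and overlap_x > 1:
        ramp = np.linspace(1.0 / (overlap_x + 1), 1.0, overlap_x, endpoint=False)
        wx[:overlap_x] = np.minimum(wx[:overlap_x], ramp)
    if right and overlap_x > 1:
        ramp = np.linspace(1.0 / (overlap_x + 1), 1.0, overlap_x, endpoint=False)
        wx[-overlap_x:] = np.minimum(wx[-overlap_x:], ramp[::-1])
    wy_ = np.ones(h)
    if top and overlap_y > 1:
        ramp = np.linspace(1.0 / (overlap_y + 1), 1.0, overlap_y, endpoint=False)
        wy_[:overlap_y] = np.minimum(wy_[:overlap_y], ramp)
    if bottom and overlap_y > 1:
        ramp = np.linspace(1.0 / (overlap_y + 1), 1.0, overlap_y, endpoint=False)
        wy_[-overlap_y:] = np.minimum(wy_[-overlap_y:], ramp[::-1])
    return wy_[:, None] * wx[None, :]
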