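"""Depth-adaptive 16-bit → 8-bit conversion and cross-session normalization.

Two-photon stacks are acquired with excitation power ramped with depth, so
raw slice statistics drift systematically in z.  Conversion first fits a
smooth (linear-in-z) gain curve to robust, background-excluded slice
statistics and divides it out, then maps intensities to [0, 255] by a convex
blend of a global (whole-stack) and a local (per-slice) robust percentile
stretch.  Both component maps are monotone, so the blended transfer is
monotone non-decreasing within any slice.  Longitudinal series are anchored
to a common pair of robust fiber-foreground percentiles before conversion so
comparisons are not driven by excitation drift between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageStack

__all__ = ["ConversionParams", "depth_adaptive_convert", "cross_session_normalize"]


@dataclass
class ConversionParams:
    low_percentile: float = 1.0
    high_percentile: float = 99.5
    depth_fit_degree: int = 1         # per-slice gain model, linear in z
    # weight of the per-slice percentile window in the transfer.  Depth
    # adaptivity is carried by the gain fit; a non-zero blend trades the
    # stability of repeated conversion for extra per-slice contrast.
    local_blend: float = 0.0
    foreground_quantile: float = 0.75  # slice voxels above this enter the gain fit
    anchor_percentiles: tuple = (50.0, 99.0)  # cross-session foreground anchors

    def __post_init__(self):
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError("need 0 <= low < high <= 100")
        if not (0.0 <= self.local_blend <= 1.0):
            raise ValueError("local_blend must lie in [0, 1]")


def _fit_depth_gain(data: np.ndarray, params: ConversionParams) -> np.ndarray:
    """Per-slice multiplicative gain, geometric mean 1.

    ``data`` must already be offset-subtracted (a pure multiplicative
    excitation model).  The fit is linear in log-space on a robust
    background-excluded slice statistic, so the fitted trend of an already
    gain-flattened stack is exactly zero.
    """
    nz = data.shape[0]
    stat = np.empty(nz)
    for z in range(nz):
        sl = data[z].ravel()
        # inter-quantile trimmed mean: background-excluded below, and
        # insensitive to highlight clipping above
        lo_t, hi_t = np.quantile(sl, [params.foreground_quantile, 0.97])
        fg = sl[(sl >= lo_t) & (sl <= hi_t)]
        stat[z] = fg.mean() if fg.size else sl.mean()
    if np.all(stat <= 0):
        return np.ones(nz)
    zs = np.arange(nz)
    good = stat > 0
    if good.sum() > params.depth_fit_degree:
        coef = np.polyfit(zs[good], np.log(stat[good]), params.depth_fit_degree)
        logfit = np.polyval(coef, zs)
    else:
        logfit = np.log(np.clip(stat, 1e-9, None))
    logfit = logfit - logfit.mean()
    return np.exp(np.clip(logfit, -3.0, 3.0))


def _percentile_map(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        return np.zeros_like(values, dtype=np.float64)
    return np.clip((values - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def depth_adaptive_convert(stack16: ImageStack,
                           params: ConversionParams | None = None) -> ImageStack:
    """Convert a 16-bit stack to 8-bit with depth-dependent adjustment.

    Degenerate constant stacks are mapped to a constant (zero stays zero).
    """
    params = params or ConversionParams()
    data = stack16.data.astype(np.float64)
    # per-slice dark level: removes the additive floor whether it is detector
    # offset or dim scattered fluorescence, leaving a purely multiplicative
    # depth dependence for the gain fit
    offset = np.percentile(data, params.low_percentile, axis=(1, 2))
    sig = np.clip(data - offset[:, None, None], 0.0, None)
    if not (sig > 0).any():
        # constant input: preserve a constant output on the 8-bit scale
        const = float(data.ravel()[0]) if data.size else 0.0
        out = np.full(stack16.shape, np.clip(round(const / 257.0), 0, 255), np.uint8)
        return stack16.with_data(out, conversion={"degenerate": True})
    gain = _fit_depth_gain(sig, params)
    flat = sig / gain[:, None, None]

    g_hi = float(np.percentile(flat, params.high_percentile))
    if g_hi <= 0:
        g_hi = float(flat.max())

    # each slice is stretched by a single linear map whose upper window is a
    # convex blend of the whole-stack and per-slice robust percentiles
    # (monotone within the slice by construction)
    out = np.empty_like(flat)
    w = params.local_blend
    for z in range(flat.shape[0]):
        sl = flat[z]
        hi_z = g_hi
        if w > 0:
            l_hi = np.percentile(sl, params.high_percentile)
            if l_hi > 0:
                hi_z = (1 - w) * g_hi + w * l_hi
        out[z] = _percentile_map(sl, 0.0, hi_z)
    out8 = np.rint(out).astype(np.uint8)
    return stack16.with_data(out8, conversion={
        "dark_offset": offset.tolist(), "gain_curve": gain.tolist(),
        "global_high": g_hi,
        "low_high_percentiles": [params.low_percentile, params.high_percentile],
        "local_blend": w})


def cross_session_normalize(stacks: list[ImageStack],
                            params: ConversionParams | None = None,
                            reference_index: int = 0) -> list[ImageStack]:
    """Anchor fiber-foreground percentiles across sessions, then convert.

    The robust anchor pair (default 50th/99th percentile of voxels above the
    foreground quantile) of every session is mapped affinely onto the
    reference session's anchors before 16→8-bit conversion, so longitudinal
    intensity comparisons are not driven by excitation drift.
    """
    params = params or ConversionParams()
    if not stacks:
        return []

    def anchors(data):
        thr = np.quantile(data, params.foreground_quantile)
        fg = data[data >= thr]
        if fg.size == 0:
            fg = data.ravel()
        return np.percentile(fg, params.anchor_percentiles)

    ref = anchors(stacks[reference_index].data.astype(np.float64))
    out = []
    for st in stacks:
        data = st.data.astype(np.float64)
        a = anchors(data)
        if a[1] > a[0] and ref[1] > ref[0]:
            scale = (ref[1] - ref[0]) / (a[1] - a[0])
            data = (data - a[0]) * scale + ref[0]
            data = np.clip(data, 0, 65535)
        adj = st.with_data(data.astype(np.float64), anchor_map={
            "session_anchors": a.tolist(), "reference_anchors": ref.tolist()})
        out.append(depth_adaptive_convert(adj, params))
    return out
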