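"""Distance-ordered homotopic 3D thinning to a one-voxel curve skeleton.

Border voxels are deleted in increasing distance-transform order; a voxel may
only be deleted when it is a *simple point* (removal preserves both the
foreground 26-topology and the background 6-topology of its 3×3×3
neighbourhood, after Bertrand & Malandain) and not a curve endpoint.  The
result is a centred, topology-preserving curve skeleton, which is what fiber
tracing needs.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from numba import njit

# --- static neighbourhood tables for the 3x3x3 cube (flat index 0..26) -----

_COORDS = np.array([(z, y, x) for z in (-1, 0, 1) for y in (-1, 0, 1)
                    for x in (-1, 0, 1)], dtype=np.int8)
_CENTER = 13
_MANH = np.abs(_COORDS).sum(axis=1)
_IS_N26 = np.arange(27) != _CENTER
_IS_N18 = (_MANH <= 2) & (np.arange(27) != _CENTER)
_IS_N6 = _MANH == 1

_ADJ26 = np.zeros((27, 27), dtype=np.bool_)
_ADJ6 = np.zeros((27, 27), dtype=np.bool_)
for _i in range(27):
    for _j in range(27):
        if _i == _j:
            continue
        d = np.abs(_COORDS[_i] - _COORDS[_j])
        if d.max() <= 1:
            _ADJ26[_i, _j] = True
        if d.sum() == 1:
            _ADJ6[_i, _j] = True


@njit(cache=True)
def _n_components(cells, adj):
    """Connected components over the marked cells with the given adjacency."""
    n = 0
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int8)
    for s in range(27):
        if not cells[s] or visited[s]:
            continue
        n += 1
        top = 0
        stack[top] = s
        top += 1
        visited[s] = True
        while top > 0:
            top -= 1
            c = stack[top]
            for t in range(27):
                if cells[t] and not visited[t] and adj[c, t]:
                    visited[t] = True
                    stack[top] = t
                    top += 1
    return n


@njit(cache=True)
def _is_simple(nb, is_n26, is_n18, is_n6, adj26, adj6):
    """Bertrand's characterization: T26(fg)=1 and T6*(bg)=1."""
    fg = np.zeros(27, dtype=np.bool_)
    for i in range(27):
        fg[i] = nb[i] and is_n26[i]
    if _n_components(fg, adj26) != 1:
        return False
    # background 6-components within N18 that touch the center 6-face set
    bg = np.zeros(27, dtype=np.bool_)
    for i in range(27):
        bg[i] = (not nb[i]) and is_n18[i]
    visited = np.zeros(27, dtype=np.bool_)
    stack = np.empty(27, dtype=np.int8)
    n_touch = 0
    for s in range(27):
        if not bg[s] or visited[s]:
            continue
        touches = False
        top = 0
        stack[top] = s
        top += 1
        visited[s] = True
        while top > 0:
            top -= 1
            c = stack[top]
            if is_n6[c]:
                touches = True
            for t in range(27):
                if bg[t] and not visited[t] and adj6[c, t]:
                    visited[t] = True
                    stack[top] = t
                    top += 1
        if touches:
            n_touch += 1
    return n_touch == 1


@njit(cache=True)
def _thin(vol, order, is_n26, is_n18, is_n6, adj26, adj6):
    nz, ny, nx = vol.shape
    nb = np.empty(27, dtype=np.bool_)
    changed = True
    while changed:
        changed = False
        for k in range(order.shape[0]):
            z = order[k, 0]
            y = order[k, 1]
            x = order[k, 2]
            if not vol[z, y, x]:
                continue
            # collect the 3x3x3 neighbourhood
            m = 0
            n_fg = 0
            border = False
            for dz in range(-1, 2):
                for dy in range(-1, 2):
                    for dx in range(-1, 2):
                        v = vol[z + dz, y + dy, x + dx]
                        nb[m] = v
                        if v and m != 13:
                            n_fg += 1
                        if (not v) and (abs(dz) + abs(dy) + abs(dx) == 1):
                            border = True
                        m += 1
            if not border:
                continue
            if n_fg <= 1:          # endpoint or isolated voxel: preserve
                continue
            if _is_simple(nb, is_n26, is_n18, is_n6, adj26, adj6):
                vol[z, y, x] = False
                changed = True
    return vol


def skeletonize_3d(mask: np.ndarray) -> np.ndarray:
    """Curve skeleton of a 3D binary mask (1-voxel wide, topology preserving).

    Voxels are deleted outside-in (distance-transform order), so the skeleton
    stays centred in tubular structures.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise ValueError("expected a 3D mask")
    if not mask.any():
        return np.zeros_like(mask)
    vol = np.pad(mask, 1).copy()
    edt = ndi.distance_transform_edt(vol)
    zz, yy, xx = np.nonzero(vol)
    order = np.argsort(edt[zz, yy, xx], kind="stable")
    order_idx = np.column_stack([zz, yy, xx])[order].astype(np.int64)
    out = _thin(vol, order_idx, _IS_N26, _IS_N18, _IS_N6, _ADJ26, _ADJ6)
    return out[1:-1, 1:-1, 1:-1]
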