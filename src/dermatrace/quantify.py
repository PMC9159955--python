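"""Structural-plasticity read-outs from registered fiber graphs.

Computes the longitudinal metrics of cutaneous innervation: total traced
fiber length, fiber endings, intra-epidermal free endings (terminal branches
crossing the dermal–epidermal boundary surface), per-caliber-class lengths,
percent-of-baseline time courses within the volume common to all sessions,
and localized gain/loss maps between sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .core import CALIBER_THICK, CALIBER_THIN, EPIDERMAL_AF, PipelineError

__all__ = ["EpidermalSurface", "PlasticityMetrics", "ChangeMap",
           "total_fiber_length", "count_endings", "estimate_epidermal_boundary",
           "segment_epidermal_endings", "longitudinal_metrics", "diff_fiber_graphs",
           "BoundaryEstimationError"]


class BoundaryEstimationError(PipelineError):
    pass


# ---------------------------------------------------------------------------
# ROI clipping helpers
# ---------------------------------------------------------------------------

def _clip_segment_lengths(poly: np.ndarray, roi) -> float:
    """Length of a polyline inside an axis-aligned box (exact per segment)."""
    if roi is None:
        return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())
    lo = np.asarray(roi[0], float)
    hi = np.asarray(roi[1], float)
    a = poly[:-1]
    b = poly[1:]
    d = b - a
    t0 = np.zeros(len(a))
    t1 = np.ones(len(a))
    for ax in range(3):
        with np.errstate(divide="ignore", invalid="ignore"):
            tA = (lo[ax] - a[:, ax]) / d[:, ax]
            tB = (hi[ax] - a[:, ax]) / d[:, ax]
        lo_t = np.where(d[:, ax] >= 0, tA, tB)
        hi_t = np.where(d[:, ax] >= 0, tB, tA)
        still = d[:, ax] != 0
        t0 = np.where(still, np.maximum(t0, np.nan_to_num(lo_t, nan=0.0)), t0)
        t1 = np.where(still, np.minimum(t1, np.nan_to_num(hi_t, nan=1.0)), t1)
        inside = (a[:, ax] >= lo[ax]) & (a[:, ax] <= hi[ax])
        t1 = np.where(~still & ~inside, 0.0, t1)
    frac = np.clip(t1 - t0, 0.0, 1.0)
    return float((np.linalg.norm(d, axis=1) * frac).sum())


def total_fiber_length(G: nx.Graph, roi=None, caliber: str | None = None) -> float:
    """Sum of edge arc lengths (µm), clipped to an ROI box ``(lo_xyz, hi_xyz)``
    and optionally restricted to one caliber class."""
    total = 0.0
    for u, v, d in G.edges(data=True):
        if caliber is not None and G.nodes[u].get("caliber") != caliber:
            continue
        total += _clip_segment_lengths(np.asarray(d["path"], float), roi)
    return total


def count_endings(G: nx.Graph, boundary_margin_um: float = 3.0,
                  box=None) -> tuple[int, np.ndarray]:
    """Count degree-1 nodes farther than the margin from every analysis-box
    face; border-clipped endpoints are excluded.  Returns (count, positions)."""
    if boundary_margin_um < 0:
        raise ValueError("margin must be >= 0")
    if box is None:
        b = G.graph.get("box_um")
        box = ((b[0], b[1], b[2]), (b[3], b[4], b[5])) if b else None
    positions = []
    for n in G.nodes:
        if G.degree(n) != 1:
            continue
        p = G.nodes[n]["pos"]
        if box is not None:
            lo, hi = np.asarray(box[0]), np.asarray(box[1])
            if np.any(p - lo < boundary_margin_um) or np.any(hi - p < boundary_margin_um):
                continue
        positions.append(p)
    return len(positions), (np.array(positions) if positions
                            else np.zeros((0, 3)))


# ---------------------------------------------------------------------------
# Epidermal boundary surface and intra-epidermal free endings
# ---------------------------------------------------------------------------

@dataclass
class EpidermalSurface:
    """Height map z(x, y) (µm) of the dermal–epidermal boundary."""
    zmap: np.ndarray                    # (ny, nx) µm
    lateral_voxel_um: tuple[float, float]  # (dx, dy)

    def z_at(self, x_um, y_um) -> np.ndarray:
        ix = np.clip(np.round(np.asarray(x_um) / self.lateral_voxel_um[0]).astype(int),
                     0, self.zmap.shape[1] - 1)
        iy = np.clip(np.round(np.asarray(y_um) / self.lateral_voxel_um[1]).astype(int),
                     0, self.zmap.shape[0] - 1)
        return self.zmap[iy, ix]


def estimate_epidermal_boundary(labels: np.ndarray | None = None,
                                voxel_size=(0.427, 0.427, 1.0),
                                metadata_depth_um: float | None = None,
                                lateral_shape: tuple | None = None,
                                median_size: int = 9,
                                psf_debias_um: float = 1.0) -> EpidermalSurface:
    """Dermal–epidermal boundary surface from an autofluorescence label map.

    Per lateral position the deepest extent of the epidermal-autofluorescence
    band is taken and median-filtered to a smooth surface; missing columns are
    filled with the surface median.  ``metadata_depth_um`` (simulator ground
    truth) overrides the estimate.
    """
    dx, dy, dz = voxel_size
    if metadata_depth_um is not None:
        if lateral_shape is None and labels is None:
            lateral_shape = (64, 64)
        shape = lateral_shape or labels.shape[1:]
        return EpidermalSurface(np.full(shape, float(metadata_depth_um)), (dx, dy))
    if labels is None or not (labels == EPIDERMAL_AF).any():
        raise BoundaryEstimationError(
            "no epidermal autofluorescence signal and no metadata depth")
    af = labels == EPIDERMAL_AF
    nz = labels.shape[0]
    zidx = np.arange(nz)[:, None, None]
    deepest = np.max(np.where(af, zidx, -1), axis=0).astype(float)
    valid = deepest >= 0
    fill = np.median(deepest[valid])
    deepest[~valid] = fill
    # the dermal–epidermal junction is laterally smooth: columns whose depth
    # is a gross outlier (appendage shafts leaking into the band class) are
    # replaced by the global level before smoothing
    mad = 1.4826 * np.median(np.abs(deepest[valid] - fill)) if valid.any() else 0.0
    outlier = np.abs(deepest - fill) > 4.0 * mad + 2.0
    deepest[outlier] = fill
    # deepest voxel index → lower face of that voxel, in µm; the classified
    # band extends ~one axial PSF extent past the true edge, so debias
    zmap = (deepest + 1.0) * dz - psf_debias_um
    zmap = ndi.median_filter(zmap, size=median_size)
    return EpidermalSurface(zmap, (dx, dy))


def segment_epidermal_endings(G: nx.Graph, surface: EpidermalSurface,
                              margin_um: float = 0.0,
                              require_crossing: bool = False
                              ) -> tuple[nx.Graph, int]:
    """Intra-epidermal free endings: terminal branches whose end node lies
    above (shallower than) the boundary surface.

    ``margin_um`` requires the ending to penetrate at least that far above
    the surface — set it to the registration error budget when graphs from
    registered sessions are compared.  With ``require_crossing`` the terminal
    branch must additionally emanate from below the surface (a free ending
    is the terminal branch of a fiber crossing the junction), which rejects
    image artefacts that float entirely inside the band.  Returns the
    subgraph of those terminal branches and their count.
    """
    ending_nodes = []
    sub_nodes = set()
    for n in G.nodes:
        if G.degree(n) != 1:
            continue
        p = G.nodes[n]["pos"]
        if p[2] >= float(surface.z_at(p[0], p[1])) - margin_um:
            continue
        # walk from the ending to the last branch point
        branch_nodes = []
        prev, cur = None, n
        while True:
            branch_nodes.append(cur)
            nbrs = [m for m in G.neighbors(cur) if m != prev]
            if G.degree(cur) >= 3 or not nbrs:
                break
            prev, cur = cur, nbrs[0]
        if require_crossing:
            proximal = G.nodes[branch_nodes[-1]]["pos"]
            crosses = proximal[2] >= float(surface.z_at(proximal[0], proximal[1]))
            if not crosses:
                # also accept branches whose polyline dips below the surface
                for a, b in zip(branch_nodes[:-1], branch_nodes[1:]):
                    path = G.edges[a, b]["path"]
                    zs = np.asarray(path)[:, 2]
                    if (zs >= surface.z_at(path[0][0], path[0][1])).any():
                        crosses = True
                        break
            if not crosses:
                continue
        ending_nodes.append(n)
        sub_nodes.update(branch_nodes)
    sub = G.subgraph(sub_nodes).copy()
    sub.graph["epidermal_ending_nodes"] = ending_nodes
    return sub, len(ending_nodes)


# ---------------------------------------------------------------------------
# Longitudinal metrics
# ---------------------------------------------------------------------------

@dataclass
class PlasticityMetrics:
    session: object
    total_length_um: float
    n_endings: int
    n_epidermal_endings: int
    thin_length_um: float
    thick_length_um: float
    percent_of_baseline: dict = field(default_factory=dict)

    def to_row(self):
        row = {"session": self.session,
               "total_length_um": self.total_length_um,
               "n_endings": self.n_endings,
               "n_epidermal_endings": self.n_epidermal_endings,
               "thin_length_um": self.thin_length_um,
               "thick_length_um": self.thick_length_um}
        for k, v in self.percent_of_baseline.items():
            row[f"{k}_pct_baseline"] = v
        return row


def longitudinal_metrics(graphs: list[nx.Graph], baseline_index: int = 0,
                         common_roi=None, surface: EpidermalSurface | None = None,
                         boundary_margin_um: float = 3.0,
                         surface_margin_um: float = 3.0) -> list[PlasticityMetrics]:
    """Per-session structural metrics, each also as percent of baseline.

    All graphs must already be registered into a common frame; metrics are
    evaluated inside ``common_roi`` only.  A zero baseline value yields a
    ``None`` percentage (undefined), not a division error.
    """
    raw = []
    for G in graphs:
        roi_box = common_roi
        total = total_fiber_length(G, roi_box)
        thin = total_fiber_length(G, roi_box, CALIBER_THIN)
        thick = total_fiber_length(G, roi_box, CALIBER_THICK)
        box = roi_box if roi_box is not None else None
        n_end, _ = count_endings(G, boundary_margin_um, box)
        n_epi = 0
        if surface is not None:
            sub, n_epi_all = segment_epidermal_endings(G, surface, surface_margin_um,
                                                       require_crossing=True)
            if roi_box is not None:
                lo, hi = np.asarray(roi_box[0]), np.asarray(roi_box[1])
                n_epi = sum(1 for n in sub.graph["epidermal_ending_nodes"]
                            if np.all(G.nodes[n]["pos"] >= lo)
                            and np.all(G.nodes[n]["pos"] <= hi))
            else:
                n_epi = n_epi_all
        raw.append(dict(total_length_um=total, thin_length_um=thin,
                        thick_length_um=thick, n_endings=n_end,
                        n_epidermal_endings=n_epi))
    base = raw[baseline_index]
    out = []
    for sess, r in enumerate(raw):
        pct = {}
        for key in ("total_length_um", "thin_length_um", "thick_length_um",
                    "n_endings", "n_epidermal_endings"):
            b = base[key]
            pct[key.replace("_um", "")] = (100.0 * r[key] / b) if b else None
        out.append(PlasticityMetrics(sess, r["total_length_um"], r["n_endings"],
                                     r["n_epidermal_endings"], r["thin_length_um"],
                                     r["thick_length_um"], pct))
    return out


def metrics_table(metrics: list[PlasticityMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in metrics])


# ---------------------------------------------------------------------------
# Gain/loss change maps
# ---------------------------------------------------------------------------

@dataclass
class ChangeMap:
    """Edge-level diff between a reference and a registered later graph.

    ``stable_ref``/``lost`` partition the reference edges; ``stable_new``/
    ``gained`` partition the new graph's edges.  ``match_distance`` maps each
    edge key to its median point-to-curve distance (µm).
    """
    stable_ref: list
    lost: list
    stable_new: list
    gained: list
    match_distance: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status, edges in (("stable", self.stable_ref), ("lost", self.lost)):
            rows += [{"graph": "reference", "edge": str(e), "status": status,
                      "match_distance_um": self.match_distance.get(("ref", e))}
                     for e in edges]
        for status, edges in (("stable", self.stable_new), ("gained", self.gained)):
            rows += [{"graph": "new", "edge": str(e), "status": status,
                      "match_distance_um": self.match_distance.get(("new", e))}
                     for e in edges]
        return pd.DataFrame(rows)


def _edge_samples(G, step=1.0):
    keys, pts, owners = [], [], []
    for u, v, d in G.edges(data=True):
        poly = np.asarray(d["path"], float)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        n = max(2, int(np.ceil(seg.sum() / step)) + 1)
        t = np.linspace(0, 1, n)
        cum = np.concatenate([[0], np.cumsum(seg)])
        total = cum[-1] if cum[-1] > 0 else 1.0
        samp = np.empty((n, 3))
        for k, tk in enumerate(t * total):
            i = np.searchsorted(cum, tk, side="right") - 1
            i = min(i, len(seg) - 1)
            f = (tk - cum[i]) / seg[i] if seg[i] > 0 else 0.0
            samp[k] = poly[i] * (1 - f) + poly[i + 1] * f
        keys.append((u, v))
        pts.append(samp)
        owners += [(u, v)] * n
    return keys, pts


def diff_fiber_graphs(graph_ref: nx.Graph, graph_new: nx.Graph,
                      match_tol_um: float = 3.0) -> ChangeMap:
    """Classify edges as stable / lost / gained by bidirectional polyline
    proximity: an edge matches when the median distance of its sample points
    to the other graph's curves is ≤ ``match_tol_um``."""
    from scipy.spatial import cKDTree
    keys_r, pts_r = _edge_samples(graph_ref)
    keys_n, pts_n = _edge_samples(graph_new)
    dist = {}

    def classify(keys, pts, other_pts):
        stable, un = [], []
        if other_pts:
            tree = cKDTree(np.vstack(other_pts))
        else:
            tree = None
        for k, p in zip(keys, pts):
            if tree is None:
                med = np.inf
            else:
                d, _ = tree.query(p, workers=-1)
                med = float(np.median(d))
            yield k, med

    for k, med in classify(keys_r, pts_r, pts_n):
        dist[("ref", k)] = med
    for k, med in classify(keys_n, pts_n, pts_r):
        dist[("new", k)] = med
    stable_ref = [k for k in keys_r if dist[("ref", k)] <= match_tol_um]
    lost = [k for k in keys_r if dist[("ref", k)] > match_tol_um]
    stable_new = [k for k in keys_n if dist[("new", k)] <= match_tol_um]
    gained = [k for k in keys_n if dist[("new", k)] > match_tol_um]
    return ChangeMap(stable_ref, lost, stable_new, gained, dist)
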