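"""Shared containers and file I/O for the skin-innervation pipeline.

Conventions used throughout the package
---------------------------------------
* Image arrays are stored ``(z, y, x)`` — one TIFF page per z plane.
* Voxel indices are 0-based; z index 0 is the skin surface (shallowest plane).
* Physical positions are ``(x, y, z)`` triples in micrometres:
  ``position = index * voxel_size``.
* All lengths are reported in micrometres.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

# Voxel classes of a LabelVolume.
BACKGROUND = 0
FIBER = 1
EPIDERMAL_AF = 2
APPENDAGE = 3
LABEL_NAMES = {BACKGROUND: "background", FIBER: "fiber",
               EPIDERMAL_AF: "epidermal_af", APPENDAGE: "appendage"}

#: lateral/axial voxel size of the acquisition this pipeline targets (µm)
DEFAULT_VOXEL_SIZE = (0.427, 0.427, 1.0)


class PipelineError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PipelineError):
    pass


class GeometryError(PipelineError):
    pass


def derive_seed(master_seed: int, *tags) -> int:
    """Derive a stage seed from a master seed and string tags.

    Stable across runs and platforms, independent of the number of other
    stages, and always below 2**31.
    """
    key = ":".join([str(int(master_seed))] + [str(t) for t in tags])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ImageStack:
    """A 3D scalar voxel grid with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(z, y, x)``.
    voxel_size
        ``(dx, dy, dz)`` in µm.
    session
        Optional session label for longitudinal series.
    meta
        Free-form provenance (seeds, tile grid position, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    session: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected 3D (z, y, x) data, got {self.data.ndim}D")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be positive")

    @property
    def shape(self):  # (z, y, x)
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in µm (index span × voxel size)."""
        nz, ny, nx = self.data.shape
        dx, dy, dz = self.voxel_size
        return (nx * dx, ny * dy, nz * dz)

    def with_data(self, data: np.ndarray, **meta) -> "ImageStack":
        return ImageStack(data, self.voxel_size, self.session, {**self.meta, **meta})

    # ------------------------------------------------------------------ I/O
    def save(self, path) -> None:
        """Write a multi-page TIFF (one page per z plane) + JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data, photometric="minisblack")
        sidecar = {
            "voxel_size_um": list(self.voxel_size),
            "session": self.session,
            "meta": _jsonable(self.meta),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "ImageStack":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        voxel_size = DEFAULT_VOXEL_SIZE
        session = None
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
            voxel_size = tuple(info.get("voxel_size_um", voxel_size))
            session = info.get("session")
            meta = info.get("meta", {})
        return cls(data, voxel_size, session, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Ground-truth skeletons (SWC-style node tables)
# ---------------------------------------------------------------------------

#: SWC structure-type codes used to encode caliber class
SWC_TYPE_THIN = 3   # dendrite code reused for thin (nociceptor-like) fibers
SWC_TYPE_THICK = 2  # axon code reused for thick (Aβ-like) fibers
CALIBER_THIN = "thin"
CALIBER_THICK = "thick"


@dataclass
class Skeleton:
    """A forest of fiber centerlines with per-node radii.

    ``nodes`` is an SWC-like table with columns
    ``id, parent, x, y, z, radius, tree_id, caliber`` (positions/radii in µm,
    ``parent == -1`` for roots).  The epidermal flag is *derived*: a node is
    epidermal iff its z is shallower than ``epidermal_boundary_um``.
    """

    nodes: pd.DataFrame
    epidermal_boundary_um: float

    @classmethod
    def empty(cls, boundary: float = 0.0) -> "Skeleton":
        cols = ["id", "parent", "x", "y", "z", "radius", "tree_id", "caliber"]
        return cls(pd.DataFrame(columns=cols), boundary)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tree_ids(self) -> np.ndarray:
        return np.unique(self.nodes["tree_id"].to_numpy()) if len(self.nodes) else np.array([], int)

    def epidermal_flags(self) -> np.ndarray:
        """True for nodes shallower than the epidermal boundary."""
        return self.nodes["z"].to_numpy() < self.epidermal_boundary_um

    def segments(self) -> np.ndarray:
        """(n, 2, 3) array of parent→child segments in µm."""
        df = self.nodes
        if df.empty:
            return np.zeros((0, 2, 3))
        pos = df.set_index("id")[["x", "y", "z"]]
        child = df[df["parent"] >= 0]
        a = pos.loc[child["parent"]].to_numpy(float)
        b = child[["x", "y", "z"]].to_numpy(float)
        return np.stack([a, b], axis=1)

    def total_length(self) -> float:
        """Total centerline length (µm): sum of parent→child Euclidean spans."""
        seg = self.segments()
        if not len(seg):
            return 0.0
        return float(np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum())

    def subset_trees(self, keep_ids) -> "Skeleton":
        keep = set(int(t) for t in keep_ids)
        df = self.nodes[self.nodes["tree_id"].isin(keep)].reset_index(drop=True)
        return Skeleton(df, self.epidermal_boundary_um)

    def caliber_of_tree(self) -> dict[int, str]:
        if self.nodes.empty:
            return {}
        return dict(self.nodes.groupby("tree_id")["caliber"].first())

    # ------------------------------------------------------------------ I/O
    def save_swc(self, path) -> None:
        """Write SWC (one forest file; type field encodes caliber) plus a
        companion CSV with per-node epidermal flags keyed by node id."""
        path = Path(path)
        df = self.nodes
        with open(path, "w") as fh:
            fh.write("# SWC forest; type 3=thin caliber, 2=thick caliber\n")
            for _, row in df.iterrows():
                t = SWC_TYPE_THIN if row["caliber"] == CALIBER_THIN else SWC_TYPE_THICK
                fh.write(f"{int(row['id'])} {t} {row['x']:.4f} {row['y']:.4f} "
                         f"{row['z']:.4f} {row['radius']:.4f} {int(row['parent'])}\n")
        flags = pd.DataFrame({"id": df["id"].astype(int),
                              "epidermal": self.epidermal_flags().astype(int)})
        flags.to_csv(path.with_suffix(".flags.csv"), index=False)

    @classmethod
    def load_swc(cls, path, epidermal_boundary_um: float) -> "Skeleton":
        path = Path(path)
        rows = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i, t, x, y, z, r, p = line.split()
            rows.append((int(i), int(p), float(x), float(y), float(z), float(r),
                         CALIBER_THIN if int(t) == SWC_TYPE_THIN else CALIBER_THICK))
        df = pd.DataFrame(rows, columns=["id", "parent", "x", "y", "z", "radius", "caliber"])
        # tree ids: connected components by parent links
        tree = {}
        parent = dict(zip(df["id"], df["parent"]))
        def root_of(i):
            while parent.get(i, -1) >= 0:
                i = parent[i]
            return i
        roots = {i: root_of(i) for i in df["id"]}
        order = {r: k for k, r in enumerate(dict.fromkeys(roots.values()))}
        df["tree_id"] = [order[roots[i]] for i in df["id"]]
        return cls(df, epidermal_boundary_um)


def save_label_volume(labels: np.ndarray, path) -> None:
    """LabelVolume → 8-bit multi-page TIFF."""
    tifffile.imwrite(Path(path), labels.astype(np.uint8))


def load_label_volume(path) -> np.ndarray:
    return tifffile.imread(Path(path))


def read_seed_csv(path) -> dict[int, np.ndarray]:
    """Read seed voxels from a CSV of ``x, y, z, class`` (voxel indices)."""
    df = pd.read_csv(path)
    out = {}
    for cls_, grp in df.groupby("class"):
        out[int(cls_)] = grp[["z", "y", "x"]].to_numpy(int)
    return out


def check_finite(arr, name="array"):
    if not np.all(np.isfinite(arr)):
        warnings.warn(f"{name} contains non-finite values")
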