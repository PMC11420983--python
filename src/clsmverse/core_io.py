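"""Shared data model, coordinate conventions and readers/writers.

Coordinate conventions
----------------------
Voxel indices are 0-based. World coordinates (mm) are obtained as
``world = affine @ (i, j, k, 1)``, i.e. the affine maps voxel *centres* to
world space. A world point belongs to the voxel whose centre is nearest,
with ties broken upward: in the voxel frame the cell of voxel ``v`` is the
half-open cube ``v + [-0.5, 0.5)`` per axis. A point exactly on a ``+0.5``
boundary therefore belongs to the higher-index voxel.

Streamlines are always held in world mm; conversion to voxel space happens
only at traversal time, so the on-disk dialect (TRK, TCK or the plain
``jsonl-polyline`` text dialect) does not affect downstream geometry.

Precision note: jsonl-polyline round-trips streamline coordinates at full
double precision (<1e-6 mm). TRK/TCK store float32, so round-trips through
those dialects are exact only to ~1e-4 mm at brain-scale coordinates.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger("clsmverse")

#: The six language-related tracts used throughout the pipeline.
DEFAULT_TRACTS = ("AF", "FAT", "SLF3", "ILF", "IFOF", "UF")

TRACTOGRAM_DIALECTS = ("trk", "tck", "jsonl-polyline")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


@dataclass
class VolumeGrid:
    """A 3D scalar or integer-label image with a grid-to-world affine."""

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {self.values.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self._inv = np.linalg.inv(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis: column norms of the linear part of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def is_label_volume(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer) or self.values.dtype == bool

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to continuous voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self._inv[:3, :3].T + self._inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world-mm coordinates of voxel centres."""
        ijk = np.atleast_2d(np.asarray(idx, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def like(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values=values, affine=self.affine.copy())


def point_to_voxel(point: Sequence[float], grid: VolumeGrid) -> tuple[int, int, int] | None:
    """Voxel index of a world point under the half-open nearest-centre rule.

    Returns ``None`` when the point falls outside the grid.
    """
    u = grid.world_to_voxel(point)[0]
    idx = np.floor(u + 0.5).astype(int)
    if np.all(idx >= 0) and np.all(idx < np.array(grid.shape)):
        return int(idx[0]), int(idx[1]), int(idx[2])
    return None


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI volume. Integer on-disk dtypes are kept (label volumes)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj)
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    return VolumeGrid(values=values, affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path: str | os.PathLike) -> None:
    values = grid.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    nib.save(nib.Nifti1Image(values, grid.affine), str(path))


@dataclass
class LesionMask:
    """A binary lesion mask; binarization is idempotent."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values)
        self.grid = self.grid.like((vals > 0).astype(np.uint8))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.values.astype(bool)

    @property
    def lesion_volume_cc(self) -> float:
        """Lesion size in cubic centimetres."""
        return float(self.mask.sum()) * self.grid.voxel_volume / 1000.0


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


@dataclass
class ParcelRecord:
    id: int
    name: str
    centroid_mm: np.ndarray
    volume_voxels: int


@dataclass
class ParcelAtlas:
    """Integer label volume plus per-parcel records and named ROI subsets."""

    labels: VolumeGrid
    parcels: dict[int, ParcelRecord]
    roi_subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels.is_label_volume:
            raise ValueError("atlas labels must be an integer volume")
        present = set(np.unique(self.labels.values)) - {0}
        if present != set(self.parcels):
            raise ValueError("every nonzero label needs exactly one parcel record")
        corners = self.labels.voxel_to_world(
            np.array([[0, 0, 0], [s - 1 for s in self.labels.shape]], dtype=float)
        )
        lo, hi = np.minimum(*corners), np.maximum(*corners)
        for rec in self.parcels.values():
            c = np.asarray(rec.centroid_mm, dtype=float)
            if np.any(c < lo - 1e-6) or np.any(c > hi + 1e-6):
                raise ValueError(f"centroid of parcel {rec.id} outside world bounding box")
        for roi, ids in self.roi_subsets.items():
            if not set(ids) <= set(self.parcels):
                raise ValueError(f"ROI subset {roi!r} references unknown parcel ids")

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.parcels))

    @classmethod
    def from_labels(
        cls,
        labels: VolumeGrid,
        names: Mapping[int, str] | None = None,
        roi_subsets: Mapping[str, Sequence[int]] | None = None,
    ) -> "ParcelAtlas":
        """Build records (centroid, voxel count) from a label volume."""
        records: dict[int, ParcelRecord] = {}
        vals = labels.values
        for pid in np.unique(vals):
            pid = int(pid)
            if pid == 0:
                continue
            idx = np.argwhere(vals == pid)
            centroid = labels.voxel_to_world(idx).mean(axis=0)
            name = names[pid] if names else f"P{pid:03d}"
            records[pid] = ParcelRecord(pid, name, centroid, int(idx.shape[0]))
        subs = {k: tuple(int(i) for i in v) for k, v in (roi_subsets or {}).items()}
        return cls(labels=labels, parcels=records, roi_subsets=subs)


# ---------------------------------------------------------------------------
# tractograms
# ---------------------------------------------------------------------------


@dataclass
class Tractogram:
    """World-mm polylines with an optional bundle label per streamline."""

    streamlines: list[np.ndarray]
    bundles: list[str | None] | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for sl in self.streamlines:
            pts = np.asarray(sl, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
                raise ValueError("each streamline needs >=2 world-space 3D points")
            if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
                raise ValueError("consecutive streamline points must be distinct")
            cleaned.append(pts)
        self.streamlines = cleaned
        if self.bundles is not None and len(self.bundles) != len(self.streamlines):
            raise ValueError("one bundle label per streamline required")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices: Sequence[int]) -> "Tractogram":
        sls = [self.streamlines[i] for i in indices]
        bundles = [self.bundles[i] for i in indices] if self.bundles is not None else None
        return Tractogram(sls, bundles)


@dataclass
class TractDefinition:
    """A named bundle: a voxel mask plus its member streamlines."""

    name: str
    mask: VolumeGrid
    streamlines: list[np.ndarray]

    def __post_init__(self) -> None:
        if not np.any(self.mask.values):
            raise ValueError(f"tract {self.name!r} has an empty voxel mask")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".trk":
        return "trk"
    if suffix == ".tck":
        return "tck"
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl-polyline"
    raise ValueError(f"cannot infer tractogram dialect from {path.name!r}")


def read_tractogram(path: str | os.PathLike, dialect: str | None = None) -> Tractogram:
    """Read a tractogram; points come back in world mm for every dialect.

    Bundle labels survive only the jsonl-polyline dialect; TRK/TCK carry
    geometry only.
    """
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect not in TRACTOGRAM_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {TRACTOGRAM_DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "jsonl-polyline":
        streamlines, bundles = [], []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    pts = np.asarray(rec["points"], dtype=float)
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(f"malformed jsonl-polyline record on line {line_no}") from exc
                streamlines.append(pts)
                bundles.append(rec.get("bundle"))
        return Tractogram(streamlines, bundles)
    tfile = nib.streamlines.load(str(path))  # points in RAS mm
    sls = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]
    return Tractogram(sls, None)


def write_tractogram(tg: Tractogram, path: str | os.PathLike, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = _infer_dialect(path)
    if dialect == "jsonl-polyline":
        with open(path, "w") as fh:
            for i, sl in enumerate(tg.streamlines):
                bundle = tg.bundles[i] if tg.bundles is not None else None
                fh.write(json.dumps({"bundle": bundle, "points": sl.tolist()}) + "\n")
        return
    if dialect not in ("trk", "tck"):
        raise ValueError(f"unknown dialect {dialect!r}")
    nt = nib.streamlines.Tractogram(tg.streamlines, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(nt, str(path))


# ---------------------------------------------------------------------------
# participants and connectomes
# ---------------------------------------------------------------------------

NAMING_MAX = 60  # Boston Naming Test maximum
TOKEN_MAX = 45  # Token Test maximum


@dataclass
class ParticipantRecord:
    id: str
    scanner: str
    naming: float
    token: float
    lesion_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.naming <= NAMING_MAX:
            raise ValueError(f"naming score {self.naming} outside [0, {NAMING_MAX}]")
        if not 0 <= self.token <= TOKEN_MAX:
            raise ValueError(f"token score {self.token} outside [0, {TOKEN_MAX}]")


@dataclass
class Connectome:
    """Symmetric non-negative node x node matrix tagged by approach and scale."""

    node_ids: tuple[int, ...]
    weights: np.ndarray
    approach: str  # direct | indirect
    scale: str  # whole | roi

    def __post_init__(self) -> None:
        self.node_ids = tuple(int(i) for i in self.node_ids)
        W = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if W.shape != (n, n):
            raise ValueError("weight matrix shape must match node ids")
        if not np.array_equal(W, W.T):
            raise ValueError("connectome weights must be exactly symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("connectome diagonal must be zero")
        if np.any(W < 0):
            raise ValueError("connectome weights must be non-negative")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def upper_values(self) -> np.ndarray:
        """Vectorized upper triangle (the edge vector used in similarity/CCA)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def edge_names(self) -> list[str]:
        iu = np.triu_indices(self.n_nodes, k=1)
        return [f"{self.node_ids[i]}-{self.node_ids[j]}" for i, j in zip(*iu)]


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg
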