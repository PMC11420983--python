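"""Tract-based disconnection metrics.

Eight metrics per participant per tract:

* direct, measured on the reconstructed bundle: tract volume (``VOL``, mm^3),
  streamline number (``SN``), and the four diffusion scalars ``FA``, ``MD``,
  ``AD``, ``RD`` averaged over the tract's voxels;
* indirect, measured from the lesion mask alone: lesion percentage (``LP``,
  percent of tract voxels inside the lesion) and disconnection percentage
  (``DP``, percent of the tract's streamlines passing through the lesion).

A streamline "passes through" the lesion iff its voxel traversal contains at
least one lesioned voxel -- a binary pass criterion with no partial-volume
weighting. Traversal uses an exact incremental grid walk (3D DDA) over the
half-open voxel cells defined in :mod:`clsmverse.core_io`.

Percentages are reported on a 0-100 scale throughout.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import LesionMask, TractDefinition, VolumeGrid

logger = logging.getLogger("clsmverse")

#: Column order of the tract metric matrix.
METRICS = ("VOL", "SN", "FA", "MD", "AD", "RD", "DP", "LP")
DIRECT_METRICS = ("VOL", "SN", "FA", "MD", "AD", "RD")
INDIRECT_METRICS = ("DP", "LP")


# ---------------------------------------------------------------------------
# geometric kernel
# ---------------------------------------------------------------------------


def _segment_cells(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int, int]]:
    """Cells crossed by the segment a->b, in *shifted* voxel coordinates.

    Shifted coordinates place cell (i,j,k) at the half-open cube
    [i,i+1) x [j,j+1) x [k,k+1), so ``floor`` gives the cell index.
    Amanatides-Woo incremental traversal; both endpoint cells included.
    """
    cell = np.floor(a).astype(np.int64)
    end = np.floor(b).astype(np.int64)
    cells = [(int(cell[0]), int(cell[1]), int(cell[2]))]
    if np.all(cell == end):
        return cells
    d = b - a
    step = np.sign(d).astype(np.int64)
    tmax = np.full(3, np.inf)
    tdelta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > 0:
            tdelta[ax] = 1.0 / d[ax]
            tmax[ax] = (cell[ax] + 1 - a[ax]) / d[ax]
        elif d[ax] < 0:
            tdelta[ax] = -1.0 / d[ax]
            tmax[ax] = (cell[ax] - a[ax]) / d[ax]
    n_cross = int(np.abs(end - cell).sum())
    for _ in range(n_cross):
        ax = int(np.argmin(tmax))
        cell[ax] += step[ax]
        tmax[ax] += tdelta[ax]
        cells.append((int(cell[0]), int(cell[1]), int(cell[2])))
        if np.all(cell == end):
            break
    if cells[-1] != (int(end[0]), int(end[1]), int(end[2])):  # numeric tie guard
        cells.append((int(end[0]), int(end[1]), int(end[2])))
    return cells


def streamline_traversal(streamline: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    """Ordered unique voxels whose half-open cells the streamline intersects.

    Parameters
    ----------
    streamline : (n, 3) array of world-mm points, n >= 2.
    grid : the reference grid.

    Returns
    -------
    (k, 3) int array of voxel indices in traversal order; voxels outside the
    grid are dropped. Zero-length segments are skipped with a warning.
    """
    pts = np.asarray(streamline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("streamline needs >=2 points")
    u = grid.world_to_voxel(pts) + 0.5  # shifted voxel coords
    out: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    shape = grid.shape
    for i in range(len(u) - 1):
        a, b = u[i], u[i + 1]
        if np.all(a == b):
            warnings.warn("zero-length streamline segment skipped", stacklevel=2)
            continue
        for c in _segment_cells(a, b):
            if c in seen:
                continue
            seen.add(c)
            if 0 <= c[0] < shape[0] and 0 <= c[1] < shape[1] and 0 <= c[2] < shape[2]:
                out.append(c)
    return np.array(out, dtype=np.int64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# per-tract metrics
# ---------------------------------------------------------------------------


def lesion_percentage(tract: TractDefinition, lesion: LesionMask) -> float:
    """Percent of the tract's voxels that fall within the lesion mask."""
    tmask = tract.mask.values.astype(bool)
    n_tract = int(tmask.sum())
    if n_tract == 0:
        raise ValueError(f"tract {tract.name!r} has an empty mask")
    if tmask.shape != lesion.mask.shape:
        raise ValueError("tract and lesion must share a grid")
    return 100.0 * float(np.logical_and(tmask, lesion.mask).sum()) / n_tract


def disconnection_percentage(
    tract: TractDefinition,
    lesion: LesionMask,
    traversals: Sequence[np.ndarray] | None = None,
) -> float:
    """Percent of the tract's streamlines whose traversal enters the lesion.

    ``traversals`` may carry precomputed voxel traversals (one per member
    streamline) to avoid re-walking the atlas bundle for every participant.
    """
    if tract.n_streamlines == 0:
        raise ValueError(f"tract {tract.name!r} has no streamlines")
    if traversals is None:
        traversals = [streamline_traversal(sl, lesion.grid) for sl in tract.streamlines]
    mask = lesion.mask
    severed = 0
    for trav in traversals:
        if len(trav) and mask[trav[:, 0], trav[:, 1], trav[:, 2]].any():
            severed += 1
    return 100.0 * severed / len(traversals)


def mean_scalar(tract: TractDefinition, scalar_map: VolumeGrid) -> float:
    """Arithmetic mean of a scalar map over the tract's voxels."""
    tmask = tract.mask.values.astype(bool)
    if not tmask.any():
        raise ValueError(f"tract {tract.name!r} has an empty mask")
    if tmask.shape != scalar_map.shape:
        raise ValueError("tract and scalar map must share a grid")
    return float(scalar_map.values[tmask].mean())


def tract_volume(tract: TractDefinition) -> float:
    """Number of tract voxels times the voxel volume, in mm^3."""
    return float(tract.mask.values.astype(bool).sum()) * tract.mask.voxel_volume


# ---------------------------------------------------------------------------
# cohort-level matrix
# ---------------------------------------------------------------------------


def mask_from_traversals(traversals: Iterable[np.ndarray], grid: VolumeGrid) -> VolumeGrid:
    """Binary union of voxel traversals, as a mask on ``grid``."""
    mask = np.zeros(grid.shape, dtype=np.uint8)
    for trav in traversals:
        if len(trav):
            mask[trav[:, 0], trav[:, 1], trav[:, 2]] = 1
    return grid.like(mask)


def build_matrix(cohort, on_intact_bundle: bool = False) -> pd.DataFrame:
    """Participants x (tract, metric) table for a synthetic cohort.

    Direct metrics (VOL, SN, FA, MD, AD, RD) are computed on the post-lesion
    bundle: streamlines severed by the lesion are removed and the tract mask
    is recomputed from the survivors, emulating per-participant tractography.
    When every streamline of a tract is severed the tract is unreconstructable
    and its direct metrics are missing (NaN), while DP/LP remain defined.
    With ``on_intact_bundle=True`` direct metrics use the intact atlas bundle
    instead. DP's denominator is always the atlas streamline count.
    """
    scalar_names = ("FA", "MD", "AD", "RD")
    records = []
    index = []
    for i, pid in enumerate(cohort.participants["id"]):
        lesion = cohort.lesions[i]
        mask = lesion.mask
        maps = cohort.scalar_maps(i)
        row: dict[tuple[str, str], float] = {}
        for tract in cohort.tract_defs:
            travs = cohort.traversals[tract.name]
            hit = [
                len(t) > 0 and bool(mask[t[:, 0], t[:, 1], t[:, 2]].any()) for t in travs
            ]
            n_severed = int(np.sum(hit))
            row[(tract.name, "DP")] = 100.0 * n_severed / len(travs)
            row[(tract.name, "LP")] = lesion_percentage(tract, lesion)
            if on_intact_bundle:
                kept = list(range(len(travs)))
            else:
                kept = [k for k, h in enumerate(hit) if not h]
            if not kept:
                for m in DIRECT_METRICS:
                    row[(tract.name, m)] = np.nan
                logger.info(
                    "participant=%s stage=tract_metrics tract=%s fully disconnected; "
                    "direct metrics missing",
                    pid,
                    tract.name,
                )
                continue
            kept_mask = mask_from_traversals([travs[k] for k in kept], lesion.grid)
            kept_tract = TractDefinition(
                name=tract.name,
                mask=kept_mask,
                streamlines=[tract.streamlines[k] for k in kept],
            )
            row[(tract.name, "VOL")] = tract_volume(kept_tract)
            row[(tract.name, "SN")] = float(len(kept))
            for m in scalar_names:
                row[(tract.name, m)] = mean_scalar(kept_tract, maps[m])
        records.append(row)
        index.append(pid)
    columns = pd.MultiIndex.from_product(
        [[t.name for t in cohort.tract_defs], METRICS], names=["tract", "metric"]
    )
    df = pd.DataFrame(records, index=pd.Index(index, name="participant"))
    return df.reindex(columns=columns)


def matrix_to_long(df: pd.DataFrame) -> pd.DataFrame:
    """Tidy long form: participant, tract, metric, value."""
    long = df.stack(["tract", "metric"], future_stack=True).rename("value").reset_index()
    return long
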