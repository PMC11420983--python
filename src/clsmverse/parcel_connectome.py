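"""Parcel-based connectomes: direct (streamline counts) and indirect
(lesion-preserved streamline counts), at whole-brain or ROI scale.

Streamline-to-parcel assignment uses the *end* criterion: only the atlas
label at each endpoint's voxel counts. A streamline contributes to an edge
iff both endpoints land in distinct nonzero parcels. The indirect connectome
removes every streamline that passes through the lesion (binary *pass*
criterion on its voxel traversal) and counts the preserved streamlines per
parcel pair.

The direct connectome optionally corrects raw counts for parcel distance and
volume. The exact correction used by common probabilistic-tractography
post-processing is not standardised, so three variants are exposed:

* ``"off"``    -- raw counts ``w_ij = n_ij``;
* ``"volume"`` -- ``w_ij = n_ij / sqrt(v_i * v_j)`` (parcel voxel counts);
* ``"full"``   -- ``w_ij = n_ij * d_ij / sqrt(v_i * v_j)`` with ``d_ij`` the
  Euclidean centroid distance in mm (longer connections are harder to track,
  larger parcels collect more seeds).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .core_io import Connectome, LesionMask, ParcelAtlas, Tractogram, point_to_voxel
from .tract_metrics import streamline_traversal

logger = logging.getLogger("clsmverse")

CORRECTIONS = ("off", "volume", "full")


def assign_endpoints(tractogram: Tractogram, atlas: ParcelAtlas) -> np.ndarray:
    """Parcel label of each streamline's first and last point (0 = none).

    Returns an (n, 2) int array. Endpoints outside the grid or in background
    map to 0.
    """
    labels = atlas.labels.values
    out = np.zeros((len(tractogram), 2), dtype=np.int64)
    for i, sl in enumerate(tractogram.streamlines):
        for j, point in enumerate((sl[0], sl[-1])):
            vox = point_to_voxel(point, atlas.labels)
            if vox is not None:
                out[i, j] = int(labels[vox])
    return out


def _pair_counts(
    endpoints: np.ndarray,
    atlas: ParcelAtlas,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    ids = atlas.ids
    index = {pid: k for k, pid in enumerate(ids)}
    n = len(ids)
    W = np.zeros((n, n))
    for s, (a, b) in enumerate(endpoints):
        if keep is not None and not keep[s]:
            continue
        if a == 0 or b == 0 or a == b:
            continue
        i, j = index[int(a)], index[int(b)]
        W[i, j] += 1
        W[j, i] += 1
    return W


def _apply_correction(W: np.ndarray, atlas: ParcelAtlas, correction: str) -> np.ndarray:
    if correction == "off":
        return W
    ids = atlas.ids
    vols = np.array([atlas.parcels[i].volume_voxels for i in ids], dtype=float)
    scale = 1.0 / np.sqrt(np.outer(vols, vols))
    if correction == "full":
        cents = np.array([atlas.parcels[i].centroid_mm for i in ids], dtype=float)
        d = np.linalg.norm(cents[:, None, :] - cents[None, :, :], axis=2)
        scale = scale * d
    out = W * scale
    np.fill_diagonal(out, 0.0)
    return out


def direct_connectome(
    tractogram: Tractogram,
    atlas: ParcelAtlas,
    correction: str = "full",
    endpoints: np.ndarray | None = None,
) -> Connectome:
    """Streamline-count connectome, optionally distance/volume corrected."""
    if len(atlas.ids) < 2:
        raise ValueError("need an atlas with at least 2 parcels")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")
    if endpoints is None:
        endpoints = assign_endpoints(tractogram, atlas)
    W = _apply_correction(_pair_counts(endpoints, atlas), atlas, correction)
    return Connectome(atlas.ids, W, approach="direct", scale="whole")


def indirect_connectome(
    tractogram: Tractogram,
    lesion: LesionMask,
    atlas: ParcelAtlas,
    endpoints: np.ndarray | None = None,
    traversals: Sequence[np.ndarray] | None = None,
) -> Connectome:
    """Preserved-streamline-count connectome after lesion filtering.

    With an empty lesion this equals the raw (uncorrected) count connectome.
    ``traversals`` may carry precomputed per-streamline voxel traversals.
    """
    if endpoints is None:
        endpoints = assign_endpoints(tractogram, atlas)
    if traversals is None:
        traversals = [streamline_traversal(sl, atlas.labels) for sl in tractogram.streamlines]
    mask = lesion.mask
    keep = np.array(
        [not (len(t) and mask[t[:, 0], t[:, 1], t[:, 2]].any()) for t in traversals]
    )
    logger.info(
        "stage=indirect_connectome streamlines_kept=%d removed=%d",
        int(keep.sum()),
        int((~keep).sum()),
    )
    W = _pair_counts(endpoints, atlas, keep=keep)
    return Connectome(atlas.ids, W, approach="indirect", scale="whole")


def disconnection_matrix(indirect: Connectome, baseline: Connectome) -> np.ndarray:
    """Convenience percent-loss matrix: 100 * (1 - preserved / baseline)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        loss = 100.0 * (1.0 - indirect.weights / baseline.weights)
    loss[baseline.weights == 0] = 0.0
    return loss


def subset(
    connectome: Connectome,
    roi: str | Sequence[int],
    atlas: ParcelAtlas | None = None,
) -> Connectome:
    """Principal submatrix on an ROI's nodes, node order preserved.

    ``roi`` is either a named subset of ``atlas`` (e.g. ``"language"``) or an
    explicit sequence of node ids.
    """
    if isinstance(roi, str):
        if atlas is None or roi not in atlas.roi_subsets:
            raise KeyError(f"unknown ROI subset {roi!r}")
        wanted = set(atlas.roi_subsets[roi])
    else:
        wanted = set(int(i) for i in roi)
    missing = wanted - set(connectome.node_ids)
    if missing:
        raise KeyError(f"ROI references nodes absent from the connectome: {sorted(missing)}")
    keep = [k for k, nid in enumerate(connectome.node_ids) if nid in wanted]
    ids = tuple(connectome.node_ids[k] for k in keep)
    W = connectome.weights[np.ix_(keep, keep)]
    return Connectome(ids, W, approach=connectome.approach, scale="roi")
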