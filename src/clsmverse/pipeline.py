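"""Composition of the pipeline stages on a synthetic cohort.

For each participant, four parcel connectomes are built (the 2 x 2 design of
approach x scale):

* **direct**: streamline counts from the participant's "own" tractography,
  emulated by removing lesion-severed streamlines, randomly dropping a
  fraction of the remainder, resampling each edge count through a
  lognormal-Poisson noise model (probabilistic tracking produces highly
  variable edge counts) and applying the distance/volume correction;
* **indirect**: preserved streamline counts after overlaying the lesion on
  the intact atlas tractogram (no correction, as in lesion-quantification
  practice);

each at whole-brain scale and restricted to the "language" ROI subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import graph_metrics as gm
from . import parcel_connectome as pc
from . import stats_engine as se
from .core_io import Connectome

logger = logging.getLogger("clsmverse")

NETWORK_KEYS = ("direct_whole", "direct_roi", "indirect_whole", "indirect_roi")


def participant_connectomes(
    cohort,
    i: int,
    correction: str = "full",
    drop_rate: float = 0.2,
    count_noise_sd: float = 0.7,
    roi: str = "language",
) -> dict[str, Connectome]:
    """The four connectomes (direct/indirect x whole/roi) for participant i."""
    atlas = cohort.atlas
    endpoints = _cohort_endpoints(cohort)
    lesion = cohort.lesions[i]
    mask = lesion.mask
    travs = cohort.all_traversals
    severed = np.array(
        [len(t) > 0 and bool(mask[t[:, 0], t[:, 1], t[:, 2]].any()) for t in travs]
    )
    rng = np.random.default_rng(cohort.map_seeds[i] + 1)
    kept_direct = (~severed) & (rng.random(len(travs)) >= drop_rate)
    counts = pc._pair_counts(endpoints, atlas, keep=kept_direct)
    if count_noise_sd > 0:
        iu = np.triu_indices(counts.shape[0], k=1)
        lam = counts[iu] * rng.lognormal(0.0, count_noise_sd, size=len(iu[0]))
        resampled = np.zeros_like(counts)
        resampled[iu] = rng.poisson(lam)
        counts = resampled + resampled.T
    W_direct = pc._apply_correction(counts, atlas, correction)
    direct = Connectome(atlas.ids, W_direct, approach="direct", scale="whole")
    W_ind = pc._pair_counts(endpoints, atlas, keep=~severed)
    indirect = Connectome(atlas.ids, W_ind, approach="indirect", scale="whole")
    return {
        "direct_whole": direct,
        "direct_roi": pc.subset(direct, roi, atlas),
        "indirect_whole": indirect,
        "indirect_roi": pc.subset(indirect, roi, atlas),
    }


def _cohort_endpoints(cohort) -> np.ndarray:
    cached = getattr(cohort, "_endpoints_cache", None)
    if cached is None:
        cached = pc.assign_endpoints(cohort.tractogram, cohort.atlas)
        cohort._endpoints_cache = cached
    return cached


def cohort_similarity(cohort, correction: str = "full") -> se.SimilarityReport:
    """Direct-vs-indirect edge-wise tau per participant, for both scales."""
    roi_pairs: tuple[list, list] = ([], [])
    whole_pairs: tuple[list, list] = ([], [])
    for i in range(len(cohort.participants)):
        conns = participant_connectomes(cohort, i, correction=correction)
        roi_pairs[0].append(conns["direct_roi"])
        roi_pairs[1].append(conns["indirect_roi"])
        whole_pairs[0].append(conns["direct_whole"])
        whole_pairs[1].append(conns["indirect_whole"])
    return se.connectome_similarity({"roi": roi_pairs, "whole": whole_pairs})


def graph_metric_table(cohort, seed: int = 0, n_null: int = 25) -> pd.DataFrame:
    """Participants x (network, graph metric) table for the 2 x 2 design.

    ``n_null`` controls the small-worldness null-ensemble size per network.
    """
    rows = []
    for i, pid in enumerate(cohort.participants["id"]):
        conns = participant_connectomes(cohort, i)
        row = {}
        for key in NETWORK_KEYS:
            mset = gm.all_metrics(conns[key], seed=seed + i, n_null=n_null)
            for name, value in mset.as_dict().items():
                row[(key, name)] = value
        rows.append(row)
        logger.info("participant=%s stage=graph_metrics done", pid)
    df = pd.DataFrame(rows, index=cohort.participants["id"].rename("participant"))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["network", "metric"])
    return df


def edge_matrix(cohort, approach: str = "indirect", scale: str = "roi") -> tuple[np.ndarray, list[str]]:
    """Participants x edges matrix of connectome weights for sparse CCA."""
    key = f"{approach}_{scale}"
    rows, names = [], None
    for i in range(len(cohort.participants)):
        conn = participant_connectomes(cohort, i)[key]
        rows.append(conn.upper_values())
        names = conn.edge_names()
    return np.vstack(rows), names
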