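"""Synthetic stroke cohort with planted ground truth.

Generates everything the downstream pipeline consumes -- a parcel atlas, tract
bundles with streamlines, diffusion scalar maps, lesions and behaviour -- so
the whole analysis chain is testable without any imaging download.

What the generator emulates
---------------------------
* a cohort of (by default) 50 left-hemisphere stroke survivors scanned on
  three scanner protocols;
* sphere-union lesions centred on a perisylvian "middle cerebral artery"
  territory, with volumes spanning roughly 2-263 cc (mean near 90 cc);
* six language-related bundles (AF, FAT, SLF3, ILF, IFOF, UF) built as tight
  streamline tubes between endpoint parcels, plus background streamlines
  between other parcel pairs so that parcel connectomes are non-trivial;
* behaviour (naming 0-60, Token 0-45) generated as
  ``intercept + b_size * lesion_cc + beta * z(target metric) + scanner + noise``
  with a strongly negative lesion-size slope, and an optional planted linear
  metric effect with configurable coefficient;
* occasional complete tract disconnection: when a lesion severs every
  streamline of a bundle, the participant's direct metrics for that tract are
  missing, mirroring per-participant tractography failure.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_TRACTS,
    LesionMask,
    ParcelAtlas,
    TractDefinition,
    Tractogram,
    VolumeGrid,
    write_tractogram,
    write_volume,
)
from .tract_metrics import mask_from_traversals, streamline_traversal

logger = logging.getLogger("clsmverse")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class LesionModel:
    """Sphere-union lesion blobs in a left perisylvian territory.

    Radii in mm; the defaults target the 2-263 cc volume range with a mean
    near 90 cc at the default grid scale. ``p_empty`` allows lesion-free
    control participants.
    """

    center_mean: tuple[float, float, float] = (-28.0, -5.0, 5.0)
    center_sd: tuple[float, float, float] = (14.0, 26.0, 18.0)
    radius_mean: float = 25.0
    radius_sd: float = 10.0
    radius_clip: tuple[float, float] = (7.0, 38.0)
    max_satellites: int = 2
    satellite_scale: float = 0.35
    p_empty: float = 0.0


@dataclass
class ScalarModel:
    """Healthy mean/sd per diffusion scalar and additive lesion shifts.

    Diffusivities are in units of 1e-3 mm^2/s. Inside the lesion FA drops and
    diffusivities rise (toward free water); values are clipped to physical
    ranges. This degradation model is a configurable stand-in, not a claim
    about tissue biophysics.
    """

    healthy: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FA": (0.45, 0.06),
            "MD": (0.80, 0.08),
            "AD": (1.20, 0.10),
            "RD": (0.60, 0.07),
        }
    )
    lesion_shift: dict[str, float] = field(
        default_factory=lambda: {"FA": -0.18, "MD": 0.45, "AD": 0.25, "RD": 0.55}
    )


@dataclass
class EffectSpec:
    """A planted linear effect of one metric on the naming score.

    ``beta`` is in naming points per standard unit of the metric, where the
    metric is standardised with the fixed reference ``metric_ref`` (mean, sd)
    rather than per-cohort estimates, so the generative model is well defined.
    """

    tract: str = "AF"
    metric: str = "DP"
    beta: float = -5.0
    metric_ref: tuple[float, float] = (40.0, 45.0)


@dataclass
class BehaviorModel:
    """Linear behaviour model with clipping to the test score ranges."""

    naming_intercept: float = 36.0
    naming_b_size: float = -0.10  # points per cc, centred at lesion_cc_center
    naming_noise_sd: float = 10.0
    token_intercept: float = 26.0
    token_b_size: float = -0.065
    token_noise_sd: float = 7.0
    lesion_cc_center: float = 90.0
    scanner_offsets: tuple[float, ...] = (0.0, 2.0, -2.0)


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_participants: int = 50
    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_parcels: int = 24
    roi_size: int = 14
    parcel_radius_vox: float = 2.0
    tracts: dict[str, tuple[int, int]] | None = None  # name -> endpoint parcel ids
    streamlines_per_bundle: int = 25
    n_background_streamlines: int = 260
    lesion: LesionModel = field(default_factory=LesionModel)
    scalars: ScalarModel = field(default_factory=ScalarModel)
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    effect: EffectSpec | None = field(default_factory=EffectSpec)
    scanner_levels: tuple[str, ...] = ("achieva", "allegra", "prisma")
    scanner_probs: tuple[float, ...] = (0.50, 0.36, 0.14)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("need n_participants >= 4 (4-fold CV downstream)")
        if not 2 <= self.roi_size <= self.n_parcels:
            raise ValueError("need n_parcels >= roi_size >= 2")
        if self.lesion.radius_clip[1] <= 0:
            raise ValueError("radius distribution must allow nonempty lesions")
        if self.effect is not None and self.effect.metric not in (
            "VOL",
            "SN",
            "FA",
            "MD",
            "AD",
            "RD",
            "DP",
            "LP",
        ):
            raise ValueError(f"unknown target metric {self.effect.metric!r}")

    def default_tracts(self) -> dict[str, tuple[int, int]]:
        """Endpoint parcel pairs for the six bundles, all within the ROI."""
        if self.tracts is not None:
            return self.tracts
        pairs = {"AF": (1, 8), "FAT": (2, 3), "SLF3": (4, 8), "ILF": (9, 12), "IFOF": (5, 13), "UF": (6, 10)}
        return {name: pairs[name] for name in DEFAULT_TRACTS}

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        vs = np.asarray(self.voxel_size, dtype=float)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -(np.asarray(self.shape) - 1) * vs / 2.0  # world origin at centre
        return aff


@dataclass
class GroundTruth:
    """Stored alongside every cohort; regeneration with the same seed matches."""

    beta: float
    target: tuple[str, str] | None
    true_metric: np.ndarray  # realised target metric per participant (pre behaviour noise)
    latent_naming: np.ndarray  # linear predictor before noise and clipping
    latent_token: np.ndarray
    fully_disconnected: list[list[str]]  # tract names per participant


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def make_atlas(spec: CohortSpec, seed: int | None = None) -> ParcelAtlas:
    """Pack ``n_parcels`` disjoint spherical parcels into the grid.

    Parcels sit on a lattice (spacing chosen from the parcel radius so blobs
    cannot touch); the ``roi_size`` slots nearest a left perisylvian anchor
    become the "language" ROI subset (ids 1..roi_size), mirroring a
    language-network subset of a whole-brain parcellation.
    """
    del seed  # placement is deterministic given the spec
    affine = spec.affine()
    grid = VolumeGrid(np.zeros(spec.shape, dtype=np.int32), affine)
    r = spec.parcel_radius_vox
    spacing = int(np.ceil(2 * r + 2))
    margin = int(np.ceil(r + 1))
    axes = [np.arange(margin, s - margin + 1, spacing) for s in spec.shape]
    slots = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    if len(slots) < spec.n_parcels:
        raise ValueError(
            f"cannot pack {spec.n_parcels} parcels of radius {r} into grid {spec.shape}"
        )
    anchor = np.array(spec.lesion.center_mean)  # perisylvian anchor, world mm
    world = grid.voxel_to_world(slots)
    order = np.argsort(np.linalg.norm(world - anchor, axis=1), kind="stable")
    chosen = slots[order[: spec.n_parcels]]
    labels = np.zeros(spec.shape, dtype=np.int32)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij")
    for pid, c in enumerate(chosen, start=1):
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        labels[d2 <= r * r] = pid
    lang = tuple(range(1, spec.roi_size + 1))
    return ParcelAtlas.from_labels(
        VolumeGrid(labels, affine),
        names={pid: f"P{pid:03d}" for pid in range(1, spec.n_parcels + 1)},
        roi_subsets={"language": lang},
    )


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


def _parcel_voxels(atlas: ParcelAtlas, pid: int) -> np.ndarray:
    return np.argwhere(atlas.labels.values == pid)


def _bezier(p0: np.ndarray, c: np.ndarray, p1: np.ndarray, n_pts: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n_pts)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * c + t**2 * p1


def make_bundles(
    atlas: ParcelAtlas, spec: CohortSpec, seed: int
) -> tuple[Tractogram, list[TractDefinition], dict[str, list[int]]]:
    """Streamline tubes between endpoint parcels plus background streamlines.

    Each bundle's streamlines start and end at voxel centres inside its two
    endpoint parcels and follow a slightly arched quadratic curve with small
    per-streamline jitter, giving a tight tube. The tract voxel mask is the
    union of the member streamlines' traversals. Background streamlines
    (bundle label ``None``) connect random distinct parcel pairs so that
    whole-brain connectomes have many edges.

    Returns the full tractogram, the six tract definitions, and the map from
    tract name to streamline indices within the tractogram.
    """
    rng = np.random.default_rng(seed)
    grid = atlas.labels
    tract_pairs = spec.default_tracts()
    streamlines: list[np.ndarray] = []
    bundles: list[str | None] = []
    members: dict[str, list[int]] = {}
    for name, (pa, pb) in tract_pairs.items():
        if pa == pb:
            raise ValueError(f"tract {name!r} has identical endpoint parcels")
        vox_a, vox_b = _parcel_voxels(atlas, pa), _parcel_voxels(atlas, pb)
        arch = rng.normal(0.0, 6.0, size=3)  # per-bundle arch, shared by members
        idxs = []
        for _ in range(spec.streamlines_per_bundle):
            p0 = grid.voxel_to_world(vox_a[rng.integers(len(vox_a))])[0]
            p1 = grid.voxel_to_world(vox_b[rng.integers(len(vox_b))])[0]
            mid = (p0 + p1) / 2 + arch + rng.normal(0.0, 1.5, size=3)
            pts = _bezier(p0, mid, p1, 15)
            idxs.append(len(streamlines))
            streamlines.append(pts)
            bundles.append(name)
        members[name] = idxs
    parcel_ids = np.array(atlas.ids)
    for _ in range(spec.n_background_streamlines):
        pa, pb = rng.choice(parcel_ids, size=2, replace=False)
        vox_a, vox_b = _parcel_voxels(atlas, int(pa)), _parcel_voxels(atlas, int(pb))
        p0 = grid.voxel_to_world(vox_a[rng.integers(len(vox_a))])[0]
        p1 = grid.voxel_to_world(vox_b[rng.integers(len(vox_b))])[0]
        mid = (p0 + p1) / 2 + rng.normal(0.0, 5.0, size=3)
        streamlines.append(_bezier(p0, mid, p1, 15))
        bundles.append(None)
    tg = Tractogram(streamlines, bundles)
    tract_defs = []
    for name, idxs in members.items():
        travs = [streamline_traversal(streamlines[i], grid) for i in idxs]
        tract_defs.append(
            TractDefinition(
                name=name,
                mask=mask_from_traversals(travs, grid),
                streamlines=[streamlines[i] for i in idxs],
            )
        )
    return tg, tract_defs, members


# ---------------------------------------------------------------------------
# lesions and scalar maps
# ---------------------------------------------------------------------------


def sphere_mask(grid: VolumeGrid, center_mm: Sequence[float], radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius_mm`` of a point."""
    out = np.zeros(grid.shape, dtype=bool)
    if radius_mm < 0:
        return out
    c_vox = grid.world_to_voxel(center_mm)[0]
    halfwidth = radius_mm / grid.voxel_size + 1.0
    lo = np.maximum(np.floor(c_vox - halfwidth).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + halfwidth).astype(int) + 1, np.array(grid.shape))
    if np.any(lo >= hi):
        return out
    ii, jj, kk = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d = np.linalg.norm(grid.voxel_to_world(idx) - np.asarray(center_mm), axis=1)
    inside = idx[d <= radius_mm]
    out[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return out


def make_lesion(grid: VolumeGrid, model: LesionModel, seed: int | np.random.Generator) -> LesionMask:
    """A sphere-union lesion blob clipped to the grid.

    One main sphere plus up to ``max_satellites`` smaller attached spheres.
    An empty lesion (all zeros) is produced with probability ``p_empty``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = np.zeros(grid.shape, dtype=bool)
    if model.p_empty > 0 and rng.random() < model.p_empty:
        return LesionMask(grid.like(mask))
    center = rng.normal(model.center_mean, model.center_sd)
    center[0] = min(center[0], -5.0)  # stay in the left hemisphere
    radius = float(np.clip(rng.normal(model.radius_mean, model.radius_sd), *model.radius_clip))
    mask |= sphere_mask(grid, center, radius)
    for _ in range(int(rng.integers(0, model.max_satellites + 1))):
        offset = rng.normal(0.0, radius * 0.8, size=3)
        mask |= sphere_mask(grid, center + offset, radius * model.satellite_scale)
    return LesionMask(grid.like(mask))


def make_scalar_maps(
    grid: VolumeGrid,
    lesion: LesionMask,
    model: ScalarModel,
    seed: int | np.random.Generator,
) -> dict[str, VolumeGrid]:
    """Per-voxel FA/MD/AD/RD maps with lesion-shifted values.

    Healthy tissue: independent Gaussian noise around the configured mean.
    Lesioned voxels receive the configured additive shift. FA is clipped to
    [0, 1]; diffusivities to >= 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    les = lesion.mask
    for name, (mu, sd) in model.healthy.items():
        vals = rng.normal(mu, sd, size=grid.shape)
        vals[les] += model.lesion_shift[name]
        if name == "FA":
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.clip(vals, 0.0, None)
        out[name] = grid.like(vals)
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """An in-memory synthetic cohort.

    Scalar maps are regenerated on demand from per-participant seeds (they
    are pure functions of the seed), which keeps 50-participant cohorts
    lightweight.
    """

    spec: CohortSpec
    atlas: ParcelAtlas
    tractogram: Tractogram
    tract_defs: list[TractDefinition]
    tract_members: dict[str, list[int]]
    traversals: dict[str, list[np.ndarray]]  # per tract, per member streamline
    all_traversals: list[np.ndarray]  # per tractogram streamline
    lesions: list[LesionMask]
    participants: pd.DataFrame
    ground_truth: GroundTruth
    map_seeds: list[int]

    def scalar_maps(self, i: int) -> dict[str, VolumeGrid]:
        return make_scalar_maps(
            self.atlas.labels, self.lesions[i], self.spec.scalars, self.map_seeds[i]
        )

    @property
    def grid(self) -> VolumeGrid:
        return self.atlas.labels


def _tract_metric_value(
    metric: str,
    tract: TractDefinition,
    travs: list[np.ndarray],
    lesion: LesionMask,
    maps: dict[str, VolumeGrid],
) -> float:
    """Target-metric evaluation used when planting the behaviour effect."""
    from . import tract_metrics as tm

    mask = lesion.mask
    hit = [len(t) > 0 and bool(mask[t[:, 0], t[:, 1], t[:, 2]].any()) for t in travs]
    if metric == "DP":
        return 100.0 * float(np.sum(hit)) / len(travs)
    if metric == "LP":
        return tm.lesion_percentage(tract, lesion)
    kept = [k for k, h in enumerate(hit) if not h]
    if not kept:
        return np.nan
    kept_mask = mask_from_traversals([travs[k] for k in kept], lesion.grid)
    kept_tract = TractDefinition(tract.name, kept_mask, [tract.streamlines[k] for k in kept])
    if metric == "VOL":
        return tm.tract_volume(kept_tract)
    if metric == "SN":
        return float(len(kept))
    return tm.mean_scalar(kept_tract, maps[metric])


def make_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full cohort: atlas, bundles, lesions, behaviour, ground truth."""
    rng = np.random.default_rng(spec.seed)
    atlas = make_atlas(spec)
    bundle_seed = int(rng.integers(2**31))
    tg, tract_defs, members = make_bundles(atlas, spec, bundle_seed)
    grid = atlas.labels
    all_travs = [streamline_traversal(sl, grid) for sl in tg.streamlines]
    traversals = {name: [all_travs[i] for i in idxs] for name, idxs in members.items()}
    tract_by_name = {t.name: t for t in tract_defs}

    beh = spec.behavior
    eff = spec.effect
    n = spec.n_participants
    scanners = rng.choice(len(spec.scanner_levels), size=n, p=spec.scanner_probs)
    offsets = np.array(beh.scanner_offsets)[scanners]

    lesions: list[LesionMask] = []
    map_seeds: list[int] = []
    lesion_cc = np.empty(n)
    true_metric = np.full(n, np.nan)
    fully_disc: list[list[str]] = []
    for i in range(n):
        lesion = make_lesion(grid, spec.lesion, rng)
        lesions.append(lesion)
        lesion_cc[i] = lesion.lesion_volume_cc
        map_seeds.append(int(rng.integers(2**31)))
        disc = []
        mask = lesion.mask
        for name, travs in traversals.items():
            if all(len(t) > 0 and bool(mask[t[:, 0], t[:, 1], t[:, 2]].any()) for t in travs):
                disc.append(name)
        fully_disc.append(disc)
        if eff is not None:
            maps = None
            if eff.metric in ("FA", "MD", "AD", "RD"):
                maps = make_scalar_maps(grid, lesion, spec.scalars, map_seeds[i])
            true_metric[i] = _tract_metric_value(
                eff.metric, tract_by_name[eff.tract], traversals[eff.tract], lesion, maps or {}
            )
        logger.info(
            "participant=%02d stage=simulate lesion_cc=%.1f fully_disconnected=%s",
            i,
            lesion_cc[i],
            ",".join(disc) or "-",
        )

    if eff is not None:
        ref_mu, ref_sd = eff.metric_ref
        z = (np.nan_to_num(true_metric, nan=ref_mu) - ref_mu) / ref_sd
        planted = eff.beta * z
    else:
        planted = np.zeros(n)
    size_dev = lesion_cc - beh.lesion_cc_center
    latent_naming = beh.naming_intercept + beh.naming_b_size * size_dev + planted + offsets
    latent_token = beh.token_intercept + beh.token_b_size * size_dev + planted * 0.6 + offsets * 0.7
    naming = latent_naming + rng.normal(0.0, beh.naming_noise_sd, size=n)
    token = latent_token + rng.normal(0.0, beh.token_noise_sd, size=n)
    naming_c = np.clip(naming, 0.0, 60.0)
    token_c = np.clip(token, 0.0, 45.0)
    clipped = float(np.mean((naming != naming_c) | (token != token_c)))
    if clipped > 0.10:
        warnings.warn(f"{clipped:.0%} of behaviour scores clipped to the test range")

    participants = pd.DataFrame(
        {
            "id": [f"sub-{i + 1:03d}" for i in range(n)],
            "scanner": [spec.scanner_levels[s] for s in scanners],
            "naming": np.round(naming_c, 3),
            "token": np.round(token_c, 3),
            "lesion_cc": np.round(lesion_cc, 3),
        }
    )
    gt = GroundTruth(
        beta=0.0 if eff is None else eff.beta,
        target=None if eff is None else (eff.tract, eff.metric),
        true_metric=true_metric,
        latent_naming=latent_naming,
        latent_token=latent_token,
        fully_disconnected=fully_disc,
    )
    return Cohort(
        spec=spec,
        atlas=atlas,
        tractogram=tg,
        tract_defs=tract_defs,
        tract_members=members,
        traversals=traversals,
        all_traversals=all_travs,
        lesions=lesions,
        participants=participants,
        ground_truth=gt,
        map_seeds=map_seeds,
    )


# ---------------------------------------------------------------------------
# regression-level simulator (used for statistical calibration/power work)
# ---------------------------------------------------------------------------


def simulate_behavior_table(
    n: int = 50,
    partial_r2: float = 0.0,
    seed: int | np.random.Generator = 0,
    beta_sign: float = -1.0,
    exact_orthogonal: bool = False,
    scanner_levels: Sequence[str] = ("achieva", "allegra", "prisma"),
    scanner_probs: Sequence[float] = (0.50, 0.36, 0.14),
) -> pd.DataFrame:
    """Behaviour table with a metric of known partial R-squared.

    The candidate metric is drawn independently of lesion size and scanner,
    so its population partial R-squared given the base covariates is exactly
    ``partial_r2`` (beta = sign * sigma_eps * sqrt(pr / (1 - pr))). With
    ``exact_orthogonal=True`` the metric is residualised against the base
    design in-sample and scaled to unit sample variance, so the planted
    signal strength (the F-test noncentrality n * pr / (1 - pr)) is imposed
    exactly in every replicate rather than on average. Scores are left on
    the unbounded latent scale: this table exists to calibrate and power the
    regression machinery, not to emulate score clipping.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lesion_cc = np.clip(rng.lognormal(np.log(70.0), 0.8, size=n), 2.0, 263.0)
    scanner_idx = rng.choice(len(scanner_levels), size=n, p=np.asarray(scanner_probs))
    offsets = np.array([0.0, 2.0, -2.0])[scanner_idx % 3]
    metric = rng.normal(0.0, 1.0, size=n)
    if exact_orthogonal:
        X = np.column_stack(
            [np.ones(n), lesion_cc]
            + [(scanner_idx == s).astype(float) for s in range(1, len(scanner_levels))]
        )
        coef, *_ = np.linalg.lstsq(X, metric, rcond=None)
        metric = metric - X @ coef
        metric /= metric.std()
    sigma = 9.0
    beta = beta_sign * sigma * np.sqrt(partial_r2 / (1.0 - partial_r2)) if partial_r2 > 0 else 0.0
    naming = 34.0 - 0.12 * (lesion_cc - 91.0) + offsets + beta * metric + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {
            "id": [f"sim-{i + 1:03d}" for i in range(n)],
            "lesion_cc": lesion_cc,
            "scanner": [scanner_levels[s] for s in scanner_idx],
            "metric": metric,
            "naming": naming,
        }
    )


# ---------------------------------------------------------------------------
# cohort directory I/O
# ---------------------------------------------------------------------------


def save_cohort(cohort: Cohort, out_dir: str | Path, write_scalar_maps: bool = False) -> Path:
    """Write a cohort directory: TSVs, NIfTI volumes and the tractogram."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    write_volume(cohort.atlas.labels, out / "atlas.nii.gz")
    rows = [
        {
            "id": rec.id,
            "name": rec.name,
            "x": rec.centroid_mm[0],
            "y": rec.centroid_mm[1],
            "z": rec.centroid_mm[2],
            "volume_voxels": rec.volume_voxels,
        }
        for rec in cohort.atlas.parcels.values()
    ]
    pd.DataFrame(rows).to_csv(out / "parcels.tsv", sep="\t", index=False)
    write_tractogram(cohort.tractogram, out / "tractogram.jsonl", "jsonl-polyline")
    lesion_dir = out / "lesions"
    lesion_dir.mkdir(exist_ok=True)
    for pid, lesion in zip(cohort.participants["id"], cohort.lesions):
        write_volume(lesion.grid, lesion_dir / f"{pid}_lesion.nii.gz")
    if write_scalar_maps:
        map_dir = out / "scalar_maps"
        map_dir.mkdir(exist_ok=True)
        for i, pid in enumerate(cohort.participants["id"]):
            for name, vol in cohort.scalar_maps(i).items():
                write_volume(vol, map_dir / f"{pid}_{name}.nii.gz")
    gt = cohort.ground_truth
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "beta": gt.beta,
                "target": list(gt.target) if gt.target else None,
                "true_metric": [None if np.isnan(v) else v for v in gt.true_metric],
                "latent_naming": gt.latent_naming.tolist(),
                "latent_token": gt.latent_token.tolist(),
                "fully_disconnected": gt.fully_disconnected,
                "seed": cohort.spec.seed,
                "map_seeds": cohort.map_seeds,
            },
            indent=1,
        )
    )
    (out / "spec.json").write_text(json.dumps(spec_to_dict(cohort.spec), indent=1))
    return out


def spec_to_dict(spec: CohortSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    for key, cls in (
        ("lesion", LesionModel),
        ("scalars", ScalarModel),
        ("behavior", BehaviorModel),
    ):
        if isinstance(d.get(key), dict):
            d[key] = cls(**d[key])
    if isinstance(d.get("effect"), dict):
        d["effect"] = EffectSpec(**d["effect"])
    for key in ("shape", "voxel_size", "scanner_levels", "scanner_probs"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("tracts"):
        d["tracts"] = {k: tuple(v) for k, v in d["tracts"].items()}
    if isinstance(d.get("effect"), EffectSpec):
        eff = d["effect"]
        eff.metric_ref = tuple(eff.metric_ref)
    return CohortSpec(**d)


def load_cohort(path: str | Path) -> Cohort:
    """Reconstruct a cohort from a directory written by :func:`save_cohort`.

    Tract masks and traversals are recomputed from the stored tractogram, so
    a loaded cohort is functionally identical to the generated one.
    """
    from .core_io import read_tractogram, read_volume

    path = Path(path)
    spec = spec_from_dict(json.loads((path / "spec.json").read_text()))
    gt_raw = json.loads((path / "ground_truth.json").read_text())
    atlas_grid = read_volume(path / "atlas.nii.gz")
    atlas = ParcelAtlas.from_labels(
        atlas_grid.like(atlas_grid.values.astype(np.int32)),
        roi_subsets={"language": tuple(range(1, spec.roi_size + 1))},
    )
    tg = read_tractogram(path / "tractogram.jsonl", "jsonl-polyline")
    grid = atlas.labels
    all_travs = [streamline_traversal(sl, grid) for sl in tg.streamlines]
    members: dict[str, list[int]] = {}
    for i, b in enumerate(tg.bundles or []):
        if b is not None:
            members.setdefault(b, []).append(i)
    tract_defs = [
        TractDefinition(
            name=name,
            mask=mask_from_traversals([all_travs[i] for i in idxs], grid),
            streamlines=[tg.streamlines[i] for i in idxs],
        )
        for name, idxs in members.items()
    ]
    participants = pd.read_csv(path / "participants.tsv", sep="\t")
    lesions = [
        LesionMask(read_volume(path / "lesions" / f"{pid}_lesion.nii.gz"))
        for pid in participants["id"]
    ]
    gt = GroundTruth(
        beta=gt_raw["beta"],
        target=tuple(gt_raw["target"]) if gt_raw["target"] else None,
        true_metric=np.array(
            [np.nan if v is None else v for v in gt_raw["true_metric"]], dtype=float
        ),
        latent_naming=np.array(gt_raw["latent_naming"], dtype=float),
        latent_token=np.array(gt_raw["latent_token"], dtype=float),
        fully_disconnected=[list(d) for d in gt_raw["fully_disconnected"]],
    )
    return Cohort(
        spec=spec,
        atlas=atlas,
        tractogram=tg,
        tract_defs=tract_defs,
        tract_members=members,
        traversals={n: [all_travs[i] for i in idxs] for n, idxs in members.items()},
        all_traversals=all_travs,
        lesions=lesions,
        participants=participants,
        ground_truth=gt,
        map_seeds=list(gt_raw["map_seeds"]),
    )
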