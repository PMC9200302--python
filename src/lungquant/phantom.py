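"""Synthetic thorax phantoms with per-voxel ground truth.

A phantom is a 96³ (by default) expiratory-phase mouse-chest scene: ambient
air at −1000 HU, an ellipsoidal soft-tissue body, two ellipsoidal lungs
filled with a spatially correlated parenchyma HU field, an optional sealed
tracheal air tube between the lungs, and — for the fibrosis model — dense
spherical lesions placed with preferential-attachment clustering (patchy,
confluent foci) each wrapped in a thin collapsed-parenchyma halo.

The clean scene defines the ground truth (labels, per-voxel air fraction,
achieved lesion fraction).  The measurement process is then emulated on top
of it: Gaussian partial-volume blur, additive HU noise, and an affine
encoding of HU into scanner grey levels whose :class:`CalibrationPair` is
returned — so any consumer must run the grey→HU calibration itself, closing
the loop over the whole pipeline.

The healthy parenchyma HU distribution is not chosen by hand: it is
calibrated with :func:`calibrate_healthy` so that the *full pipeline*
(calibration → segmentation → band classification) reproduces the
normo/hypo split of a healthy (saline) cohort, ~78/21% of lung volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage as ndi

from .errors import CalibrationSearchError, PhantomInfeasibleError
from .volume_io import AIR_HU, CalibrationPair, ImageVolume, Unit

log = logging.getLogger(__name__)


class TruthLabel(IntEnum):
    BACKGROUND = 0
    BODY = 1
    LUNG = 2
    AIRWAY = 3
    LESION = 4


#: Healthy parenchyma HU distribution, the output of
#: calibrate_healthy(78.5, 21.5) on the default geometry (seeds 1-5):
#: seed-averaged pipeline fractions normo 78.3%, hypo 20.8%.
HEALTHY_PARENCHYMA_MEAN: float = -575.0
HEALTHY_PARENCHYMA_SD: float = 160.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic thorax scene.

    Geometry defaults are derived from ``shape`` (ellipsoid semi-axes and
    centres as fixed fractions of the grid), so the same anatomy scales to
    small test grids.  ``parenchyma_corr_vox`` is the correlation length of
    the parenchyma HU field: healthy-lung texture (vessels, alveolar
    clustering) varies on a scale coarser than one voxel, which is what
    lets the HU spread survive the partial-volume blur.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.05, 0.05, 0.05)
    parenchyma_mean_hu: float = HEALTHY_PARENCHYMA_MEAN
    parenchyma_sd_hu: float = HEALTHY_PARENCHYMA_SD
    parenchyma_corr_vox: float = 2.5
    soft_tissue_mean_hu: float = 40.0
    soft_tissue_sd_hu: float = 15.0
    lesion_fraction: float = 0.0
    lesion_hu_range: tuple[float, float] = (-100.0, 60.0)
    lesion_radius_vox: tuple[float, float] = (2.0, 6.0)
    lesion_cluster_prob: float = 0.7
    lesion_cluster_sd_vox: float = 4.0
    halo_width_vox: int = 2
    halo_mean_hu: float = -140.0
    halo_sd_hu: float = 20.0
    include_airway: bool = True
    blur_sigma_vox: float = 1.0
    noise_sd_hu: float = 25.0
    g_air: float = 2000.0
    g_water: float = 6000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_fraction <= 0.6:
            raise PhantomInfeasibleError(
                f"lesion_fraction must be in [0, 0.6], got {self.lesion_fraction}"
            )
        if self.blur_sigma_vox < 0 or self.noise_sd_hu < 0:
            raise ValueError("blur_sigma_vox and noise_sd_hu must be >= 0")
        if any(n < 16 for n in self.shape):
            raise ValueError("phantom grid must be at least 16 voxels per axis")

    # geometry as fractions of the grid -------------------------------------
    def body_geometry(self):
        nz, ny, nx = self.shape
        centre = (0.50 * nz, 0.50 * ny, 0.50 * nx)
        semi = (0.47 * nz, 0.42 * ny, 0.42 * nx)
        return centre, semi

    def lung_geometries(self):
        nz, ny, nx = self.shape
        semi = (0.29 * nz, 0.17 * ny, 0.125 * nx)
        left = (0.54 * nz, 0.50 * ny, 0.29 * nx)
        right = (0.54 * nz, 0.50 * ny, 0.71 * nx)
        return [(left, semi), (right, semi)]

    def trachea_geometry(self):
        nz, ny, nx = self.shape
        radius = max(1.5, 0.03 * nx)
        return {"radius": radius, "y": 0.50 * ny, "x": 0.50 * nx,
                "z0": 0.15 * nz, "z1": 0.52 * nz}

    def airway_seed_index(self) -> tuple[int, int, int]:
        """A voxel safely inside the tracheal lumen (for region growing)."""
        t = self.trachea_geometry()
        return (int((t["z0"] + t["z1"]) / 2), int(t["y"]), int(t["x"]))

    def calibration(self) -> CalibrationPair:
        return CalibrationPair(g_air=self.g_air, g_water=self.g_water)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom (from the clean, pre-blur scene).

    ``air_fraction`` maps clean HU to true fractional air content via
    clip(HU / AIR_HU, 0, 1) — 1 for pure air, 0 for water-density tissue.
    """

    labels: np.ndarray
    air_fraction: np.ndarray
    true_lesion_fraction: float
    airway_seed: tuple[int, int, int] | None

    @property
    def lung_mask(self) -> np.ndarray:
        """Boolean lung parenchyma incl. lesions, excl. airway lumen."""
        return (self.labels == TruthLabel.LUNG) | (self.labels == TruthLabel.LESION)

    @property
    def lung_air_fraction(self) -> float:
        """Mean true air fraction over the lung — the reference for FRC/V_exp."""
        return float(self.air_fraction[self.lung_mask].mean())


def _ellipsoid(shape, centre, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, s in zip(grids, centre, semi):
        acc = acc + ((g - c) / s) ** 2
    return acc <= 1.0


def _correlated_field(rng: np.random.Generator, shape, corr_vox: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian field with the given correlation length."""
    white = rng.standard_normal(shape)
    if corr_vox <= 0:
        return white
    smooth = ndi.gaussian_filter(white, sigma=corr_vox, mode="nearest")
    return (smooth - smooth.mean()) / smooth.std()


def _sphere_voxels(shape, centre, radius):
    lo = [max(0, int(math.floor(c - radius))) for c in centre]
    hi = [min(n, int(math.ceil(c + radius)) + 1) for n, c in zip(shape, centre)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2
              + (xx - centre[2]) ** 2) <= radius * radius
    return (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2])), inside


def _place_lesions(
    spec: PhantomSpec, lung: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Grow clustered lesion spheres inside the lung until the target fraction.

    Draws (centre, radius, HU) sequentially from a dedicated RNG stream; the
    stream never depends on the target fraction, so a larger target extends
    the same lesion sequence — that prefix property is what gives
    progression series their monotone lesion nesting.  Near the target the
    sampled radius is capped so the achieved fraction lands within ±0.01.
    """
    lesion = np.zeros(spec.shape, dtype=bool)
    lesion_hu = np.zeros(spec.shape, dtype=np.float64)
    lung_count = int(lung.sum())
    target = spec.lesion_fraction * lung_count
    if target <= 0:
        return lesion, lesion_hu
    # keep a parenchyma rim between lesion+halo and the pleura: interior
    # dense blobs become holes the mask closing/hole-fill can recover
    depth = ndi.distance_transform_edt(lung)
    r_lo, r_hi = spec.lesion_radius_vox
    # halo + 3-voxel parenchyma rim keeps blurred blobs enclosed holes;
    # on small grids shrink to whatever depth the lung offers
    margin = min(spec.halo_width_vox + 3.0, max(1.0, float(depth.max()) - r_lo - 1.0))
    lung_idx = np.argwhere(depth > r_lo + margin)
    if len(lung_idx) == 0:
        raise PhantomInfeasibleError("lung too small for any interior lesion")
    centres: list[np.ndarray] = []
    achieved = 0
    attempts = 0
    max_attempts = 200000
    while achieved < target - 0.001 * lung_count:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomInfeasibleError(
                f"could not reach lesion fraction {spec.lesion_fraction:.3f} "
                f"(achieved {achieved / lung_count:.3f})"
            )
        if centres and rng.random() < spec.lesion_cluster_prob:
            base = centres[rng.integers(len(centres))]
            centre = base + rng.normal(0.0, spec.lesion_cluster_sd_vox, size=3)
        else:
            centre = lung_idx[rng.integers(len(lung_idx))].astype(np.float64)
        r_raw = rng.uniform(r_lo, r_hi)
        hu = rng.uniform(*spec.lesion_hu_range)
        ci = tuple(int(round(c)) for c in centre)
        if not (all(0 <= c < n for c, n in zip(ci, spec.shape)) and lung[ci]):
            continue
        remaining = target - achieved
        r_cap = max(r_lo, (3.0 * remaining / (4.0 * math.pi)) ** (1.0 / 3.0) + 0.7)
        radius = min(r_raw, r_cap, max(r_lo, depth[ci] - margin))
        if depth[ci] <= r_lo + margin:
            continue
        sph = _sphere_voxels(spec.shape, centre, radius)
        if sph is None:
            continue
        sl, inside = sph
        new = inside & lung[sl] & ~lesion[sl]
        n_new = int(new.sum())
        if n_new == 0:
            continue
        lesion[sl][new] = True          # sl is basic slicing -> view
        lesion_hu[sl][new] = hu
        centres.append(np.asarray(centre))
        achieved += n_new
    return lesion, lesion_hu


def build_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, PhantomTruth, CalibrationPair]:
    """Generate one phantom scan.

    Returns the *grey-level* measured volume (the consumer must calibrate
    it to HU with the returned :class:`CalibrationPair`), plus the ground
    truth taken from the clean pre-blur scene.  Identical spec (including
    seed) gives a bit-identical phantom.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_scene, rng_lesion, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    shape = spec.shape

    body = _ellipsoid(shape, *spec.body_geometry())
    lung = np.zeros(shape, dtype=bool)
    for centre, semi in spec.lung_geometries():
        lung |= _ellipsoid(shape, centre, semi)
    lung &= body
    airway = np.zeros(shape, dtype=bool)
    if spec.include_airway:
        t = spec.trachea_geometry()
        zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
        airway = (
            ((yy - t["y"]) ** 2 + (xx - t["x"]) ** 2 <= t["radius"] ** 2)
            & (zz >= t["z0"]) & (zz <= t["z1"])
        )
        airway &= body & ~lung

    hu = np.full(shape, AIR_HU, dtype=np.float64)
    hu[body] = spec.soft_tissue_mean_hu + spec.soft_tissue_sd_hu * \
        rng_scene.standard_normal(shape)[body]
    parenchyma = spec.parenchyma_mean_hu + spec.parenchyma_sd_hu * \
        _correlated_field(rng_scene, shape, spec.parenchyma_corr_vox)
    hu[lung] = parenchyma[lung]
    hu[airway] = AIR_HU

    lesion, lesion_hu = _place_lesions(spec, lung, rng_lesion)
    if lesion.any():
        if spec.halo_width_vox > 0:
            halo = ndi.binary_dilation(
                lesion, iterations=spec.halo_width_vox) & lung & ~lesion
            hu[halo] = spec.halo_mean_hu + spec.halo_sd_hu * \
                rng_lesion.standard_normal(int(halo.sum()))
        hu[lesion] = lesion_hu[lesion]

    labels = np.zeros(shape, dtype=np.uint8)
    labels[body] = TruthLabel.BODY
    labels[lung] = TruthLabel.LUNG
    labels[airway] = TruthLabel.AIRWAY
    labels[lesion] = TruthLabel.LESION
    air_fraction = np.clip(hu / AIR_HU, 0.0, 1.0).astype(np.float32)
    lung_count = int(lung.sum())
    truth = PhantomTruth(
        labels=labels,
        air_fraction=air_fraction,
        true_lesion_fraction=float(lesion.sum()) / lung_count if lung_count else 0.0,
        airway_seed=spec.airway_seed_index() if spec.include_airway else None,
    )

    measured = hu
    if spec.blur_sigma_vox > 0:
        measured = ndi.gaussian_filter(measured, sigma=spec.blur_sigma_vox,
                                       mode="nearest")
    if spec.noise_sd_hu > 0:
        measured = measured + spec.noise_sd_hu * rng_noise.standard_normal(shape)

    calib = spec.calibration()
    grey = calib.g_air + (measured - AIR_HU) * \
        (calib.g_water - calib.g_air) / (0.0 - AIR_HU)
    vol = ImageVolume(grey.astype(np.float32), spec.spacing, Unit.GREY)
    return vol, truth, calib


@dataclass(frozen=True)
class ParenchymaCalibration:
    """Result of the closed-loop healthy-parenchyma search."""

    mean_hu: float
    sd_hu: float
    f_normo_pct: float
    f_hypo_pct: float


def calibrate_healthy(
    target_normo_pct: float,
    target_hypo_pct: float,
    base_spec: PhantomSpec | None = None,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    tol_pct: float = 2.0,
) -> ParenchymaCalibration:
    """Grid-search the healthy parenchyma HU distribution in closed loop.

    For each candidate Gaussian(mean, sd), lesion-free phantoms are built
    for every seed and pushed through the full pipeline (grey→HU,
    segmentation with airway removal, band classification); the first
    candidate whose seed-averaged normo and hypo fractions land within
    ``tol_pct`` percentage points of the targets wins.  Deterministic given
    the seed list.
    """
    from .pipeline import quantify_phantom  # local import: avoids cycle

    if not (0 < target_normo_pct < 100 and 0 < target_hypo_pct < 100):
        raise CalibrationSearchError("targets must be in (0, 100)%")
    if target_normo_pct + target_hypo_pct > 100:
        raise CalibrationSearchError("targets sum to more than 100%")
    base_spec = base_spec or PhantomSpec()
    means = np.arange(-750.0, -549.0, 25.0) if means is None else np.asarray(means)
    sds = np.arange(60.0, 161.0, 20.0) if sds is None else np.asarray(sds)

    best: ParenchymaCalibration | None = None
    best_dev = math.inf
    for mean in means:
        for sd in sds:
            f_normo, f_hypo = [], []
            for seed in seeds:
                spec = replace(base_spec, parenchyma_mean_hu=float(mean),
                               parenchyma_sd_hu=float(sd),
                               lesion_fraction=0.0, seed=int(seed))
                profile, _ = quantify_phantom(spec)
                f_normo.append(profile.f_normo)
                f_hypo.append(profile.f_hypo)
            cand = ParenchymaCalibration(
                float(mean), float(sd),
                float(np.mean(f_normo)), float(np.mean(f_hypo)))
            dev = max(abs(cand.f_normo_pct - target_normo_pct),
                      abs(cand.f_hypo_pct - target_hypo_pct))
            log.debug("calibrate_healthy mean=%.0f sd=%.0f -> normo %.1f hypo %.1f",
                      mean, sd, cand.f_normo_pct, cand.f_hypo_pct)
            if dev <= tol_pct:
                return cand
            if dev < best_dev:
                best, best_dev = cand, dev
    raise CalibrationSearchError(
        f"no (mean, sd) on the grid within ±{tol_pct} points of "
        f"({target_normo_pct}, {target_hypo_pct})%; best candidate "
        f"mean={best.mean_hu:.0f} sd={best.sd_hu:.0f} gave "
        f"normo {best.f_normo_pct:.1f}%, hypo {best.f_hypo_pct:.1f}%",
        best_candidate=best,
    )


def progression_series(
    base: PhantomSpec,
    days: list[int],
    lesion_schedule: dict[int, float],
) -> tuple[list[tuple[int, ImageVolume, PhantomTruth, CalibrationPair]], dict]:
    """Longitudinal phantoms for one animal.

    One phantom per day with the lesion fraction taken from the schedule.
    All phantoms share the base seed, so anatomy, parenchyma texture and
    noise are those of the same animal and — thanks to the lesion-stream
    prefix property — a non-decreasing schedule produces nested lesions.
    A non-monotone schedule (lesion resolution) is allowed but flagged in
    the returned metadata.
    """
    missing = [d for d in days if d not in lesion_schedule]
    if missing:
        raise PhantomInfeasibleError(f"lesion_schedule missing days {missing}")
    fractions = [lesion_schedule[d] for d in days]
    monotone = all(a <= b for a, b in zip(fractions, fractions[1:]))
    if not monotone:
        log.warning("non-monotone lesion schedule %s: lesions will not nest",
                    lesion_schedule)
    series = []
    for day in days:
        spec = replace(base, lesion_fraction=float(lesion_schedule[day]))
        vol, truth, calib = build_phantom(spec)
        series.append((day, vol, truth, calib))
    meta = {"monotone_schedule": monotone,
            "days": list(days),
            "lesion_schedule": {int(d): float(lesion_schedule[d]) for d in days}}
    return series, meta


#: CLI presets: inserted dense-lesion fraction of lung volume.
PRESETS = {"healthy": 0.0, "fibrotic-mild": 0.05, "fibrotic-severe": 0.12}
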