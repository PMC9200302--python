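"""Aeration compartments and densitometric lung-function readouts.

This is the core computation: inside the segmented parenchyma, voxels are
binned by HU into normo-aerated [−860, −435), hypo-aerated [−435, −121) and
non-aerated [−121, 121] compartments; from the mean lung attenuation (MLA)
over the mask the expiratory air content (functional residual capacity,
FRC), tissue volume, air/tissue ratio and FRC/V_exp are derived:

    FRC    = V_exp · MLA / AIR_HU          (AIR_HU = −1000)
    Tissue = V_exp − FRC
    A/T    = FRC / Tissue

Band boundaries are half-open low-side-inclusive for normo and hypo and
closed for non, so each shared edge belongs to the denser band.  Voxels
outside all three bands are tracked separately (HYPER below −860 HU,
DENSE_OUT above 121 HU) and counted in V_exp, so compartment volumes always
sum exactly to the mask volume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import EmptyMaskError, UndefinedRatioError
from .segmentation import LungMask
from .volume_io import AIR_HU, ImageVolume, Unit

log = logging.getLogger(__name__)


class AerationLabel(IntEnum):
    """Per-voxel compartment labels produced by :func:`classify_aeration`."""

    BACKGROUND = 0
    HYPER = 1       # HU below the normo band
    NORMO = 2
    HYPO = 3
    NON = 4
    DENSE_OUT = 5   # HU above the non band


@dataclass(frozen=True)
class ClassificationBands:
    """Contiguous HU bands for the three aeration compartments.

    Each band is (low, high); normo and hypo are half-open [low, high),
    non is closed [low, high].  Adjacent bands must share their edge.
    """

    normo: tuple[float, float] = (-860.0, -435.0)
    hypo: tuple[float, float] = (-435.0, -121.0)
    non: tuple[float, float] = (-121.0, 121.0)

    def __post_init__(self) -> None:
        n, h, d = self.normo, self.hypo, self.non
        if not (n[0] < n[1] == h[0] < h[1] == d[0] < d[1]):
            raise ValueError(
                "bands must be contiguous and increasing: "
                f"normo={n}, hypo={h}, non={d}"
            )


DEFAULT_BANDS = ClassificationBands()


def classify_aeration(
    vol: ImageVolume, mask: LungMask, bands: ClassificationBands = DEFAULT_BANDS
) -> np.ndarray:
    """Label every in-mask voxel with its aeration compartment.

    Returns an int8 grid of :class:`AerationLabel` values; out-of-mask
    voxels are BACKGROUND.
    """
    vol.require_unit(Unit.HU)
    if vol.shape != mask.mask.shape:
        raise EmptyMaskError(
            f"volume/mask shape mismatch: {vol.shape} vs {mask.mask.shape}"
        )
    hu = vol.data
    labels = np.zeros(vol.shape, dtype=np.int8)
    m = mask.mask
    labels[m & (hu < bands.normo[0])] = AerationLabel.HYPER
    labels[m & (hu >= bands.normo[0]) & (hu < bands.normo[1])] = AerationLabel.NORMO
    labels[m & (hu >= bands.hypo[0]) & (hu < bands.hypo[1])] = AerationLabel.HYPO
    labels[m & (hu >= bands.non[0]) & (hu <= bands.non[1])] = AerationLabel.NON
    labels[m & (hu > bands.non[1])] = AerationLabel.DENSE_OUT
    return labels


@dataclass
class AerationProfile:
    """Per-scan densitometric readouts.

    Volumes are mm³; fractions f_* are percentages of V_exp; ``at_ratio``
    is NaN when the tissue volume is zero (pure-air limit).
    """

    v_exp: float
    v_hyper: float
    v_normo: float
    v_hypo: float
    v_non: float
    v_dense_out: float
    f_normo: float
    f_hypo: float
    f_non: float
    mla: float = math.nan
    frc: float = math.nan
    tissue: float = math.nan
    at_ratio: float = math.nan
    frc_over_vexp: float = math.nan
    frc_clamped: bool = False

    def to_dict(self) -> dict[str, float]:
        return {
            "v_exp_mm3": self.v_exp,
            "f_normo_pct": self.f_normo,
            "f_hypo_pct": self.f_hypo,
            "f_non_pct": self.f_non,
            "mla_hu": self.mla,
            "frc_mm3": self.frc,
            "tissue_mm3": self.tissue,
            "at_ratio": self.at_ratio,
            "frc_over_vexp": self.frc_over_vexp,
        }


def compartment_volumes(
    labels: np.ndarray, spacing: tuple[float, float, float]
) -> AerationProfile:
    """Compartment volumes and percentage fractions from a label grid.

    Voxel counts per label times the voxel volume; the five in-mask
    compartments sum exactly to V_exp by construction.
    """
    counts = np.bincount(labels.ravel().astype(np.int64), minlength=6)
    in_mask = int(counts[1:].sum())
    if in_mask == 0:
        raise EmptyMaskError("label grid contains no in-mask voxels")
    dz, dy, dx = spacing
    vox = dz * dy * dx
    v = {lab: float(counts[lab]) * vox for lab in AerationLabel if lab != 0}
    v_exp = in_mask * vox
    return AerationProfile(
        v_exp=v_exp,
        v_hyper=v[AerationLabel.HYPER],
        v_normo=v[AerationLabel.NORMO],
        v_hypo=v[AerationLabel.HYPO],
        v_non=v[AerationLabel.NON],
        v_dense_out=v[AerationLabel.DENSE_OUT],
        f_normo=100.0 * v[AerationLabel.NORMO] / v_exp,
        f_hypo=100.0 * v[AerationLabel.HYPO] / v_exp,
        f_non=100.0 * v[AerationLabel.NON] / v_exp,
    )


def mean_lung_attenuation(vol: ImageVolume, mask: LungMask) -> float:
    """Arithmetic mean HU over the in-mask voxels."""
    vol.require_unit(Unit.HU)
    if vol.shape != mask.mask.shape:
        raise EmptyMaskError("volume/mask shape mismatch")
    if not mask.mask.any():
        raise EmptyMaskError("MLA undefined for an empty mask")
    return float(vol.data[mask.mask].mean())


def frc(v_exp: float, mla: float) -> tuple[float, bool]:
    """Expiratory air content (FRC) from total lung volume and MLA.

    FRC = V_exp · MLA / AIR_HU, clamped to [0, V_exp].  Noise can push the
    MLA slightly outside [−1000, 0]; clamping is reported (and logged),
    never silent.  Returns (frc_mm3, clamped).
    """
    if v_exp <= 0:
        raise EmptyMaskError(f"v_exp must be > 0, got {v_exp}")
    raw = v_exp * mla / AIR_HU
    clamped = min(max(raw, 0.0), v_exp)
    if clamped != raw:
        log.warning("FRC %.3f mm3 clamped to [0, %.3f] (MLA %.1f HU)", raw, v_exp, mla)
    return clamped, clamped != raw


def tissue_volume(v_exp: float, frc_mm3: float) -> float:
    """Tissue volume = V_exp − FRC."""
    if not 0 <= frc_mm3 <= v_exp:
        raise EmptyMaskError(
            f"FRC {frc_mm3} outside [0, v_exp={v_exp}]; clamp FRC first"
        )
    return v_exp - frc_mm3


def air_tissue_ratio(frc_mm3: float, tissue_mm3: float) -> float:
    """Air/tissue ratio FRC / Tissue; fails explicitly on zero tissue."""
    if tissue_mm3 < 0:
        raise UndefinedRatioError(f"negative tissue volume {tissue_mm3}")
    if tissue_mm3 == 0:
        raise UndefinedRatioError("air/tissue ratio undefined: tissue volume is 0")
    return frc_mm3 / tissue_mm3


def summarize(
    vol: ImageVolume, mask: LungMask, bands: ClassificationBands = DEFAULT_BANDS
) -> AerationProfile:
    """Full per-scan profile: compartments, MLA, FRC, tissue, A/T, FRC/V_exp.

    In the pure-air limit (zero tissue) the A/T ratio is undefined and
    reported as NaN with a warning rather than raising, so batch runs keep
    the remaining readouts.
    """
    labels = classify_aeration(vol, mask, bands)
    profile = compartment_volumes(labels, vol.spacing)
    profile.mla = mean_lung_attenuation(vol, mask)
    profile.frc, profile.frc_clamped = frc(profile.v_exp, profile.mla)
    profile.tissue = tissue_volume(profile.v_exp, profile.frc)
    profile.frc_over_vexp = min(max(profile.frc / profile.v_exp, 0.0), 1.0)
    try:
        profile.at_ratio = air_tissue_ratio(profile.frc, profile.tissue)
    except UndefinedRatioError:
        log.warning("A/T undefined (tissue volume 0); reported as NaN")
        profile.at_ratio = math.nan
    return profile
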