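"""End-to-end per-scan quantification helpers.

Composes calibration, segmentation and aeration profiling into single
calls used by the CLI, the tests and the phantom calibration loop.
"""

from __future__ import annotations

from .aeration import AerationProfile, ClassificationBands, DEFAULT_BANDS, summarize
from .phantom import PhantomSpec, build_phantom
from .segmentation import (
    LungMask,
    MergeMode,
    SegmentationParams,
    merge_manual,
    segment_lungs,
)
from .volume_io import CalibrationPair, ImageVolume, Unit, grey_to_hu


def quantify_volume(
    vol: ImageVolume,
    calib: CalibrationPair | None = None,
    seg_params: SegmentationParams | None = None,
    bands: ClassificationBands = DEFAULT_BANDS,
    manual_mask: LungMask | None = None,
    merge_mode: MergeMode | str = MergeMode.UNION,
) -> tuple[AerationProfile, LungMask]:
    """Quantify one scan: calibrate if needed, segment, profile.

    A grey-level volume requires ``calib``; an HU volume is used as-is.
    When a manual mask is supplied it is merged with the automatic one
    (or replaces it, per ``merge_mode``).
    """
    if vol.unit is Unit.GREY:
        if calib is None:
            raise ValueError("grey-level volume requires a CalibrationPair")
        vol = grey_to_hu(vol, calib)
    if manual_mask is not None and MergeMode(merge_mode) is MergeMode.REPLACE:
        mask = merge_manual(manual_mask, manual_mask, MergeMode.REPLACE)
    else:
        mask = segment_lungs(vol, seg_params)
        if manual_mask is not None:
            mask = merge_manual(mask, manual_mask, merge_mode)
    return summarize(vol, mask, bands), mask


def quantify_phantom(
    spec: PhantomSpec,
    seg_params: SegmentationParams | None = None,
    bands: ClassificationBands = DEFAULT_BANDS,
):
    """Build a phantom and push it through the full pipeline.

    The airway seed of the phantom's sealed trachea is passed to the
    segmenter so the conducting-airway lumen is excluded from V_exp.
    Returns (profile, mask); the truth is recoverable by rebuilding the
    phantom from the same spec (determinism contract).
    """
    vol, truth, calib = build_phantom(spec)
    if seg_params is None:
        seg_params = SegmentationParams(airway_seed=truth.airway_seed)
    return quantify_volume(vol, calib=calib, seg_params=seg_params, bands=bands)
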