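"""Exception hierarchy.

Every failure mode the pipeline can surface deliberately derives from
:class:`LungQuantError` so batch drivers can distinguish "this scan is bad"
from programming errors.
"""


class LungQuantError(Exception):
    """Base class for all lungquant failures."""


class UnitError(LungQuantError):
    """An operation received a volume in the wrong intensity unit."""


class VolumeFormatError(LungQuantError):
    """Unreadable, non-3D or otherwise unsupported volume file."""


class DegenerateCalibrationError(LungQuantError):
    """Air and water grey anchors coincide; the HU rescaling is undefined."""


class NoLungFoundError(LungQuantError):
    """Segmentation produced an empty parenchyma mask."""


class SeedNotInAirError(LungQuantError):
    """Airway region-growing seed does not sit in an air voxel."""


class EmptyMaskError(LungQuantError):
    """A mask-consuming statistic was given a mask with no voxels."""


class UndefinedRatioError(LungQuantError):
    """Air/tissue ratio requested for a lung with zero tissue volume."""


class UndefinedCorrelationError(LungQuantError):
    """Rank correlation undefined (constant input after ranking)."""


class PhantomInfeasibleError(LungQuantError):
    """Requested lesion load cannot be placed in the phantom geometry."""


class CalibrationSearchError(LungQuantError):
    """Closed-loop parenchyma calibration found no parameters on the grid.

    Carries the best candidate examined so the caller can inspect how far
    off the grid was.
    """

    def __init__(self, message: str, best_candidate=None):
        super().__init__(message)
        self.best_candidate = best_candidate


class ConfigError(LungQuantError):
    """Invalid or incomplete batch-run configuration."""
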