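"""Exception hierarchy shared across the pipeline stages."""


class T2NomoError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(T2NomoError):
    """The voxel grid is too small to place the muscle VOI template."""


class MetadataError(T2NomoError):
    """A required sidecar field (e.g. echo times) is missing or inconsistent."""


class LabelTableError(T2NomoError):
    """A mask volume contains labels not described by its label table."""


class EmptyVOIError(T2NomoError):
    """A VOI selection yielded no valid voxels."""


class DegenerateDistributionError(T2NomoError):
    """Zero-variance input where a shape statistic is undefined."""


class DegenerateLabelsError(T2NomoError):
    """Only one outcome class present where two are required."""


class DegenerateTableError(T2NomoError):
    """A 2x2 table has a zero margin, so the chi-square statistic is undefined."""


class IncompleteDesignError(T2NomoError):
    """Missing cells in a subjects x raters agreement design."""


class CollinearityError(T2NomoError):
    """Singular or constant-column design matrix in a regression."""


class SchemaError(T2NomoError):
    """A table or value set does not match the expected column/name schema."""


class StateError(T2NomoError):
    """Operation requested on an object in an invalid state (e.g. unfitted model)."""


class PipelineError(T2NomoError):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage={stage}] {message}")
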