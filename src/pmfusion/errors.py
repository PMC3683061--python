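"""Named exceptions raised across the pipeline.

Every contract violation raises a subclass of :class:`PMFusionError` so
callers can distinguish pipeline errors from programming errors.
"""


class PMFusionError(Exception):
    """Base class for all pmfusion errors."""


class NonFiniteInputError(PMFusionError):
    """Input array contains NaN or infinite entries."""


class SingleClassError(PMFusionError):
    """A label vector for training or evaluation contains only one class."""


class NotPositiveSemidefiniteError(PMFusionError):
    """A Gram matrix is indefinite beyond numerical tolerance."""


class ViewMismatchError(PMFusionError):
    """Feature views disagree in subject count, ordering or modality set."""


class KernelShapeError(PMFusionError):
    """Kernel matrices passed together do not share a common dimension."""


class QCError(PMFusionError):
    """Genotype quality control removed every subject or every SNP."""


class PanelMatchError(PMFusionError):
    """No SNP of the requested panel is present in the genotype data."""


class MissingDataError(PMFusionError):
    """A column or SNP is entirely missing where values are required."""


class EmptyTableError(PMFusionError):
    """Table cleaning removed every row or every column."""


class EmptyIntersectionError(PMFusionError):
    """Subject matching across modalities produced an empty cohort."""


class ProtocolError(PMFusionError):
    """A cross-validation split cannot satisfy the protocol guarantees."""


class CodebookError(PMFusionError):
    """Codebook construction received fewer descriptors than clusters."""


class SimulationError(PMFusionError):
    """A simulation configuration cannot produce a usable cohort."""
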