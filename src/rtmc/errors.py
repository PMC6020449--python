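"""Exception hierarchy shared by all rtmc modules."""


class RTMCError(Exception):
    """Base class for every error raised by rtmc."""


class FormatError(RTMCError):
    """A file does not conform to the expected format or modality."""


class PlanContentError(RTMCError):
    """An RT plan is structurally valid DICOM but misses required content."""


class UnsupportedTechniqueError(RTMCError):
    """A delivery technique cannot be discretized into static beams."""


class SeriesError(RTMCError):
    """CT slices do not form a single consistent series."""


class GeometryError(RTMCError):
    """Inconsistent or degenerate spatial geometry."""


class ConversionError(RTMCError):
    """A HU value cannot be mapped to a material/density."""


class CapacityError(RTMCError):
    """A fixed-size code space (e.g. egsphant material codes) is exhausted."""


class TemplateError(RTMCError):
    """A parameter locator cannot be resolved inside an MC input template."""


class FormattingError(RTMCError):
    """A bound value does not fit the declared printf-style format width."""


class InfeasibleError(RTMCError):
    """A work distribution request cannot be satisfied (e.g. fewer nodes than beams)."""


class SimulationError(RTMCError):
    """A map-phase worker failed or the simulation request is degenerate."""


class EvaluationError(RTMCError):
    """Dose evaluation on empty or all-zero regions."""
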