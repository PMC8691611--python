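"""Exception taxonomy used across the package."""


class ActimetryError(Exception):
    """Base class for all actimetry errors."""


class FormatError(ActimetryError):
    """Malformed file header, columns, or container layout."""


class SamplingError(ActimetryError):
    """Timestamps deviate from uniform sampling beyond tolerance."""


class RangeError(ActimetryError):
    """Samples fall outside the sensor's full-scale range."""


class ParameterError(ActimetryError):
    """Invalid parameter value (cutoffs, thresholds, step sizes...)."""


class SizeError(ActimetryError):
    """Input too short for the requested operation."""


class AlignmentError(ActimetryError):
    """Series that must share a grid / lineage do not."""


class ApplicabilityError(ActimetryError):
    """(metric, dataset) pair not permitted by the applicability matrix."""


class CoverageError(ActimetryError):
    """A subject is missing catalog entries required for aggregation."""


class UndefinedCorrelationError(ActimetryError):
    """Pearson coefficient undefined because an input is constant."""


class DegenerateThresholdWarning(UserWarning):
    """SD-adaptive threshold collapsed to its base offset (constant data)."""
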