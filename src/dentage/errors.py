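"""Exception hierarchy for the dentage package."""


class DentageError(Exception):
    """Base class for all dentage errors."""


class RatingError(DentageError):
    """Invalid tooth-stage rating (missing tooth, unknown stage, bad dates)."""


class WeightTableError(DentageError):
    """Stage-weight table violates its invariants."""


class AgeRangeError(DentageError):
    """Chronological age outside the validated range."""


class CoverageError(DentageError):
    """Score or age outside a conversion standard's coverage."""


class StandardFormatError(DentageError):
    """Conversion-standard document fails schema validation."""


class FitError(DentageError):
    """Polynomial fit cannot be performed (rank deficiency, empty data)."""


class ReliabilityError(DentageError):
    """Reliability coefficient undefined (zero total variance)."""
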