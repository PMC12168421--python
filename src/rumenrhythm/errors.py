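"""Exception hierarchy shared across the package."""


class RumenRhythmError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RumenRhythmError, ValueError):
    """A numeric argument is outside its valid domain (negative SD, zero denominator, ...)."""


class RankDeficiencyError(RumenRhythmError, ValueError):
    """Too few distinct time points (mod period) to identify the harmonic terms."""


class InsufficientDataError(RumenRhythmError, ValueError):
    """Not enough observations / taxa / subjects for the requested analysis."""


class ConfigurationError(RumenRhythmError, ValueError):
    """An inconsistent study design, class mix, or pipeline configuration."""


class FormatError(RumenRhythmError, ValueError):
    """A malformed input table (duplicate ids, negative values, bad row sums)."""


class ConsistencyError(RumenRhythmError, ValueError):
    """Cross-table mismatch, e.g. a classified taxon missing from the abundance table."""


class AlignmentError(RumenRhythmError, ValueError):
    """Sample sets of two matrices/tables do not match."""


class UndefinedStatisticError(RumenRhythmError, ValueError):
    """A statistic is undefined for the given input (all-zero vector, zero TVFA, ...)."""
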