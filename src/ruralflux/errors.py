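"""Exception hierarchy."""


class RuralFluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RuralFluxError, ValueError):
    """Invalid generator or pipeline configuration."""


class GridParseError(RuralFluxError, ValueError):
    """A grid/census/settlement file is malformed; message names the line."""


class GridIntegrityError(RuralFluxError, ValueError):
    """Duplicate (cell_id, day) rows, unmapped cells, or inconsistent tables."""


class DegenerateSeriesError(RuralFluxError, ValueError):
    """Series has no residual variation; the break t-statistic is undefined."""


class SeriesLengthError(RuralFluxError, ValueError):
    """Series too short for the requested analysis."""
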