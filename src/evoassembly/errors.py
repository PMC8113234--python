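"""Exception types shared across the pipeline stages."""


class EvoAssemblyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EvoAssemblyError, ValueError):
    """Input table is structurally malformed (missing columns, bad dialect)."""


class DataError(EvoAssemblyError, ValueError):
    """Input table parsed but violates a data invariant (e.g. fractions not summing to 1)."""


class ConfigError(EvoAssemblyError, ValueError):
    """Simulation or run configuration is invalid."""


class UndefinedResultError(EvoAssemblyError, ValueError):
    """A statistic is undefined for the given input (e.g. variability of one replicate)."""
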