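"""Exception hierarchy shared across the package."""


class HeritkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HeritkitError, ValueError):
    """Invalid configuration value (threshold, distribution tag, grid, ...)."""


class DataError(HeritkitError, ValueError):
    """Input data violates a precondition (all-missing SNP, bad index, ...)."""


class FormatError(HeritkitError, ValueError):
    """A file does not parse under the declared dialect."""


class PedigreeError(HeritkitError, ValueError):
    """Structurally invalid pedigree (cycles, missing parents, bad zygosity groups)."""


class DesignError(HeritkitError, ValueError):
    """Rank-deficient or otherwise unusable fixed-effect design."""


class NumericalError(HeritkitError, RuntimeError):
    """Numerical failure during model fitting; carries the iteration trace when available."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
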