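"""Exception types shared across the package."""


class LnclocError(Exception):
    """Base class for package errors."""


class AlphabetError(LnclocError, ValueError):
    """A residue outside the working alphabet was encountered."""


class EmptyDatasetError(LnclocError, ValueError):
    """An input file or dataset contained no usable records."""


class ConfigError(LnclocError, ValueError):
    """An invalid configuration value."""


class DegenerateInputError(LnclocError, ValueError):
    """Input too short or too uniform for the requested statistic."""


class StructureParseError(LnclocError, ValueError):
    """A dot-bracket string is unbalanced or contains unsupported symbols."""


class EngineUnavailableError(LnclocError, RuntimeError):
    """The external folding engine could not be run."""


class NotFittedError(LnclocError, RuntimeError):
    """A transformation was applied before being fitted."""


class StratificationError(LnclocError, ValueError):
    """A class is too small for the requested cross-validation layout."""
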