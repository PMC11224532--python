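"""Exception hierarchy shared across the package."""


class TriReadError(Exception):
    """Base class for all triread errors."""


class EncodingError(TriReadError, ValueError):
    """A spelling or pronunciation does not fit the slot template."""


class GenerationError(TriReadError, ValueError):
    """Infeasible synthetic-lexicon parameters."""


class LexiconParseError(TriReadError, ValueError):
    """Malformed lexicon file; the message names the offending row."""


class NumericError(TriReadError, FloatingPointError):
    """Non-finite activations or losses during network computation."""


class ConfigurationError(TriReadError, ValueError):
    """Invalid or out-of-order use of the training/analysis pipeline."""


class AnalysisError(TriReadError, ValueError):
    """A statistical procedure cannot be run on the given data."""
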