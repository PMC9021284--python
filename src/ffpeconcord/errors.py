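"""Exception types shared across the package."""


class FFPEConcordError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(FFPEConcordError):
    """A VCF record violates the assumptions of the analysis (e.g. short PL)."""


class ConsistencyError(FFPEConcordError):
    """Two call sets disagree in a way that indicates different references."""


class ConfigError(FFPEConcordError):
    """Invalid run or simulation configuration."""
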