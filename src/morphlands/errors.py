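"""Exception hierarchy shared across the pipeline stages."""


class MorphlandsError(Exception):
    """Base class for all package errors."""


class SchemaError(MorphlandsError):
    """A required column or trait declaration is missing or malformed."""


class ValidationError(MorphlandsError):
    """Input data violate an invariant (nonpositive linear trait, missing label, ...)."""


class DegeneracyError(MorphlandsError):
    """A computation is undefined on this input (zero variance, constant surface, ...)."""
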