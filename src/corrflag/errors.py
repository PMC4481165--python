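"""Exception types shared across corrflag modules."""


class ValidationError(ValueError):
    """Input data violates a structural invariant (duplicate ids, bad shape, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; message carries row/column coordinates."""


class ConstantInputError(ValueError):
    """Correlation requested on a constant vector, where it is undefined."""


class DegeneratePairError(RuntimeError):
    """Too few valid bootstrap replicates to form a confidence interval."""


class FitError(RuntimeError):
    """A mixture fit failed (EM degeneracy) for every candidate model size."""
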