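"""Exception types shared across the pipeline."""


class ModcogError(Exception):
    """Base class for all modcog errors."""


class ParameterError(ModcogError, ValueError):
    """An argument is outside its valid range or inconsistent with others."""


class FormatError(ModcogError, ValueError):
    """An input array or file does not have the expected shape/columns."""


class DegenerateInputError(ModcogError, ValueError):
    """Input is technically well-formed but carries no usable signal."""


class ConvergenceError(ModcogError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostic trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace
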