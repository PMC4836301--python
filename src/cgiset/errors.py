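class CgisetError(Exception):
    """Base class for all package errors."""


class ValidationError(CgisetError, ValueError):
    """An input violated a structural or numeric invariant."""


class SamplerError(CgisetError, RuntimeError):
    """The MCMC sampler hit a non-finite or degenerate state."""
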