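"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data (malformed sequence, table, pedigree...).

    CLI maps this to exit code 2.
    """


class NonConvergenceError(RuntimeError):
    """A model fit did not converge and no usable iterate is available.

    CLI maps this to exit code 3.  Note that :func:`fit_reml` normally returns
    the best iterate with ``converged=False`` instead of raising.
    """


class NoProductError(InputError):
    """In-silico PCR found no amplification product."""


class MultiProductError(InputError):
    """In-silico PCR found more than one distinct product."""
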