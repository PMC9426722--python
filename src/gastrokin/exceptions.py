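"""Exception and warning types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A configuration value is invalid or internally inconsistent."""


class DataError(ValueError):
    """An input table violates the expected schema or preconditions."""


class ConvergenceWarning(UserWarning):
    """An MCMC fit did not meet the convergence gate; summaries are flagged."""
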