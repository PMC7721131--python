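"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value or combination of values."""


class FeasibilityError(ConfigError):
    """A generator configuration whose implied variance decomposition is impossible.

    The message names the violated constraint.
    """


class AlignmentError(ValueError):
    """Summary statistics and reference panel disagree on SNP identity or alleles."""
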