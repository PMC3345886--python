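"""Exception and warning types shared across the package."""


class InputError(ValueError):
    """Invalid user input: bad ranges, unknown variables, malformed files.

    The command-line interface maps this to exit code 1; any other
    exception maps to exit code 2.
    """


class ConfigError(InputError):
    """A pipeline configuration failed schema validation.

    The message always names the offending key.
    """


class SeparationWarning(UserWarning):
    """Complete or quasi-complete separation detected during a logistic fit.

    The fitted coefficients are reported but at least one of them is
    diverging; its maximum-likelihood estimate does not exist.
    """
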