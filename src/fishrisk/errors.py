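"""Exception hierarchy shared across the pipeline stages."""


class FishriskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FishriskError):
    """A configuration object or file is invalid; the message names the field."""


class InputError(FishriskError):
    """Input data violate a precondition (bad coordinates, missing countries...)."""


class UndefinedResultError(FishriskError):
    """The requested quantity is mathematically undefined for these inputs."""


class ValidationError(FishriskError):
    """One or more rows of an input table failed validation.

    Carries the full list of issues so callers see every problem at once.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__(
            "input validation failed:\n" + "\n".join(f"  - {i}" for i in self.issues)
        )
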