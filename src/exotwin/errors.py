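"""Exception hierarchy for the exoskeleton twin."""


class ExotwinError(Exception):
    """Base class for all package errors."""


class OutOfWorkspaceError(ExotwinError):
    """A requested platform position cannot be reached by one or more arms."""

    def __init__(self, message: str, arm: int | None = None):
        super().__init__(message)
        self.arm = arm


class ConfigurationError(ExotwinError):
    """Invalid geometry, parameters, or joint configuration."""


class SingularityError(ExotwinError):
    """Operation requested at (or too near) a kinematic singularity."""


class JointLimitError(ExotwinError):
    """Joint angles outside the configured limits."""
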