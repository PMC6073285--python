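"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so scripted pipelines can
tell a bad parameter file from a bad image from a bad path.
"""


class NMJQuantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NMJQuantError, ValueError):
    """Input data violates a documented precondition (e.g. empty region)."""


class ConfigurationError(NMJQuantError):
    """Configuration is missing or inconsistent (e.g. unknown channel)."""


class PlacementError(NMJQuantError):
    """Synthetic geometry could not be placed under the stated constraints."""
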