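"""Exception hierarchy shared across the package."""


class DdrCnaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DdrCnaError, ValueError):
    """A scenario, genome or run configuration is internally inconsistent."""


class DataError(DdrCnaError, ValueError):
    """Input data violate a structural contract (duplicates, bad coordinates...)."""
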