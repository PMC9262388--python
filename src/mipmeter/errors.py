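"""Exception hierarchy shared across the package."""


class MipmeterError(Exception):
    """Base class for all package errors."""


class FormatError(MipmeterError):
    """An input file could not be parsed."""


class MissingStrainError(MipmeterError):
    """A requested strain is absent from the VCF header."""

    def __init__(self, strains):
        self.strains = list(strains)
        super().__init__(f"strains absent from VCF header: {', '.join(self.strains)}")


class ProbeRejection(MipmeterError):
    """A candidate SNV admits no valid probe placement.

    Carries a machine-readable ``reason`` so panel construction can report
    per-strain shortfalls without aborting.
    """

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


class ConfigError(MipmeterError):
    """A configuration file or object violates the documented schema."""


class DependencyError(MipmeterError):
    """A pipeline stage was requested without its upstream inputs."""
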