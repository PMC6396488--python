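"""Exception types shared across the package."""


class GdparentError(Exception):
    """Base class for all package errors."""


class GenotypeFormatError(GdparentError):
    """The input genotype table violates the expected tab-delimited format."""


class NoUsableLociError(GdparentError):
    """Every locus was dropped during encoding (tri-allelic or all-missing)."""


class ConfigurationError(GdparentError):
    """An analysis cannot be set up from the given roster or parameters."""
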