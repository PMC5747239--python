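"""Exception hierarchy for bovimpute."""


class BovimputeError(Exception):
    """Base class for all package errors."""


class VcfParseError(BovimputeError):
    """Malformed or unsupported VCF content."""


class MultiallelicError(VcfParseError):
    """A record carries more than one ALT allele (only biallelic SNPs are supported)."""


class PedigreeError(BovimputeError):
    """Invalid pedigree structure (cycles, duplicate ids, missing parents)."""


class DimensionError(BovimputeError):
    """Array shapes inconsistent with samples/sites."""
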