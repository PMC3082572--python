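"""Exception types shared across the pipeline."""


class RadprintError(Exception):
    """Base class for all pipeline errors."""


class ManifestError(RadprintError):
    """Invalid barcode/pedigree manifest."""


class FastqError(RadprintError):
    """Malformed or inconsistent FASTQ input."""


class NormalizationError(RadprintError):
    """Fragment-count normalization could not be performed automatically."""
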