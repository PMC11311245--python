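"""Exception hierarchy for m2mcalib."""


class M2MError(Exception):
    """Base class for all m2mcalib errors."""


class FormatError(M2MError):
    """A dataset container is missing required structure or attributes."""


class GeometryError(M2MError):
    """A frame is too small for the requested patch grid."""


class CoverageError(M2MError):
    """A patch collection does not cover every required axial zone."""


class DegenerateInputError(M2MError):
    """Input is degenerate for the requested computation (e.g. all-zero
    spectrum, all-tied paired samples)."""
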