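"""Exception hierarchy shared across the pipeline stages."""


class ChimeranetError(Exception):
    """Base class for all package-specific errors."""


class PositionNotExonicError(ChimeranetError, ValueError):
    """A genomic position does not fall inside any exon of the transcript."""


class OffsetOutOfRangeError(ChimeranetError, ValueError):
    """A transcript-relative breakpoint offset lies outside the spliced sequence."""


class NoInitiationCodonError(ChimeranetError, ValueError):
    """The chimeric coding sequence contains no ATG initiation codon."""


class UnknownSymbolError(ChimeranetError, ValueError):
    """A sequence symbol is outside the 22-letter encoding alphabet."""


class MalformedTensorError(ChimeranetError, ValueError):
    """An encoded tensor violates the one-hot invariant."""


class ShapeInfeasibleError(ChimeranetError, ValueError):
    """A network configuration collapses the feature map to zero length."""


class EmptyClassError(ChimeranetError, ValueError):
    """A training set does not contain both classes."""


class SplitInfeasibleError(ChimeranetError, ValueError):
    """No group-disjoint partition satisfies the requested sizes."""


class UnknownIdError(ChimeranetError, KeyError):
    """A split plan refers to a fusion id absent from the dataset."""
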