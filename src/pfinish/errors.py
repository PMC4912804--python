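"""Exception hierarchy for pfinish."""


class PfinishError(Exception):
    """Base class for all package errors."""


class ParameterError(PfinishError, ValueError):
    """Invalid parameter value (bad lengths, rates, geometry)."""


class LocusNotFoundError(PfinishError, KeyError):
    """A named feature/marker is absent from the annotation."""


class AmbiguousMergeError(PfinishError):
    """One contig end has two distinct, equally good merge partners."""

    def __init__(self, end: str, partners):
        self.end = end
        self.partners = list(partners)
        super().__init__(
            f"contig end {end} matches multiple partners: {', '.join(self.partners)}"
        )


class AnnotationStateError(PfinishError, RuntimeError):
    """Operation requires an annotated plastome."""


class UndefinedRatioError(PfinishError, ZeroDivisionError):
    """Depth ratio undefined (zero coverage in the reference interval)."""


class SizeError(PfinishError, ValueError):
    """Problem size outside the supported range (e.g. > 7 taxa for
    exhaustive tree enumeration)."""


class FormatError(PfinishError, ValueError):
    """Malformed input (ragged alignment, bad primer table, ...)."""
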