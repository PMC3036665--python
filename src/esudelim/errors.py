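"""Exception hierarchy shared across the pipeline."""


class EsudelimError(Exception):
    """Base class for all pipeline errors."""


class FormatError(EsudelimError):
    """An input file or value violates its expected format/vocabulary."""


class AlignmentError(EsudelimError):
    """Sequences cannot form a valid alignment (e.g. unequal lengths)."""


class LabelMismatchError(EsudelimError):
    """Tree leaves and alignment/matrix labels do not correspond."""


class UndefinedDistanceError(EsudelimError):
    """No comparable sites remain for a pair (pairwise deletion removed all)."""


class SaturationError(EsudelimError):
    """Observed divergence is at or beyond the model's saturation point."""
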