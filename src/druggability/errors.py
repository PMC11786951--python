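"""Exception hierarchy for the druggability pipeline."""


class DruggabilityError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(DruggabilityError):
    """A structure contains no atoms after parsing/stripping."""


class DegenerateInputError(DruggabilityError):
    """Input too small or ill-posed for the requested computation."""


class UndefinedDescriptorError(DruggabilityError):
    """A pocket descriptor is undefined for the given geometry."""


class NoNeighborsError(DruggabilityError):
    """No reference pockets within the neighborhood radius (density DLID)."""


class MissingScoreError(DruggabilityError):
    """A required raw or normalized score is absent."""
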