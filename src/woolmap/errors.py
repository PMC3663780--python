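"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class NotASimpleDeletionError(ValueError):
    """Raised when two sequences differ by anything other than one contiguous deletion.

    Carries ``conflict_pos``, the first position (0-based, on the longer
    sequence) at which the single-deletion model breaks down.
    """

    def __init__(self, message: str, conflict_pos: int):
        super().__init__(message)
        self.conflict_pos = conflict_pos
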