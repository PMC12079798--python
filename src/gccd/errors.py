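"""Exception types shared across the package."""


class GccdError(Exception):
    """Base class for package-specific errors."""


class FormatError(GccdError):
    """A structure or table file could not be parsed in the named format."""


class EmptySelectionError(GccdError):
    """A residue/chain selection matched no alpha-carbon atoms."""


class RosterMismatchError(GccdError):
    """Frames of one trajectory disagree on their (chain, residue) roster."""

    def __init__(self, frame_index: int, message: str):
        self.frame_index = frame_index
        super().__init__(f"frame {frame_index}: {message}")


class ParameterError(GccdError):
    """An argument violates an operation's contract."""


class SizeError(GccdError):
    """Input too large for a combinatorial (brute-force) routine."""


class SelectionError(GccdError):
    """Automatic epsilon-grid selection failed (e.g. all sample barcodes empty)."""
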