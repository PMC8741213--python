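"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2, ``StageError`` to exit code 3.
"""


class AllonetError(Exception):
    """Base class for all package errors."""


class InputError(AllonetError, ValueError):
    """Invalid user input: bad parameter, mismatched residue sets, missing file."""


class StageError(AllonetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
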