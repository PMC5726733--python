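"""Exception hierarchy shared across the package."""


class ContigPathError(Exception):
    """Base class for all package-specific errors."""


class InputError(ContigPathError, ValueError):
    """Invalid user input: bad file, bad residue key, bad parameter."""


class EmptyStructureError(InputError):
    """A structure ended up with zero residues after parsing/filtering."""


class GenerationError(ContigPathError, RuntimeError):
    """Synthetic-structure packing could not be satisfied within the retry budget."""


class EnumerationLimitError(ContigPathError, RuntimeError):
    """Exhaustive enumeration refused: combination count above the configured limit."""


class FitError(ContigPathError, RuntimeError):
    """Curve fit failed to converge; carries solver diagnostics in ``args``."""
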