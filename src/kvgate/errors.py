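"""Exception hierarchy shared by all kvgate modules."""


class KvgateError(Exception):
    """Base class for all kvgate-specific errors."""


class ParseError(KvgateError):
    """A text input (PDB record, window series, metadata line) could not be parsed."""


class StructureError(KvgateError):
    """A trajectory or frame violates a structural invariant (e.g. inconsistent atom counts)."""


class SelectionError(KvgateError):
    """A residue or atom selection could not be resolved on a frame/trajectory."""


class UndefinedTorsionError(KvgateError):
    """A dihedral or angle is undefined because of collinear/coincident points."""


class GenerationError(KvgateError):
    """A synthetic-fixture specification is unsatisfiable."""


class ReconstructionError(KvgateError):
    """WHAM cannot reconstruct a profile (e.g. no histogram overlap between windows)."""


class ConfigError(KvgateError):
    """An analysis configuration file is invalid or incomplete."""
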