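"""Exception hierarchy for fibrilkit."""


class FibrilError(Exception):
    """Base class for all fibrilkit errors."""


class StructureFormatError(FibrilError):
    """Input coordinate file could not be parsed."""


class EmptyModelError(FibrilError):
    """Structure contains no polymer chain with amino-acid residues."""


class CorrespondenceError(FibrilError):
    """Layers cannot be matched residue-by-residue."""


class UnsupportedResidueError(FibrilError):
    """Requested residue type is not a standard amino acid."""


class ConfigurationError(FibrilError):
    """A rule, threshold or config entry is missing or inconsistent."""
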