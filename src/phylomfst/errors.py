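"""Exception hierarchy."""


class PhyloError(Exception):
    """Base class for all errors raised by phylomfst."""


class NewickParseError(PhyloError):
    """Malformed Newick input."""


class DuplicateLeafError(PhyloError):
    """A leaf label occurs more than once in a single tree."""


class LeafNotFoundError(PhyloError):
    """A requested leaf label is absent from the tree."""


class InvalidTreeError(PhyloError):
    """A structural invariant is violated (e.g. an internal node with < 2 children)."""


class ConfigError(PhyloError):
    """Invalid mining configuration (support fraction, input sizes, ...)."""


class MiningLimitError(PhyloError):
    """The configured enumeration-node cap was exceeded."""


class JoinConsistencyError(PhyloError):
    """A constructed join failed its defensive post-verification.

    This signals an internal classification bug, never bad user input.
    """
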