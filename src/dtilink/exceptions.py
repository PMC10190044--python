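"""Exception hierarchy shared across the pipeline stages."""


class DTILinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidMoleculeError(DTILinkError):
    """A SMILES string could not be parsed into a molecule."""


class InvalidSequenceError(DTILinkError):
    """A protein sequence contains characters outside the amino-acid alphabet."""


class DimensionError(DTILinkError):
    """Vector or matrix dimensions do not match the operation's contract."""


class DuplicateIdentifierError(DTILinkError):
    """An identifier appears more than once where uniqueness is required."""


class UnknownNodeError(DTILinkError):
    """An association references a drug or protein absent from the similarity layers."""


class MissingEmbeddingError(DTILinkError):
    """A node required for feature construction has no embedding vector."""


class VocabularyError(DTILinkError):
    """An interaction label is not part of the six-type vocabulary."""


class LabelConflictError(DTILinkError):
    """A drug-protein pair is recorded both as positive and as 'inactive'."""


class ConfigError(DTILinkError):
    """A configuration value is missing, unknown, or inconsistent."""
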