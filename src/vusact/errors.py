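"""Exception hierarchy for vusact.

All library errors derive from :class:`VusactError` so callers can catch
one base class at pipeline boundaries.
"""


class VusactError(Exception):
    """Base class for all vusact errors."""


class ParseError(VusactError):
    """A protein-change string does not match any accepted dialect."""


class FormatError(VusactError):
    """An input file is malformed (missing columns, bad values)."""


class IntegrityError(VusactError):
    """Knowledgebase invariant violated (duplicate keys, unknown genes)."""


class UnknownGeneError(VusactError):
    """A gene symbol is absent from the gene registry."""


class GeneMismatchError(VusactError):
    """Two variants on different genes were compared for distance."""


class EmptyInputError(VusactError):
    """An operation requiring a non-empty input received an empty one."""


class DegenerateTableError(VusactError):
    """A 2x2 contingency table has a zero margin."""


class MissingWildtypeError(VusactError):
    """No wildtype behavior recorded for a (gene, cell line) in an assay batch."""


class NonActionableGeneError(VusactError):
    """Assay integration requested for a gene not classified actionable."""


class ConfigError(VusactError):
    """Invalid simulation or run configuration."""


class JoinError(VusactError):
    """Classification and assay tables could not be joined on (gene, change)."""
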