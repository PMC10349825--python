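"""Protein-level variant model and change-string parser.

Variants arrive as one-letter protein HGVS-style strings attached to a gene
symbol (``BRAF V600E``, ``KIT Y375_K455del``). The parser normalizes the
string, classifies the event subtype, and records the 1-based inclusive
codon span the event touches. Two curation dialects beyond standard protein
HGVS are accepted because they occur in real curated knowledgebases: an
extra underscore before ``delins`` (``H64_Y65_delinsQS``) and the ``>``
shorthand for a deletion-insertion (``P551_M552 > L``).

Coordinates are protein codon positions, 1-based and inclusive. For an
insertion between two flanking residues (``D770_N771insGF``) the span covers
both flanking residues, [770, 771].
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum

from .errors import ParseError

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"


class VariantSubtype(str, Enum):
    """Event subtype of a protein-level change.

    The proximity-eligible subset — the subtypes that may serve as, or be
    scored against, an actionable neighbor — is exactly ``{missense,
    inframe_deletion, inframe_insertion, duplication, delins}``. Nonsense and
    frameshift changes are truncating and are handled by literature review,
    not proximity.
    """

    MISSENSE = "missense"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Subtypes that can participate in proximity scoring.
PROXIMITY_ELIGIBLE: frozenset[VariantSubtype] = frozenset(
    {
        VariantSubtype.MISSENSE,
        VariantSubtype.INFRAME_DELETION,
        VariantSubtype.INFRAME_INSERTION,
        VariantSubtype.DUPLICATION,
        VariantSubtype.DELINS,
    }
)

#: Subtypes that truncate the protein.
TRUNCATING: frozenset[VariantSubtype] = frozenset(
    {VariantSubtype.NONSENSE, VariantSubtype.FRAMESHIFT}
)


@dataclass(frozen=True, order=True)
class CodonSpan:
    """1-based inclusive codon interval on a protein."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ParseError(f"invalid codon span [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def contains_span(self, other: "CodonSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "CodonSpan") -> bool:
        return self.start <= other.end and other.start <= self.end

    @property
    def is_single(self) -> bool:
        return self.start == self.end


@dataclass(frozen=True)
class ProteinVariant:
    """A parsed protein-level change on a gene.

    Attributes
    ----------
    gene : str
        Uppercase gene symbol.
    raw : str
        The change string as supplied.
    normalized : str
        Canonical form of the change string; parsing it reproduces this
        variant exactly.
    subtype : VariantSubtype
        Event classification.
    span : CodonSpan
        Codon interval the event touches (1-based, inclusive).
    alt_residues : str or None
        Inserted or substituted residues, when the dialect carries them.
    """

    gene: str
    raw: str
    normalized: str
    subtype: VariantSubtype
    span: CodonSpan
    alt_residues: str | None = None

    @property
    def key(self) -> tuple[str, str]:
        """Identity key used throughout the package: (gene, normalized)."""
        return (self.gene, self.normalized)

    def is_proximity_eligible(self) -> bool:
        return self.subtype in PROXIMITY_ELIGIBLE

    def is_truncating(self) -> bool:
        return self.subtype in TRUNCATING


# --- grammar -----------------------------------------------------------------

_POS = r"([A-Z])(\d+)"
_RANGE = rf"{_POS}(?:_{_POS})?"

# Matching happens on the cleaned, uppercased string, so event
# keywords appear uppercase here; normalized output uses lowercase keywords.
_RE_DELINS = re.compile(rf"^{_RANGE}_?DELINS([A-Z*]+)$")
_RE_ARROW = re.compile(rf"^{_RANGE}>([A-Z*]+)$")
_RE_DUP = re.compile(rf"^{_RANGE}DUP$")
_RE_DEL = re.compile(rf"^{_RANGE}DEL$")
_RE_INS = re.compile(rf"^{_POS}_{_POS}INS([A-Z]+)$")
_RE_FS = re.compile(rf"^{_POS}([A-Z]?)FS(\*?\d*|X\d*)$")
_RE_SUB = re.compile(rf"^{_POS}([A-Z*=])$")


def _clean(text: str) -> str:
    s = "".join(text.split())
    if s.lower().startswith("p."):
        s = s[2:]
    return s


def _span(m: re.Match, lo: int = 1, hi: int = 3) -> CodonSpan:
    start = int(m.group(lo + 1))
    end = int(m.group(hi + 1)) if m.group(hi + 1) is not None else start
    if end < start:
        raise ParseError(f"span end {end} precedes start {start}")
    return CodonSpan(start, end)


def parse_protein_change(
    gene: str, text: str, *, strict: bool = False
) -> ProteinVariant:
    """Parse a one-letter protein change string into a :class:`ProteinVariant`.

    Parameters
    ----------
    gene : str
        Gene symbol; stored uppercase.
    text : str
        Change string, optionally prefixed ``p.``; whitespace tolerated.
    strict : bool
        When true, a string matching no accepted dialect raises
        :class:`~vusact.errors.ParseError`. When false (default) such a
        string yields ``subtype=other`` with a best-effort span, and a
        warning is logged, so cohort files with stray records do not abort
        a run.

    Examples
    --------
    >>> v = parse_protein_change("BRAF", "V600E")
    >>> v.subtype.value, (v.span.start, v.span.end)
    ('missense', (600, 600))
    """
    if not text or not text.strip():
        raise ParseError("empty protein change string")
    gene = gene.strip().upper()
    if not gene:
        raise ParseError("empty gene symbol")
    raw = text
    s = _clean(text).upper()

    def build(
        subtype: VariantSubtype, span: CodonSpan, normalized: str, alt: str | None
    ) -> ProteinVariant:
        return ProteinVariant(gene, raw, normalized, subtype, span, alt)

    m = _RE_DELINS.match(s) or _RE_ARROW.match(s)
    if m:
        span = _span(m)
        alt = m.group(5)
        ref = _norm_range(m)
        return build(VariantSubtype.DELINS, span, f"{ref}delins{alt}", alt)

    m = _RE_DUP.match(s)
    if m:
        span = _span(m)
        return build(VariantSubtype.DUPLICATION, span, f"{_norm_range(m)}dup", None)

    m = _RE_DEL.match(s)
    if m:
        span = _span(m)
        return build(
            VariantSubtype.INFRAME_DELETION, span, f"{_norm_range(m)}del", None
        )

    m = _RE_INS.match(s)
    if m:
        start, end = int(m.group(2)), int(m.group(4))
        if end < start:
            raise ParseError(f"span end {end} precedes start {start}")
        span = CodonSpan(start, end)
        alt = m.group(5)
        norm = f"{m.group(1)}{start}_{m.group(3)}{end}ins{alt}"
        return build(VariantSubtype.INFRAME_INSERTION, span, norm, alt)

    m = _RE_FS.match(s)
    if m:
        pos = int(m.group(2))
        span = CodonSpan(pos, pos)
        return build(VariantSubtype.FRAMESHIFT, span, f"{m.group(1)}{pos}fs", None)

    m = _RE_SUB.match(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        span = CodonSpan(pos, pos)
        norm = f"{ref}{pos}{alt}"
        if alt in ("*", "X"):
            return build(VariantSubtype.NONSENSE, span, f"{ref}{pos}*", None)
        if alt == "=" or alt == ref:
            return build(VariantSubtype.SYNONYMOUS, span, norm, alt)
        return build(VariantSubtype.MISSENSE, span, norm, alt)

    if strict:
        raise ParseError(f"unrecognized protein change: {text!r}")
    logger.warning("unrecognized protein change %r (gene %s); subtype=other", text, gene)
    span = _best_effort_span(s)
    return build(VariantSubtype.OTHER, span, s, None)


def _norm_range(m: re.Match) -> str:
    start = int(m.group(2))
    if m.group(3) is not None:
        return f"{m.group(1)}{start}_{m.group(3)}{int(m.group(4))}"
    return f"{m.group(1)}{start}"


def _best_effort_span(s: str) -> CodonSpan:
    nums = [int(n) for n in re.findall(r"\d+", s) if int(n) >= 1]
    if not nums:
        raise ParseError(f"no codon position found in {s!r}")
    return CodonSpan(min(nums), max(nums))


def normalize_protein_change(text: str, *, strict: bool = True) -> str:
    """Return the canonical form of a change string.

    Strips the ``p.`` prefix and whitespace, uppercases residues, removes the
    spurious underscore before ``delins``, and rewrites the ``A_B > X``
    shorthand as ``A_BdelinsX``. Idempotent on its own output.
    """
    return parse_protein_change("_NORM", text, strict=strict).normalized


def is_proximity_eligible(v: ProteinVariant) -> bool:
    """True iff the variant subtype may participate in proximity scoring."""
    return v.is_proximity_eligible()
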