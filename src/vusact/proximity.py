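"""Inter-variant codon distance and nearest-actionable-neighbor search.

The distance between two protein variants on the same gene is defined on
their codon spans, in amino acids:

1. both single-codon: the absolute difference of the two positions
   (D323A vs D323E -> 0; G12D vs G13D -> 1);
2. single vs multi-codon: 0 when the single position lies inside the
   other's span (K385M vs Y375_K455del -> 0);
3. the mirror of case 2;
4. both multi-codon: 0 when the spans are identical or one is nested
   inside the other (P551_M552delinsL vs K550_K558del -> 0).

Every remaining configuration falls back to the difference of the two most
N-terminal positions (D770_N771insGF vs N771_P772insH -> 1). For the
non-contained single-vs-multi configurations, where only the containment
branch is pinned down by the scheme, the same start-difference fallback is
applied by default; ``fallback="boundary"`` instead measures to the nearest
span boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import GeneMismatchError, UnknownGeneError
from .knowledgebase import Knowledgebase, KnowledgebaseRecord, ProteinFeature
from .knowledgebase import actionable_variants
from .variant import ProteinVariant

DistanceFallback = Literal["start", "boundary"]


@dataclass(frozen=True)
class NeighborResult:
    """Nearest actionable neighbor of a variant, or none when the gene has
    no proximity-eligible Yes-actionable records."""

    neighbor: KnowledgebaseRecord | None
    distance: int | None

    def __bool__(self) -> bool:
        return self.neighbor is not None


def variant_distance(
    a: ProteinVariant,
    b: ProteinVariant,
    *,
    fallback: DistanceFallback = "start",
) -> int:
    """Amino-acid distance between two variants on the same gene.

    Symmetric, non-negative, and zero on identical spans. Raises
    :class:`~vusact.errors.GeneMismatchError` when the genes differ.
    """
    if a.gene != b.gene:
        raise GeneMismatchError(f"cannot compare {a.gene} with {b.gene}")
    sa, sb = a.span, b.span

    if sa.is_single and sb.is_single:
        return abs(sa.start - sb.start)
    if sa.is_single and sb.contains(sa.start):
        return 0
    if sb.is_single and sa.contains(sb.start):
        return 0
    if not sa.is_single and not sb.is_single:
        if sa.contains_span(sb) or sb.contains_span(sa):
            return 0
    if fallback == "boundary":
        if sa.overlaps(sb):
            return 0
        return max(sa.start, sb.start) - min(sa.end, sb.end)
    return abs(sa.start - sb.start)


def nearest_actionable(
    v: ProteinVariant,
    kb: Knowledgebase,
    *,
    fallback: DistanceFallback = "start",
) -> NeighborResult:
    """Nearest proximity-eligible Yes-actionable record to ``v`` on its gene.

    The variant itself (same gene + normalized change) never counts as its
    own neighbor. Ties are broken by smaller span start, then lexicographic
    normalized string — the same order ``actionable_variants`` returns, so a
    plain minimum scan is stable.
    """
    candidates = [
        r
        for r in actionable_variants(kb, v.gene, eligible_only=True)
        if r.key != v.key
    ]
    if not candidates:
        return NeighborResult(neighbor=None, distance=None)
    best = min(
        candidates,
        key=lambda r: (
            variant_distance(v, r.variant, fallback=fallback),
            r.variant.span.start,
            r.variant.normalized,
        ),
    )
    return NeighborResult(
        neighbor=best, distance=variant_distance(v, best.variant, fallback=fallback)
    )


def in_qualifying_feature(
    v: ProteinVariant,
    kb: Knowledgebase,
    *,
    full_containment: bool = False,
) -> tuple[bool, ProteinFeature | None]:
    """Does ``v`` sit in a functional, non-disordered feature that also
    contains at least one proximity-eligible Yes-actionable record?

    A feature qualifies when (a) it is flagged functional and not
    disordered, (b) the variant's span overlaps the feature's span (or is
    fully contained, with ``full_containment``), and (c) some Yes-actionable
    eligible record other than ``v`` itself overlaps the feature. The first
    qualifying feature in (start, name) order is returned.
    """
    if v.gene not in kb.genes:
        raise UnknownGeneError(f"gene {v.gene!r} not in registry")
    anchors = [
        r for r in actionable_variants(kb, v.gene, eligible_only=True) if r.key != v.key
    ]
    for feature in kb.features_for_gene(v.gene):
        if not feature.functional or feature.disordered:
            continue
        hit = (
            feature.span.contains_span(v.span)
            if full_containment
            else feature.span.overlaps(v.span)
        )
        if not hit:
            continue
        if any(r.variant.span.overlaps(feature.span) for r in anchors):
            return True, feature
    return False, None
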