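"""Rule engine assigning an actionability value to a variant.

The decision cascade, applied in order:

1. gene not therapeutically actionable -> **No**;
2. exact curated match in the knowledgebase (same gene and normalized
   change, with known functional significance or explicit assertions) ->
   the curated aggregate value;
3. truncating variant (nonsense, frameshift) -> **Unknown**, routed to
   manual literature review rather than proximity scoring;
4. the variant sits in a functional, non-disordered protein feature that
   contains an actionable mutation -> **Potentially** (domain rule);
5. the variant is within ``proximity_threshold`` amino acids (default 5,
   inclusive) of a proximity-eligible Yes-actionable record ->
   **Potentially** (proximity rule);
6. otherwise -> **Unknown**.

Every result carries the rule that fired and its evidence (the qualifying
feature, or the neighbor and distance), so downstream audit never needs to
recompute a classification.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, UnknownGeneError
from .knowledgebase import (
    ActionabilityValue,
    FunctionalSignificance,
    Knowledgebase,
)
from .proximity import (
    DistanceFallback,
    NeighborResult,
    in_qualifying_feature,
    nearest_actionable,
)
from .variant import ProteinVariant, parse_protein_change

logger = logging.getLogger(__name__)

DEFAULT_PROXIMITY_THRESHOLD = 5


class RuleFired(str, Enum):
    GENE_NOT_ACTIONABLE = "gene_not_actionable"
    CURATED_MATCH = "curated_match"
    TRUNCATING_MANUAL_REVIEW = "truncating_manual_review"
    DOMAIN_RULE = "domain_rule"
    PROXIMITY_RULE = "proximity_rule"
    NO_RULE = "no_rule"


@dataclass(frozen=True)
class ClassificationResult:
    variant: ProteinVariant
    value: ActionabilityValue
    rule_fired: RuleFired
    neighbor: str | None = None
    distance: int | None = None
    feature: str | None = None


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunables of the rule engine.

    ``proximity_threshold`` is inclusive: "within five amino acids" fires at
    distance 5 and not at 6. ``distance_fallback`` selects the convention
    for non-contained span pairs (see :mod:`vusact.proximity`).
    """

    proximity_threshold: int = DEFAULT_PROXIMITY_THRESHOLD
    distance_fallback: DistanceFallback = "start"
    full_containment: bool = False
    strict: bool = False


def classify_variant(
    v: ProteinVariant,
    kb: Knowledgebase,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Run the decision cascade for one parsed variant."""
    cfg = config or ClassifierConfig()

    info = kb.gene_info(v.gene, strict=cfg.strict)
    if not info.actionable:
        return ClassificationResult(
            v, ActionabilityValue.NO, RuleFired.GENE_NOT_ACTIONABLE
        )

    # A curated record only short-circuits the cascade when it asserts
    # something: known functional significance, or an actionability value
    # beyond Unknown. A placeholder record (unknown FS, Unknown value) still
    # flows through the domain/proximity rules like any uncurated VUS.
    curated = kb.records.get(v.key)
    if curated is not None and (
        curated.functional_significance is not FunctionalSignificance.UNKNOWN
        or curated.aggregate_value is not ActionabilityValue.UNKNOWN
    ):
        return ClassificationResult(
            v, curated.aggregate_value, RuleFired.CURATED_MATCH
        )

    if v.is_truncating():
        return ClassificationResult(
            v, ActionabilityValue.UNKNOWN, RuleFired.TRUNCATING_MANUAL_REVIEW
        )

    in_feature, feature = in_qualifying_feature(
        v, kb, full_containment=cfg.full_containment
    )
    if in_feature:
        return ClassificationResult(
            v,
            ActionabilityValue.POTENTIALLY,
            RuleFired.DOMAIN_RULE,
            feature=feature.name,
        )

    near: NeighborResult = nearest_actionable(v, kb, fallback=cfg.distance_fallback)
    if near and near.distance <= cfg.proximity_threshold:
        return ClassificationResult(
            v,
            ActionabilityValue.POTENTIALLY,
            RuleFired.PROXIMITY_RULE,
            neighbor=near.neighbor.variant.normalized,
            distance=near.distance,
        )

    return ClassificationResult(v, ActionabilityValue.UNKNOWN, RuleFired.NO_RULE)


def classify_cohort(
    variants: Iterable[ProteinVariant | tuple[str, str]],
    kb: Knowledgebase,
    config: ClassifierConfig | None = None,
) -> list[ClassificationResult]:
    """Classify a cohort, preserving input order.

    Accepts parsed variants or raw ``(gene, change)`` pairs. In lenient mode
    (the default) an unparseable row is skipped with a warning; strict mode
    propagates the error. Summary counts per value are logged.
    """
    cfg = config or ClassifierConfig()
    results: list[ClassificationResult] = []
    skipped = 0
    for item in variants:
        if isinstance(item, ProteinVariant):
            v = item
        else:
            gene, change = item
            try:
                v = parse_protein_change(gene, change, strict=cfg.strict)
            except ParseError:
                if cfg.strict:
                    raise
                logger.warning("skipping unparseable row (%s, %s)", gene, change)
                skipped += 1
                continue
        results.append(classify_variant(v, kb, cfg))
    tally = Counter(r.value.label for r in results)
    logger.info(
        "classified %d variants (%d skipped): %s", len(results), skipped, dict(tally)
    )
    return results


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Tabulate classification results with stable column order."""
    return pd.DataFrame(
        [
            {
                "gene": r.variant.gene,
                "protein_change": r.variant.normalized,
                "actionability": r.value.label,
                "rule_fired": r.rule_fired.value,
                "neighbor": r.neighbor or "",
                "distance": "" if r.distance is None else r.distance,
                "feature": r.feature or "",
            }
            for r in results
        ],
        columns=[
            "gene",
            "protein_change",
            "actionability",
            "rule_fired",
            "neighbor",
            "distance",
            "feature",
        ],
    )
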