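"""Functional-genomics viability assay interpretation.

Each variant is expressed in growth-factor-dependent cell lines (Ba/F3 and
MCF10A) alongside the wildtype gene, and its effect on viability under
growth-factor withdrawal is recorded categorically: ``increased``,
``no_change`` or ``decreased`` relative to wildtype. The quantitative
thresholding of raw viability curves happens upstream on the assay
platform; this module consumes the categorical calls.

Interpretation has two stages. First, **informativeness gating** per gene x
cell line: a context is informative only if the wildtype or at least one
variant of the gene promoted viability there (otherwise the gene's
oncogenic potential is simply not observable in that background), and the
wildtype's behavior must not contradict the gene's role — an oncogene whose
wildtype suppresses growth, or a tumor suppressor whose wildtype promotes
it, cannot be scored for the effect under study. Second, **calling**: over
the informative lines only, increased viability in at least one line (with
no decrease elsewhere) is *oncogenic*; opposing effects across lines are
*conflicting*; anything else is *not oncogenic*.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    MissingWildtypeError,
    NonActionableGeneError,
)
from .knowledgebase import (
    ActionabilityAssertion,
    ActionabilityValue,
    AssertionBasis,
    GeneInfo,
    GeneRole,
    KnowledgebaseRecord,
)
from .variant import ProteinVariant, parse_protein_change

BAF3 = "BaF3"
MCF10A = "MCF10A"
DEFAULT_CELL_LINES = (BAF3, MCF10A)


class Effect(str, Enum):
    """Categorical viability effect of a variant vs its wildtype."""

    INCREASED = "increased"
    NO_CHANGE = "no_change"
    DECREASED = "decreased"


class WildtypeEffect(str, Enum):
    """Behavior of the wildtype construct in a cell line."""

    PROMOTES = "promotes"
    SUPPRESSES = "suppresses"
    NEUTRAL = "neutral"


class AssayVerdict(str, Enum):
    ONCOGENIC = "oncogenic"
    NOT_ONCOGENIC = "not_oncogenic"
    CONFLICTING = "conflicting"
    NON_INFORMATIVE = "non_informative"


class IntegrationOutcome(str, Enum):
    """How an assay call lands in the knowledgebase next to the literature."""

    BECAME_ACTIONABLE = "became_actionable"
    BECAME_NOT_ACTIONABLE = "became_not_actionable"
    KNOWN_ACTIONABLE = "known_actionable"
    KNOWN_NOT_ACTIONABLE = "known_not_actionable"
    UNCLEAR = "unclear"


@dataclass(frozen=True)
class AssayObservation:
    variant: ProteinVariant
    cell_line: str
    effect: Effect


@dataclass(frozen=True)
class WildtypeBehavior:
    gene: str
    cell_line: str
    wt_effect: WildtypeEffect


@dataclass(frozen=True)
class AssayCall:
    variant: ProteinVariant
    call: AssayVerdict
    informative_lines: tuple[str, ...]


def gene_line_informative(
    gene: str,
    cell_line: str,
    batch_observations: Sequence[AssayObservation],
    wt_behavior: Mapping[tuple[str, str], WildtypeEffect],
    gene_info: GeneInfo,
) -> bool:
    """Is the (gene, cell line) context informative for oncogenicity calls?

    Requires (a) a positive control — the wildtype promotes viability or at
    least one variant of the gene shows increased viability in the line —
    and (b) no role contradiction: an oncogene whose wildtype suppresses
    viability, or a tumor suppressor whose wildtype promotes it, is
    non-informative in that line. Genes of role ``both`` or ``unknown`` are
    only subject to the positive-control requirement.
    """
    key = (gene.upper(), cell_line)
    if key not in wt_behavior:
        raise MissingWildtypeError(f"no wildtype behavior for {key}")
    wt = wt_behavior[key]

    some_variant_promotes = any(
        o.variant.gene == gene.upper()
        and o.cell_line == cell_line
        and o.effect is Effect.INCREASED
        for o in batch_observations
    )
    if wt is not WildtypeEffect.PROMOTES and not some_variant_promotes:
        return False

    role = gene_info.role
    if role is GeneRole.ONCOGENE and wt is WildtypeEffect.SUPPRESSES:
        return False
    if role is GeneRole.TUMOR_SUPPRESSOR and wt is WildtypeEffect.PROMOTES:
        return False
    return True


def call_variant_assay(
    observations: Sequence[AssayObservation],
    informative: Mapping[str, bool],
) -> AssayCall:
    """Collapse one variant's per-line observations into a single verdict.

    ``informative`` maps cell-line label -> gating result for this variant's
    gene. Observations in non-informative lines are discarded before
    calling; with no informative line left the verdict is
    ``non_informative``.
    """
    if not observations:
        raise EmptyInputError("no assay observations for variant")
    variant = observations[0].variant
    if any(o.variant.key != variant.key for o in observations):
        raise ValueError("observations span multiple variants")

    usable = [o for o in observations if informative.get(o.cell_line, False)]
    lines = tuple(sorted({o.cell_line for o in usable}))
    if not usable:
        return AssayCall(variant, AssayVerdict.NON_INFORMATIVE, lines)

    effects = {o.effect for o in usable}
    if Effect.INCREASED in effects and Effect.DECREASED in effects:
        return AssayCall(variant, AssayVerdict.CONFLICTING, lines)
    if Effect.INCREASED in effects:
        return AssayCall(variant, AssayVerdict.ONCOGENIC, lines)
    return AssayCall(variant, AssayVerdict.NOT_ONCOGENIC, lines)


def call_batch(
    observations: Sequence[AssayObservation],
    wt_behavior: Mapping[tuple[str, str], WildtypeEffect],
    gene_registry: Mapping[str, GeneInfo],
) -> list[AssayCall]:
    """Gate and call every variant in a batch; one call per variant,
    in first-appearance order."""
    gating: dict[tuple[str, str], bool] = {}
    for gene, line in sorted({(o.variant.gene, o.cell_line) for o in observations}):
        gating[(gene, line)] = gene_line_informative(
            gene, line, observations, wt_behavior, gene_registry[gene]
        )

    by_variant: dict[tuple[str, str], list[AssayObservation]] = {}
    order: list[tuple[str, str]] = []
    for o in observations:
        if o.variant.key not in by_variant:
            order.append(o.variant.key)
        by_variant.setdefault(o.variant.key, []).append(o)

    calls = []
    for key in order:
        obs = by_variant[key]
        gene = obs[0].variant.gene
        informative = {
            line: gating[(gene, line)] for line in {o.cell_line for o in obs}
        }
        calls.append(call_variant_assay(obs, informative))
    return calls


def integrate_assay(
    call: AssayCall,
    gene_info: GeneInfo,
    existing_record: KnowledgebaseRecord | None = None,
) -> tuple[IntegrationOutcome, ActionabilityAssertion | None]:
    """Fold an assay verdict into the knowledgebase next to curated literature.

    Curated literature takes precedence: a record already asserting Yes or
    No keeps its value (``known_actionable`` / ``known_not_actionable``),
    and a contradiction between the assay verdict and that curated value is
    flagged ``unclear`` with no new assertion. With no literature in the
    way, an oncogenic verdict yields a Yes assertion and a not-oncogenic
    verdict a No assertion, both with basis ``functional_genomics``.
    """
    if not gene_info.actionable:
        raise NonActionableGeneError(
            f"gene {gene_info.gene} is not classified actionable"
        )

    literature = None
    if existing_record is not None:
        lit_values = [
            a.value
            for a in existing_record.assertions
            if a.basis is not AssertionBasis.FUNCTIONAL_GENOMICS
        ]
        if lit_values:
            literature = max(lit_values)

    if call.call in (AssayVerdict.CONFLICTING, AssayVerdict.NON_INFORMATIVE):
        return IntegrationOutcome.UNCLEAR, None

    if literature is ActionabilityValue.YES:
        if call.call is AssayVerdict.NOT_ONCOGENIC:
            return IntegrationOutcome.UNCLEAR, None
        return IntegrationOutcome.KNOWN_ACTIONABLE, None
    if literature is ActionabilityValue.NO:
        if call.call is AssayVerdict.ONCOGENIC:
            return IntegrationOutcome.UNCLEAR, None
        return IntegrationOutcome.KNOWN_NOT_ACTIONABLE, None

    if call.call is AssayVerdict.ONCOGENIC:
        return (
            IntegrationOutcome.BECAME_ACTIONABLE,
            ActionabilityAssertion(
                ActionabilityValue.YES,
                context="functional genomics",
                basis=AssertionBasis.FUNCTIONAL_GENOMICS,
            ),
        )
    return (
        IntegrationOutcome.BECAME_NOT_ACTIONABLE,
        ActionabilityAssertion(
            ActionabilityValue.NO,
            context="functional genomics",
            basis=AssertionBasis.FUNCTIONAL_GENOMICS,
        ),
    )


# --- TSV I/O -----------------------------------------------------------------

ASSAY_COLUMNS = ["gene", "protein_change", "cell_line", "effect"]


def read_assay_tsv(
    path, *, strict: bool = False
) -> tuple[list[AssayObservation], dict[tuple[str, str], WildtypeEffect]]:
    """Read an assay batch TSV into observations and wildtype behavior.

    Columns: gene, protein_change, cell_line, effect. Wildtype rows carry
    ``protein_change=WT`` and an effect of ``promotes``/``suppresses``/
    ``neutral``; variant rows carry ``increased``/``no_change``/
    ``decreased``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    observations: list[AssayObservation] = []
    wt_behavior: dict[tuple[str, str], WildtypeEffect] = {}
    for row in df.itertuples(index=False):
        gene = row.gene.strip().upper()
        if row.protein_change.strip().upper() == "WT":
            wt_behavior[(gene, row.cell_line)] = WildtypeEffect(row.effect.strip())
        else:
            variant = parse_protein_change(gene, row.protein_change, strict=strict)
            observations.append(
                AssayObservation(variant, row.cell_line, Effect(row.effect.strip()))
            )
    return observations, wt_behavior


def calls_to_frame(calls: Sequence[AssayCall]):
    """Tabulate assay calls (gene, protein_change, call, informative_lines)."""
    return pd.DataFrame(
        [
            {
                "gene": c.variant.gene,
                "protein_change": c.variant.normalized,
                "call": c.call.value,
                "informative_lines": ";".join(c.informative_lines),
            }
            for c in calls
        ],
        columns=["gene", "protein_change", "call", "informative_lines"],
    )
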