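"""Seeded synthetic knowledgebases, VUS cohorts and assay batches.

Real curated knowledgebases cannot be redistributed, so every pipeline
stage here runs against synthetic inputs with the same statistical
structure: actionable genes carrying Yes-actionable "anchor" variants
inside functional domains, cohorts of VUS placed either near those anchors
(so the Potentially rules fire) or in empty stretches of the protein (so
they stay Unknown), and assay outcomes drawn class-conditionally — a VUS
classified Potentially is oncogenic with higher probability than one
classified Unknown. The default probabilities (0.37 vs 0.13) and cohort
size (438, ~47% Potentially, 20 genes) mirror the prospective validation
cohort of the classification scheme; the conflicting-call rate defaults to
4/438.

Two fully deterministic fixture cohorts are also provided, reproducing the
validation study's exact count flows end-to-end (classifier -> assay ->
contingency): see :func:`curated_cohort_fixture` (438 variants) and
:func:`computational_cohort_fixture` (777 variants). Gene names and codon
positions in the fixtures are synthetic placeholders; only the count
structure is real.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import (
    DEFAULT_CELL_LINES,
    AssayObservation,
    Effect,
    WildtypeBehavior,
    WildtypeEffect,
)
from .errors import ConfigError
from .knowledgebase import (
    ActionabilityAssertion,
    ActionabilityValue,
    AssertionBasis,
    FunctionalSignificance,
    GeneInfo,
    GeneRole,
    Knowledgebase,
    KnowledgebaseRecord,
    ProteinFeature,
)
from .variant import CodonSpan, ProteinVariant, parse_protein_change

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic generator.

    Defaults emulate the prospective validation cohort: 20 actionable
    genes, 438 VUS of which ~47% satisfy a Potentially rule, oncogenic
    probability 0.37 given Potentially and 0.13 given Unknown, and a ~1%
    conflicting-call rate. ``seed`` must be explicit; all draws flow from
    one generator seeded with it.
    """

    n_genes: int = 20
    features_per_gene: int = 3
    actionable_fraction_of_genes: float = 1.0
    n_curated_yes_per_gene: int = 3
    cohort_size: int = 438
    potentially_fraction: float = 206 / 438
    p_oncogenic_given_potentially: float = 0.37
    p_oncogenic_given_unknown: float = 0.13
    p_conflicting: float = 4 / 438
    proximity_threshold: int = 5
    protein_length: int = 2000
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "actionable_fraction_of_genes": self.actionable_fraction_of_genes,
            "potentially_fraction": self.potentially_fraction,
            "p_oncogenic_given_potentially": self.p_oncogenic_given_potentially,
            "p_oncogenic_given_unknown": self.p_oncogenic_given_unknown,
            "p_conflicting": self.p_conflicting,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name, n in {
            "n_genes": self.n_genes,
            "cohort_size": self.cohort_size,
            "protein_length": self.protein_length,
        }.items():
            if n <= 0:
                raise ConfigError(f"{name}={n} must be positive")
        if self.features_per_gene < 0 or self.n_curated_yes_per_gene < 0:
            raise ConfigError("feature/record counts must be non-negative")
        if self.proximity_threshold < 0:
            raise ConfigError("proximity_threshold must be non-negative")
        if self.protein_length < 600:
            raise ConfigError("protein_length < 600 leaves no empty stretch")


def _residue(position: int) -> str:
    """Deterministic pseudo-sequence: the residue at a codon position."""
    return _AA[position % len(_AA)]


def _alt_for(ref: str) -> str:
    return "A" if ref != "A" else "V"


def _missense(gene: str, position: int, alt: str | None = None) -> ProteinVariant:
    ref = _residue(position)
    alt = alt or _alt_for(ref)
    return parse_protein_change(gene, f"{ref}{position}{alt}")


def generate_knowledgebase(cfg: SimulationConfig) -> Knowledgebase:
    """Synthesize genes, domain annotations and Yes-actionable anchors.

    Each gene gets ``features_per_gene`` non-overlapping functional
    features in the N-terminal half of the protein (one in three flagged
    disordered) and ``n_curated_yes_per_gene`` Yes-actionable missense
    anchors placed inside the non-disordered features. The C-terminal
    ~third of every protein is left empty so cohort variants can be placed
    out of reach of every rule. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    kb = Knowledgebase()

    n_actionable = int(round(cfg.n_genes * cfg.actionable_fraction_of_genes))
    for g in range(cfg.n_genes):
        gene = f"SYN{g + 1:03d}"
        actionable = g < n_actionable
        kb.genes[gene] = GeneInfo(
            gene=gene,
            actionable=actionable,
            role=GeneRole.ONCOGENE,
        )

        # Features tile the N-terminal half; the last third stays empty.
        usable_end = cfg.protein_length // 2
        clean_features: list[ProteinFeature] = []
        if cfg.features_per_gene:
            slot = usable_end // cfg.features_per_gene
            for i in range(cfg.features_per_gene):
                lo = i * slot + 10
                width = int(rng.integers(slot // 4, slot // 2 + 1))
                start = int(rng.integers(lo, max(lo + 1, (i + 1) * slot - width)))
                disordered = i % 3 == 2
                feature = ProteinFeature(
                    gene=gene,
                    name=("disordered region " if disordered else "domain ")
                    + str(i + 1),
                    span=CodonSpan(start, start + width),
                    functional=not disordered,
                    disordered=disordered,
                )
                kb.add_feature(feature)
                if not disordered:
                    clean_features.append(feature)

        if actionable and cfg.n_curated_yes_per_gene and clean_features:
            for j in range(cfg.n_curated_yes_per_gene):
                home = clean_features[j % len(clean_features)]
                position = int(
                    rng.integers(home.span.start, home.span.end + 1)
                )
                anchor = _missense(gene, position)
                if anchor.key in kb.records:
                    continue
                kb.add_record(
                    KnowledgebaseRecord(
                        variant=anchor,
                        functional_significance=FunctionalSignificance.GAIN_OF_FUNCTION,
                        assertions=(
                            ActionabilityAssertion(
                                ActionabilityValue.YES,
                                context="synthetic inhibitor",
                                basis=AssertionBasis.LITERATURE,
                            ),
                        ),
                    )
                )
    return kb


@dataclass
class SyntheticCohort:
    """A generated (or fixture) cohort ready to run through the pipeline."""

    kb: Knowledgebase
    variants: list[ProteinVariant]
    observations: list[AssayObservation]
    wt_behavior: dict[tuple[str, str], WildtypeEffect]

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": v.gene, "protein_change": v.normalized} for v in self.variants],
            columns=["gene", "protein_change"],
        )

    def assay_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": gene,
                "protein_change": "WT",
                "cell_line": line,
                "effect": wt.value,
            }
            for (gene, line), wt in sorted(self.wt_behavior.items())
        ]
        rows += [
            {
                "gene": o.variant.gene,
                "protein_change": o.variant.normalized,
                "cell_line": o.cell_line,
                "effect": o.effect.value,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=["gene", "protein_change", "cell_line", "effect"])


def _draw_effects(
    rng: np.random.Generator, p_oncogenic: float, p_conflicting: float
) -> tuple[Effect, Effect]:
    """Per-variant effects in (Ba/F3, MCF10A), class-conditionally drawn."""
    u = rng.random()
    if u < p_conflicting:
        return Effect.INCREASED, Effect.DECREASED
    if rng.random() < p_oncogenic:
        # Oncogenic in at least one line; second line never opposes.
        second = Effect.NO_CHANGE if rng.random() < 0.7 else Effect.INCREASED
        return Effect.INCREASED, second
    first = Effect.NO_CHANGE if rng.random() < 0.8 else Effect.DECREASED
    return first, Effect.NO_CHANGE


def generate_cohort(kb: Knowledgebase, cfg: SimulationConfig) -> SyntheticCohort:
    """Place VUS on the knowledgebase's genes and draw their assay effects.

    A ``potentially_fraction`` share of the cohort is placed within
    ``proximity_threshold`` of a Yes-actionable anchor (or inside its
    domain), the rest in the empty C-terminal stretch; assay effects are
    then drawn with the class-conditional oncogenic probabilities and the
    conflicting rate. Wildtype behavior is `promotes` everywhere, so every
    gene x line context is informative.
    """
    cfg.validate()
    rng = np.random.default_rng((cfg.seed, 1))
    actionable_genes = [
        g for g, info in sorted(kb.genes.items()) if info.actionable
    ]
    anchors = {
        g: [
            r.variant
            for r in kb.records_for_gene(g)
            if r.aggregate_value is ActionabilityValue.YES
        ]
        for g in actionable_genes
    }
    anchored_genes = [g for g in actionable_genes if anchors[g]]
    # Without any Yes-actionable anchor no variant can satisfy a Potentially
    # rule; the whole cohort is then placed in the empty stretch.
    host_genes = anchored_genes or sorted(kb.genes)
    n_potentially = (
        int(round(cfg.cohort_size * cfg.potentially_fraction))
        if anchored_genes
        else 0
    )
    used: set[tuple[str, str]] = {k for k in kb.records}
    variants: list[ProteinVariant] = []
    classes: list[bool] = []  # True => placed to satisfy a Potentially rule

    empty_start = cfg.protein_length * 2 // 3

    for i in range(cfg.cohort_size):
        near = i < n_potentially
        gene = host_genes[int(rng.integers(len(host_genes)))]
        for _ in range(1000):
            if near:
                anchor = anchors[gene][int(rng.integers(len(anchors[gene])))]
                offset = int(
                    rng.integers(-cfg.proximity_threshold, cfg.proximity_threshold + 1)
                )
                position = max(1, anchor.span.start + offset)
            else:
                position = int(rng.integers(empty_start, cfg.protein_length + 1))
            v = _missense(gene, position)
            if v.key not in used:
                break
            # Collision: try a different alt residue before re-drawing.
            ref = _residue(position)
            alts = [a for a in _AA if a != ref]
            v = _missense(gene, position, alts[int(rng.integers(len(alts)))])
            if v.key not in used:
                break
        else:
            raise ConfigError("could not place a unique variant; cohort too dense")
        used.add(v.key)
        variants.append(v)
        classes.append(near)

    observations: list[AssayObservation] = []
    for v, near in zip(variants, classes):
        p_onc = (
            cfg.p_oncogenic_given_potentially
            if near
            else cfg.p_oncogenic_given_unknown
        )
        e_baf3, e_mcf = _draw_effects(rng, p_onc, cfg.p_conflicting)
        observations.append(AssayObservation(v, DEFAULT_CELL_LINES[0], e_baf3))
        observations.append(AssayObservation(v, DEFAULT_CELL_LINES[1], e_mcf))

    wt = {
        (g, line): WildtypeEffect.PROMOTES
        for g in kb.genes
        for line in DEFAULT_CELL_LINES
    }
    return SyntheticCohort(kb=kb, variants=variants, observations=observations, wt_behavior=wt)


# --- deterministic fixture cohorts ------------------------------------------


def _fixture_build(
    prefix: str,
    n_genes: int,
    potentially_counts: tuple[int, int, int],
    unknown_counts: tuple[int, int, int],
) -> SyntheticCohort:
    """Deterministically build a cohort with exact class x outcome counts.

    ``*_counts`` are (oncogenic, not_oncogenic, conflicting) per
    classification class. Genes are laid out identically: one functional
    domain [100, 400] anchored by a Yes missense at 150, a disordered
    region [500, 600], a lone Yes anchor at codon 1000, and an empty
    stretch from 2000 up where Unknown variants live.
    """
    kb = Knowledgebase()
    genes = [f"{prefix}{g + 1:03d}" for g in range(n_genes)]
    for gene in genes:
        kb.genes[gene] = GeneInfo(gene=gene, actionable=True, role=GeneRole.ONCOGENE)
        kb.add_feature(
            ProteinFeature(gene, "kinase domain", CodonSpan(100, 400), True, False)
        )
        kb.add_feature(
            ProteinFeature(
                gene, "disordered region", CodonSpan(500, 600), False, True
            )
        )
        for position in (150, 1000):
            kb.add_record(
                KnowledgebaseRecord(
                    variant=_missense(gene, position),
                    functional_significance=FunctionalSignificance.GAIN_OF_FUNCTION,
                    assertions=(
                        ActionabilityAssertion(
                            ActionabilityValue.YES,
                            context="synthetic inhibitor",
                            basis=AssertionBasis.LITERATURE,
                        ),
                    ),
                )
            )

    used: set[tuple[str, str]] = set(kb.records)

    def place(index: int, near: bool) -> ProteinVariant:
        gene = genes[index % n_genes]
        slot = index // n_genes
        if near:
            # Alternate between the domain interior (domain rule) and the
            # +/-5 window around the lone anchor at 1000 (proximity rule).
            if slot % 2 == 0:
                position = 101 + slot  # inside [100, 400]
            else:
                position = 995 + (slot % 11)  # within 5 of 1000
        else:
            position = 2000 + slot  # beyond every feature and anchor
        ref = _residue(position)
        for alt in _AA:
            if alt == ref:
                continue
            v = _missense(gene, position, alt)
            if v.key not in used:
                used.add(v.key)
                return v
        raise ConfigError("fixture placement exhausted alt residues")

    variants: list[ProteinVariant] = []
    outcomes: list[str] = []
    for near, (n_onc, n_not, n_conf) in (
        (True, potentially_counts),
        (False, unknown_counts),
    ):
        start = len(variants)
        for j in range(n_onc + n_not + n_conf):
            variants.append(place(start + j, near))
            outcomes.append(
                "oncogenic"
                if j < n_onc
                else ("not_oncogenic" if j < n_onc + n_not else "conflicting")
            )

    effect_map = {
        "oncogenic": (Effect.INCREASED, Effect.NO_CHANGE),
        "not_oncogenic": (Effect.NO_CHANGE, Effect.NO_CHANGE),
        "conflicting": (Effect.INCREASED, Effect.DECREASED),
    }
    observations: list[AssayObservation] = []
    for v, outcome in zip(variants, outcomes):
        e_baf3, e_mcf = effect_map[outcome]
        observations.append(AssayObservation(v, DEFAULT_CELL_LINES[0], e_baf3))
        observations.append(AssayObservation(v, DEFAULT_CELL_LINES[1], e_mcf))

    wt = {
        (g, line): WildtypeEffect.PROMOTES
        for g in genes
        for line in DEFAULT_CELL_LINES
    }
    return SyntheticCohort(kb=kb, variants=variants, observations=observations, wt_behavior=wt)


def curated_cohort_fixture() -> SyntheticCohort:
    """The 438-variant validation cohort with its exact count flows.

    206 variants satisfy a Potentially rule and 232 do not; assay outcomes
    are fixed so the batch yields 106 oncogenic, 328 not oncogenic and 4
    conflicting calls (2 per class), giving the 2x2 table
    [[76, 128], [30, 200]] after conflict exclusion. Gene symbols and codon
    positions are synthetic placeholders.
    """
    return _fixture_build(
        "FIX", n_genes=20, potentially_counts=(76, 128, 2), unknown_counts=(30, 200, 2)
    )


def computational_cohort_fixture() -> SyntheticCohort:
    """The 777-variant computationally classified cohort.

    659 variants satisfy a Potentially rule (290 oncogenic) and 118 do not
    (9 oncogenic); no conflicting calls. Contingency after exclusion:
    [[290, 369], [9, 109]].
    """
    return _fixture_build(
        "CMP", n_genes=20, potentially_counts=(290, 369, 0), unknown_counts=(9, 109, 0)
    )
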