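"""Curated-variant knowledgebase: data model, TSV I/O, precedence rules.

A knowledgebase bundles three flat tables:

* **records** — curated variants, each carrying one or more actionability
  assertions (value + drug context + evidence basis) and a functional
  significance call;
* **genes** — the gene registry, marking which genes are therapeutically
  actionable and their oncogene / tumor-suppressor role;
* **features** — protein features (domains, regions) as codon intervals,
  flagged functional and/or disordered.

When a variant carries several actionability assertions (one per drug or
drug class), the aggregate value is the maximum under the fixed precedence
Yes > Potentially > Unknown > No.

All files are tab-delimited UTF-8 with a header row; see the ``load_*``
functions for the expected columns.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    IntegrityError,
    UnknownGeneError,
)
from .variant import CodonSpan, ProteinVariant, parse_protein_change

logger = logging.getLogger(__name__)


@total_ordering
class ActionabilityValue(Enum):
    """Variant actionability, totally ordered Yes > Potentially > Unknown > No."""

    NO = 0
    UNKNOWN = 1
    POTENTIALLY = 2
    YES = 3

    def __lt__(self, other: "ActionabilityValue") -> bool:
        if not isinstance(other, ActionabilityValue):
            return NotImplemented
        return self.value < other.value

    @classmethod
    def from_label(cls, label: str) -> "ActionabilityValue":
        try:
            return _ACTIONABILITY_LABELS[label.strip().lower()]
        except KeyError:
            raise FormatError(f"unknown actionability value {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.capitalize() if self is not ActionabilityValue.NO else "No"


_ACTIONABILITY_LABELS = {
    "yes": ActionabilityValue.YES,
    "potentially": ActionabilityValue.POTENTIALLY,
    "unknown": ActionabilityValue.UNKNOWN,
    "no": ActionabilityValue.NO,
}


class FunctionalSignificance(str, Enum):
    GAIN_OF_FUNCTION = "gain_of_function"
    LOSS_OF_FUNCTION = "loss_of_function"
    NEUTRAL = "neutral"
    UNKNOWN = "unknown"
    CONFLICTING = "conflicting"


class AssertionBasis(str, Enum):
    LITERATURE = "literature"
    FUNCTIONAL_GENOMICS = "functional_genomics"
    INFERRED = "inferred"


class GeneRole(str, Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    BOTH = "both"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ActionabilityAssertion:
    """One actionability value tied to a drug or drug-class context."""

    value: ActionabilityValue
    context: str = ""
    basis: AssertionBasis = AssertionBasis.LITERATURE


@dataclass(frozen=True)
class KnowledgebaseRecord:
    """A curated variant with its assertions and functional significance."""

    variant: ProteinVariant
    functional_significance: FunctionalSignificance
    assertions: tuple[ActionabilityAssertion, ...]
    evidence_note: str = ""

    def __post_init__(self) -> None:
        if not self.assertions:
            raise IntegrityError(
                f"curated record {self.variant.key} has no actionability assertions"
            )

    @property
    def aggregate_value(self) -> ActionabilityValue:
        return aggregate_actionability([a.value for a in self.assertions])

    @property
    def key(self) -> tuple[str, str]:
        return self.variant.key


@dataclass(frozen=True)
class GeneInfo:
    gene: str
    actionable: bool
    role: GeneRole = GeneRole.UNKNOWN


@dataclass(frozen=True)
class ProteinFeature:
    """A named codon interval on a gene, e.g. a kinase domain.

    Disordered regions never qualify a variant for the domain rule, whatever
    their ``functional`` flag says.
    """

    gene: str
    name: str
    span: CodonSpan
    functional: bool = True
    disordered: bool = False


@dataclass
class Knowledgebase:
    """Curated records keyed by (gene, normalized change) + registry + features."""

    records: dict[tuple[str, str], KnowledgebaseRecord] = field(default_factory=dict)
    genes: dict[str, GeneInfo] = field(default_factory=dict)
    features: dict[str, list[ProteinFeature]] = field(default_factory=dict)

    def add_record(self, record: KnowledgebaseRecord) -> None:
        if record.key in self.records:
            raise IntegrityError(f"duplicate knowledgebase key {record.key}")
        self.records[record.key] = record

    def add_feature(self, feature: ProteinFeature) -> None:
        self.features.setdefault(feature.gene, []).append(feature)

    def gene_info(self, gene: str, *, strict: bool = True) -> GeneInfo:
        """Look up the registry entry for ``gene``.

        In lenient mode an unregistered gene is treated as non-actionable
        with unknown role (and logged) rather than raising.
        """
        gene = gene.upper()
        if gene in self.genes:
            return self.genes[gene]
        if strict:
            raise UnknownGeneError(f"gene {gene!r} not in registry")
        logger.warning("gene %s not in registry; treating as non-actionable", gene)
        return GeneInfo(gene=gene, actionable=False, role=GeneRole.UNKNOWN)

    def records_for_gene(self, gene: str) -> list[KnowledgebaseRecord]:
        gene = gene.upper()
        return [r for k, r in self.records.items() if k[0] == gene]

    def features_for_gene(self, gene: str) -> list[ProteinFeature]:
        return sorted(
            self.features.get(gene.upper(), ()), key=lambda f: (f.span, f.name)
        )

    def validate(self) -> None:
        """Check referential integrity: every referenced gene is registered."""
        referenced = {k[0] for k in self.records} | set(self.features)
        missing = sorted(referenced - set(self.genes))
        if missing:
            raise IntegrityError(f"genes missing from registry: {missing}")


def aggregate_actionability(
    values: Sequence[ActionabilityValue],
) -> ActionabilityValue:
    """Collapse several actionability values to one under the fixed precedence.

    A variant may carry one assertion per drug context; all analyses use the
    highest value, Yes > Potentially > Unknown > No.
    """
    if not values:
        raise EmptyInputError("no actionability values to aggregate")
    return max(values)


def actionable_variants(
    kb: Knowledgebase, gene: str, *, eligible_only: bool = True
) -> list[KnowledgebaseRecord]:
    """Curated records on ``gene`` whose aggregate actionability is Yes.

    With ``eligible_only`` (the default) the list is restricted to
    proximity-eligible subtypes (missense, in-frame indels, duplication,
    deletion-insertion), i.e. the records that may serve as actionable
    neighbors. Order is deterministic: span start, then normalized string.
    """
    gene = gene.upper()
    if gene not in kb.genes:
        raise UnknownGeneError(f"gene {gene!r} not in registry")
    hits = [
        r
        for r in kb.records_for_gene(gene)
        if r.aggregate_value is ActionabilityValue.YES
        and (not eligible_only or r.variant.is_proximity_eligible())
    ]
    hits.sort(key=lambda r: (r.variant.span.start, r.variant.normalized))
    return hits


# --- TSV / JSON I/O ----------------------------------------------------------

RECORD_COLUMNS = [
    "gene",
    "protein_change",
    "functional_significance",
    "actionability_value",
    "context",
    "basis",
]
GENE_COLUMNS = ["gene", "actionable", "role"]
FEATURE_COLUMNS = ["gene", "name", "start", "end", "functional", "disordered"]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def _parse_bool(value: str, column: str, path: str | Path) -> bool:
    try:
        return _BOOL[value.strip().lower()]
    except KeyError:
        raise FormatError(f"{path}: bad boolean {value!r} in column {column}") from None


def load_knowledgebase(
    records_path: str | Path,
    genes_path: str | Path,
    features_path: str | Path,
    *,
    strict: bool = True,
) -> Knowledgebase:
    """Load and validate a knowledgebase from its three TSV files.

    The records file holds one row per actionability assertion; rows sharing
    a (gene, protein_change) key are grouped into one record. Duplicate keys
    with conflicting functional significance, or genes absent from the
    registry, raise :class:`~vusact.errors.IntegrityError` (strict mode).
    """
    kb = Knowledgebase()

    genes = _read_tsv(genes_path, GENE_COLUMNS)
    for row in genes.itertuples(index=False):
        gene = row.gene.strip().upper()
        if gene in kb.genes:
            raise IntegrityError(f"{genes_path}: duplicate gene {gene}")
        kb.genes[gene] = GeneInfo(
            gene=gene,
            actionable=_parse_bool(row.actionable, "actionable", genes_path),
            role=GeneRole(row.role.strip().lower()),
        )

    feats = _read_tsv(features_path, FEATURE_COLUMNS)
    for row in feats.itertuples(index=False):
        kb.add_feature(
            ProteinFeature(
                gene=row.gene.strip().upper(),
                name=row.name,
                span=CodonSpan(int(row.start), int(row.end)),
                functional=_parse_bool(row.functional, "functional", features_path),
                disordered=_parse_bool(row.disordered, "disordered", features_path),
            )
        )

    recs = _read_tsv(records_path, RECORD_COLUMNS)
    grouped: dict[tuple[str, str], dict] = {}
    for row in recs.itertuples(index=False):
        variant = parse_protein_change(row.gene, row.protein_change, strict=strict)
        entry = grouped.setdefault(
            variant.key, {"variant": variant, "fs": None, "assertions": []}
        )
        fs = FunctionalSignificance(row.functional_significance.strip().lower())
        if entry["fs"] is None:
            entry["fs"] = fs
        elif entry["fs"] is not fs:
            raise IntegrityError(
                f"{records_path}: conflicting functional_significance for {variant.key}"
            )
        entry["assertions"].append(
            ActionabilityAssertion(
                value=ActionabilityValue.from_label(row.actionability_value),
                context=row.context,
                basis=AssertionBasis(row.basis.strip().lower()),
            )
        )
    for entry in grouped.values():
        kb.add_record(
            KnowledgebaseRecord(
                variant=entry["variant"],
                functional_significance=entry["fs"],
                assertions=tuple(entry["assertions"]),
            )
        )

    if strict:
        kb.validate()
    return kb


def write_knowledgebase(
    kb: Knowledgebase,
    records_path: str | Path,
    genes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write a knowledgebase back to its three TSV files (round-trip safe)."""
    rec_rows = []
    for key in sorted(kb.records):
        rec = kb.records[key]
        for a in rec.assertions:
            rec_rows.append(
                {
                    "gene": rec.variant.gene,
                    "protein_change": rec.variant.normalized,
                    "functional_significance": rec.functional_significance.value,
                    "actionability_value": a.value.label,
                    "context": a.context,
                    "basis": a.basis.value,
                }
            )
    pd.DataFrame(rec_rows, columns=RECORD_COLUMNS).to_csv(
        records_path, sep="\t", index=False
    )

    gene_rows = [
        {"gene": g.gene, "actionable": str(g.actionable).lower(), "role": g.role.value}
        for g in (kb.genes[name] for name in sorted(kb.genes))
    ]
    pd.DataFrame(gene_rows, columns=GENE_COLUMNS).to_csv(
        genes_path, sep="\t", index=False
    )

    feat_rows = [
        {
            "gene": f.gene,
            "name": f.name,
            "start": f.span.start,
            "end": f.span.end,
            "functional": str(f.functional).lower(),
            "disordered": str(f.disordered).lower(),
        }
        for gene in sorted(kb.features)
        for f in kb.features_for_gene(gene)
    ]
    pd.DataFrame(feat_rows, columns=FEATURE_COLUMNS).to_csv(
        features_path, sep="\t", index=False
    )


def knowledgebase_to_json(kb: Knowledgebase) -> str:
    """Serialize a knowledgebase to a JSON string (fixtures, debugging)."""
    payload = {
        "genes": [
            {"gene": g.gene, "actionable": g.actionable, "role": g.role.value}
            for g in (kb.genes[n] for n in sorted(kb.genes))
        ],
        "features": [
            {
                "gene": f.gene,
                "name": f.name,
                "start": f.span.start,
                "end": f.span.end,
                "functional": f.functional,
                "disordered": f.disordered,
            }
            for gene in sorted(kb.features)
            for f in kb.features_for_gene(gene)
        ],
        "records": [
            {
                "gene": r.variant.gene,
                "protein_change": r.variant.normalized,
                "functional_significance": r.functional_significance.value,
                "assertions": [
                    {"value": a.value.label, "context": a.context, "basis": a.basis.value}
                    for a in r.assertions
                ],
            }
            for key in sorted(kb.records)
            for r in [kb.records[key]]
        ],
    }
    return json.dumps(payload, indent=2)
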