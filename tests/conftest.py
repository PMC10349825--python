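import pytest

from vusact.knowledgebase import (
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
from vusact.variant import CodonSpan, parse_protein_change


def make_record(
    gene: str,
    change: str,
    value: ActionabilityValue = ActionabilityValue.YES,
    fs: FunctionalSignificance = FunctionalSignificance.GAIN_OF_FUNCTION,
    basis: AssertionBasis = AssertionBasis.LITERATURE,
) -> KnowledgebaseRecord:
    return KnowledgebaseRecord(
        variant=parse_protein_change(gene, change),
        functional_significance=fs,
        assertions=(ActionabilityAssertion(value, context="drug", basis=basis),),
    )


def make_kb(
    *records,
    genes=None,
    features=(),
) -> Knowledgebase:
    """Assemble a small knowledgebase; genes inferred as actionable oncogenes
    unless given explicitly as GeneInfo objects."""
    kb = Knowledgebase()
    names = set()
    for rec in records:
        names.add(rec.variant.gene)
    for f in features:
        names.add(f.gene)
        kb.add_feature(f)
    for info in genes or ():
        kb.genes[info.gene] = info
        names.discard(info.gene)
    for name in names:
        kb.genes.setdefault(
            name, GeneInfo(gene=name, actionable=True, role=GeneRole.ONCOGENE)
        )
    for rec in records:
        kb.add_record(rec)
    return kb


@pytest.fixture(scope="session")
def curated_cohort():
    from vusact.synthetic import curated_cohort_fixture

    return curated_cohort_fixture()


@pytest.fixture(scope="session")
def computational_cohort():
    from vusact.synthetic import computational_cohort_fixture

    return computational_cohort_fixture()


@pytest.fixture
def kinase_feature():
    return ProteinFeature(
        gene="GENE1", name="kinase domain", span=CodonSpan(500, 700)
    )
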