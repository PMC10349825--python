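"""Assay informativeness gating, oncogenicity calls and integration."""
import pytest

from conftest import make_record
from vusact.assay import (
    BAF3,
    MCF10A,
    AssayObservation,
    AssayVerdict,
    Effect,
    IntegrationOutcome,
    WildtypeEffect,
    call_batch,
    call_variant_assay,
    gene_line_informative,
    integrate_assay,
)
from vusact.errors import EmptyInputError, MissingWildtypeError, NonActionableGeneError
from vusact.knowledgebase import ActionabilityValue, GeneInfo, GeneRole
from vusact.variant import parse_protein_change


def _obs(gene, change, line, effect):
    return AssayObservation(parse_protein_change(gene, change), line, effect)


def _info(gene, role=GeneRole.ONCOGENE, actionable=True):
    return GeneInfo(gene, actionable, role)


# --- gating ------------------------------------------------------------------


def test_oncogene_with_suppressing_wildtype_is_non_informative():
    # FGF6-like: oncogene whose wildtype suppressed growth in the assay
    wt = {("FGFL", BAF3): WildtypeEffect.SUPPRESSES}
    batch = [_obs("FGFL", "A10V", BAF3, Effect.INCREASED)]
    assert not gene_line_informative("FGFL", BAF3, batch, wt, _info("FGFL"))


def test_tumor_suppressor_with_promoting_wildtype_is_non_informative():
    # PTCH1-like: tumor suppressor whose wildtype increased viability
    wt = {("PTCL", BAF3): WildtypeEffect.PROMOTES}
    assert not gene_line_informative(
        "PTCL", BAF3, [], wt, _info("PTCL", GeneRole.TUMOR_SUPPRESSOR)
    )


def test_line_specific_contradiction():
    # ARAF-like: wildtype suppresses in MCF10A only -> non-informative there,
    # informative in Ba/F3
    wt = {
        ("ARFL", MCF10A): WildtypeEffect.SUPPRESSES,
        ("ARFL", BAF3): WildtypeEffect.PROMOTES,
    }
    assert not gene_line_informative("ARFL", MCF10A, [], wt, _info("ARFL"))
    assert gene_line_informative("ARFL", BAF3, [], wt, _info("ARFL"))


def test_no_positive_control_is_non_informative():
    wt = {("G1", BAF3): WildtypeEffect.NEUTRAL}
    batch = [_obs("G1", "A10V", BAF3, Effect.NO_CHANGE)]
    assert not gene_line_informative("G1", BAF3, batch, wt, _info("G1"))
    # a single increased-viability variant rescues informativeness
    batch.append(_obs("G1", "A11V", BAF3, Effect.INCREASED))
    assert gene_line_informative("G1", BAF3, batch, wt, _info("G1"))


def test_role_both_or_unknown_skips_contradiction_check():
    wt = {("G1", BAF3): WildtypeEffect.PROMOTES}
    for role in (GeneRole.BOTH, GeneRole.UNKNOWN):
        assert gene_line_informative("G1", BAF3, [], wt, _info("G1", role))


def test_missing_wildtype_raises():
    with pytest.raises(MissingWildtypeError):
        gene_line_informative("G1", BAF3, [], {}, _info("G1"))


# --- calling -----------------------------------------------------------------

BOTH_INFORMATIVE = {BAF3: True, MCF10A: True}


@pytest.mark.parametrize(
    "effects, verdict",
    [
        ((Effect.INCREASED, Effect.NO_CHANGE), AssayVerdict.ONCOGENIC),
        ((Effect.INCREASED, Effect.INCREASED), AssayVerdict.ONCOGENIC),
        ((Effect.INCREASED, Effect.DECREASED), AssayVerdict.CONFLICTING),
        ((Effect.NO_CHANGE, Effect.NO_CHANGE), AssayVerdict.NOT_ONCOGENIC),
        ((Effect.DECREASED, Effect.NO_CHANGE), AssayVerdict.NOT_ONCOGENIC),
        ((Effect.DECREASED, Effect.DECREASED), AssayVerdict.NOT_ONCOGENIC),
    ],
)
def test_two_line_verdicts(effects, verdict):
    obs = [
        _obs("G1", "A10V", BAF3, effects[0]),
        _obs("G1", "A10V", MCF10A, effects[1]),
    ]
    assert call_variant_assay(obs, BOTH_INFORMATIVE).call is verdict


def test_non_informative_lines_never_influence_the_call():
    obs = [
        _obs("G1", "A10V", BAF3, Effect.DECREASED),
        _obs("G1", "A10V", MCF10A, Effect.INCREASED),
    ]
    # with MCF10A gated out, the remaining decrease means not oncogenic
    call = call_variant_assay(obs, {BAF3: True, MCF10A: False})
    assert call.call is AssayVerdict.NOT_ONCOGENIC
    assert call.informative_lines == (BAF3,)


def test_all_lines_gated_out_is_non_informative():
    obs = [_obs("G1", "A10V", BAF3, Effect.INCREASED)]
    assert (
        call_variant_assay(obs, {BAF3: False}).call is AssayVerdict.NON_INFORMATIVE
    )


def test_empty_observations_raise():
    with pytest.raises(EmptyInputError):
        call_variant_assay([], BOTH_INFORMATIVE)


def test_batch_partition_every_variant_gets_one_call():
    registry = {"G1": _info("G1"), "G2": _info("G2", GeneRole.TUMOR_SUPPRESSOR)}
    wt = {
        ("G1", BAF3): WildtypeEffect.PROMOTES,
        ("G1", MCF10A): WildtypeEffect.PROMOTES,
        ("G2", BAF3): WildtypeEffect.PROMOTES,  # contradiction: TS promotes
        ("G2", MCF10A): WildtypeEffect.NEUTRAL,
    }
    obs = []
    for i, eff in enumerate(
        [Effect.INCREASED, Effect.NO_CHANGE, Effect.DECREASED], start=10
    ):
        obs.append(_obs("G1", f"A{i}V", BAF3, eff))
        obs.append(_obs("G1", f"A{i}V", MCF10A, Effect.NO_CHANGE))
    obs.append(_obs("G2", "C50W", BAF3, Effect.INCREASED))
    calls = call_batch(obs, wt, registry)
    assert len(calls) == 4
    assert [c.call for c in calls] == [
        AssayVerdict.ONCOGENIC,
        AssayVerdict.NOT_ONCOGENIC,
        AssayVerdict.NOT_ONCOGENIC,
        AssayVerdict.NON_INFORMATIVE,  # G2's only line is gated out
    ]


# --- integration -------------------------------------------------------------


def _call(verdict, gene="G1", change="A10V"):
    from vusact.assay import AssayCall

    return AssayCall(parse_protein_change(gene, change), verdict, (BAF3,))


def test_oncogenic_without_literature_becomes_actionable():
    outcome, assertion = integrate_assay(_call(AssayVerdict.ONCOGENIC), _info("G1"))
    assert outcome is IntegrationOutcome.BECAME_ACTIONABLE
    assert assertion.value is ActionabilityValue.YES
    assert assertion.basis.value == "functional_genomics"


def test_not_oncogenic_without_literature_becomes_not_actionable():
    outcome, assertion = integrate_assay(_call(AssayVerdict.NOT_ONCOGENIC), _info("G1"))
    assert outcome is IntegrationOutcome.BECAME_NOT_ACTIONABLE
    assert assertion.value is ActionabilityValue.NO


def test_literature_contradiction_is_unclear():
    record = make_record("G1", "A10V", ActionabilityValue.NO)
    outcome, assertion = integrate_assay(
        _call(AssayVerdict.ONCOGENIC), _info("G1"), record
    )
    assert outcome is IntegrationOutcome.UNCLEAR and assertion is None


def test_literature_agreement_keeps_curated_value():
    record = make_record("G1", "A10V", ActionabilityValue.YES)
    outcome, assertion = integrate_assay(
        _call(AssayVerdict.ONCOGENIC), _info("G1"), record
    )
    assert outcome is IntegrationOutcome.KNOWN_ACTIONABLE and assertion is None


def test_conflicting_call_is_unclear():
    outcome, _ = integrate_assay(_call(AssayVerdict.CONFLICTING), _info("G1"))
    assert outcome is IntegrationOutcome.UNCLEAR


def test_non_actionable_gene_rejected():
    with pytest.raises(NonActionableGeneError):
        integrate_assay(_call(AssayVerdict.ONCOGENIC), _info("G1", actionable=False))
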