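"""The rule engine: per-rule checks, severities, determinism, compliance."""

from dataclasses import replace

import pytest

from mi2cast.findings import Severity
from mi2cast.model import (
    BioEntity,
    CausalRelation,
    CausalStatement,
    EntityContext,
    Evidence,
    ModificationState,
)
from mi2cast.registry import parse_identifier as _id
from mi2cast.rules import (
    RuleConfig,
    compliance_level,
    equivalent_activity,
    equivalent_mechanism,
    validate,
)


def findings_of(stmt, cfg, rule_id=None, severity=None):
    report = validate(stmt, cfg)
    out = list(report)
    if rule_id is not None:
        out = [f for f in out if f.rule_id == rule_id]
    if severity is not None:
        out = [f for f in out if f.severity is severity]
    return out


@pytest.fixture()
def base(lyn_ptpn6):
    return lyn_ptpn6


class TestRule1:
    def test_missing_target_is_an_error_at_its_path(self, base, cfg):
        errors = findings_of(replace(base, target=None), cfg, severity=Severity.ERROR)
        assert [(f.rule_id, f.path) for f in errors] == [("R1.entity", "target")]

    def test_complex_with_components_passes(self, clean_corpus, cfg):
        complexes = [
            s
            for s in clean_corpus
            if s.source.biological_type in (_id("mi:0314"), _id("mi:1304"))
        ]
        assert complexes, "generator should emit complex/family statements"
        for stmt in complexes:
            assert not findings_of(stmt, cfg, rule_id="R1.components")

    def test_complex_without_components_is_an_error(self, base, cfg):
        source = BioEntity(
            identifier=_id("complexportal:CPX-1"),
            biological_type=_id("mi:0314"),
        )
        errors = findings_of(
            replace(base, source=source), cfg, rule_id="R1.components"
        )
        assert [f.severity for f in errors] == [Severity.ERROR]
        assert errors[0].path == "source.components"


class TestRule2:
    def test_causal_branch_terms_pass(self, base, cfg):
        for curie in ("ro:0002629", "mi:2235", "ro:0002212"):
            stmt = replace(
                base, relation=replace(base.relation, relation_term=_id(curie))
            )
            assert not findings_of(stmt, cfg, rule_id="R2.relation")

    def test_wrong_branch_term_is_an_error(self, base, cfg):
        stmt = replace(
            base, relation=replace(base.relation, relation_term=_id("mi:0326"))
        )
        errors = findings_of(stmt, cfg, rule_id="R2.relation")
        assert [f.severity for f in errors] == [Severity.ERROR]

    def test_bare_root_relation_warns_unsigned(self, base, cfg):
        for root in ("ro:0002410", "mi:2233"):
            stmt = replace(
                base, relation=replace(base.relation, relation_term=_id(root))
            )
            warnings = findings_of(stmt, cfg, rule_id="R2.relation")
            assert [f.severity for f in warnings] == [Severity.WARNING]

    def test_unresolvable_term_is_unverifiable_info(self, base, cfg):
        stmt = replace(
            base, relation=replace(base.relation, relation_term=_id("ro:0009999"))
        )
        assert not findings_of(stmt, cfg, rule_id="R2.relation")
        infos = findings_of(stmt, cfg, rule_id="X.unverifiable")
        assert [f.path for f in infos] == ["relation.relation_term"]


class TestRule3:
    def test_empty_references_single_error(self, base, cfg):
        stmt = replace(base, evidence=replace(base.evidence, references=()))
        errors = findings_of(stmt, cfg, severity=Severity.ERROR)
        assert [(f.rule_id, f.path) for f in errors] == [
            ("R3.1.reference", "evidence.references")
        ]

    def test_non_eco_evidence_type_is_an_error(self, base, cfg):
        stmt = replace(
            base, evidence=replace(base.evidence, evidence_types=(_id("go:0008150"),))
        )
        errors = findings_of(stmt, cfg, rule_id="R3.2.evidence")
        assert [f.severity for f in errors] == [Severity.ERROR]

    def test_specific_evidence_with_setup_is_clean(self, base, cfg):
        # yeast 2-hybrid with the source overexpressed: no R3 findings
        stmt = replace(
            base,
            source=replace(
                base.source,
                context=replace(
                    base.source.context, experimental_setup=(_id("mi:0506"),)
                ),
            ),
            evidence=replace(base.evidence, evidence_types=(_id("eco:0005805"),)),
        )
        assert not [
            f for f in validate(stmt, cfg) if f.rule_id.startswith("R3")
        ]

    def test_experimental_evidence_without_setup_warns(self, base, cfg):
        warnings = findings_of(base, cfg, rule_id="R3.3.setup")
        assert [f.severity for f in warnings] == [Severity.WARNING]
        assert warnings[0].missing

    def test_author_statement_needs_no_setup(self, base, cfg):
        stmt = replace(
            base,
            evidence=replace(base.evidence, evidence_types=(_id("eco:0000204"),)),
        )
        assert not findings_of(stmt, cfg, rule_id="R3.3.setup")


class TestRule4:
    def test_fallback_namespace_without_type_is_an_error(self, base, cfg):
        source = replace(base.source, identifier=_id("ncbigene:4067"))
        errors = findings_of(replace(base, source=source), cfg, severity=Severity.ERROR)
        assert [(f.rule_id, f.path) for f in errors] == [
            ("R4.2.biotype", "source.biological_type")
        ]

    def test_declaring_protein_type_clears_the_error(self, base, cfg):
        source = replace(
            base.source,
            identifier=_id("ncbigene:4067"),
            biological_type=_id("mi:0326"),
        )
        assert not findings_of(replace(base, source=source), cfg, severity=Severity.ERROR)

    def test_contradicting_declared_type_warns(self, base, cfg):
        # a UniProt accession implies protein; declaring 'gene' contradicts it
        source = replace(base.source, biological_type=_id("mi:0250"))
        warnings = findings_of(
            replace(base, source=source), cfg, rule_id="R4.2.biotype"
        )
        assert [f.severity for f in warnings] == [Severity.WARNING]

    def test_no_activity_and_no_mechanism_warns_absent_context(self, base, cfg):
        stmt = replace(
            base,
            source=replace(base.source, context=EntityContext(taxon=_id("ncbitaxon:9606"))),
            relation=replace(
                base.relation, mechanism=None, target_modification_effect=None
            ),
        )
        warnings = findings_of(stmt, cfg, rule_id="R4.1.activity")
        assert [f.missing for f in warnings] == [True]
        assert compliance_level(validate(stmt, cfg)) == "minimum"

    def test_activity_with_mapping_and_no_mechanism_suggests_equivalent(self, base, cfg):
        stmt = replace(
            base,
            relation=replace(
                base.relation, mechanism=None, target_modification_effect=None
            ),
        )
        infos = findings_of(stmt, cfg, rule_id="R4.1.mechanism")
        assert [f.severity for f in infos] == [Severity.INFO]
        assert "mi:0217" in infos[0].message

    def test_modifying_mechanism_without_resulting_state_warns(self, base, cfg):
        stmt = replace(
            base, relation=replace(base.relation, target_modification_effect=None)
        )
        warnings = findings_of(stmt, cfg, rule_id="R4.3.modification")
        assert [f.missing for f in warnings] == [True]

    def test_non_numeric_taxon_warns(self, base, cfg):
        source = replace(
            base.source,
            context=replace(base.source.context, taxon=_id("ncbitaxon:human")),
        )
        warnings = findings_of(replace(base, source=source), cfg, rule_id="R4.4.taxon")
        assert [f.path for f in warnings] == ["source.context.taxon"]

    def test_compartment_outside_cc_branch_warns(self, base, cfg):
        source = replace(
            base.source,
            context=replace(base.source.context, compartment=_id("go:0016301")),
        )
        warnings = findings_of(replace(base, source=source), cfg, rule_id="R4.5.location")
        assert [f.severity for f in warnings] == [Severity.WARNING]

    def test_cell_line_accessions_are_syntax_checked_only(self, base, cfg):
        source = replace(
            base.source,
            context=replace(base.source.context, cell=_id("cellosaurus:CVCL_0030")),
        )
        report = validate(replace(base, source=source), cfg)
        assert not [f for f in report if f.path == "source.context.cell"]


class TestCrossCutting:
    def test_malformed_accession_is_flagged_at_its_path(self, base, cfg):
        source = replace(base.source, identifier=_id("uniprotkb:ZZZ"))
        findings = findings_of(replace(base, source=source), cfg, rule_id="X.syntax")
        assert [f.path for f in findings] == ["source.identifier"]

    def test_obsolete_term_warns(self, base, cfg):
        stmt = replace(base, relation=replace(base.relation, mechanism=_id("mi:0802")))
        findings = findings_of(stmt, cfg, rule_id="X.obsolete")
        assert [f.path for f in findings] == ["relation.mechanism"]


class TestEquivalenceMapping:
    def test_kinase_activity_maps_to_phosphorylation(self):
        assert equivalent_mechanism(_id("go:0016301")) == _id("mi:0217")
        assert equivalent_activity(_id("mi:0217")) == _id("go:0016301")

    def test_unmapped_term_gives_none(self):
        assert equivalent_mechanism(_id("go:0005488")) is None

    def test_mapping_is_a_bijection(self):
        from mi2cast.rules import _activity_mechanism_table

        forward, inverse = _activity_mechanism_table()
        for activity, mechanism in forward.items():
            assert inverse[mechanism] == activity
        assert len(forward) == len(inverse)


class TestReportSemantics:
    def test_validate_is_deterministic(self, corpus, cfg):
        statements, _ = corpus
        for stmt in statements[:50]:
            assert validate(stmt, cfg) == validate(stmt, cfg)

    def test_findings_sorted_by_path_then_rule(self, corpus, cfg):
        statements, _ = corpus
        for stmt in statements[:200]:
            keys = [(f.path, f.rule_id) for f in validate(stmt, cfg)]
            assert keys == sorted(keys)

    def test_minimum_profile_keeps_only_errors(self, base, cfg):
        minimal = RuleConfig(profile="minimum", index=cfg.index)
        stmt = replace(base, evidence=replace(base.evidence, references=()))
        report = validate(stmt, minimal)
        assert report.findings and all(
            f.severity is Severity.ERROR for f in report
        )

    def test_adding_valid_optional_fields_never_adds_errors(self, clean_corpus, cfg):
        for stmt in clean_corpus[:30]:
            enriched = replace(
                stmt,
                target=replace(
                    stmt.target,
                    context=replace(
                        stmt.target.context,
                        tissue=_id("bto:0000089"),
                        cell=_id("cl:0000057"),
                    ),
                ),
            )
            assert not validate(enriched, cfg).errors

    def test_compliance_levels(self, base, cfg):
        assert compliance_level(validate(base, cfg)) == "context_enriched"
        broken = replace(base, evidence=replace(base.evidence, references=()))
        assert compliance_level(validate(broken, cfg)) == "non_compliant"
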