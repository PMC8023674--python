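"""CURIE parsing and the namespace registry."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mi2cast.registry import (
    ParseError,
    RegistryError,
    allowed_namespaces,
    check_accession_syntax,
    curation_note,
    default_registry,
    implied_biological_type,
    parse_identifier,
)


class TestParseIdentifier:
    @pytest.mark.parametrize(
        "curie, prefix, local",
        [
            ("GO:0016301", "go", "0016301"),
            ("doi:10.1093/x:y", "doi", "10.1093/x:y"),  # first-colon split
            ("psi-mi:0217", "mi", "0217"),  # alias normalization
            ("uniprotkb:P08631-2", "uniprotkb", "P08631-2"),  # isoform suffix
            ("taxid:9606", "ncbitaxon", "9606"),
        ],
    )
    def test_parse(self, curie, prefix, local):
        ident = parse_identifier(curie)
        assert (ident.prefix, ident.local_id) == (prefix, local)

    @pytest.mark.parametrize("bad", ["nocolon", ":x", "x:", ":", ""])
    def test_malformed(self, bad):
        with pytest.raises(ParseError) as err:
            parse_identifier(bad)
        assert repr(bad)[1:-1] in str(err.value)


class TestAccessionSyntax:
    def test_known_good(self):
        assert check_accession_syntax(parse_identifier("go:0016301")) == []

    def test_pattern_mismatch(self):
        findings = check_accession_syntax(parse_identifier("go:16301"))
        assert [f.rule_id for f in findings] == ["X.syntax"]

    def test_unknown_prefix(self):
        findings = check_accession_syntax(parse_identifier("mystery:1"))
        assert len(findings) == 1
        assert "unknown" in findings[0].message

    # independent oracle: the published UniProtKB accession expression
    _UNIPROT = re.compile(
        r"[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2}\Z"
    )

    @pytest.mark.parametrize(
        "accession",
        ["P08631", "Q9Y243", "O15530", "A2BC19", "A0A023GPI8",
         "ZZZ", "P0863", "p08631", "O1553O", "123456"],
    )
    def test_uniprot_pattern_matches_published_expression(self, accession):
        expected_ok = bool(self._UNIPROT.fullmatch(accession))
        findings = check_accession_syntax(parse_identifier(f"uniprotkb:{accession}"))
        assert (findings == []) == expected_ok


class TestImpliedType:
    @pytest.mark.parametrize(
        "curie, implied",
        [
            ("uniprotkb:P08631", "mi:0326"),  # a UniProt accession names a protein
            ("pubchem.compound:2244", "mi:0328"),  # chemical
            ("chebi:15422", "mi:0328"),
            ("ncbigene:4067", None),  # gene db used as protein fallback
            ("mystery:1", None),  # unknown prefix
        ],
    )
    def test_implied(self, curie, implied):
        expected = parse_identifier(implied) if implied else None
        assert implied_biological_type(parse_identifier(curie)) == expected

    def test_implied_types_live_in_the_interactor_type_branch(self, cfg):
        from mi2cast.ontology import Membership, in_branch

        for spec in default_registry().specs:
            if spec.implied_type is not None:
                assert (
                    in_branch(spec.implied_type, cfg.branches["biotype"], cfg.index)
                    is Membership.YES
                )


class TestAllowedNamespaces:
    def test_chemical_primary_before_alternative(self):
        prefixes = [s.prefix for s in allowed_namespaces("chemical")]
        assert prefixes.index("chebi") < prefixes.index("pubchem.compound")

    def test_mrna_has_a_primary_ensembl_namespace(self):
        specs = allowed_namespaces("mRNA")  # case-insensitive token
        assert any(s.prefix == "ensembl" and s.rank == "primary" for s in specs)

    def test_unknown_type_errors_and_lists_tokens(self):
        with pytest.raises(RegistryError) as err:
            allowed_namespaces("prion")
        assert "protein" in str(err.value)


@settings(max_examples=50, derandomize=True)
@given(data=st.data())
def test_registry_roundtrip_generated_accessions_pass(data):
    """Any accession generated from a namespace's own pattern yields zero
    syntax findings."""
    registry = default_registry()
    spec = data.draw(st.sampled_from(registry.specs))
    local = data.draw(st.from_regex(spec.accession_pattern, fullmatch=True))
    if not local or any(c.isspace() for c in local):
        return  # not constructible as an Identifier
    ident = parse_identifier(f"{spec.prefix}:{local}")
    assert check_accession_syntax(ident) == []


def test_swissprot_preference_is_a_note_not_a_finding():
    ident = parse_identifier("uniprotkb:P08631")
    assert check_accession_syntax(ident) == []
    assert "Swiss-Prot" in curation_note(ident)
    assert curation_note(parse_identifier("chebi:15422")) is None
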