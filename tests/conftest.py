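import pytest

from mi2cast.fixtures import ViolationSpec, generate, worked_example
from mi2cast.rules import RuleConfig

#: the rule ids the generator can corrupt, at the corpus-wide default rate
CORPUS_RATES = {
    rule_id: 0.1
    for rule_id in (
        "R1.entity",
        "R1.components",
        "R2.relation",
        "R3.1.reference",
        "R3.2.evidence",
        "R4.2.biotype",
        "R4.3.modification",
        "X.syntax",
    )
}


@pytest.fixture(scope="session")
def cfg():
    """One strict-profile configuration with the bundled fixture ontologies."""
    return RuleConfig.default()


@pytest.fixture(scope="session")
def lyn_ptpn6():
    return worked_example()


@pytest.fixture(scope="session")
def corpus():
    """1000 statements with violations seeded at rate 0.1 per rule."""
    return generate(ViolationSpec(n=1000, seed=7, rates=CORPUS_RATES))


@pytest.fixture(scope="session")
def clean_corpus():
    """200 statements generated without any seeded violation."""
    statements, truth = generate(ViolationSpec(n=200, seed=3))
    assert all(not v for v in truth.violations)
    return statements
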