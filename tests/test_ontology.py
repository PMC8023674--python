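"""OBO loading and branch-membership queries, checked against a brute-force
depth-first-search oracle."""

import random

import pytest

from mi2cast.ontology import (
    BranchSpec,
    Membership,
    OntologyLoadError,
    in_branch,
    is_most_specific_usage,
    load_obo,
    load_obo_dir,
)
from mi2cast.registry import parse_identifier as _id

CHAIN = """\
format-version: 1.2

[Term]
id: XX:0000001
name: root

[Term]
id: XX:0000002
name: middle
is_a: XX:0000001

[Term]
id: XX:0000003
name: leaf
is_a: XX:0000002
"""


def test_load_chain():
    index = load_obo(CHAIN)
    assert len(index) == 3
    assert index.roots == {_id("XX:0000001")}
    assert index.name(_id("XX:0000003")) == "leaf"


def test_cycle_is_a_load_error():
    doc = CHAIN + "\n[Term]\nid: XX:0000004\nis_a: XX:0000005\n\n" \
        "[Term]\nid: XX:0000005\nis_a: XX:0000004\n"
    with pytest.raises(OntologyLoadError, match="cycle"):
        load_obo(doc)


def test_dangling_parent_is_a_load_error():
    with pytest.raises(OntologyLoadError, match="dangling"):
        load_obo("[Term]\nid: XX:0000001\nis_a: XX:0000099\n")


def test_empty_document_gives_empty_index():
    assert len(load_obo("format-version: 1.2\n")) == 0


def test_obsolete_terms_are_kept_and_flagged():
    index = load_obo_dir()
    assert index.is_obsolete(_id("mi:0802"))
    assert not index.is_obsolete(_id("mi:0217"))


class TestInBranch:
    def test_fixture_path(self, cfg):
        # phosphorylation reaction sits inside the direct-interaction branch
        branch = BranchSpec(roots=frozenset({_id("mi:0407")}), label="direct")
        assert in_branch(_id("mi:0217"), branch, cfg.index) is Membership.YES

    def test_reflexivity(self, cfg):
        branch = BranchSpec(roots=frozenset({_id("mi:0407")}))
        assert in_branch(_id("mi:0407"), branch, cfg.index) is Membership.YES

    def test_absent_term_is_unknown(self, cfg):
        branch = BranchSpec(roots=frozenset({_id("mi:0407")}))
        assert in_branch(_id("mi:9999"), branch, cfg.index) is Membership.UNKNOWN

    def test_absent_roots_are_unknown(self, cfg):
        branch = BranchSpec(roots=frozenset({_id("zz:1")}))
        assert in_branch(_id("mi:0217"), branch, cfg.index) is Membership.UNKNOWN

    def test_wrong_branch_is_no(self, cfg):
        branch = BranchSpec(roots=frozenset({_id("mi:0313")}))
        assert in_branch(_id("mi:0217"), branch, cfg.index) is Membership.NO


def random_dag_obo(n_terms: int, seed: int) -> str:
    """A random is_a DAG in OBO text: node i may take parents among 0..i-1."""
    rng = random.Random(seed)
    stanzas = ["format-version: 1.2\nontology: random-dag"]
    for i in range(n_terms):
        lines = ["[Term]", f"id: RD:{i:07d}", f"name: term {i}"]
        if i > 0:
            for parent in rng.sample(range(i), k=min(i, rng.choice([0, 1, 1, 2]))):
                lines.append(f"is_a: RD:{parent:07d}")
        stanzas.append("\n".join(lines))
    return "\n\n".join(stanzas) + "\n"


def brute_force_reaches(index, term, root) -> bool:
    """Independent plain DFS over parent links, no memoization."""
    stack, seen = [term], set()
    while stack:
        node = stack.pop()
        if node == root:
            return True
        if node in seen:
            continue
        seen.add(node)
        record = index.terms.get(node)
        if record:
            stack.extend(record.parents)
    return False


def test_in_branch_agrees_with_dfs_oracle_exhaustively():
    index = load_obo(random_dag_obo(200, seed=42))
    terms = sorted(index.terms, key=lambda t: t.curie)
    for root in terms:
        branch = BranchSpec(roots=frozenset({root}))
        for term in terms:
            expected = (
                Membership.YES
                if brute_force_reaches(index, term, root)
                else Membership.NO
            )
            assert in_branch(term, branch, index) is expected


def test_membership_is_monotone_down_the_hierarchy():
    """If a term is in a branch, every child of it is too."""
    index = load_obo(random_dag_obo(150, seed=5))
    children = {t: set() for t in index.terms}
    for term, record in index.terms.items():
        for parent in record.parents:
            children[parent].add(term)
    roots = sorted(index.roots, key=lambda t: t.curie)
    for root in roots:
        branch = BranchSpec(roots=frozenset({root}))
        for term in index.terms:
            if in_branch(term, branch, index) is Membership.YES:
                for child in children[term]:
                    assert in_branch(child, branch, index) is Membership.YES


class TestMostSpecificUsage:
    def test_root_usage_is_flagged(self, cfg):
        branch = cfg.branches["relation.ro"]
        assert not is_most_specific_usage(_id("ro:0002410"), branch, cfg.index)

    def test_leaf_and_midlevel_pass(self, cfg):
        branch = cfg.branches["relation.ro"]
        assert is_most_specific_usage(_id("ro:0002629"), branch, cfg.index)  # leaf
        assert is_most_specific_usage(_id("ro:0002213"), branch, cfg.index)  # mid
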