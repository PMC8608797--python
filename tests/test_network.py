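"""Structure of the cascade reaction network and its validation machinery."""

from collections import Counter

import pytest

from braferk import (ReactionNetwork, build_cascade_network, load_reaction_table,
                     species_inventory, validate_network)
from braferk.network import Reaction, Species, classify_species

# Regression constants recorded from the shipped reaction inventory: with both
# drugs the network is 36 reactions / 36 species; dropping dabrafenib removes
# its 3 starred reactions, dropping trametinib its 11 double-starred ones.
EXPECTED = {
    (True, True): (36, 36),
    (True, False): (25, 29),
    (False, True): (33, 32),
    (False, False): (22, 25),
}


@pytest.mark.parametrize("flags,expected", EXPECTED.items(),
                         ids=["both", "dbf-only", "tmt-only", "drug-free"])
def test_reaction_and_species_counts(flags, expected):
    net = build_cascade_network(*flags)
    assert (net.n_reactions, net.n_species) == expected


def test_drug_toggles_remove_exactly_the_tagged_subsets(full_network):
    tagged = Counter(r.drug_tag for r in full_network.reactions)
    assert tagged == {"none": 22, "dbf": 3, "tmt": 11}
    for flags, tag in [((False, True), "dbf"), ((True, False), "tmt")]:
        net = build_cascade_network(*flags)
        kept = {r.rid for r in net.reactions}
        removed = {r.rid for r in full_network.reactions} - kept
        assert removed == {r.rid for r in full_network.reactions if r.drug_tag == tag}


def test_drugfree_network_contains_no_drug_material(drugfree_network):
    assert all(r.drug_tag == "none" for r in drugfree_network.reactions)
    for s in drugfree_network.species:
        assert not {"DBF", "TMT"} & set(drugfree_network.moiety_counts(s.name))
    free = {s.name for s in drugfree_network.species if not s.is_complex}
    assert free == {"BRAF", "ATP", "ADP", "MEK", "pMEK", "ppMEK",
                    "ERK", "pERK", "ppERK", "phosph1", "phosph2"}


def test_build_is_deterministic(full_network):
    again = build_cascade_network(True, True)
    assert again == full_network
    assert again.species_names == full_network.species_names


def test_species_inventory_is_deduplicated_and_ordered(full_network):
    inv = species_inventory(full_network)
    names = [s.name for s in inv]
    assert len(names) == len(set(names)) == 36
    assert names == list(full_network.species_names)
    empty = ReactionNetwork(species=(), reactions=(),
                            include_dbf=False, include_tmt=False)
    assert species_inventory(empty) == []


@pytest.mark.parametrize("flags", list(EXPECTED), ids=["both", "dbf", "tmt", "none"])
def test_built_networks_validate_cleanly(flags):
    assert validate_network(build_cascade_network(*flags)).ok


def test_constituent_conservation_across_every_reaction(full_network):
    """Each reaction preserves the protein/drug moiety multiset exactly and
    the ATP + ADP pool as a whole."""
    for r in full_network.reactions:
        lhs, rhs = Counter(), Counter()
        for n in r.reactants:
            lhs.update(full_network.moiety_counts(n))
        for n in r.products:
            rhs.update(full_network.moiety_counts(n))
        pooled_l = {**lhs, "ADE": lhs.get("ATP", 0) + lhs.get("ADP", 0)}
        pooled_r = {**rhs, "ADE": rhs.get("ATP", 0) + rhs.get("ADP", 0)}
        for m in ("BRAF", "MEK", "ERK", "phosph1", "phosph2", "DBF", "TMT", "ADE"):
            assert pooled_l.get(m, 0) == pooled_r.get(m, 0), (r.rid, m)


def test_atp_contracted_network_reduces_to_classic_two_tier_cascade(drugfree_network):
    """Treating kinase·ATP as the active enzyme, each tier is the classic
    E + S <-> E·S -> E + P motif of the two lower cascade tiers."""
    rids = {r.rid: r for r in drugfree_network.reactions}
    motifs = [  # (enzyme-with-ATP, substrate, phosphorylated product)
        ("BRAF·ATP", "MEK", "pMEK"), ("BRAF·ATP", "pMEK", "ppMEK"),
        ("ppMEK·ATP", "ERK", "pERK"), ("ppMEK·ATP", "pERK", "ppERK"),
        ("phosph1", "pMEK", "MEK"), ("phosph1", "ppMEK", "pMEK"),
        ("phosph2", "pERK", "ERK"), ("phosph2", "ppERK", "pERK"),
    ]
    for enzyme, substrate, product in motifs:
        bindings = [r for r in rids.values() if r.kind == "binding"
                    and set(r.reactants) == {enzyme, substrate}]
        assert len(bindings) == 1, (enzyme, substrate)
        complex_name = bindings[0].products[0]
        catalyses = [r for r in rids.values() if r.kind == "catalysis"
                     and r.reactants == (complex_name,)]
        assert len(catalyses) == 1 and product in catalyses[0].products


def test_elementary_step_expansion(full_network):
    steps = full_network.elementary_steps()
    kinds = Counter(s.kind for s in steps)
    assert kinds == {"binding": 28, "dissociation": 28, "catalysis": 8}
    for s in steps:
        if s.kind == "binding":
            assert len(s.reactants) == 2 and len(s.products) == 1
        elif s.kind == "dissociation":
            assert len(s.reactants) == 1 and len(s.products) == 2
        else:
            assert len(s.reactants) == 1 and len(s.products) >= 2


def test_species_invariants(full_network):
    for s in full_network.species:
        if s.is_complex:
            assert len(s.constituents) >= 2
        else:
            assert s.constituents == ()
        assert s.phospho_count in (0, 1, 2)
        if s.role in ("drug", "nucleotide", "phosphatase") or s.name == "BRAF":
            assert s.phospho_count == 0
    assert classify_species("ppMEK").phospho_count == 2
    assert classify_species("phosph1").role == "phosphatase"
    assert classify_species("BRAF·ATP·MEK").constituents == ("BRAF", "ATP", "MEK")


# --- constructed negative cases -------------------------------------------

def _with_replaced_reaction(net, rid, new):
    reactions = tuple(new if r.rid == rid else r for r in net.reactions)
    return ReactionNetwork(species=net.species, reactions=reactions,
                           include_dbf=net.include_dbf, include_tmt=net.include_tmt)


def test_dropping_adp_from_a_catalysis_is_one_balance_violation(full_network):
    broken = _with_replaced_reaction(
        full_network, "R.3",
        Reaction("R.3", "catalysis", ("BRAF·ATP·MEK",), ("BRAF", "pMEK"), "k12"))
    rep = validate_network(broken)
    balance = [v for v in rep if v.check == "balance"]
    assert len(balance) == 1 and balance[0].reaction_id == "R.3"


def test_starred_reaction_with_flag_off_is_flagged(full_network):
    net = ReactionNetwork(species=full_network.species,
                          reactions=full_network.reactions,
                          include_dbf=False, include_tmt=True)
    rep = validate_network(net)
    assert any(v.check == "flag-consistency" and "R.12" in v.message for v in rep)


def test_wrong_arity_binding_is_flagged(full_network):
    broken = _with_replaced_reaction(
        full_network, "R.1",
        Reaction("R.1", "binding", ("BRAF",), ("BRAF·ATP", "ATP"), "a1", "d1"))
    rep = validate_network(broken)
    assert any(v.check == "arity" and v.reaction_id == "R.1" for v in rep)


def test_mistagged_drug_reaction_is_flagged(full_network):
    broken = _with_replaced_reaction(
        full_network, "R.12",
        Reaction("R.12", "binding", ("BRAF", "DBF"), ("BRAF·DBF",), "a4", "d4",
                 drug_tag="none"))
    rep = validate_network(broken)
    assert any(v.check == "drug-tag" and v.reaction_id == "R.12" for v in rep)


def test_reaction_table_is_the_single_source_of_truth():
    table = load_reaction_table()
    assert [r.rid for r in table] == [f"R.{i}" for i in range(1, 37)]
    assert sum(r.kind == "catalysis" for r in table) == 8
    # every binding carries an a/d pair, every catalysis one of the four k's
    for r in table:
        if r.kind == "binding":
            assert r.fwd_rate.startswith("a") and r.rev_rate.startswith("d")
        else:
            assert r.fwd_rate in {"k12", "k3", "k56", "k7"} and r.rev_rate is None


def test_species_rejects_malformed_construction():
    with pytest.raises(ValueError):
        Species("X·Y", "complex", constituents=("X",))
    with pytest.raises(ValueError):
        Species("X", "substrate", phospho_count=3)
    with pytest.raises(ValueError):
        Species("X", "substrate", constituents=("A", "B"))
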