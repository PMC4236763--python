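import json
import warnings

import numpy as np
import pytest

from efmdfs.dfs_search import enumerate_efms
from efmdfs.model_io import (MetabolicNetwork, ModelParseError,
                             ModelValidationError, as_irreversible, compress,
                             expand_efms, fva_reduce, merge_split_pairs,
                             read_network, replace_with_drains,
                             split_reversible, write_network, CompressionMap)
from efmdfs.oracle_fixtures import brute_force_efms, _net
from conftest import random_networks


def test_json_roundtrip(tmp_path, toy):
    path = tmp_path / "toy.json"
    write_network(toy, str(path))
    back = read_network(path)
    assert back.reaction_ids == toy.reaction_ids
    assert back.metabolite_ids == toy.metabolite_ids
    assert np.array_equal(back.stoich, toy.stoich)


def test_tsv_dialect(tmp_path):
    text = ("R1\t-> A\tI\n"
            "R2\tA -> 2 B\tR\n"
            "R3\tB + x_cof -> x_out\tI\n")
    path = tmp_path / "m.tsv"
    path.write_text(text)
    net = read_network(path)
    assert net.metabolite_ids == ["A", "B"]  # external x_ species excluded
    assert net.reversible.tolist() == [False, True, False]
    assert net.stoich[1, 1] == 2.0 and net.stoich[1, 2] == -1.0


@pytest.mark.parametrize("line,phrase", [
    ("R1\t-> A\tX\n", "reversibility"),
    ("R1\tA  B\tI\n", "->"),
    ("R1\tq A -> B\tI\n", "coefficient"),
    ("R1\t-> A\n", "expected"),
])
def test_tsv_parse_errors_name_the_line(tmp_path, line, phrase):
    path = tmp_path / "bad.tsv"
    path.write_text("R0\t-> Z\tI\n" + line)
    with pytest.raises(ModelParseError, match="line 2"):
        read_network(path)
    with pytest.raises(ModelParseError, match=phrase):
        read_network(path)


def test_json_duplicate_reaction_id(tmp_path):
    doc = {"metabolites": [{"id": "A", "external": False}],
           "reactions": [{"id": "R1", "stoich": {"A": 1}, "reversible": False},
                         {"id": "R1", "stoich": {"A": -1}, "reversible": False}]}
    path = tmp_path / "dup.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ModelValidationError, match="duplicate reaction id"):
        read_network(path)


def test_json_nonfinite_coefficient(tmp_path):
    path = tmp_path / "nan.json"
    path.write_text('{"metabolites": [{"id": "A"}], '
                    '"reactions": [{"id": "R1", "stoich": {"A": NaN}}]}')
    with pytest.raises((ModelValidationError, ModelParseError)):
        read_network(path)


def test_zero_column_dropped_with_warning(tmp_path):
    doc = {"metabolites": [{"id": "A"}, {"id": "B", "external": True}],
           "reactions": [{"id": "R1", "stoich": {"A": 1}},
                         {"id": "Rx", "stoich": {"B": 1}},  # external only: zero column
                         {"id": "R2", "stoich": {"A": -1}}]}
    path = tmp_path / "z.json"
    path.write_text(json.dumps(doc))
    with pytest.warns(UserWarning, match="all-zero"):
        net = read_network(path)
    assert net.reaction_ids == ["R1", "R2"]


def test_sbml_import(tmp_path):
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    for sid, boundary in (("A", False), ("B", False), ("Aext", True)):
        sp = model.createSpecies()
        sp.setId(sid)
        sp.setCompartment("c")
        sp.setBoundaryCondition(boundary)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
    r1 = model.createReaction()
    r1.setId("uptake")
    r1.setReversible(False)
    sr = r1.createReactant()
    sr.setSpecies("Aext")
    sr.setStoichiometry(1)
    sr.setConstant(True)
    sp = r1.createProduct()
    sp.setSpecies("A")
    sp.setStoichiometry(1)
    sp.setConstant(True)
    r2 = model.createReaction()
    r2.setId("conv")
    r2.setReversible(True)
    sr = r2.createReactant()
    sr.setSpecies("A")
    sr.setStoichiometry(1)
    sr.setConstant(True)
    sp = r2.createProduct()
    sp.setSpecies("B")
    sp.setStoichiometry(2)
    sp.setConstant(True)
    path = tmp_path / "m.xml"
    libsbml.writeSBMLToFile(doc, str(path))
    net = read_network(path)
    assert net.metabolite_ids == ["A", "B"]
    assert net.reaction_ids == ["uptake", "conv"]
    assert net.reversible.tolist() == [False, True]
    assert net.stoich[0, 0] == 1.0 and net.stoich[1, 1] == 2.0


class TestSplitReversible:
    def test_identity_when_all_irreversible(self, chain):
        inet = split_reversible(chain)
        assert inet.split_map == {}
        assert np.array_equal(inet.stoich, chain.stoich)

    def test_single_reversible_pair(self):
        net = MetabolicNetwork(np.array([[1.0], [-1.0]]), ["r"], ["A", "B"],
                               np.array([True]))
        inet = split_reversible(net)
        assert inet.reaction_ids == ["r", "r_rev"]
        assert np.array_equal(inet.stoich[:, 1], -inet.stoich[:, 0])
        assert inet.split_map == {"r": ("r", "r_rev")}

    def test_merge_back_recovers_original(self, toy):
        rev = toy.copy()
        rev.reversible[np.array([1, 5, 9])] = True
        inet = split_reversible(rev)
        back = merge_split_pairs(inet)
        assert back.reaction_ids == rev.reaction_ids
        assert np.array_equal(back.stoich, rev.stoich)
        assert back.reversible.tolist() == rev.reversible.tolist()

    def test_suffix_collision_is_resolved(self):
        net = MetabolicNetwork(np.array([[1.0, 1.0]]), ["r", "r_rev"], ["A"],
                               np.array([True, False]))
        inet = split_reversible(net)
        assert len(set(inet.reaction_ids)) == 3


class TestCompress:
    def test_chain_lumps_to_single_exchange(self, chain):
        comp, cmap = compress(as_irreversible(chain))
        assert comp.n_reactions == 1
        groups = cmap.groups
        assert len(groups) == 1 and groups[0].kind == "subset"
        members = dict(groups[0].members)
        assert set(members) == {"R1", "R2", "R3"}
        assert np.allclose(list(members.values()), 1.0)

    def test_duplicate_columns_merge_as_choice(self):
        net = _net(["A", "B"], ["r1", "d1", "d2", "r4"],
                   [{"A": 1}, {"A": -1, "B": 1}, {"A": -1, "B": 1}, {"B": -1}])
        comp, cmap = compress(net, lump_subsets=False)
        assert comp.n_reactions == 3
        choice = [g for g in cmap.groups if g.kind == "choice"]
        assert len(choice) == 1
        assert {m[0] for m in choice[0].members} == {"d1", "d2"}

    def test_blocked_reactions_are_dropped(self):
        # r3 consumes C which nothing produces: blocked
        net = _net(["A", "C"], ["r1", "r2", "r3"],
                   [{"A": 1}, {"A": -1}, {"C": -1}])
        comp, cmap = compress(net, lump_subsets=False)
        assert "r3" in cmap.dropped

    def test_requires_irreversible(self):
        net = MetabolicNetwork(np.array([[1.0, -1.0]]), ["a", "b"], ["A"],
                               np.array([True, False]))
        with pytest.raises(ModelValidationError, match="irreversible"):
            compress(net)

    def test_roundtrip_preserves_efm_sets(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for net in random_networks(10, seed=42, max_rxns=13, max_dof=4):
                full = brute_force_efms(net)
                comp, cmap = compress(net)
                if comp.n_reactions == 0:
                    assert len(full) == 0
                    continue
                back = expand_efms(enumerate_efms(comp).efms, cmap)
                assert back.same_supports(full)

    def test_map_json_roundtrip(self, chain):
        _, cmap = compress(as_irreversible(chain))
        again = CompressionMap.from_json(cmap.to_json())
        assert again.trees == cmap.trees
        assert again.dropped == cmap.dropped


def test_expand_dimension_mismatch(chain):
    comp, cmap = compress(as_irreversible(chain))
    wrong = enumerate_efms(chain).efms  # 3 reactions, map expects 1
    with pytest.raises(ValueError, match="compression map"):
        expand_efms(wrong, cmap)


class TestFvaReduce:
    def test_diamond_keeps_both_optimal_branches(self, diamond):
        red = fva_reduce(diamond, "r6", "r1")
        assert red.reaction_ids == diamond.reaction_ids

    def test_lossy_branch_excluded_at_max_yield(self, lossy_diamond):
        red = fva_reduce(lossy_diamond, "r6", "r1")
        assert set(red.reaction_ids) == {"r1", "r2", "r4", "r6"}

    def test_unique_optimum_keeps_exactly_the_pathway(self, chain):
        red = fva_reduce(chain, "R3", "R1")
        assert red.reaction_ids == chain.reaction_ids

    def test_idempotent(self, lossy_diamond):
        red = fva_reduce(lossy_diamond, "r6", "r1")
        again = fva_reduce(red, "r6", "r1")
        assert again.reaction_ids == red.reaction_ids

    def test_output_is_column_subset(self, lossy_diamond):
        red = fva_reduce(lossy_diamond, "r6", "r1")
        assert set(red.reaction_ids) <= set(lossy_diamond.reaction_ids)

    def test_unknown_objective(self, diamond):
        with pytest.raises(KeyError):
            fva_reduce(diamond, "nope", "r1")


class TestReplaceWithDrains:
    def test_consumed_and_produced_metabolites(self):
        net = _net(["X", "Y", "Z"], ["mkX", "mkY", "biomass"],
                   [{"X": 1}, {"Y": 1}, {"X": -1, "Y": -2, "Z": 0.5}])
        out = replace_with_drains(net, "biomass")
        assert "biomass" not in out.reaction_ids
        assert "drain_X" in out.reaction_ids and "drain_Y" in out.reaction_ids
        assert "source_Z" in out.reaction_ids
        j = out.reaction_index("drain_Y")
        assert out.stoich[out.metabolite_ids.index("Y"), j] == -1.0

    def test_missing_reaction(self, chain):
        with pytest.raises(KeyError):
            replace_with_drains(chain, "nope")

    def test_reaction_must_consume_something(self, chain):
        with pytest.raises(ValueError, match="consumes no"):
            replace_with_drains(chain, "R1")
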