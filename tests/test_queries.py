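"""Presence/absence matrices, pattern queries, clade queries, run comparison."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_pattern, brute_force_single_copy
from panfam.queries import (CladeTree, PresenceAbsenceMatrix,
                            clade_conservation, clade_unique_families,
                            cross_run_presence, families_by_pattern,
                            presence_matrix, single_copy_core)
from panfam.store import ClusterRun


def _mat(counts: dict, genomes: list[str]) -> PresenceAbsenceMatrix:
    df = pd.DataFrame.from_dict(counts, orient="index", columns=genomes)
    df.index.name = "family_id"
    return PresenceAbsenceMatrix(counts=df)


# the worked 3-genome example: f1 in all, f2 in {A,B}, f3 in {C}
ABC = _mat({"f1": [1, 1, 1], "f2": [1, 1, 0], "f3": [0, 0, 1]}, ["A", "B", "C"])


class TestPresenceMatrix:
    def test_copy_number_counting(self):
        run = ClusterRun("g", "MCL", "maxbit", 0.3, 2.0, {
            0: frozenset({"gA1", "gA2", "gB1"}), 1: frozenset({"gC1"})})
        genomes = {"gA1": "A", "gA2": "A", "gB1": "B", "gC1": "C"}
        mat = presence_matrix(run, genomes)
        assert mat.counts.loc[0, "A"] == 2
        assert mat.counts.loc[0, "B"] == 1
        assert mat.counts.loc[1].tolist() == [0, 0, 1]

    def test_column_sums_equal_gene_totals_on_fixture(self, small_run,
                                                      small_store, small_truth):
        mat = presence_matrix(small_run, small_store.gene_genome_map())
        for genome in small_truth.genomes:
            assert mat.counts[genome].sum() == \
                len(small_store.genes_by_genome(genome))


class TestPatternQueries:
    def test_worked_example_all_only_none(self):
        assert families_by_pattern(ABC, ["A", "B"], "all") == {"f1", "f2"}
        assert families_by_pattern(ABC, ["A", "B"], "only",
                                   all_organisms=["A", "B", "C"]) == {"f2"}
        assert families_by_pattern(ABC, ["A", "B"], "none") == {"f3"}
        assert families_by_pattern(ABC, ["A", "B"], "any") == {"f1", "f2"}

    def test_fraction_threshold_uses_ceiling(self):
        # 90% of 3 genomes must require all 3, not 2
        mat = _mat({"f1": [1, 1, 1], "f2": [1, 1, 0]}, ["A", "B", "C"])
        assert families_by_pattern(mat, ["A", "B", "C"], "all",
                                   fraction=0.9) == {"f1"}
        assert families_by_pattern(mat, ["A", "B", "C"], "all",
                                   fraction=0.6) == {"f1", "f2"}

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            families_by_pattern(ABC, [], "all")
        with pytest.raises(ValueError):
            families_by_pattern(ABC, ["A"], "all", fraction=0.0)
        with pytest.raises(ValueError):
            families_by_pattern(ABC, ["A"], "everything")

    def test_single_copy_core_requires_exactly_one_everywhere(self):
        mat = _mat({"f1": [1, 1, 1], "f2": [2, 1, 1], "f3": [1, 1, 0]},
                   ["A", "B", "C"])
        assert single_copy_core(mat, ["A", "B", "C"]) == {"f1"}

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(5)
        genomes = [f"G{i}" for i in range(5)]
        for _ in range(20):
            raw = {f"f{j}": rng.integers(0, 3, size=5).tolist()
                   for j in range(20)}
            counts = {f: dict(zip(genomes, row)) for f, row in raw.items()}
            mat = _mat(raw, genomes)
            group = [g for g in genomes if rng.random() < 0.6] or [genomes[0]]
            frac = float(rng.uniform(0.1, 1.0))
            for mode in ("all", "any", "only", "none"):
                got = families_by_pattern(mat, group, mode, fraction=frac
                                          if mode == "all" else 1.0,
                                          all_organisms=genomes)
                want = brute_force_pattern(counts, genomes, group, mode,
                                           fraction=frac if mode == "all" else 1.0,
                                           all_organisms=genomes)
                assert got == want, (mode, group, frac)
            assert single_copy_core(mat, group) == \
                brute_force_single_copy(counts, group)

    def test_set_algebra_and_fraction_monotonicity(self):
        rng = np.random.default_rng(9)
        genomes = [f"G{i}" for i in range(5)]
        for _ in range(20):
            counts = {f"f{j}": rng.integers(0, 2, size=5).tolist()
                      for j in range(20)}
            mat = _mat(counts, genomes)
            group = genomes[:3]
            alls = families_by_pattern(mat, group, "all")
            anys = families_by_pattern(mat, group, "any")
            onlys = families_by_pattern(mat, group, "only",
                                        all_organisms=genomes)
            nones = families_by_pattern(mat, group, "none")
            assert alls <= anys
            assert not (onlys & nones)
            assert single_copy_core(mat, group) <= alls
            lo = families_by_pattern(mat, group, "all", fraction=0.5)
            assert alls <= lo  # weaker threshold admits more families


FOUR_LEAF = "((A:1,B:1)AB:1,(C:1,D:1)CD:1)root;"


class TestCladeQueries:
    def _mat4(self):
        return _mat({
            "core": [1, 1, 1, 1],       # everywhere
            "left": [1, 1, 0, 0],       # the A,B pair only
            "solo": [0, 0, 1, 0],       # C only
            "patchy": [1, 0, 1, 0],     # one leaf in each pair
        }, ["A", "B", "C", "D"])

    def test_four_leaf_hand_enumeration(self):
        table = clade_conservation(self._mat4(), CladeTree.from_newick(FOUR_LEAF))
        by_node = {r.node_id: set(r.families) for r in table.itertuples()}
        assert by_node["root"] == {"core"}
        assert by_node["AB"] == {"core", "left"}
        assert by_node["CD"] == {"core"}
        assert by_node["A"] == {"core", "left", "patchy"}

    def test_children_reading_counts_patchy_families(self):
        tree = CladeTree.from_newick(FOUR_LEAF)
        table = clade_conservation(self._mat4(), tree, reading="children")
        by_node = {r.node_id: set(r.families) for r in table.itertuples()}
        # patchy has a representative under each child of the root
        assert by_node["root"] == {"core", "patchy"}

    def test_conserved_nested_parent_subset_of_child(self):
        table = clade_conservation(self._mat4(), CladeTree.from_newick(FOUR_LEAF))
        by_node = {r.node_id: set(r.families) for r in table.itertuples()}
        assert by_node["root"] <= by_node["AB"] <= by_node["A"]
        assert by_node["root"] <= by_node["CD"]

    def test_unique_families_enumeration(self):
        table = clade_unique_families(self._mat4(),
                                      CladeTree.from_newick(FOUR_LEAF))
        by_node = {r.node_id: set(r.families) for r in table.itertuples()}
        assert by_node["AB"] == {"left"}
        assert by_node["root"] == {"core", "left", "solo", "patchy"}
        assert by_node["C"] == {"solo"}
        assert "solo" not in by_node["CD"] or by_node["CD"] == {"solo"}
        # a single-leaf family is unique to that leaf, not to wider clades
        assert "solo" not in by_node["root"] - {"core", "left", "solo", "patchy"}

    def test_unlabeled_internal_nodes_get_stable_ids(self):
        tree = CladeTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ids = [n.node_id for n in tree.nodes() if not n.is_leaf()]
        assert len(ids) == len(set(ids)) == 3
        assert all(i.startswith("N") for i in ids)

    def test_missing_leaf_is_error(self):
        with pytest.raises(ValueError, match="leaves"):
            clade_conservation(ABC, CladeTree.from_newick(FOUR_LEAF))


class TestCrossRunPresence:
    G = {"g1": "A", "g2": "B", "g3": "C"}

    def test_split_family_maps_to_both_and_unions_coverage(self):
        run_a = ClusterRun("a", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"g1", "g2"})})
        run_b = ClusterRun("b", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"g1"}), 1: frozenset({"g2", "g3"})})
        table = cross_run_presence(run_a, run_b, ["A", "B", "C"], self.G)
        row = table.iloc[0]
        assert row["mapped_families_b"] == [0, 1]
        assert row["covered_genomes_in_b"] == ["A", "B", "C"]
        assert row["missing_in"] == []

    def test_identical_runs_have_nothing_missing(self):
        run = ClusterRun("a", "MCL", "maxbit", 0.3, 2.0,
                         {0: frozenset({"g1", "g2"}), 1: frozenset({"g3"})})
        table = cross_run_presence(run, run, ["A", "B", "C"], self.G)
        # families cover their own genomes, so only uncovered focus genomes
        # show up; family 0 misses C, family 1 misses A and B
        by_fam = table.set_index("family_a")
        assert by_fam.loc[0, "missing_in"] == ["C"]
        assert by_fam.loc[1, "missing_in"] == ["A", "B"]

    def test_deleted_genome_reported_missing(self):
        run_a = ClusterRun("a", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"g1", "g2", "g3"})})
        run_b = ClusterRun("b", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"g1", "g2"})})  # C's gene dropped
        table = cross_run_presence(run_a, run_b, ["A", "B", "C"], self.G)
        assert table.iloc[0]["missing_in"] == ["C"]

    def test_disjoint_namespaces_warn(self):
        run_a = ClusterRun("a", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"x1"})})
        run_b = ClusterRun("b", "MCL", "maxbit", 0.3, 2.0,
                           {0: frozenset({"g1"})})
        with pytest.warns(UserWarning, match="share no gene ids"):
            cross_run_presence(run_a, run_b, ["A"], {"x1": "A", "g1": "A"})
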