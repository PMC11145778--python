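import numpy as np
import pytest

import phylogrid as pg
from conftest import canape_endemic_fixture


class TestEndemicRichness:
    def _matrix(self):
        return pg.OccurrenceMatrix(["c1"], list("wxyz"), np.ones((1, 4), dtype=int))

    def test_no_flags_all_zero(self):
        m = self._matrix()
        assert pg.endemic_richness(m, {s: False for s in m.species}).iloc[0] == 0

    def test_all_flagged_equals_richness(self):
        m = self._matrix()
        assert pg.endemic_richness(m, {s: True for s in m.species}).iloc[0] == 4

    def test_partial_flags(self):
        m = self._matrix()
        flags = {"w": True, "x": True, "y": False, "z": False}
        assert pg.endemic_richness(m, flags).iloc[0] == 2


class TestWeightedEndemism:
    def test_hand_computation(self):
        m = pg.OccurrenceMatrix(["c1", "c2"], ["A", "B"], np.array([[1, 1], [0, 1]]))
        we = pg.weighted_endemism(m)
        assert we["c1"] == pytest.approx(1.5)
        assert we["c2"] == pytest.approx(0.5)

    def test_sum_equals_species_count(self, default_dataset):
        m = default_dataset["matrix"]
        assert pg.weighted_endemism(m).sum() == pytest.approx(len(m.species), abs=1e-9)

    def test_uniform_occupancy_constant(self):
        m = pg.OccurrenceMatrix(["c1", "c2"], ["A", "B", "C"], np.ones((2, 3), dtype=int))
        we = pg.weighted_endemism(m)
        assert np.allclose(we, 1.5)  # S/C

    def test_range_threshold_restricts(self):
        m = pg.OccurrenceMatrix(["c1", "c2"], ["A", "B"], np.array([[1, 1], [0, 1]]))
        we = pg.weighted_endemism(m, range_threshold=1)
        assert we["c1"] == pytest.approx(1.0)  # only the single-cell species counts
        assert we["c2"] == pytest.approx(0.0)


class TestPhylogeneticEndemism:
    def test_hand_branch_ranges(self, pe_tree):
        m = pg.OccurrenceMatrix(["c1", "c2"], ["A", "B", "C"],
                                np.array([[1, 1, 0], [0, 1, 1]]))
        pe = pg.phylogenetic_endemism(pe_tree, m)
        assert pe["c1"] == pytest.approx(2.0)
        assert pe["c2"] == pytest.approx(3.0)
        assert pe.sum() == pytest.approx(5.0)  # occurring total branch length

    def test_single_cell_dataset_equals_pd(self, balanced_tree):
        m = pg.OccurrenceMatrix(["c1"], ["A", "C"], np.ones((1, 2), dtype=int))
        pe = pg.phylogenetic_endemism(balanced_tree, m)
        assert pe["c1"] == pytest.approx(pg.faith_pd(balanced_tree, ["A", "C"]))

    @pytest.mark.parametrize("seed", range(3))
    def test_star_tree_pe_equals_we(self, seed):
        """On a unit-branch star tree each tip's branch is its own clade, so
        PE reduces to weighted endemism."""
        rng = np.random.default_rng(seed)
        species = [f"s{i}" for i in range(6)]
        star = pg.Phylogeny.from_newick("(" + ",".join(f"{s}:1" for s in species) + ");")
        inc = (rng.random((8, 6)) < 0.4).astype(int)
        inc[0, :] |= (inc.sum(axis=0) == 0).astype(int)
        m = pg.OccurrenceMatrix([f"c{i}" for i in range(8)], species, inc)
        assert np.allclose(pg.phylogenetic_endemism(star, m), pg.weighted_endemism(m))

    def test_functional_endemism_conserves_dendrogram_length(self, default_dataset,
                                                             default_dendrogram):
        fe = pg.functional_endemism(default_dendrogram, default_dataset["matrix"])
        assert fe.sum() == pytest.approx(default_dendrogram.total_branch_length(), rel=1e-12)


class TestComparisonTree:
    def test_equal_branches_preserve_total(self, balanced_tree):
        alt = pg.comparison_tree(balanced_tree)
        assert alt.total_branch_length() == pytest.approx(6.0)
        non_root = np.delete(alt.length, alt.root)
        assert np.allclose(non_root, non_root[0])
        assert sorted(alt.tip_labels) == sorted(balanced_tree.tip_labels)


class TestCurveball:
    @pytest.mark.parametrize("seed", range(5))
    def test_margins_preserved(self, seed):
        rng = np.random.default_rng(seed)
        inc = (rng.random((15, 12)) < 0.3).astype(np.int8)
        out = pg.curveball(inc, np.random.default_rng(seed + 100), 500)
        assert np.array_equal(out.sum(axis=0), inc.sum(axis=0))
        assert np.array_equal(out.sum(axis=1), inc.sum(axis=1))

    def test_mixes_matrix(self):
        rng = np.random.default_rng(0)
        inc = (rng.random((15, 12)) < 0.3).astype(np.int8)
        out = pg.curveball(inc, np.random.default_rng(1), 500)
        assert not np.array_equal(out, inc)


class TestCanape:
    def test_degenerate_all_ones_non_significant(self):
        species = [f"s{i}" for i in range(5)]
        tree = pg.Phylogeny.from_newick("(" + ",".join(f"{s}:1" for s in species) + ");")
        m = pg.OccurrenceMatrix([f"c{i}" for i in range(4)], species,
                                np.ones((4, 5), dtype=int))
        with pytest.warns(UserWarning, match="degenerate"):
            res = pg.canape(tree, m, n_reps=99, seed=0)
        assert set(res.classes()) == {"non_significant"}
        assert (res.table["p_PE_obs"] == 1.0).all()

    def test_long_branch_endemic_cell_is_paleo(self):
        tree, m = canape_endemic_fixture(1.0)
        res = pg.canape(tree, m, n_reps=999, seed=42)
        assert res.table.loc["c5", "canape_class"] == "paleo"

    def test_short_branch_endemic_cell_is_neo(self):
        tree, m = canape_endemic_fixture(0.01)
        res = pg.canape(tree, m, n_reps=999, seed=42)
        assert res.table.loc["c5", "canape_class"] == "neo"

    def test_classes_partition_cells(self, default_dataset):
        m = default_dataset["matrix"]
        res = pg.canape(default_dataset["tree"], m, n_reps=199, seed=7)
        assert set(res.classes()) <= set(pg.CANAPE_CLASSES)
        assert len(res.table) == len(m.cells)


class TestHotspots:
    def test_top_decile_of_1_to_100(self):
        import pandas as pd
        v = pd.Series(np.arange(1, 101, dtype=float),
                      index=[f"c{i}" for i in range(100)])
        top = pg.top_fraction_hotspots(v, 0.10)
        assert top == {f"c{i}" for i in range(90, 100)}

    def test_ties_at_cutoff_included(self):
        import pandas as pd
        v = pd.Series([1, 2, 3, 3, 3.0], index=list("abcde"))
        top = pg.top_fraction_hotspots(v, 0.2)
        assert top == {"c", "d", "e"}

    def test_half_of_four(self):
        import pandas as pd
        v = pd.Series([1, 2, 3, 4.0], index=list("abcd"))
        assert pg.top_fraction_hotspots(v, 0.5) == {"c", "d"}

    def test_all_equal_returns_grid_with_warning(self):
        import pandas as pd
        v = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        with pytest.warns(UserWarning):
            assert pg.top_fraction_hotspots(v, 0.1) == {"a", "b", "c"}

    def test_integration_and_protection_gap(self, default_dataset):
        m = default_dataset["matrix"]
        res = pg.canape(default_dataset["tree"], m, n_reps=99, seed=3)
        we = pg.weighted_endemism(m)
        tops = [pg.top_fraction_hotspots(we)]
        hot = pg.integrate_hotspots(tops, res)
        sig = set(res.table.index[res.table["canape_class"] != "non_significant"])
        assert hot == tops[0] | sig
        gaps = pg.protection_gap(hot, default_dataset["cells"])
        protected = {c.cell_id for c in default_dataset["cells"] if c.protected}
        assert gaps == hot - protected
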