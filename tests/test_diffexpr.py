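import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emtcre import (Contrast, SimConfig, hier_cluster, qpcr_fold_change,
                    rank_de, shared_with_endpoint, simulate_probe_matrix,
                    up_down_ratio, venn_partition)
from emtcre.diffexpr import select_genes, stage_profiles
from emtcre.errors import ConfigurationError, DataError
from emtcre.normalization import NormalizedMatrix, normalize_experiment

from helpers import brute_force_average_linkage, brute_force_venn


def _manual_nm(values: dict[str, np.ndarray], genes: list[str]
               ) -> NormalizedMatrix:
    idx = pd.Index([f"p{i}" for i in range(len(genes))], name="probe_id")
    return NormalizedMatrix(
        log2=pd.DataFrame(values, index=idx),
        gene_ids=pd.Series(genes, index=idx, name="gene_id"),
        baseline=list(values)[0])


class TestRankDE:
    def test_identical_groups_select_nothing(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8.0, 1.0, 60)
        genes = [f"g{i // 3}" for i in range(60)]
        nm = _manual_nm({f"A_r{r}": base for r in (1, 2, 3)} |
                        {f"B_r{r}": base for r in (1, 2, 3)}, genes)
        c = Contrast("B_vs_A", ("B_r1", "B_r2", "B_r3"),
                     ("A_r1", "A_r2", "A_r3"))
        t = rank_de(nm, c, seed=0)
        assert (t["fold_change"] == 1.0).all()
        assert (t["direction"] == "null").all()

    def test_planted_genes_recovered(self, small_experiment):
        cfg, _, truth, nm = small_experiment
        c = Contrast("T6_vs_T0", tuple(nm.arrays_for("T6")),
                     tuple(nm.arrays_for("T0")))
        t = rank_de(nm, c, seed=1)
        ups = set(truth.genes_with_label("T6", "up"))
        downs = set(truth.genes_with_label("T6", "down"))
        hit = len(select_genes(t, "up") & ups) + \
            len(select_genes(t, "down") & downs)
        assert hit / (len(ups) + len(downs)) >= 0.9
        # selected direction never contradicts the planted one
        assert not (select_genes(t, "up") & downs)
        assert not (select_genes(t, "down") & ups)

    def test_type_one_error_controlled_under_null(self):
        cfg = SimConfig(n_genes=1000, probes_per_gene=8, frac_up=0.0,
                        frac_down=0.0, timepoints=("T0", "T6"), seed=13)
        pm, _ = simulate_probe_matrix(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nm = normalize_experiment(pm)
        c = Contrast("T6_vs_T0", tuple(nm.arrays_for("T6")),
                     tuple(nm.arrays_for("T0")))
        t = rank_de(nm, c, seed=3)
        # binomial 99% upper bound on false selections at alpha = 0.01
        assert int((t["direction"] != "null").sum()) <= 20
        # permutation p-values are (super-)uniform under the global null
        for alpha in (0.01, 0.05, 0.1, 0.25):
            se = np.sqrt(alpha * (1 - alpha) / len(t))
            assert (t["p_value"] < alpha).mean() <= alpha + 3 * se

    def test_one_vs_one_has_no_permutations(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i // 2}" for i in range(40)]
        nm = _manual_nm({"A_r1": rng.normal(8, 1, 40),
                         "B_r1": rng.normal(8, 1, 40)}, genes)
        c = Contrast("B_vs_A", ("B_r1",), ("A_r1",))
        with pytest.warns(UserWarning, match="permutations"):
            t = rank_de(nm, c, seed=0)
        assert (t["p_value"] == 1.0).all()

    def test_single_probe_genes_excluded(self):
        rng = np.random.default_rng(2)
        genes = ["solo"] + [f"g{i // 2}" for i in range(60)]
        cols = {f"{c}_r{r}": rng.normal(8, 1, 61)
                for c in "AB" for r in (1, 2, 3)}
        nm = _manual_nm(cols, genes)
        c = Contrast("B_vs_A", ("B_r1", "B_r2", "B_r3"),
                     ("A_r1", "A_r2", "A_r3"))
        with pytest.warns(UserWarning, match="single"):
            t = rank_de(nm, c, seed=0)
        assert "solo" not in t.index

    def test_contrast_validation(self):
        with pytest.raises(ConfigurationError):
            Contrast("bad", ("A",), ())
        with pytest.raises(ConfigurationError):
            Contrast("bad", ("A",), ("A",))


class TestVennPartition:
    def test_disjoint_sets(self):
        vp = venn_partition({"a": {1, 2}, "b": {3, 4, 5}, "c": {6, 7, 8, 9}})
        assert len(vp.region("a")) == 2
        assert len(vp.region("b")) == 3
        assert len(vp.region("c")) == 4
        assert all(len(vp.regions[k]) == 0 for k in vp.regions if len(k) > 1)

    def test_matches_brute_force_enumeration(self):
        sets = {"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"}, "s3": {"c", "e"}}
        vp = venn_partition(sets)
        assert vp.regions == brute_force_venn(sets)
        assert vp.region("s1", "s2", "s3") == {"c"}

    def test_identical_sets_fill_triple_region(self):
        s = {"x", "y"}
        vp = venn_partition({"a": s, "b": s, "c": s})
        assert vp.region("a", "b", "c") == s
        assert sum(vp.counts.values()) == 2

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sets(st.integers(0, 20)), min_size=3, max_size=3))
    def test_partition_properties(self, three):
        sets = {"A": three[0], "B": three[1], "C": three[2]}
        vp = venn_partition(sets)
        union = set().union(*three)
        regions = list(vp.regions.values())
        assert set().union(*regions) == union
        assert sum(len(r) for r in regions) == len(union)  # pairwise disjoint
        # invariant to input order
        flipped = venn_partition({"C": three[2], "B": three[1], "A": three[0]})
        assert flipped.regions == vp.regions


class TestEndpointOverlap:
    @staticmethod
    def _table(directions: dict[str, str]) -> pd.DataFrame:
        return pd.DataFrame({"direction": pd.Series(directions)},
                            index=pd.Index(directions, name="gene_id"))

    def test_hand_built_overlap_count(self):
        universe = [f"g{i}" for i in range(10)]
        stage = {g: "null" for g in universe}
        endpoint = {g: "null" for g in universe}
        for g in ("g0", "g1", "g2", "g3"):  # matching direction
            stage[g] = endpoint[g] = "up"
        stage["g4"], endpoint["g4"] = "up", "down"  # direction conflict
        stage["g5"] = "down"  # stage only
        ov = shared_with_endpoint(self._table(stage), self._table(endpoint))
        assert len(ov.shared) == 4
        assert ov.frac_of_stage == 4 / 6
        assert ov.frac_of_endpoint == 4 / 5

    def test_empty_endpoint(self):
        stage = self._table({"g0": "up", "g1": "null"})
        endpoint = self._table({"g0": "null", "g1": "null"})
        ov = shared_with_endpoint(stage, endpoint)
        assert ov.shared == set() and ov.frac_of_endpoint == 0.0

    def test_stage_subset_of_endpoint(self):
        stage = self._table({"g0": "up", "g1": "null", "g2": "null"})
        endpoint = self._table({"g0": "up", "g1": "down", "g2": "null"})
        ov = shared_with_endpoint(stage, endpoint)
        assert ov.frac_of_stage == 1.0

    def test_mismatched_universe_rejected(self):
        with pytest.raises(DataError):
            shared_with_endpoint(self._table({"g0": "up"}),
                                 self._table({"g1": "up"}))


class TestUpDownRatio:
    def test_percentages(self):
        t_up = pd.DataFrame({"direction": ["up"] * 72 + ["down"] * 28})
        assert up_down_ratio({"s": t_up}).iloc[0]["percent_up"] == 72.0
        t_down = pd.DataFrame({"direction": ["down"] * 5})
        assert up_down_ratio({"s": t_down}).iloc[0]["percent_up"] == 0.0
        t_none = pd.DataFrame({"direction": ["null"] * 5})
        assert np.isnan(up_down_ratio({"s": t_none}).iloc[0]["percent_up"])

    def test_recovers_planted_balance(self, small_experiment):
        cfg, _, truth, nm = small_experiment
        c = Contrast("T6_vs_T0", tuple(nm.arrays_for("T6")),
                     tuple(nm.arrays_for("T0")))
        t = rank_de(nm, c, seed=1)
        pct = up_down_ratio({"T6": t}).iloc[0]["percent_up"]
        assert abs(pct - 50.0) < 15.0  # planted frac_up == frac_down


class TestHierarchicalClustering:
    def test_identical_profiles_merge_at_zero(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0]] * 2 + [[3.0, 1.0, -2.0]],
                            index=["a", "b", "c"])
        res = hier_cluster(prof)
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_at_max_distance(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]],
                            index=["a", "b"])
        res = hier_cluster(prof)
        assert res.distances.loc["a", "b"] == pytest.approx(2.0)

    def test_merge_order_matches_brute_force(self):
        rng = np.random.default_rng(7)
        block1 = [np.array([1.0, 2.0, 3.0, 4.0]) + rng.normal(0, 0.05, 4)
                  for _ in range(3)]
        block2 = [np.array([4.0, 1.0, -3.0, 0.5]) + rng.normal(0, 0.05, 4)
                  for _ in range(2)]
        prof = pd.DataFrame(block1 + block2,
                            index=["a1", "a2", "a3", "b1", "b2"])
        res = hier_cluster(prof)
        merges = brute_force_average_linkage(res.distances.to_numpy())
        # first two merges stay within the planted blocks
        for a, b in merges[:2]:
            members = {prof.index[i][0] for i in a | b}
            assert len(members) == 1
        # scipy linkage merges in the same order (same pairs of clusters)
        n = len(prof)
        scipy_clusters = {i: frozenset([i]) for i in range(n)}
        for row_idx, (a, b) in enumerate(merges):
            i, j = int(res.linkage[row_idx, 0]), int(res.linkage[row_idx, 1])
            assert {scipy_clusters[i], scipy_clusters[j]} == {a, b}
            scipy_clusters[n + row_idx] = a | b

    def test_constant_profile_warns_and_is_distant(self):
        prof = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                            index=["a", "flat"])
        with pytest.warns(UserWarning, match="constant"):
            res = hier_cluster(prof)
        assert res.distances.loc["a", "flat"] == 2.0

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(9)
        genes = [f"gene{i}" for i in range(6)]
        prof = pd.DataFrame(rng.normal(size=(6, 4)), index=genes)
        res = hier_cluster(prof)
        assert res.newick.endswith(";")
        for g in genes:
            assert g in res.newick
        assert sorted(res.ordered_genes) == sorted(genes)

    def test_too_few_genes_rejected(self):
        with pytest.raises(DataError):
            hier_cluster(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestQpcrFoldChange:
    @pytest.mark.parametrize("xn,yn,expected", [
        (20.0, 20.0, 1.0),   # equal thresholds: no change
        (19.0, 20.0, 2.0),   # one cycle earlier: doubling
        (22.0, 20.0, 0.25),  # two cycles later: four-fold down
    ])
    def test_formula(self, xn, yn, expected):
        assert qpcr_fold_change(xn, yn) == pytest.approx(expected)

    def test_rejects_nonfinite(self):
        with pytest.raises(DataError):
            qpcr_fold_change(np.nan, 20.0)
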