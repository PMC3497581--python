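import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy import optimize

from acsiva import phylo
from acsiva.errors import DataError, DomainError, ParseError

from conftest import bruteforce_pls, circular_diff, random_tree


class TestReadNewick:
    def test_lengths_preserved(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:2,B:1):1,C:3);\n")
        tree = phylo.read_newick(p)
        assert sorted(phylo.tip_labels(tree)) == ["A", "B", "C"]
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 2.0, "B": 1.0, "C": 3.0}

    def test_missing_lengths_become_one(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),C);\n")
        with caplog.at_level("WARNING"):
            tree = phylo.read_newick(p)
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None:
                assert edge.length == 1.0
        assert "replaced" in caplog.text

    def test_zero_length_replaced(self, tmp_path, caplog):
        p = tmp_path / "t.nwk"
        p.write_text("((A:0,B:1):1,C:3);\n")
        with caplog.at_level("WARNING"):
            tree = phylo.read_newick(p)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["A"] == 1.0
        assert "replaced 1" in caplog.text

    def test_malformed_raises(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A:2,B:1:1,C;\n")
        with pytest.raises(ParseError):
            phylo.read_newick(p)


class TestPrune:
    def test_collapses_and_sums(self):
        tree = phylo.tree_from_string("((A:2,B:1):1,C:3);")
        pruned = phylo.prune_to_taxa(tree, ["A", "C"])
        lengths = {lf.taxon.label: lf.edge.length for lf in pruned.leaf_node_iter()}
        assert lengths == {"A": 3.0, "C": 3.0}

    def test_prune_all_is_identity(self):
        tree = phylo.tree_from_string("((A:2,B:1):1,C:3);")
        pruned = phylo.prune_to_taxa(tree, ["A", "B", "C"])
        assert sorted(phylo.tip_labels(pruned)) == ["A", "B", "C"]
        pdm0 = tree.phylogenetic_distance_matrix()
        pdm1 = pruned.phylogenetic_distance_matrix()
        t0 = {x.label: x for x in tree.taxon_namespace}
        t1 = {x.label: x for x in pruned.taxon_namespace}
        for a, b in itertools.combinations("ABC", 2):
            assert pdm0.patristic_distance(t0[a], t0[b]) == pytest.approx(
                pdm1.patristic_distance(t1[a], t1[b])
            )

    def test_unknown_label_reported(self):
        tree = phylo.tree_from_string("((A:2,B:1):1,C:3);")
        with pytest.raises(DataError, match="Nope"):
            phylo.prune_to_taxa(tree, ["A", "Nope"])

    def test_single_label_raises(self):
        tree = phylo.tree_from_string("((A:2,B:1):1,C:3);")
        with pytest.raises(DomainError):
            phylo.prune_to_taxa(tree, ["A"])

    def test_random_subsets_conserve_path_lengths(self, rng):
        for _ in range(10):
            tree = random_tree(rng, 8)
            labels = sorted(phylo.tip_labels(tree))
            keep = sorted(rng.choice(labels, size=4, replace=False))
            pdm0 = tree.phylogenetic_distance_matrix()
            t0 = {x.label: x for x in tree.taxon_namespace}
            expected = {
                (a, b): pdm0.patristic_distance(t0[a], t0[b])
                for a, b in itertools.combinations(keep, 2)
            }
            pruned = phylo.prune_to_taxa(tree, keep)
            pdm1 = pruned.phylogenetic_distance_matrix()
            t1 = {x.label: x for x in pruned.taxon_namespace}
            for (a, b), d in expected.items():
                assert pdm1.patristic_distance(t1[a], t1[b]) == pytest.approx(d)


class TestDedupe:
    def test_keeps_type_species(self):
        tree = phylo.tree_from_string(
            "((Gen_alpha:1,Gen_beta:1):1,(Other_x:1,Gen_gamma:2):1);"
        )
        out = phylo.dedupe_congeneric_tips(tree, {"Gen": "Gen beta"})
        assert sorted(phylo.tip_labels(out)) == ["Gen", "Other"]

    def test_defaults_to_first(self):
        tree = phylo.tree_from_string("((Gen_a:1,Gen_b:1):1,Oth_x:2);")
        out = phylo.dedupe_congeneric_tips(tree)
        assert sorted(phylo.tip_labels(out)) == ["Gen", "Oth"]


class TestTipsToCartesian:
    def test_unit_vector_east(self):
        assert phylo.tips_to_cartesian({"A": (0.0, 1.0)})["A"] == pytest.approx((2.0, 1.0))

    def test_north_half(self):
        assert phylo.tips_to_cartesian({"A": (90.0, 0.5)})["A"] == pytest.approx((1.0, 1.5))

    def test_published_row_projection(self):
        x, y = phylo.tips_to_cartesian({"A": (52.0, 0.74)})["A"]
        assert x == pytest.approx(1.4556, abs=1e-4)
        assert y == pytest.approx(1.5831, abs=1e-4)


class TestPLS:
    def test_cherry_midpoint(self):
        tree = phylo.tree_from_string("(A:1,B:1);")
        states = phylo.pls_ancestral_states(tree, {"A": 0.0, "B": 2.0})
        assert states["N0"] == pytest.approx(1.0)

    def test_star_closed_form(self, rng):
        k = 5
        labels = [f"T{i}" for i in range(k)]
        lengths = np.round(rng.uniform(0.2, 3.0, k), 6)
        values = rng.normal(size=k)
        newick = "(" + ",".join(
            f"{t}:{b:.6f}" for t, b in zip(labels, lengths)
        ) + ");"
        tree = phylo.tree_from_string(newick)
        states = phylo.pls_ancestral_states(tree, dict(zip(labels, values)))
        expected = np.sum(values / lengths) / np.sum(1.0 / lengths)
        assert states["N0"] == pytest.approx(expected, abs=1e-10)

    def test_matches_incidence_regression(self, rng):
        for _ in range(25):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            tips = {t: float(rng.normal()) for t in phylo.tip_labels(tree)}
            states = phylo.pls_ancestral_states(tree, tips)
            oracle = bruteforce_pls(tree, tips)
            for node, val in oracle.items():
                assert states[node.acsiva_id] == pytest.approx(val, abs=1e-8)

    def test_matches_numeric_minimizer(self, rng):
        tree = random_tree(rng, 6)
        tips = {t: float(rng.normal()) for t in phylo.tip_labels(tree)}
        states = phylo.pls_ancestral_states(tree, tips)
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]

        def objective(x):
            vals = {id(nd): v for nd, v in zip(internal, x)}
            for lf in tree.leaf_node_iter():
                vals[id(lf)] = tips[lf.taxon.label]
            total = 0.0
            for node in tree.preorder_node_iter():
                if node.edge.tail_node is None:
                    continue
                d = vals[id(node)] - vals[id(node.edge.tail_node)]
                total += d * d / node.edge.length
            return total

        res = optimize.minimize(objective, np.zeros(len(internal)), method="BFGS",
                                options={"gtol": 1e-12})
        for nd, v in zip(internal, res.x):
            assert states[nd.acsiva_id] == pytest.approx(v, abs=1e-6)

    def test_missing_tip_raises(self):
        tree = phylo.tree_from_string("(A:1,B:1);")
        with pytest.raises(DataError, match="B"):
            phylo.pls_ancestral_states(tree, {"A": 0.0})

    def test_affine_equivariance(self, rng):
        tree = random_tree(rng, 7)
        tips = {t: float(rng.normal()) for t in phylo.tip_labels(tree)}
        a, b = 2.5, -3.75
        base = phylo.pls_ancestral_states(tree, tips)
        scaled = phylo.pls_ancestral_states(
            tree, {k: a * v + b for k, v in tips.items()}
        )
        for node, v in base.items():
            assert scaled[node] == pytest.approx(a * v + b, abs=1e-9)

    def test_equal_lengths_equals_unit_flag(self, rng):
        tree = random_tree(rng, 6, scale_lengths=False)
        for edge in tree.preorder_edge_iter():
            if edge.tail_node is not None:
                edge.length = 2.0
        tips = {t: float(rng.normal()) for t in phylo.tip_labels(tree)}
        weighted = phylo.pls_ancestral_states(tree, tips)
        unit = phylo.pls_ancestral_states(tree, tips, unit_lengths=True)
        for node in weighted:
            assert weighted[node] == pytest.approx(unit[node], abs=1e-10)

    def test_root_in_convex_hull(self, rng):
        for _ in range(10):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            tips = {t: float(rng.normal()) for t in phylo.tip_labels(tree)}
            states = phylo.pls_ancestral_states(tree, tips)
            lo, hi = min(tips.values()), max(tips.values())
            for v in states.values():
                assert lo - 1e-9 <= v <= hi + 1e-9


class TestStatesToAngles:
    @pytest.mark.parametrize(
        "xy,angle,sector",
        [((2.0, 1.0), 0.0, 0), ((0.0, 1.0), 180.0, 4), ((1.5, 0.5), 315.0, 7)],
    )
    def test_examples(self, xy, angle, sector):
        df = phylo.states_to_angles({"n": xy})
        assert df.loc[0, "angle_deg"] == pytest.approx(angle)
        assert df.loc[0, "sector"] == sector

    def test_centroid_point_flagged(self):
        df = phylo.states_to_angles({"n": (1.0, 1.0)})
        assert math.isnan(df.loc[0, "angle_deg"])
        assert math.isnan(df.loc[0, "sector"])
        assert df.loc[0, "N_label"] == "at-centroid"

    def test_axis_labels(self):
        df = phylo.states_to_angles({"n": (0.5, 1.5)})
        assert df.loc[0, "N_label"] == "enriched"
        assert df.loc[0, "C_label"] == "depleted"


class TestTransitions:
    def test_all_same_label(self):
        tree = phylo.tree_from_string("((A:1,B:1):1,C:1);")
        phylo.assign_node_ids(tree)
        labels = {nid: "enriched" for nid in ("A", "B", "C", "N0", "N1")}
        assert phylo.count_axis_transitions(tree, labels)[0] == 0

    def test_cherry_single_transition(self):
        tree = phylo.tree_from_string("(A:1,B:1);")
        phylo.assign_node_ids(tree)
        labels = {"N0": "enriched", "A": "depleted", "B": "enriched"}
        assert phylo.count_axis_transitions(tree, labels)[0] == 1

    def test_hand_counted_fixture(self):
        tree = phylo.tree_from_string(
            "(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);"
        )
        phylo.assign_node_ids(tree)
        # preorder internal ids: N0 root, N1=(AB,CD), N2=(A,B), N3=(C,D), N4=(E,F)
        labels = {
            "N0": "dep", "N1": "dep", "N2": "enr", "N3": "dep", "N4": "enr",
            "A": "enr", "B": "dep", "C": "dep", "D": "enr", "E": "enr", "F": "dep",
        }
        # branch-by-branch: N0-N1 same, N1-N2 diff, N2-A diff, N2-B same... -> 6
        expected = 0
        edges = [("N0", "N1"), ("N1", "N2"), ("N2", "A"), ("N2", "B"),
                 ("N1", "N3"), ("N3", "C"), ("N3", "D"),
                 ("N0", "N4"), ("N4", "E"), ("N4", "F")]
        for a, b in edges:
            expected += labels[a] != labels[b]
        assert phylo.count_axis_transitions(tree, labels)[0] == expected

    def test_undefined_labels_skipped(self):
        tree = phylo.tree_from_string("(A:1,B:1);")
        phylo.assign_node_ids(tree)
        labels = {"N0": "enriched", "A": None, "B": "depleted"}
        trans, skipped = phylo.count_axis_transitions(tree, labels)
        assert (trans, skipped) == (1, 1)  # A's branch skipped, B's counted


class TestReconstructVectorStates:
    def test_cherry_symmetry(self):
        tree = phylo.tree_from_string("(A:1,B:1);")
        df = phylo.reconstruct_vector_states(
            tree, {"A": (45.0, 1.0), "B": (135.0, 1.0)}
        )
        root = df[df["node"] == "N0"].iloc[0]
        assert root["angle_deg"] == pytest.approx(90.0)
        assert root["sector"] == 2

    def test_separability_xy(self, rng):
        # the joint reconstruction equals the per-axis reconstructions
        tree = random_tree(rng, 6)
        mv = {t: (float(rng.uniform(0, 360)), float(rng.uniform(0.1, 1.0)))
              for t in phylo.tip_labels(tree)}
        df = phylo.reconstruct_vector_states(tree, mv)
        cart = phylo.tips_to_cartesian(mv)
        xs = phylo.pls_ancestral_states(tree, {k: v[0] for k, v in cart.items()})
        ys = phylo.pls_ancestral_states(tree, {k: v[1] for k, v in cart.items()})
        for _, row in df.iterrows():
            assert row["X"] == pytest.approx(xs[row["node"]], abs=1e-12)
            assert row["Y"] == pytest.approx(ys[row["node"]], abs=1e-12)

    def test_shift_neutrality(self, rng):
        # the +1 shift then -1 unshift leaves reconstructed angles unchanged
        # versus reconstructing the raw components directly
        tree = random_tree(rng, 5)
        mv = {t: (float(rng.uniform(0, 360)), float(rng.uniform(0.1, 1.0)))
              for t in phylo.tip_labels(tree)}
        df = phylo.reconstruct_vector_states(tree, mv)
        raw = {
            t: (math.cos(math.radians(a)) * r, math.sin(math.radians(a)) * r)
            for t, (a, r) in mv.items()
        }
        xs = phylo.pls_ancestral_states(tree, {k: v[0] for k, v in raw.items()})
        ys = phylo.pls_ancestral_states(tree, {k: v[1] for k, v in raw.items()})
        for _, row in df.iterrows():
            angle = math.degrees(
                math.atan2(ys[row["node"]], xs[row["node"]])
            ) % 360.0
            assert abs(circular_diff(row["angle_deg"], angle)) < 1e-9

    def test_orphan_tip_errors_without_prune(self):
        tree = phylo.tree_from_string("((A:1,B:1):1,C:1);")
        with pytest.raises(DataError, match="C"):
            phylo.reconstruct_vector_states(tree, {"A": (0, 1), "B": (90, 1)})

    def test_orphan_tip_pruned_on_request(self):
        tree = phylo.tree_from_string("((A:1,B:1):1,C:1);")
        df = phylo.reconstruct_vector_states(
            tree, {"A": (0.0, 1.0), "B": (90.0, 1.0)}, prune=True
        )
        assert set(df[df["is_tip"]]["node"]) == {"A", "B"}
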