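import random

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import minmax_predict
from polysynergy.io import KdMatrix
from polysynergy.timma import (CombinationNetwork, binarize_targets,
                               build_combination_network,
                               network_cut_inference, normalize_dss,
                               predict_combination, predict_sensitivity,
                               select_essential_targets)


def _kd_row(values, kinases=None):
    kinases = kinases or [f"k{i + 1}" for i in range(len(values))]
    return KdMatrix(pd.DataFrame([values], index=["d"], columns=kinases))


class TestBinarize:
    @pytest.mark.parametrize("fold,expected", [
        (50.0, {"k1", "k2"}),   # threshold 500: keeps 400, drops 600
        (10.0, {"k1"}),         # threshold 100
        (1.0, {"k1"}),          # exactly the argmin kinase
    ])
    def test_fold_rule(self, fold, expected):
        kd = _kd_row([10.0, 400.0, 600.0])
        assert binarize_targets(kd, fold)["d"].targets == expected

    def test_inclusive_boundary(self):
        kd = _kd_row([10.0, 500.0])
        assert binarize_targets(kd, 50.0)["d"].targets == {"k1", "k2"}

    def test_missing_never_target(self, small_kd):
        assert "k4" not in binarize_targets(small_kd, 50.0)["dA"].targets

    def test_no_finite_kd_rejected(self):
        with pytest.raises(ValueError):
            KdMatrix(pd.DataFrame([[np.nan]], index=["d"], columns=["k"]))


class TestNormalize:
    def test_linear_map(self):
        prof = normalize_dss({"a": 0.0, "b": 5.0, "c": 10.0})
        assert np.allclose(prof.y[["a", "b", "c"]], [0.0, 0.5, 1.0])

    def test_degenerate_screen_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_dss({"a": 3.0, "b": 3.0})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=3,
                    max_size=12, unique=True))
    def test_rank_order_preserved(self, values):
        prof = normalize_dss({f"d{i}": v for i, v in enumerate(values)})
        raw = prof.dss_raw.to_numpy()
        y = prof.y.to_numpy()
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(y[order]) >= -1e-15)  # order-preserving
        assert y.min() == 0.0 and y.max() == 1.0


class TestPredictSensitivity:
    def test_exact_match_branch_averages(self):
        d = {"t1", "t2"}
        y = predict_sensitivity(d, [{"t1", "t2"}, {"t1", "t2"}, {"t1"}],
                                [0.2, 0.4, 0.9])
        assert y == pytest.approx(0.3)

    def test_pseudo_drug_convention(self):
        # no match, no subset, no superset -> (0 + 1) / 2
        y = predict_sensitivity({"t4"}, [{"t1"}, {"t2", "t3"}], [0.3, 0.8])
        assert y == pytest.approx(0.5)

    def test_nested_profiles_hand_case(self):
        # frozen from the literal enumeration oracle
        profiles = [{"t1"}, {"t1", "t2"}, {"t1", "t2", "t3"}]
        ys = [0.1, 0.5, 0.9]
        d = {"t1", "t2", "t4"}
        expected = minmax_predict(d, profiles, ys)
        # strict subsets of d: {t1}, {t1,t2}; h = {t1,t2} (y=0.5);
        # {t1} qualifies (subset of d, superset... no: {t1} not > {t1,t2});
        # y_min = 0.5; no superset -> y_max = 1; prediction 0.75
        assert expected == pytest.approx(0.75)
        assert predict_sensitivity(d, profiles, ys) == pytest.approx(expected)

    def test_output_in_unit_interval(self):
        rng = random.Random(11)
        kin = "abcde"
        for _ in range(200):
            profiles = [frozenset(rng.sample(kin, rng.randint(0, 5)))
                        for _ in range(rng.randint(1, 6))]
            ys = [rng.random() for _ in profiles]
            d = frozenset(rng.sample(kin, rng.randint(0, 5)))
            assert 0.0 <= predict_sensitivity(d, profiles, ys) <= 1.0

    def test_monotone_edit_of_maximal_subset_drug(self):
        # raising the sensitivity of the currently most-sensitive
        # strict-subset drug never lowers the prediction (with no
        # superset training drug the upper bound is pinned at 1).
        # Note: the edit is NOT monotone for arbitrary subset drugs —
        # promoting a low drug to the new argmax can pull previously
        # excluded low sensitivities into the lower average.
        rng = random.Random(5)
        kin = "abcd"
        for _ in range(200):
            d = frozenset(kin)  # full universe -> no strict supersets
            profiles = [frozenset(rng.sample(kin, rng.randint(0, 3)))
                        for _ in range(4)]
            ys = [rng.random() for _ in profiles]
            subs = [i for i, p in enumerate(profiles) if p < d]
            if not subs:
                continue
            h = max(subs, key=lambda i: ys[i])
            bumped = list(ys)
            bumped[h] = min(1.0, ys[h] + rng.random())
            lo = predict_sensitivity(d, profiles, ys)
            hi = predict_sensitivity(d, profiles, bumped)
            assert hi >= lo - 1e-12


class TestSelectEssentialTargets:
    def test_perfect_single_target_signal(self):
        # y = 1 iff drug hits the planted kinase, zero noise
        profiles = {"d1": {"t*"}, "d2": {"t*", "x"}, "d3": {"x"},
                    "d4": {"y"}, "d5": {"t*", "y"}}
        sens = {"d1": 1.0, "d2": 1.0, "d3": 0.0, "d4": 0.0, "d5": 1.0}
        model = select_essential_targets(profiles, sens, max_size=5)
        assert model.selected_targets == ("t*",)
        assert model.loo_error == pytest.approx(0.0)

    def test_constant_target_not_selected_first(self):
        # 'c' is hit by every drug and carries no information
        profiles = {"d1": {"c", "t"}, "d2": {"c", "t", "x"}, "d3": {"c", "x"},
                    "d4": {"c"}}
        sens = {"d1": 1.0, "d2": 1.0, "d3": 0.0, "d4": 0.0}
        model = select_essential_targets(profiles, sens, max_size=4)
        assert model.selected_targets[0] != "c"
        assert "t" in model.selected_targets

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        profiles = {f"d{i}": set(np.array(list("abcdef"))[
            rng.random(6) < 0.4]) for i in range(10)}
        profiles = {d: set(map(str, p)) or {"a"} for d, p in profiles.items()}
        sens = {d: float(rng.random()) for d in profiles}
        m1 = select_essential_targets(profiles, sens, max_size=4, seed=1)
        m2 = select_essential_targets(profiles, sens, max_size=4, seed=1)
        assert m1 == m2

    def test_too_few_drugs_rejected(self):
        with pytest.raises(ValueError):
            select_essential_targets({"d1": {"a"}, "d2": {"b"}},
                                     {"d1": 0.0, "d2": 1.0})

    def test_bad_max_size_rejected(self):
        profiles = {"d1": {"a"}, "d2": {"b"}, "d3": {"a", "b"}}
        with pytest.raises(ValueError):
            select_essential_targets(profiles, {"d1": 0.0, "d2": 0.5,
                                                "d3": 1.0}, max_size=0)


class TestPredictCombination:
    @pytest.fixture
    def and_model(self):
        # sensitive only when t1 and t2 both hit (planted AND truth)
        profiles = {"a": {"t1"}, "b": {"t2"}, "c": {"t1", "t2"},
                    "d": {"t1", "t3"}, "e": {"t2", "t3"}, "f": {"t3"}}
        sens = {"a": 0.05, "b": 0.05, "c": 1.0, "d": 0.1, "e": 0.1, "f": 0.0}
        return select_essential_targets(profiles, sens, max_size=3)

    def test_identical_drugs_zero_synergy(self, and_model):
        p = predict_combination(and_model, "a", "a")
        assert p.synergy == pytest.approx(0.0)

    def test_planted_and_combination_scores_high(self, and_model):
        p = predict_combination(and_model, "a", "b")
        assert p.synergy > 0.2
        assert p.y_combination > max(p.y_single1, p.y_single2)

    def test_raw_score_mode(self, and_model):
        p = predict_combination(and_model, "a", "b", score_mode="raw")
        assert p.synergy == pytest.approx(p.y_combination)

    def test_unknown_drug_rejected(self, and_model):
        with pytest.raises(KeyError):
            predict_combination(and_model, "a", "zzz")


class TestCombinationNetwork:
    def test_identical_patterns_merge(self):
        from polysynergy.timma import TimmaModel
        model = TimmaModel(
            selected_targets=("k1", "k2", "k3"),
            profiles={"d1": frozenset({"k1", "k2"}),
                      "d2": frozenset({"k1", "k2", "k3"}),
                      "d3": frozenset({"k3"})},
            sensitivities={"d1": 0.9, "d2": 1.0, "d3": 0.2},
            loo_error=0.0)
        net = build_combination_network(model)
        merged = [n for n in net.nodes if net.members_of(n) == {"k1", "k2"}]
        assert len(merged) == 1  # k1, k2 bound by exactly the same drugs
        members = [k for n in net.nodes for k in net.members_of(n)]
        assert sorted(members) == ["k1", "k2", "k3"]  # partition

    def test_single_target_network(self):
        profiles = {"d1": {"k1"}, "d2": {"k1", "k2"}, "d3": {"k2"}}
        sens = {"d1": 0.1, "d2": 0.6, "d3": 1.0}
        model = select_essential_targets(profiles, sens, max_size=1)
        net = build_combination_network(model)
        assert len(net.nodes) == 1

    def _path_network(self):
        g = nx.Graph()
        g.add_node("A", members=frozenset({"A"}), drugs=frozenset({"dA"}))
        g.add_node("B", members=frozenset({"B"}), drugs=frozenset({"dB"}))
        g.add_node("C", members=frozenset({"C"}), drugs=frozenset({"dC"}))
        g.add_edge("A", "B")
        g.add_edge("B", "C")
        return CombinationNetwork(graph=g)

    def test_cut_inference_on_path_graph(self):
        net = self._path_network()
        ends = network_cut_inference(net, "dA", "dC")
        assert ends["components_after_removal"] == 1
        assert not ends["predicted_effective"]
        middle = network_cut_inference(net, "dB", "dB")
        assert middle["components_after_removal"] == 2
        assert middle["predicted_effective"]

    def test_removing_everything_is_effective(self):
        net = self._path_network()
        g = net.graph
        g.nodes["B"]["drugs"] = frozenset({"dA"})
        g.nodes["C"]["drugs"] = frozenset({"dA"})
        out = network_cut_inference(net, "dA", "dA")
        assert out["predicted_effective"]


class TestBruteForceEquivalence:
    def test_random_instances_match_oracle(self):
        rng = random.Random(99)
        kin = "abcde"
        for _ in range(500):
            nd, nk = rng.randint(1, 6), rng.randint(1, 5)
            profiles = [frozenset(rng.sample(kin[:nk], rng.randint(0, nk)))
                        for _ in range(nd)]
            ys = [round(rng.random(), 3) for _ in range(nd)]
            d = frozenset(rng.sample(kin[:nk], rng.randint(0, nk)))
            assert predict_sensitivity(d, profiles, ys) == pytest.approx(
                minmax_predict(d, profiles, ys), abs=1e-12)
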