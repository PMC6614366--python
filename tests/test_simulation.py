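import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from polysynergy import synthetic
from polysynergy.io import SignedNetwork
from polysynergy.simulate import (GrowthParams, calibrate_rates,
                                  compile_reactions, hill_growth_factor,
                                  knockout_experiment, ode_twin,
                                  parameter_sensitivity, select_network_genes,
                                  silence, ssa_simulate)


def _birth_death(c=10.0, k_d=0.1, growth=None):
    net = SignedNetwork(())
    return compile_reactions(net, ["G"], k_p={"G": c}, k_d={"G": k_d},
                             source_genes=["G"],
                             growth=growth or GrowthParams(pgrowth0=0))


class TestGeneSelection:
    @pytest.mark.parametrize("self_expr,mean,included", [
        (10.0, 10.0, False),   # D = 0
        (30.0, 10.0, True),    # D = 2
        (20.0, 10.0, False),   # D = 1, strict threshold
    ])
    def test_normalized_deviation(self, self_expr, mean, included):
        df = select_network_genes({"g": self_expr}, {"g": mean})
        assert df.loc["g", "included"] == included

    def test_zero_panel_mean_rejected(self):
        with pytest.raises(ValueError):
            select_network_genes({"g": 1.0}, {"g": 0.0})


class TestCompile:
    def test_two_gene_activation_count(self):
        net = SignedNetwork((("A", "B", "activation"),))
        sys_ = compile_reactions(net, ["A", "B"], source_genes=None)
        # 1 conversion + 2 degradations
        assert len(sys_.reactions) == 3

    def test_inhibition_propensity_mass_action(self):
        net = SignedNetwork((("B", "C", "inhibition"),))
        sys_ = compile_reactions(net, ["B", "C"], k_d={"C": 0.1, "B": 0.1},
                                 source_genes=None)
        r = next(r for r in sys_.reactions if r.kind == "inhibition")
        x = {"B": 2, "C": 3}
        propensity = sys_.rate(r) * math.prod(
            x[sys_.species[s]] for s in r.reactants)
        assert propensity == pytest.approx(0.6)

    def test_unknown_sign_token_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            SignedNetwork((("A", "B", "maybe"),))

    def test_edges_to_unselected_genes_dropped(self):
        net = SignedNetwork((("A", "B", "activation"),
                             ("A", "OUT", "activation")))
        sys_ = compile_reactions(net, ["A", "B"], source_genes=None)
        assert all("OUT" not in
                   [sys_.species[s] for s in r.reactants + r.products]
                   for r in sys_.reactions)

    def test_catalytic_variant_keeps_source(self):
        net = SignedNetwork((("A", "B", "activation"),))
        sys_ = compile_reactions(net, ["A", "B"], catalytic=True,
                                 source_genes=None)
        r = next(r for r in sys_.reactions if r.kind == "activation")
        assert sys_.species[r.reactants[0]] == "A"
        assert sorted(sys_.species[s] for s in r.products) == ["A", "B"]


class TestOdeTwin:
    def test_birth_death_closed_form(self):
        ss = ode_twin(_birth_death(c=10.0, k_d=0.1))
        assert ss["G"] == pytest.approx(100.0, rel=1e-6)

    def test_linear_activation_chain_closed_form(self):
        # A (source) -> B -> C with consuming activations:
        # A* = kpA/(kdA+kpB); B* = kpB A*/(kdB+kpC); C* = kpC B*/kdC
        net = SignedNetwork((("A", "B", "activation"),
                             ("B", "C", "activation")))
        k_p = {"A": 10.0, "B": 0.05, "C": 0.04}
        k_d = {"A": 0.1, "B": 0.1, "C": 0.1}
        sys_ = compile_reactions(net, ["A", "B", "C"], k_p=k_p, k_d=k_d,
                                 source_genes="roots")
        ss = ode_twin(sys_)
        a = 10.0 / (0.1 + 0.05)
        b = 0.05 * a / (0.1 + 0.04)
        c = 0.04 * b / 0.1
        assert ss["A"] == pytest.approx(a, rel=1e-6)
        assert ss["B"] == pytest.approx(b, rel=1e-6)
        assert ss["C"] == pytest.approx(c, rel=1e-6)


class TestCalibration:
    def test_isolated_gene_exact(self):
        sys_ = calibrate_rates(_birth_death(c=10.0, k_d=0.5), {"G": 100.0})
        assert ode_twin(sys_)["G"] == pytest.approx(100.0, rel=0.05)

    def test_three_gene_chain_within_tolerance(self):
        net = SignedNetwork((("A", "B", "activation"),
                             ("B", "C", "activation")))
        sys_ = compile_reactions(net, ["A", "B", "C"],
                                 k_p={"A": 10.0, "B": 0.05, "C": 0.04},
                                 source_genes="roots")
        targets = {"A": 100.0, "B": 50.0, "C": 20.0}
        cal = calibrate_rates(sys_, targets, tol=0.05)
        ss = ode_twin(cal)
        for g, t in targets.items():
            assert abs(ss[g] - t) / t < 0.05

    def test_idempotent(self):
        net = SignedNetwork((("A", "B", "activation"),))
        sys_ = compile_reactions(net, ["A", "B"], k_p={"A": 8.0, "B": 0.05},
                                 source_genes="roots")
        targets = {"A": 80.0, "B": 40.0}
        once = calibrate_rates(sys_, targets, tol=0.02)
        twice = calibrate_rates(once, targets, tol=0.02)
        for g in targets:
            assert twice.k_d[g] == pytest.approx(once.k_d[g], rel=0.02)

    def test_unreachable_target_reported(self):
        with pytest.raises((RuntimeError, ValueError)):
            calibrate_rates(_birth_death(), {"G": -5.0})


class TestHillFactor:
    def test_boundary_values(self):
        assert hill_growth_factor(0.0) == 1.0
        assert hill_growth_factor(65.0) == pytest.approx(0.5)
        assert hill_growth_factor(1e6) < 1e-6

    def test_monotone_decreasing(self):
        xs = np.linspace(0, 300, 100)
        fs = [hill_growth_factor(x) for x in xs]
        assert all(a >= b for a, b in zip(fs, fs[1:]))


class TestSsa:
    def test_reproducible_for_fixed_seed(self):
        sys_ = _birth_death()
        a = ssa_simulate(sys_, {"G": 50}, t_end=200.0, seed=5)
        b = ssa_simulate(sys_, {"G": 50}, t_end=200.0, seed=5)
        assert np.array_equal(a.mean_expression["G"], b.mean_expression["G"])
        assert np.array_equal(a.cell_count, b.cell_count)

    def test_growth_disabled_without_pgrowth(self):
        res = ssa_simulate(_birth_death(), {"G": 100}, t_end=100.0, seed=1)
        assert res.n_divisions == 0
        assert res.cell_count[-1] == 1.0

    def test_population_doubles_every_t_div(self):
        # TP53 absent -> f = 1 -> asymptotic doubling every t_div
        sys_ = _birth_death(growth=GrowthParams(t_div=38.0))
        ratios = []
        for seed in range(10):
            r = ssa_simulate(sys_, {"G": 100}, t_end=190.0, seed=seed,
                             window=1.0)
            n1 = r.cell_count[np.searchsorted(r.times, 152.0)]
            ratios.append(r.cell_count[-1] / n1)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_growth_rate_halves_at_hill_midpoint(self):
        # TP53 pinned near Q = 65 -> f ~ 0.5 -> per-t_div factor ~ sqrt(2)^2/2
        net = SignedNetwork(())
        sys_ = compile_reactions(net, ["TP53"], k_p={"TP53": 65.0},
                                 k_d={"TP53": 1.0}, source_genes=["TP53"],
                                 growth=GrowthParams(t_div=38.0))
        ratios = []
        for seed in range(10):
            r = ssa_simulate(sys_, {"TP53": 65}, t_end=304.0, seed=seed,
                             window=1.0)
            n1 = r.cell_count[np.searchsorted(r.times, 152.0)]
            ratios.append((r.cell_count[-1] / n1) ** (38.0 / 152.0))
        assert np.mean(ratios) == pytest.approx(2.0 ** 0.5, rel=0.10)

    def test_division_conserves_molecules(self):
        sys_ = _birth_death(growth=GrowthParams(t_div=20.0))
        res = ssa_simulate(sys_, {"G": 100}, t_end=120.0, seed=3,
                           record_divisions=True)
        assert res.n_divisions > 0
        for _t, mother, d1, d2 in res.divisions:
            assert [a + b for a, b in zip(d1, d2)] == mother

    def test_population_cap_subsampling_keeps_weighted_count(self):
        sys_ = _birth_death(growth=GrowthParams(t_div=10.0))
        capped = ssa_simulate(sys_, {"G": 20}, t_end=80.0, seed=9,
                              population_cap=8)
        assert capped.cap_hits > 0
        # weighted count still grows ~2^(t/10) within broad bounds
        assert capped.cell_count[-1] > 50


class TestKnockout:
    def test_isolated_gene_has_no_effect(self, demo_system):
        res = knockout_experiment(demo_system, ["PKN1"], n_runs=4,
                                  t_end=100.0, window=40.0, seed=2,
                                  population_cap=300)
        assert res.viability_ratio == pytest.approx(1.0, abs=0.15)

    def test_unknown_gene_rejected(self, demo_system):
        with pytest.raises(KeyError):
            knockout_experiment(demo_system, ["NOPE"], n_runs=1, t_end=10.0)

    def test_knockdown_scales_production(self, demo_system):
        kd = silence(demo_system, ["AURKB"], mode="knockdown", eff=0.8)
        prod = [r for r in kd.reactions if r.kind == "source"
                and kd.species[r.products[0]] == "AURKB"]
        assert prod and prod[0].scale == pytest.approx(0.2)

    def test_knockout_removes_production(self, demo_system):
        ko = silence(demo_system, ["AURKB"])
        assert not any(r.kind in ("source", "activation")
                       and any(ko.species[s] == "AURKB" for s in r.products)
                       for r in ko.reactions)
        assert ko.initial_counts["AURKB"] == 0


class TestSensitivity:
    def test_self_degradation_sensitivity_is_minus_one(self):
        report = parameter_sensitivity(_birth_death())
        row = report[report.parameter == "k_d(G)"].iloc[0]
        assert row["S_G"] == pytest.approx(-1.0, rel=1e-3)
        kp = report[report.parameter == "k_p(G)"].iloc[0]
        assert kp["S_G"] == pytest.approx(1.0, rel=1e-3)

    def test_terminal_gene_parameters_do_not_propagate(self, demo_system):
        # PKN1 has no outgoing edges: its rates influence only itself
        report = parameter_sensitivity(demo_system).set_index("parameter")
        others = [c for c in report.columns
                  if c.startswith("S_") and c != "S_PKN1"]
        assert np.nanmax(np.abs(report.loc["k_d(PKN1)", others]
                                .to_numpy(dtype=float))) < 1e-6

    def test_ranking_stable_under_step_size(self, demo_system):
        a = parameter_sensitivity(demo_system, perturbation=0.005)
        b = parameter_sensitivity(demo_system, perturbation=0.02)
        merged = a.merge(b, on="parameter", suffixes=("_a", "_b"))
        rho = spearmanr(merged["mean_abs_sensitivity_a"],
                        merged["mean_abs_sensitivity_b"]).statistic
        assert rho >= 0.95
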