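"""Synthetic input generators with planted ground truth.

Every external table the pipeline consumes can be generated here with a
known planted signal, so each stage is testable end-to-end without any
download: sparse log-normal Kd screens whose sensitivities follow a
Boolean rule over a planted essential-target set, 4PL dose-response
surfaces with a planted Bliss excess, knockdown tables with planted
multiplicative synergy, expression profiles, and a small signed
signaling network whose knockout phenotypes mirror an
AURKB/ZAK/CSF1R/TP53-like motif.

All generators are seed-deterministic and their outputs pass the
corresponding readers' validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from polysynergy.io import ExpressionTable, KdMatrix, SignedNetwork
from polysynergy.simulate import (GrowthParams, ReactionSystem,
                                  calibrate_rates, compile_reactions)
from polysynergy.synergy import DoseResponseMatrix, _four_pl
from polysynergy.timma import binarize_targets, normalize_dss

__all__ = [
    "PlantedScreen", "PlantedSurface", "gen_screen", "gen_surface",
    "gen_network", "gen_knockdown_tables", "gen_expression", "demo_system",
    "consistent_production_rates", "DEMO_EXPRESSION_TARGETS",
]


# ---------------------------------------------------------------------------
# Drug screens with a planted essential-target set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedScreen:
    """A synthetic single-drug screen with known essential targets."""

    kd: KdMatrix
    planted: frozenset[str]
    rule: str
    sigma: float
    seed: int
    y_true: pd.Series        # noise-free rule output per drug
    sensitivity: object      # SensitivityProfile


def gen_screen(n_drugs: int = 41, n_kinases: int = 385, n_essential: int = 3,
               rule: str = "OR", sigma: float = 0.05, seed: int = 0,
               fold: float = 50.0) -> PlantedScreen:
    """Generate a Kd screen whose sensitivity is a Boolean rule over T*.

    Kd values are log-normal with a heavy no-bind mass (each drug binds a
    Poisson-sized handful of kinases); sensitivity is 1 for drugs whose
    binarized profile covers the planted set per ``rule`` (OR: any
    planted target, AND: all, weighted: covered fraction), plus Gaussian
    noise clipped to [0, 1], then rescaled to a DSS-like score.
    """
    if n_essential > n_kinases:
        raise ValueError("more essential targets than kinases")
    if rule not in ("OR", "AND", "weighted"):
        raise ValueError(f"unknown rule: {rule!r}")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_kinases)))
    kinases = [f"K{i + 1:0{width}d}" for i in range(n_kinases)]
    drugs = [f"D{i + 1:03d}" for i in range(n_drugs)]

    grid = np.full((n_drugs, n_kinases), np.nan)
    for i in range(n_drugs):
        m = int(min(1 + rng.poisson(4), n_kinases))
        cols = rng.choice(n_kinases, size=m, replace=False)
        grid[i, cols] = rng.lognormal(mean=np.log(50.0), sigma=1.2, size=m)
    kd = KdMatrix(pd.DataFrame(grid, index=drugs, columns=kinases))

    # plant essential targets among kinases the panel can interrogate
    # (bound by at least a few drugs); with a sparse 385-kinase panel a
    # uniformly chosen kinase is usually hit by no drug at all
    coverage = np.isfinite(grid).sum(axis=0)
    pool = np.flatnonzero(coverage >= 3)
    if len(pool) < n_essential:
        pool = np.argsort(-coverage, kind="stable")[:max(n_essential, 3)]
    planted = frozenset(
        kinases[int(j)]
        for j in rng.choice(pool, size=n_essential, replace=False))

    profiles = binarize_targets(kd, fold=fold)
    coverage = np.array([len(profiles[d].targets & planted) for d in drugs])
    hit_any, hit_all = coverage > 0, coverage == n_essential
    # keep the screen informative: force at least one hit and one miss
    if not hit_any.any() or hit_any.all():
        if not hit_any.any():
            grid[0, kinases.index(sorted(planted)[0])] = 10.0
        else:
            grid[1, [kinases.index(k) for k in sorted(planted)]] = np.nan
            if not np.isfinite(grid[1]).any():
                spare = next((j for j, k in enumerate(kinases)
                              if k not in planted), None)
                if spare is None:
                    raise ValueError("cannot plant a missing drug: every "
                                     "kinase is an essential target")
                grid[1, spare] = 50.0
        kd = KdMatrix(pd.DataFrame(grid, index=drugs, columns=kinases))
        profiles = binarize_targets(kd, fold=fold)
        coverage = np.array([len(profiles[d].targets & planted) for d in drugs])
        hit_any, hit_all = coverage > 0, coverage == n_essential

    if rule == "OR":
        y0 = hit_any.astype(float)
    elif rule == "AND":
        y0 = hit_all.astype(float)
    else:
        y0 = coverage / n_essential
    y = np.clip(y0 + rng.normal(0.0, sigma, size=n_drugs) if sigma > 0 else y0,
                0.0, 1.0)
    dss_raw = pd.Series(y * 30.0, index=drugs, name="dss_raw")
    sens = normalize_dss(dss_raw)
    return PlantedScreen(kd=kd, planted=planted, rule=rule, sigma=sigma,
                         seed=seed, y_true=pd.Series(y0, index=drugs),
                         sensitivity=sens)


# ---------------------------------------------------------------------------
# Dose-response surfaces with a planted Bliss excess
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSurface:
    """Synthetic combination matrix: Bliss expectation + planted excess."""

    matrix: DoseResponseMatrix
    params1: tuple[float, float, float, float]  # (L, U, slope, EC50 nM)
    params2: tuple[float, float, float, float]
    delta: float  # planted uniform excess, percentage points
    sigma: float
    seed: int


def gen_surface(params1: tuple = (0.0, 100.0, 1.0, 100.0),
                params2: tuple = (0.0, 100.0, 1.2, 300.0),
                delta: float = 0.0, sigma: float = 0.0, n: int = 8,
                seed: int = 0, drug1: str = "drugA",
                drug2: str = "drugB") -> PlantedSurface:
    """An n x n grid: 0 plus n-1 log-spaced doses from 10 to 10000 nM.

    Margins follow exact 4PL curves; combination cells are the Bliss
    independence expectation plus ``delta`` percentage points plus
    Gaussian noise of ``sigma`` points on every treated cell.
    """
    rng = np.random.default_rng(seed)
    doses = np.concatenate([[0.0], np.geomspace(10.0, 10000.0, n - 1)])
    y1 = np.concatenate([[0.0], _four_pl(doses[1:], *params1)])
    y2 = np.concatenate([[0.0], _four_pl(doses[1:], *params2)])
    f1, f2 = y1 / 100.0, y2 / 100.0
    grid = np.zeros((n, n))
    grid[:, 0] = y1
    grid[0, :] = y2
    bliss = f1[1:, None] + f2[None, 1:] - np.outer(f1[1:], f2[1:])
    grid[1:, 1:] = 100.0 * bliss + delta
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=(n, n))
        noise[0, 0] = 0.0
        grid = grid + noise
    m = DoseResponseMatrix(drug1=drug1, drug2=drug2, conc1=doses, conc2=doses,
                           inhibition=grid)
    return PlantedSurface(matrix=m, params1=tuple(params1),
                          params2=tuple(params2), delta=delta, sigma=sigma,
                          seed=seed)


# ---------------------------------------------------------------------------
# Knockdown tables and expression profiles
# ---------------------------------------------------------------------------

def gen_knockdown_tables(genes: list[str], delta: float = 0.0,
                         sigma: float = 0.0, seed: int = 0):
    """Single and double knockdown % inhibition (as fractions).

    Doubles follow the multiplicative null y_ij = y_i * y_j plus the
    planted excess ``delta`` (fractional) and noise, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    singles = {g: float(rng.uniform(0.2, 0.7)) for g in genes}
    doubles = {}
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            i, j = genes[a], genes[b]
            y = singles[i] * singles[j] + delta
            if sigma > 0:
                y += rng.normal(0.0, sigma)
            doubles[(i, j)] = float(np.clip(y, 0.0, 1.0))
    return singles, doubles


def gen_expression(genes: list[str], seed: int = 0, mean_log2: float = 7.0,
                   sd_log2: float = 2.0) -> ExpressionTable:
    """Log2 expression ~ Normal(mean, sd) with matching RPKM values."""
    rng = np.random.default_rng(seed)
    log2 = pd.Series(rng.normal(mean_log2, sd_log2, size=len(genes)),
                     index=genes, name="log2_expression")
    rpkm = (2.0 ** (log2 - 5.0)).rename("rpkm")
    return ExpressionTable(log2, rpkm)


# ---------------------------------------------------------------------------
# Signaling networks
# ---------------------------------------------------------------------------

# Demo motif: AURKB and p38 (MAPK14, fed by ZAK via MAP2K3) both deplete
# TP53; CSF1R supports TP53 production through a TGF-beta-like branch.
# Silencing AURKB de-represses TP53 (growth brake engages); silencing
# ZAK removes the second brake-release so the double knockout drives
# TP53 far past the Hill threshold; silencing CSF1R starves TP53 of
# production and rescues growth.  PKN1/PARP1 are unconnected bystanders.
_DEMO_EDGES = (
    ("AURKB", "TP53", "inhibition"),
    ("MAPK14", "TP53", "inhibition"),
    ("MAP2K3", "MAPK14", "activation"),
    ("ZAK", "MAP2K3", "activation"),
    ("CSF1R", "TGFB1", "activation"),
    ("TGFB1", "TP53", "activation"),
)

DEMO_EXPRESSION_TARGETS = {
    "AURKB": 60.0, "ZAK": 50.0, "CSF1R": 40.0, "MAP2K3": 45.0,
    "MAPK14": 40.0, "TGFB1": 35.0, "TP53": 30.0, "PKN1": 50.0, "PARP1": 45.0,
}

_DEMO_KD = {
    "AURKB": 0.08, "ZAK": 0.06, "CSF1R": 0.08, "MAP2K3": 0.06,
    "MAPK14": 0.6, "TGFB1": 0.05, "TP53": 0.0008, "PKN1": 0.1, "PARP1": 0.1,
}


def gen_network(motif: str = "aurkb_zak_csf1r_demo", n_genes: int = 10,
                seed: int = 0):
    """A signed network plus per-gene expression targets.

    ``aurkb_zak_csf1r_demo`` returns the fixed, documented demo motif;
    ``random`` samples an acyclic signed network with in-degree <= 2.
    """
    if motif == "aurkb_zak_csf1r_demo":
        return SignedNetwork(_DEMO_EDGES), dict(DEMO_EXPRESSION_TARGETS)
    if motif == "random":
        rng = np.random.default_rng(seed)
        genes = [f"G{i + 1:02d}" for i in range(n_genes)]
        edges = []
        for i in range(1, n_genes):
            for parent in rng.choice(i, size=min(int(rng.integers(0, 3)), i),
                                     replace=False):
                sign = "activation" if rng.random() < 0.7 else "inhibition"
                edges.append((genes[parent], genes[i], sign))
        if not edges:
            edges.append((genes[0], genes[-1], "activation"))
        targets = {g: float(rng.integers(20, 81)) for g in genes}
        return SignedNetwork(tuple(edges)), targets
    raise ValueError(f"unknown motif: {motif!r}")


def consistent_production_rates(net: SignedNetwork, targets: dict,
                                k_d: dict) -> dict:
    """Production rates that make the target vector an exact steady state.

    Solved in reverse topological order of the activation edges (the
    consumption of a source gene by an activation depends on the target
    gene's production rate); requires an acyclic activation structure.
    """
    genes = list(targets)
    activators = {g: [s for s, t, sg in net.edges
                      if t == g and sg == "activation" and s in targets]
                  for g in genes}
    out_act = {g: [t for s, t, sg in net.edges
                   if s == g and sg == "activation" and t in targets]
               for g in genes}
    inhibits = {g: [t for s, t, sg in net.edges
                    if s == g and sg == "inhibition" and t in targets]
                for g in genes}
    inhibited_by = {g: [s for s, t, sg in net.edges
                        if t == g and sg == "inhibition" and s in targets]
                    for g in genes}

    k_p: dict[str, float] = {}
    remaining = set(genes)
    while remaining:
        ready = [g for g in remaining if all(t in k_p for t in out_act[g])]
        if not ready:
            raise ValueError("activation edges form a cycle; no closed form")
        for g in sorted(ready):
            x = targets[g]
            loss = k_d[g] * x
            loss += sum(k_d[c] * x * targets[c] for c in inhibits[g])
            loss += sum(k_d[g] * targets[b] * x for b in inhibited_by[g])
            loss += sum(k_p[t] * x for t in out_act[g])
            drive = sum(targets[s] for s in activators[g])
            k_p[g] = loss / drive if drive > 0 else loss
            remaining.discard(g)
    return k_p


def demo_system(growth: GrowthParams | None = None,
                catalytic: bool = False) -> ReactionSystem:
    """The calibrated demo signaling system, ready to simulate.

    Rates are derived in closed form so the documented expression targets
    are an exact ODE steady state, then verified by the calibration loop.
    """
    net, targets = gen_network("aurkb_zak_csf1r_demo")
    k_p = consistent_production_rates(net, targets, _DEMO_KD)
    sys = compile_reactions(net, targets.keys(), k_p=k_p, k_d=_DEMO_KD,
                            catalytic=catalytic, source_genes="roots",
                            growth=growth)
    return calibrate_rates(sys, targets, tol=0.05)
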