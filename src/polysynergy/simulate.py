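"""Stochastic simulation of a signed signaling network in dividing cells.

A signed network is compiled into mass-action reactions: an activation
edge A -> B becomes the source-consuming conversion ``A -> B`` at rate
k_p(B) (catalytic variant ``A -> A + B`` behind a flag), an inhibition
edge B -| C becomes ``B + C -> 0`` at rate k_d(C), and every gene
self-degrades ``A -> 0`` at rate k_d(A).  Genes without activating inputs
can be given a constant zeroth-order source at rate k_p(A) so the system
has a nontrivial steady state.

Cell growth is a birth reaction for a dedicated pGrowth species with
propensity ``pGrowth * (ln 2 / t_div) * f(TP53)``, where the decreasing
Hill factor ``f(x) = 1 / (1 + (x/Q)^beta)`` (Q = 65 molecules, beta = 7)
throttles growth when TP53 accumulates.  A cell divides instantly when
pGrowth reaches a threshold (2x its birth value), partitioning every
molecule count binomially between two daughters.  Viability of a
perturbation is the mean cell count over the last hours of simulation,
normalized to unperturbed control runs with paired seeds.

A deterministic ODE twin of the same reaction set provides steady states
for rate calibration and scaled parameter-sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from polysynergy.io import SignedNetwork

logger = logging.getLogger(__name__)

HUB_GENES = ("AURKB", "ZAK", "CSF1R", "TP53")

__all__ = [
    "GrowthParams", "Reaction", "ReactionSystem", "CellPopulationState",
    "SimulationResult", "KnockoutResult", "hill_growth_factor",
    "select_network_genes", "compile_reactions", "calibrate_rates",
    "ode_twin", "ssa_simulate", "knockout_experiment", "silence",
    "parameter_sensitivity",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Cell growth / division parameters.

    t_div: doubling time in hours (MDA-MB-231-like default 38 h);
    Q, beta: Hill threshold (molecules) and exponent of the TP53 brake;
    pgrowth0: pGrowth molecules at birth; theta: division threshold
    (default 2 * pgrowth0 -> doubling criterion).
    """

    t_div: float = 38.0
    Q: float = 65.0
    beta: float = 7.0
    pgrowth0: int = 100
    theta: int | None = None

    @property
    def division_threshold(self) -> int:
        return self.theta if self.theta is not None else 2 * self.pgrowth0


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction over species indices (stoichiometry 1).

    ``param`` names the owning rate parameter ('k_p' or 'k_d', gene);
    the effective rate is that parameter times ``scale`` (used for
    knock-downs).
    """

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    param: tuple[str, str]
    kind: str  # source | activation | inhibition | degradation
    scale: float = 1.0


def hill_growth_factor(x: float, Q: float = 65.0, beta: float = 7.0) -> float:
    """Decreasing Hill brake on growth: f(0)=1, f(Q)=0.5, f->0 as x->inf."""
    return 1.0 / (1.0 + (x / Q) ** beta)


@dataclass
class ReactionSystem:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    k_p: dict[str, float]
    k_d: dict[str, float]
    growth: GrowthParams = field(default_factory=GrowthParams)
    tp53: str | None = None
    initial_counts: dict[str, int] | None = None
    calibration_errors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.tp53 is None and "TP53" in self.species:
            self.tp53 = "TP53"
        for g in self.species:
            if self.k_p.get(g, 0) <= 0 or self.k_d.get(g, 0) <= 0:
                raise ValueError(f"non-positive rate parameter for {g}")
        deg = [r for r in self.reactions if r.kind == "degradation"]
        if len(deg) != len(self.species):
            raise ValueError("every gene needs exactly one self-degradation")

    def rate(self, r: Reaction) -> float:
        kind, gene = r.param
        base = self.k_p[gene] if kind == "k_p" else self.k_d[gene]
        return base * r.scale

    def index(self, gene: str) -> int:
        return self.species.index(gene)

    def with_rates(self, k_p: Mapping[str, float] | None = None,
                   k_d: Mapping[str, float] | None = None) -> "ReactionSystem":
        return replace(self, k_p=dict(k_p or self.k_p), k_d=dict(k_d or self.k_d))


@dataclass
class CellPopulationState:
    """Per-cell species counts plus the growth variable."""

    counts: list[np.ndarray]
    pgrowth: list[int]
    time: float = 0.0

    def __post_init__(self) -> None:
        for x in self.counts:
            if np.any(np.asarray(x) < 0):
                raise ValueError("negative molecule count")


@dataclass
class SimulationResult:
    times: np.ndarray
    cell_count: np.ndarray
    mean_expression: pd.DataFrame
    viability: float
    n_divisions: int
    cap_hits: int
    seed: int
    divisions: list | None = None


@dataclass
class KnockoutResult:
    genes: tuple[str, ...]
    mode: str
    viability_ratio: float
    perturbed: list[float]
    control: list[float]

    @property
    def standard_error(self) -> float:
        p = np.asarray(self.perturbed, float)
        c = np.asarray(self.control, float)
        ratios = p / np.mean(c)
        return float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))


# ---------------------------------------------------------------------------
# Network-gene selection (differential expression)
# ---------------------------------------------------------------------------

def select_network_genes(expr_self: Mapping[str, float],
                         expr_panel_mean: Mapping[str, float],
                         threshold: float = 1.0) -> pd.DataFrame:
    """Normalized deviation D = |x_self - mean| / mean; include iff D > threshold."""
    rows = []
    for gene, mean in expr_panel_mean.items():
        if mean <= 0:
            raise ValueError(f"non-positive panel mean for {gene}")
        if gene not in expr_self:
            continue
        d = abs(expr_self[gene] - mean) / mean
        rows.append({"gene": gene, "D": d, "included": bool(d > threshold)})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def compile_reactions(net: SignedNetwork, genes: Iterable[str],
                      k_p: Mapping[str, float] | None = None,
                      k_d: Mapping[str, float] | None = None,
                      hub_genes: Sequence[str] = HUB_GENES,
                      catalytic: bool = False,
                      source_genes: str | Iterable[str] | None = "roots",
                      growth: GrowthParams | None = None) -> ReactionSystem:
    """Compile signed edges into a mass-action reaction system.

    Edges touching genes outside the kept set (selected genes plus any
    hub genes present in the network) are dropped with a warning.
    ``source_genes='roots'`` gives every gene without an incoming
    activation edge a constant source; pass an iterable for explicit
    control or None for no sources (edge + degradation reactions only).
    """
    keep = set(genes) | (set(hub_genes) & set(net.genes))
    species = tuple(sorted(keep))
    idx = {g: i for i, g in enumerate(species)}
    k_p = {g: float((k_p or {}).get(g, 1.0)) for g in species}
    k_d = {g: float((k_d or {}).get(g, 0.1)) for g in species}

    reactions: list[Reaction] = []
    activated: set[str] = set()
    for src, dst, sign in net.edges:
        if src not in keep or dst not in keep:
            logger.warning("compile_reactions: dropping edge %s-%s (unselected gene)",
                           src, dst)
            continue
        if sign == "activation":
            products = (idx[src], idx[dst]) if catalytic else (idx[dst],)
            reactions.append(Reaction(reactants=(idx[src],), products=products,
                                      param=("k_p", dst), kind="activation"))
            activated.add(dst)
        else:  # inhibition B -| C : B + C -> 0
            reactions.append(Reaction(reactants=(idx[src], idx[dst]), products=(),
                                      param=("k_d", dst), kind="inhibition"))

    if source_genes == "roots":
        sources = [g for g in species if g not in activated]
    elif source_genes is None:
        sources = []
    else:
        sources = sorted(set(source_genes) & keep)
    for g in sources:
        reactions.append(Reaction(reactants=(), products=(idx[g],),
                                  param=("k_p", g), kind="source"))
    for g in species:
        reactions.append(Reaction(reactants=(idx[g],), products=(),
                                  param=("k_d", g), kind="degradation"))

    return ReactionSystem(species=species, reactions=tuple(reactions),
                          k_p=k_p, k_d=k_d,
                          growth=growth or GrowthParams())


# ---------------------------------------------------------------------------
# ODE twin
# ---------------------------------------------------------------------------

def _rhs_factory(sys: ReactionSystem):
    terms = []
    for r in sys.reactions:
        delta: dict[int, int] = {}
        for s in r.reactants:
            delta[s] = delta.get(s, 0) - 1
        for s in r.products:
            delta[s] = delta.get(s, 0) + 1
        terms.append((sys.rate(r), r.reactants, tuple(delta.items())))

    n = len(sys.species)

    def rhs(_t, x):
        dx = np.zeros(n)
        for k, reactants, delta in terms:
            flux = k
            for s in reactants:
                flux *= x[s]
            for s, d in delta:
                dx[s] += d * flux
        return dx

    return rhs


def ode_twin(sys: ReactionSystem, x0: Mapping[str, float] | None = None,
             t_max: float = 20000.0, ss_tol: float = 1e-7) -> pd.Series:
    """Deterministic steady state of the same reaction set.

    Integrates the mass-action rate equations until the relative rate of
    change is negligible, then polishes with a root find.  Growth/division
    is excluded: cell counts enter the twin only through the analytic
    growth factor.  Raises if no steady state is found within ``t_max``.
    """
    rhs = _rhs_factory(sys)
    n = len(sys.species)
    if x0 is None:
        x = np.full(n, 10.0)
        if sys.initial_counts:
            x = np.array([float(sys.initial_counts.get(g, 10.0))
                          for g in sys.species])
    else:
        x = np.array([float(x0.get(g, 0.0)) for g in sys.species])

    t, chunk = 0.0, 500.0
    while t < t_max:
        sol = solve_ivp(rhs, (0.0, chunk), x, method="LSODA",
                        rtol=1e-9, atol=1e-9)
        x = np.maximum(sol.y[:, -1], 0.0)
        t += chunk
        scale = np.maximum(np.abs(x), 1.0)
        if np.max(np.abs(rhs(0.0, x)) / scale) < ss_tol:
            break
    else:
        raise RuntimeError(
            "no steady state within horizon; final state: "
            + ", ".join(f"{g}={v:.3g}" for g, v in zip(sys.species, x)))

    polish = root(lambda v: rhs(0.0, v), x, method="hybr")
    if polish.success and np.all(polish.x > -1e-6):
        x = np.maximum(polish.x, 0.0)
    return pd.Series(x, index=list(sys.species), name="steady_state")


def calibrate_rates(sys: ReactionSystem, targets: Mapping[str, float],
                    tol: float = 0.05, max_iter: int = 60) -> ReactionSystem:
    """Rescale per-gene degradation rates until the ODE steady state hits
    the target expression counts within ``tol`` relative error.

    Automates manual tuning of the degradation/production ratio.  Raises
    on non-convergence, naming the offending genes.
    """
    for g in sys.species:
        if targets.get(g, 0) <= 0:
            raise ValueError(f"missing or non-positive target for {g}")
    cur = sys
    tgt = np.array([float(targets[g]) for g in sys.species])
    ss = None
    for _ in range(max_iter):
        ss = ode_twin(cur, x0=dict(zip(cur.species, tgt)))
        rel = np.abs(ss.to_numpy() - tgt) / tgt
        if np.max(rel) <= tol:
            errors = dict(zip(cur.species, rel))
            return replace(cur,
                           initial_counts={g: int(round(targets[g]))
                                           for g in cur.species},
                           calibration_errors=errors)
        k_d = dict(cur.k_d)
        for g, x_g, t_g in zip(cur.species, ss.to_numpy(), tgt):
            factor = float(np.clip((max(x_g, 1e-12) / t_g) ** 0.8, 0.2, 5.0))
            k_d[g] = k_d[g] * factor
        cur = cur.with_rates(k_d=k_d)
    rel = np.abs(ss.to_numpy() - tgt) / tgt
    bad = [g for g, r in zip(cur.species, rel) if r > tol]
    raise RuntimeError(f"calibration did not converge for: {bad}")


# ---------------------------------------------------------------------------
# Stochastic simulation with growth and division
# ---------------------------------------------------------------------------

def ssa_simulate(sys: ReactionSystem,
                 initial: Mapping[str, int] | CellPopulationState | None = None,
                 t_end: float = 250.0, *,
                 population_cap: int = 2000,
                 seed: int = 0,
                 record_dt: float = 1.0,
                 window: float = 50.0,
                 record_divisions: bool = False) -> SimulationResult:
    """Exact Gillespie simulation of a growing, dividing cell population.

    Each cell runs all compiled reactions plus the pGrowth birth reaction
    with propensity ``pGrowth * (ln2 / t_div) * f(TP53)``; on reaching the
    division threshold every species (pGrowth included) is split
    Binomial(n, 1/2) between two daughters.  Beyond ``population_cap``
    tracked cells, divisions keep one daughter at doubled statistical
    weight (uniform subsampling); the weighted cell count is unbiased and
    the cap events are reported.  Setting ``growth.pgrowth0 = 0`` (or an
    initial state with zero pGrowth) disables growth.  Bitwise
    reproducible for a fixed seed; divisions pre-empt simultaneous
    reactions by construction (they fire the instant the threshold is
    crossed).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    species = sys.species
    n_s = len(species)

    if isinstance(initial, CellPopulationState):
        start_counts = [list(map(int, x)) for x in initial.counts]
        start_pg = list(initial.pgrowth)
    else:
        base = initial if initial is not None else (sys.initial_counts or {})
        start_counts = [[int(round(base.get(g, 0))) for g in species]]
        start_pg = [sys.growth.pgrowth0]
    if not start_counts:
        raise ValueError("need at least one cell")

    # flatten reactions for the hot loop
    rxn = list(sys.reactions)
    n_r = len(rxn)
    r1 = [r.reactants[0] if len(r.reactants) > 0 else -1 for r in rxn]
    r2 = [r.reactants[1] if len(r.reactants) > 1 else -1 for r in rxn]
    rates = [sys.rate(r) for r in rxn]
    deltas: list[list[tuple[int, int]]] = []
    for r in rxn:
        d: dict[int, int] = {}
        for s in r.reactants:
            d[s] = d.get(s, 0) - 1
        for s in r.products:
            d[s] = d.get(s, 0) + 1
        deltas.append(sorted(d.items()))
    # reaction indices whose propensity depends on each species
    dep: list[list[int]] = [[] for _ in range(n_s)]
    for i in range(n_r):
        if r1[i] >= 0:
            dep[r1[i]].append(i)
        if r2[i] >= 0 and r2[i] != r1[i]:
            dep[r2[i]].append(i)

    g = sys.growth
    theta = g.division_threshold
    growth_rate = math.log(2.0) / g.t_div if math.isfinite(g.t_div) else 0.0
    i_tp53 = species.index(sys.tp53) if sys.tp53 in species else -1
    Q, beta = g.Q, g.beta

    rng = random.Random(seed)
    nprng = np.random.default_rng((seed + 1) & 0x7FFFFFFF)

    times = np.arange(0.0, t_end + record_dt / 2, record_dt)
    n_g = len(times)
    expr_sum = np.zeros((n_g, n_s))
    wsum = np.zeros(n_g)
    birth_delta = np.zeros(n_g)
    end_delta = np.zeros(n_g)
    division_times: list[float] = []
    division_records: list | None = [] if record_divisions else None
    cap_hits = 0
    tracked = len(start_counts)

    # stack of (birth_time, counts, pgrowth, weight)
    stack = [(0.0, list(c), pg, 1.0) for c, pg in zip(start_counts, start_pg)]

    while stack:
        t0, x, pg, w = stack.pop()
        birth_delta[np.searchsorted(times, t0 - 1e-12)] += w
        gi = int(np.searchsorted(times, t0 - 1e-12))
        t = t0

        a = [0.0] * n_r
        for i in range(n_r):
            v = rates[i]
            if r1[i] >= 0:
                v *= x[r1[i]]
            if r2[i] >= 0:
                v *= x[r2[i]]
            a[i] = v
        a_sum = sum(a)
        ag = 0.0
        if growth_rate > 0.0 and pg > 0:
            f = 1.0 if i_tp53 < 0 else 1.0 / (1.0 + (x[i_tp53] / Q) ** beta)
            ag = growth_rate * pg * f
        steps = 0
        divided_at = None

        while True:
            a0 = a_sum + ag
            t_event = t + (rng.expovariate(a0) if a0 > 1e-300 else float("inf"))
            # a cell surviving past t_end is recorded at every remaining
            # grid point (the grid never extends beyond t_end)
            lim = t_event if t_event < t_end else float("inf")
            while gi < n_g and times[gi] < lim:
                row = expr_sum[gi]
                for s in range(n_s):
                    row[s] += w * x[s]
                wsum[gi] += w
                gi += 1
            if t_event >= t_end:
                break
            t = t_event
            u = rng.random() * a0
            if u >= a_sum:  # growth event
                pg += 1
                if pg >= theta:
                    divided_at = t
                    break
                if i_tp53 >= 0:
                    f = 1.0 / (1.0 + (x[i_tp53] / Q) ** beta)
                else:
                    f = 1.0
                new_ag = growth_rate * pg * f
                ag = new_ag
            else:
                i = 0
                acc = a[0]
                while acc < u and i < n_r - 1:
                    i += 1
                    acc += a[i]
                changed = deltas[i]
                for s, d in changed:
                    x[s] += d
                for s, _ in changed:
                    for j in dep[s]:
                        v = rates[j]
                        if r1[j] >= 0:
                            v *= x[r1[j]]
                        if r2[j] >= 0:
                            v *= x[r2[j]]
                        a_sum += v - a[j]
                        a[j] = v
                    if s == i_tp53 and growth_rate > 0.0 and pg > 0:
                        ag = growth_rate * pg / (1.0 + (x[i_tp53] / Q) ** beta)
            steps += 1
            if (steps & 0xFFF) == 0:  # guard against float drift
                a_sum = 0.0
                for i in range(n_r):
                    v = rates[i]
                    if r1[i] >= 0:
                        v *= x[r1[i]]
                    if r2[i] >= 0:
                        v *= x[r2[i]]
                    a[i] = v
                    a_sum += v

        if divided_at is None:
            continue  # survived to t_end; no end event (alive at the horizon)

        t = divided_at
        end_delta[np.searchsorted(times, t - 1e-12)] += w
        division_times.append(t)
        xa = np.asarray(x, dtype=np.int64)
        d1 = nprng.binomial(xa, 0.5)
        d2 = xa - d1
        pg1 = int(nprng.binomial(pg, 0.5))
        pg2 = pg - pg1
        if division_records is not None:
            division_records.append((t, xa.tolist() + [pg],
                                     d1.tolist() + [pg1], d2.tolist() + [pg2]))
        if tracked < population_cap:
            stack.append((t, d1.tolist(), pg1, w))
            stack.append((t, d2.tolist(), pg2, w))
            tracked += 1
        else:
            # subsample: one daughter carries both lineages' weight
            cap_hits += 1
            keep = (d1.tolist(), pg1) if nprng.integers(2) == 0 else (d2.tolist(), pg2)
            stack.append((t, keep[0], keep[1], 2.0 * w))

    # every pushed cell added +w to birth_delta when popped and -w to
    # end_delta if it divided, so the cumulative sum is the weighted count
    # of cells alive at each grid time.
    cell_count = np.cumsum(birth_delta - end_delta)
    mean_expr = pd.DataFrame(
        np.where(wsum[:, None] > 0, expr_sum / np.maximum(wsum, 1e-300)[:, None],
                 np.nan),
        index=pd.Index(times, name="time_h"), columns=list(species))
    in_window = times >= (t_end - window)
    viability = float(np.mean(cell_count[in_window]))
    return SimulationResult(times=times, cell_count=cell_count,
                            mean_expression=mean_expr, viability=viability,
                            n_divisions=len(division_times), cap_hits=cap_hits,
                            seed=seed, divisions=division_records)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def silence(sys: ReactionSystem, genes: Iterable[str], mode: str = "knockout",
            eff: float = 0.8) -> ReactionSystem:
    """Structurally remove (knockout) or scale down (knockdown) production.

    Knockout drops every source/activation reaction producing the gene;
    knockdown multiplies their rates by (1 - eff).
    """
    genes = set(genes)
    missing = genes - set(sys.species)
    if missing:
        raise KeyError(f"genes not in system: {sorted(missing)}")
    if mode not in ("knockout", "knockdown"):
        raise ValueError("mode must be 'knockout' or 'knockdown'")
    new: list[Reaction] = []
    for r in sys.reactions:
        net: dict[str, int] = {}
        for s in r.products:
            net[sys.species[s]] = net.get(sys.species[s], 0) + 1
        for s in r.reactants:
            net[sys.species[s]] = net.get(sys.species[s], 0) - 1
        produces = {g for g, d in net.items() if d > 0} & genes
        if r.kind in ("source", "activation") and produces:
            if mode == "knockout":
                continue
            new.append(replace(r, scale=r.scale * (1.0 - eff)))
        else:
            new.append(r)
    init = dict(sys.initial_counts or {})
    if mode == "knockout":
        for gname in genes:
            init[gname] = 0
    return replace(sys, reactions=tuple(new), initial_counts=init or None)


def knockout_experiment(sys: ReactionSystem, genes_to_silence: Iterable[str],
                        mode: str = "knockout", eff: float = 0.8,
                        n_runs: int = 10, t_end: float = 250.0,
                        window: float = 50.0, seed: int = 0,
                        population_cap: int = 2000,
                        control_viabilities: Sequence[float] | None = None
                        ) -> KnockoutResult:
    """Normalized viability of a gene silencing versus paired controls.

    Runs ``n_runs`` perturbed and control simulations with paired seeds
    and returns mean(perturbed viability) / mean(control viability).
    Pass precomputed ``control_viabilities`` to share controls across
    perturbations.
    """
    genes = tuple(sorted(set(genes_to_silence)))
    pert = silence(sys, genes, mode=mode, eff=eff)
    perturbed, control = [], []
    for i in range(n_runs):
        run_seed = (seed + 7919 * i) & 0x7FFFFFFF
        perturbed.append(ssa_simulate(pert, t_end=t_end, window=window,
                                      seed=run_seed,
                                      population_cap=population_cap).viability)
        if control_viabilities is None:
            control.append(ssa_simulate(sys, t_end=t_end, window=window,
                                        seed=run_seed,
                                        population_cap=population_cap).viability)
    if control_viabilities is not None:
        control = list(control_viabilities)
    ratio = float(np.mean(perturbed) / np.mean(control))
    return KnockoutResult(genes=genes, mode=mode, viability_ratio=ratio,
                          perturbed=perturbed, control=control)


# ---------------------------------------------------------------------------
# Parameter sensitivity
# ---------------------------------------------------------------------------

def parameter_sensitivity(sys: ReactionSystem,
                          perturbation: float = 0.01) -> pd.DataFrame:
    """Scaled steady-state sensitivities by central finite differences.

    For every rate parameter p, S(i, p) = (p / X_i) dX_i/dp at the ODE
    steady state; the report ranks parameters by the mean |S| over genes.
    Parameters whose perturbed steady state cannot be found are marked
    undefined (NaN).
    """
    base = ode_twin(sys)
    x_base = base.to_numpy()
    ok = x_base > 1e-9
    rows = []
    for kind in ("k_p", "k_d"):
        params = sys.k_p if kind == "k_p" else sys.k_d
        for gene in sys.species:
            if not any(r.param == (kind, gene) for r in sys.reactions):
                continue
            p0 = params[gene]
            ss = {}
            try:
                for sgn in (+1, -1):
                    mod = dict(params)
                    mod[gene] = p0 * (1.0 + sgn * perturbation)
                    pert = sys.with_rates(k_p=mod if kind == "k_p" else None,
                                          k_d=mod if kind == "k_d" else None)
                    ss[sgn] = ode_twin(pert, x0=dict(base)).to_numpy()
                s = (ss[+1] - ss[-1]) / (2.0 * perturbation * np.where(ok, x_base, np.nan))
                mean_abs = float(np.nanmean(np.abs(s[ok])))
                per_gene = dict(zip(sys.species, s))
            except RuntimeError:
                mean_abs = float("nan")
                per_gene = {g: float("nan") for g in sys.species}
            rows.append({"parameter": f"{kind}({gene})", "kind": kind,
                         "gene": gene, "mean_abs_sensitivity": mean_abs,
                         **{f"S_{g}": per_gene[g] for g in sys.species}})
    df = pd.DataFrame(rows).sort_values("mean_abs_sensitivity",
                                        ascending=False, ignore_index=True)
    return df
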