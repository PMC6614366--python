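"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` drives generate -> predict -> score -> deconvolve ->
simulate over either user-supplied flat files or the bundled synthetic
generators, writing each stage's products plus a reproducibility
manifest (config hash, seeds, package version, per-output checksums).
Re-running the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import mannwhitneyu

from polysynergy import io, synthetic
from polysynergy.deconvolution import pair_catalog
from polysynergy.simulate import knockout_experiment, ode_twin, ssa_simulate
from polysynergy.synergy import bliss_score, hsa_score
from polysynergy.timma import (binarize_targets, build_combination_network,
                               predict_combination, select_essential_targets)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "compare_groups"]


@dataclass
class PipelineConfig:
    """All thresholds and knobs as data, so printed cutoffs are config.

    ``fold_timma`` (inclusive 50-fold rule) binarizes target profiles for
    model fitting, ``fold_deconv`` (strict 10-fold rule) picks potent
    targets for deconvolution, ``expr_min_log2`` drops non-expressed
    genes, ``d_threshold`` selects differentially expressed network genes.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "generate": True, "timma": True, "synergy": True,
        "deconvolve": True, "simulate": True})
    fold_timma: float = 50.0
    fold_deconv: float = 10.0
    expr_min_log2: float = 6.0
    d_threshold: float = 1.0
    max_targets: int = 8
    n_drugs: int = 20
    n_kinases: int = 30
    n_essential: int = 3
    screen_sigma: float = 0.05
    n_surfaces: int = 6
    sim_runs: int = 3
    sim_t_end: float = 120.0
    sim_window: float = 50.0
    sim_cap: int = 400

    def __post_init__(self) -> None:
        for name in ("fold_timma", "fold_deconv", "d_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def compare_groups(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two labeled samples."""
    a = np.asarray(list(scores_a), float)
    b = np.asarray(list(scores_b), float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all observations tied; p = 1")
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(obj, rel: str) -> Path:
        p = io.write_results(obj, out / rel)
        written.append(p)
        return p

    screen = surfaces = None
    if cfg.stages.get("generate", True):
        screen = synthetic.gen_screen(n_drugs=cfg.n_drugs,
                                      n_kinases=cfg.n_kinases,
                                      n_essential=cfg.n_essential,
                                      sigma=cfg.screen_sigma, seed=cfg.seed)
        save(screen.kd, "inputs/kd.csv")
        save(screen.sensitivity, "inputs/dss.csv")
        surfaces = []
        for i in range(cfg.n_surfaces):
            delta = [5.0, 2.0, 0.0, 0.0, -3.0, 8.0][i % 6]
            s = synthetic.gen_surface(delta=delta, sigma=3.0,
                                      seed=cfg.seed + 100 + i,
                                      drug1=f"D{2 * i + 1:03d}",
                                      drug2=f"D{2 * i + 2:03d}")
            save(s.matrix, f"inputs/surface_{i}.csv")
            surfaces.append(s)
        expr = synthetic.gen_expression(screen.kd.kinases, seed=cfg.seed + 1)
        save(expr, "inputs/expression.csv")
        net, targets = synthetic.gen_network("aurkb_zak_csf1r_demo")
        save(net, "inputs/network.sif")
        save({"expression_targets": targets}, "inputs/network_targets.json")

    model = None
    if cfg.stages.get("timma", True) and screen is not None:
        profiles = {d: p.targets for d, p in
                    binarize_targets(screen.kd, fold=cfg.fold_timma).items()}
        sens = dict(zip(screen.sensitivity.drugs,
                        screen.sensitivity.y.to_numpy()))
        model = select_essential_targets(profiles, sens,
                                         max_size=cfg.max_targets,
                                         seed=cfg.seed)
        save(model, "timma/model.json")
        drugs = model.drugs
        rows = []
        for i, d1 in enumerate(drugs):
            for d2 in drugs[i + 1:]:
                p = predict_combination(model, d1, d2)
                rows.append({"drug1": d1, "drug2": d2,
                             "y_combination": p.y_combination,
                             "synergy": p.synergy})
        scores = pd.DataFrame(rows)
        path = out / "timma/predicted_combinations.csv"
        scores.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        net = build_combination_network(model)
        save({"nodes": {n: {"members": sorted(net.members_of(n)),
                            "drugs": sorted(net.drugs_of(n))}
                        for n in net.nodes},
              "edges": sorted(map(sorted, net.graph.edges))},
             "timma/combination_network.json")
        # high vs low predicted synergy, split at the mean score
        mean_score = scores["synergy"].mean()
        hi = scores.loc[scores["synergy"] > mean_score, "y_combination"]
        lo = scores.loc[scores["synergy"] <= mean_score, "y_combination"]
        p_val = compare_groups(hi, lo) if len(hi) >= 3 and len(lo) >= 3 else None
        save({"mean_predicted_synergy": float(mean_score),
              "n_high": int(len(hi)), "n_low": int(len(lo)),
              "rank_sum_p": p_val}, "timma/synergy_split.json")

    if cfg.stages.get("synergy", True) and surfaces is not None:
        results = []
        for s in surfaces:
            m = s.matrix
            b = bliss_score(m)
            h = hsa_score(m.inhibition[-1, -1], m.margin1[-1], m.margin2[-1],
                          entity1=m.drug1, entity2=m.drug2)
            results.extend([b, h])
        save(results, "synergy/scores.csv")

    if cfg.stages.get("deconvolve", True) and screen is not None:
        expr = io.read_results(out / "inputs/expression.csv", "expression")
        drugs = screen.kd.drugs[:4]
        try:
            catalog = pair_catalog((drugs[0], drugs[1]), (drugs[0], drugs[2]),
                                   screen.kd, expr, fold=cfg.fold_deconv,
                                   min_log2=cfg.expr_min_log2)
            rows = catalog.to_rows()
        except ValueError as exc:  # a drug lost all targets to the filters
            logger.warning("deconvolution skipped: %s", exc)
            rows = []
        path = out / "deconvolution/catalog.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows, columns=["gene1", "gene2", "group"]).to_csv(
            path, index=False)
        written.append(path)

    if cfg.stages.get("simulate", True):
        system = synthetic.demo_system()
        ss = ode_twin(system)
        control = [ssa_simulate(system, t_end=cfg.sim_t_end,
                                window=cfg.sim_window,
                                population_cap=cfg.sim_cap,
                                seed=(cfg.seed + 7919 * i) & 0x7FFFFFFF).viability
                   for i in range(cfg.sim_runs)]
        viability = {}
        for genes in (("AURKB",), ("ZAK",), ("CSF1R",), ("AURKB", "ZAK"),
                      ("AURKB", "CSF1R")):
            res = knockout_experiment(system, genes, n_runs=cfg.sim_runs,
                                      t_end=cfg.sim_t_end,
                                      window=cfg.sim_window,
                                      population_cap=cfg.sim_cap,
                                      seed=cfg.seed,
                                      control_viabilities=control)
            viability["+".join(genes)] = res.viability_ratio
        save({"ode_steady_state": {g: float(v) for g, v in ss.items()},
              "viability_ratio": viability,
              "n_runs": cfg.sim_runs, "t_end": cfg.sim_t_end},
             "simulation/viability.json")

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __import__("polysynergy").__version__,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
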