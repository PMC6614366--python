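"""Set-theoretic prediction of multi-target inhibition sensitivity (TIMMA).

The model treats each drug as the set of kinases it binds (binarized from
Kd profiles) and predicts the sensitivity of an arbitrary target set ``d``
from the training drugs' sets by min-max averaging:

* if some training drugs have exactly the profile ``d``, the prediction is
  the mean of their sensitivities;
* otherwise the prediction is ``(y_min + y_max) / 2`` where ``y_min``
  averages the best strict-subset drug ``h`` with every strict-subset drug
  nested above ``d_h`` that is *less* sensitive than ``h``, and ``y_max``
  symmetrically averages the worst strict-superset drug ``l`` with every
  strict-superset drug nested below ``d_l`` that is *more* sensitive.

Boundary convention: when no strict subset (superset) training drug
exists, a virtual empty-profile drug with y = 0 (full-universe drug with
y = 1) stands in, so the predictor is total: inhibiting nothing kills
nothing, inhibiting everything kills everything.

A greedy forward-floating search over kinases minimizes the mean
leave-one-out absolute prediction error to find the "essential" target
set that best explains the single-drug screen; a drug combination is then
scored on the union of its projected profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from polysynergy.io import KdMatrix, SensitivityProfile

__all__ = [
    "TargetProfile", "TimmaModel", "CombinationPrediction", "CombinationNetwork",
    "binarize_targets", "normalize_dss", "predict_sensitivity",
    "select_essential_targets", "predict_combination",
    "build_combination_network", "network_cut_inference",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetProfile:
    """A drug's binarized kinase-target set."""

    drug: str
    targets: frozenset[str]


@dataclass(frozen=True)
class CombinationPrediction:
    drug1: str
    drug2: str
    combined_targets: frozenset[str]
    y_combination: float
    y_single1: float
    y_single2: float
    synergy: float
    score_mode: str = "hsa"  # 'hsa' = y_d - max(y1, y2); 'raw' = y_d


@dataclass
class TimmaModel:
    """Fitted essential-target model.

    ``selected_targets`` is the ordered essential set S; profiles are the
    full binarized training profiles (projection onto S happens at
    prediction time); ``loo_error`` is the mean leave-one-out absolute
    prediction error of the fit.
    """

    selected_targets: tuple[str, ...]
    profiles: dict[str, frozenset[str]]
    sensitivities: dict[str, float]
    loo_error: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.selected_targets:
            raise ValueError("empty essential target set")
        if not 0.0 <= self.loo_error <= 1.0:
            raise ValueError("loo_error outside [0, 1]")

    @property
    def drugs(self) -> list[str]:
        return list(self.profiles)

    def projected(self, drug: str) -> frozenset[str]:
        if drug not in self.profiles:
            raise KeyError(f"unknown drug: {drug}")
        return self.profiles[drug] & set(self.selected_targets)

    def predict(self, targets: Iterable[str]) -> float:
        """Predict sensitivity of an arbitrary target set via the fitted S."""
        d = frozenset(targets) & set(self.selected_targets)
        profs = [self.projected(drug) for drug in self.profiles]
        ys = [self.sensitivities[drug] for drug in self.profiles]
        return predict_sensitivity(d, profs, ys)

    def to_json(self) -> str:
        payload = {
            "selected_targets": list(self.selected_targets),
            "profiles": {d: sorted(p) for d, p in self.profiles.items()},
            "sensitivities": {d: float(y) for d, y in self.sensitivities.items()},
            "loo_error": float(self.loo_error),
            "seed": int(self.seed),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "TimmaModel":
        obj = json.loads(text)
        return cls(
            selected_targets=tuple(obj["selected_targets"]),
            profiles={d: frozenset(p) for d, p in obj["profiles"].items()},
            sensitivities={d: float(y) for d, y in obj["sensitivities"].items()},
            loo_error=float(obj["loo_error"]),
            seed=int(obj.get("seed", 0)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimmaModel):
            return NotImplemented
        return (self.selected_targets == other.selected_targets
                and self.profiles == other.profiles
                and self.sensitivities.keys() == other.sensitivities.keys()
                and all(abs(self.sensitivities[d] - other.sensitivities[d]) < 1e-12
                        for d in self.sensitivities)
                and abs(self.loo_error - other.loo_error) < 1e-12)


@dataclass
class CombinationNetwork:
    """Drug-target combination network.

    Nodes are groups of selected kinases with identical drug-binding
    patterns over the training drugs; each node is annotated with the set
    of drugs hitting it.  Edges join groups sharing at least one drug, so
    removing everything a drug pair hits can disconnect redundant
    sensitivity routes.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def drugs_of(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["drugs"]

    def members_of(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["members"]


# ---------------------------------------------------------------------------
# Binarization and normalization
# ---------------------------------------------------------------------------

def binarize_targets(kd: KdMatrix, fold: float = 50.0) -> dict[str, TargetProfile]:
    """Binarize Kd rows: target iff Kd <= fold * (row-minimum Kd).

    The 50-fold-or-less rule; missing Kd is never a target.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    out: dict[str, TargetProfile] = {}
    for drug in kd.drugs:
        row = kd.row(drug)
        finite = row.dropna()
        if finite.empty:
            raise ValueError(f"drug {drug} has no finite Kd")
        thr = fold * finite.min()
        hits = frozenset(finite.index[finite <= thr])
        out[drug] = TargetProfile(drug=drug, targets=hits)
    return out


def normalize_dss(dss_raw: Mapping[str, float] | pd.Series) -> SensitivityProfile:
    """Min-max normalize raw drug sensitivity scores into [0, 1]."""
    ser = pd.Series(dict(dss_raw)) if not isinstance(dss_raw, pd.Series) else dss_raw.astype(float)
    if (ser < 0).any():
        raise ValueError("negative raw DSS")
    lo, hi = float(ser.min()), float(ser.max())
    if hi == lo:
        raise ValueError("degenerate screen: all DSS equal")
    y = (ser - lo) / (hi - lo)
    return SensitivityProfile(ser.rename("dss_raw"), y.rename("y"))


# ---------------------------------------------------------------------------
# Eq.-style min-max predictor (bitmask engine)
# ---------------------------------------------------------------------------

def _predict_mask(d: int, masks: Sequence[int], ys: Sequence[float]) -> float:
    """Min-max averaging on integer bitmask profiles.

    Ties in the argmax/argmin are broken by the first index in training
    order; the documented tie-break rule.
    """
    match_sum = 0.0
    match_n = 0
    for m, y in zip(masks, ys):
        if m == d:
            match_sum += y
            match_n += 1
    if match_n:
        return match_sum / match_n

    # y_min from the best strict-subset drug h
    h = -1
    for i, (m, y) in enumerate(zip(masks, ys)):
        if m != d and (m & d) == m:  # m strictly contained in d
            if h < 0 or y > ys[h]:
                h = i
    if h < 0:
        y_min = 0.0  # virtual empty-profile drug, y = 0
    else:
        mh, yh = masks[h], ys[h]
        s, n = yh, 1
        for j, (m, y) in enumerate(zip(masks, ys)):
            if j == h or y >= yh:
                continue
            if m != d and (m & d) == m and m != mh and (mh & m) == mh:
                s += y
                n += 1
        y_min = s / n

    # y_max from the worst strict-superset drug l
    l = -1
    for i, (m, y) in enumerate(zip(masks, ys)):
        if m != d and (m & d) == d:  # m strictly contains d
            if l < 0 or y < ys[l]:
                l = i
    if l < 0:
        y_max = 1.0  # virtual full-universe drug, y = 1
    else:
        ml, yl = masks[l], ys[l]
        s, n = yl, 1
        for j, (m, y) in enumerate(zip(masks, ys)):
            if j == l or y <= yl:
                continue
            if m != d and (m & d) == d and m != ml and (m & ml) == m:
                s += y
                n += 1
        y_max = s / n

    return (y_min + y_max) / 2.0


def predict_sensitivity(d: Iterable[str],
                        profiles: Sequence[Iterable[str]],
                        sensitivities: Sequence[float]) -> float:
    """Predict the sensitivity of target set ``d`` from training drugs.

    ``profiles`` and ``sensitivities`` are aligned; all sets live over the
    same kinase universe.  Output is in [0, 1] whenever sensitivities are.
    """
    if len(profiles) != len(sensitivities):
        raise ValueError("profiles and sensitivities not aligned")
    universe = sorted(set().union(frozenset(d), *map(frozenset, profiles)))
    bit = {k: 1 << i for i, k in enumerate(universe)}

    def mask(s: Iterable[str]) -> int:
        out = 0
        for k in s:
            out |= bit[k]
        return out

    return _predict_mask(mask(d), [mask(p) for p in profiles],
                         [float(y) for y in sensitivities])


# ---------------------------------------------------------------------------
# Essential-target subset search
# ---------------------------------------------------------------------------

def _loo_error(masks: list[int], ys: list[float], s_mask: int) -> float:
    """Mean leave-one-out |y_i - yhat_i| with profiles projected onto S."""
    proj = [m & s_mask for m in masks]
    total = 0.0
    n = len(masks)
    for i in range(n):
        rest_m = proj[:i] + proj[i + 1:]
        rest_y = ys[:i] + ys[i + 1:]
        total += abs(ys[i] - _predict_mask(proj[i], rest_m, rest_y))
    return total / n


def select_essential_targets(profiles: Mapping[str, Iterable[str]],
                             sensitivities: Mapping[str, float],
                             max_size: int = 20,
                             seed: int = 0) -> TimmaModel:
    """Greedy forward-floating search for the most predictive target set.

    Adds the kinase that most reduces the mean leave-one-out absolute
    prediction error, then attempts removals that improve it further.
    Deterministic: ties break toward the lexicographically smallest
    kinase symbol, and strict improvement is required to grow the set
    (preferring smaller sets).  ``seed`` is recorded for provenance; the
    search itself has no random element.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if len(profiles) < 3:
        raise ValueError("need at least 3 training drugs")

    drugs = list(profiles)
    kinases = sorted(set().union(*[frozenset(profiles[d]) for d in drugs]))
    if max_size > len(kinases):
        max_size = len(kinases)
    bit = {k: 1 << i for i, k in enumerate(kinases)}
    masks = [sum(bit[k] for k in frozenset(profiles[d])) for d in drugs]
    ys = [float(sensitivities[d]) for d in drugs]
    if any(not 0 <= y <= 1 for y in ys):
        raise ValueError("sensitivities must be normalized to [0, 1]")

    eps = 1e-12
    s_mask = 0
    err = _loo_error(masks, ys, 0)

    def best_candidate(candidates: list[str], base: int, adding: bool):
        best_k, best_e = None, None
        for k in candidates:  # lexicographic order = tie-break
            trial = (base | bit[k]) if adding else (base & ~bit[k])
            e = _loo_error(masks, ys, trial)
            if best_e is None or e < best_e - eps:
                best_k, best_e = k, e
        return best_k, best_e

    selected: set[str] = set()
    while len(selected) < max_size:
        cands = [k for k in kinases if k not in selected]
        if not cands:
            break
        k_add, e_add = best_candidate(cands, s_mask, adding=True)
        if selected and e_add >= err - eps:
            break  # no strict improvement -> stop (smaller set preferred)
        selected.add(k_add)
        s_mask |= bit[k_add]
        err = e_add
        # floating removal phase
        while len(selected) > 1:
            k_rm, e_rm = best_candidate(sorted(selected), s_mask, adding=False)
            if e_rm < err - eps:
                selected.discard(k_rm)
                s_mask &= ~bit[k_rm]
                err = e_rm
            else:
                break

    return TimmaModel(
        selected_targets=tuple(sorted(selected)),
        profiles={d: frozenset(profiles[d]) for d in drugs},
        sensitivities=dict(zip(drugs, ys)),
        loo_error=float(err),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Combination prediction and the combination network
# ---------------------------------------------------------------------------

def predict_combination(model: TimmaModel, drug1: str, drug2: str,
                        score_mode: str = "hsa") -> CombinationPrediction:
    """Predict a drug pair's sensitivity on the union of projected profiles.

    ``score_mode='hsa'`` (default) reports y_d - max(yhat_1, yhat_2);
    ``'raw'`` reports y_d itself as the synergy score.
    """
    if score_mode not in ("hsa", "raw"):
        raise ValueError("score_mode must be 'hsa' or 'raw'")
    for drug in (drug1, drug2):
        if drug not in model.profiles:
            raise KeyError(f"unknown drug: {drug}")
    d1 = model.projected(drug1)
    d2 = model.projected(drug2)
    combined = d1 | d2
    profs = [model.projected(d) for d in model.profiles]
    ys = [model.sensitivities[d] for d in model.profiles]
    y_d = predict_sensitivity(combined, profs, ys)
    y1 = predict_sensitivity(d1, profs, ys)
    y2 = predict_sensitivity(d2, profs, ys)
    synergy = y_d if score_mode == "raw" else y_d - max(y1, y2)
    return CombinationPrediction(drug1=drug1, drug2=drug2,
                                 combined_targets=combined,
                                 y_combination=y_d, y_single1=y1,
                                 y_single2=y2, synergy=synergy,
                                 score_mode=score_mode)


def build_combination_network(model: TimmaModel) -> CombinationNetwork:
    """Partition selected kinases into target-group nodes.

    Kinases indistinguishable by their drug-binding pattern (over the
    training drugs) merge into one node; groups sharing a drug are
    adjacent.  Every selected kinase lands in exactly one node.
    """
    if not model.selected_targets:
        raise ValueError("model has an empty target set")
    drugs = model.drugs
    pattern: dict[tuple[str, ...], list[str]] = {}
    for k in model.selected_targets:
        key = tuple(d for d in drugs if k in model.profiles[d])
        pattern.setdefault(key, []).append(k)

    g = nx.Graph()
    for key, members in sorted(pattern.items(), key=lambda kv: kv[1]):
        name = "+".join(sorted(members))
        g.add_node(name, members=frozenset(members), drugs=frozenset(key))
    names = list(g.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if g.nodes[a]["drugs"] & g.nodes[b]["drugs"]:
                g.add_edge(a, b)
    return CombinationNetwork(graph=g)


def network_cut_inference(net: CombinationNetwork, drug1: str, drug2: str) -> dict:
    """Does removing everything the pair hits break the network apart?

    Removes all nodes hit by either drug and counts connected components
    among the remainder; the pair is predicted effective iff the count
    increases versus the intact network, or nothing remains.
    """
    g = net.graph
    hit = [n for n in g.nodes if g.nodes[n]["drugs"] & {drug1, drug2}]
    rest = g.copy()
    rest.remove_nodes_from(hit)
    before = nx.number_connected_components(g)
    after = nx.number_connected_components(rest)
    effective = (rest.number_of_nodes() == 0) or (after > before)
    return {"removed_nodes": sorted(hit),
            "components_before": int(before),
            "components_after_removal": int(after),
            "predicted_effective": bool(effective)}
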