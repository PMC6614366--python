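"""Kd- and expression-based deconvolution of target pairs behind drug combos.

Given two drug combinations sharing a common drug, derives the kinase
pairs that could mediate each combination's effect: potent targets are
kinases with Kd strictly below 10x the drug's minimal Kd, restricted to
genes expressed above log2 = 6, and the resulting cross-drug pairs are
classified as unique to combination A (G1), shared (G2), or unique to
combination B (G3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from polysynergy.io import ExpressionTable, KdMatrix

logger = logging.getLogger(__name__)

__all__ = ["TargetPairCatalog", "potent_targets", "expression_filter",
           "pair_catalog"]


@dataclass(frozen=True)
class TargetPairCatalog:
    """Unordered kinase pairs grouped by combination membership.

    G1: unique to combination A, G2: shared, G3: unique to combination B.
    Groups are disjoint; every gene passed the expression filter.
    """

    g1: frozenset[frozenset[str]]
    g2: frozenset[frozenset[str]]
    g3: frozenset[frozenset[str]]

    def __post_init__(self) -> None:
        if self.g1 & self.g2 or self.g1 & self.g3 or self.g2 & self.g3:
            raise ValueError("pair groups must be disjoint")

    @property
    def pairs(self) -> frozenset[frozenset[str]]:
        return self.g1 | self.g2 | self.g3

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.pairs:
            out |= p
        return frozenset(out)

    def to_rows(self) -> list[dict]:
        rows = []
        for label, group in (("G1", self.g1), ("G2", self.g2), ("G3", self.g3)):
            for pair in sorted(tuple(sorted(p)) for p in group):
                rows.append({"gene1": pair[0], "gene2": pair[1], "group": label})
        return rows


def potent_targets(kd: KdMatrix, drug: str, fold: float = 10.0) -> frozenset[str]:
    """Kinases with Kd strictly lower than ``fold`` x the drug's minimal Kd.

    Note the strict "<" here, unlike the inclusive 50-fold binarization
    rule used for model fitting; the two thresholds intentionally differ
    in boundary semantics.
    """
    row = kd.row(drug).dropna()
    thr = fold * row.min()
    return frozenset(row.index[row < thr])


def expression_filter(targets: frozenset[str] | set[str],
                      expr: ExpressionTable,
                      min_log2: float = 6.0) -> frozenset[str]:
    """Keep genes with log2 expression >= ``min_log2``.

    Genes missing from the table count as non-expressed (logged).
    """
    missing = [g for g in targets if g not in expr.log2_expression.index]
    if missing:
        logger.warning("expression_filter: %d genes missing from table, "
                       "treated as non-expressed: %s", len(missing),
                       sorted(missing))
    return frozenset(g for g in targets
                     if g in expr.log2_expression.index
                     and expr.log2_expression[g] >= min_log2)


def _combo_pairs(combo: tuple[str, str], kd: KdMatrix, expr: ExpressionTable,
                 fold: float, min_log2: float) -> frozenset[frozenset[str]]:
    filtered = []
    for drug in combo:
        t = expression_filter(potent_targets(kd, drug, fold), expr, min_log2)
        if not t:
            raise ValueError(f"drug {drug} has no surviving targets after filtering")
        filtered.append(t)
    t1, t2 = filtered
    return frozenset(frozenset((i, j)) for i in t1 for j in t2 if i != j)


def pair_catalog(combo_a: tuple[str, str], combo_b: tuple[str, str],
                 kd: KdMatrix, expr: ExpressionTable,
                 fold: float = 10.0, min_log2: float = 6.0) -> TargetPairCatalog:
    """Classify the candidate target pairs of two drug combinations.

    Cross pairs of each combination are the unordered distinct-gene pairs
    (drug-1 target, drug-2 target) surviving the potency and expression
    filters; G2 is the intersection of the two combinations' pair sets
    and G1/G3 the set differences.
    """
    pairs_a = _combo_pairs(combo_a, kd, expr, fold, min_log2)
    pairs_b = _combo_pairs(combo_b, kd, expr, fold, min_log2)
    return TargetPairCatalog(g1=frozenset(pairs_a - pairs_b),
                             g2=frozenset(pairs_a & pairs_b),
                             g3=frozenset(pairs_b - pairs_a))
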