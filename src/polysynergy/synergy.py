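"""Experimental combination-effect scoring.

Dose-response surfaces are scored by the excess volume over the Bliss
independence expectation (fractional inhibition f1 + f2 - f1*f2), HSA
relative to the better single agent, and siRNA double-knockdown tables by
the mean multiplicative excess.  Single-agent margins are smoothed with
four-parameter logistic (4PL) fits before scoring, matching common
response-surface practice; raw margins and the literal product-form
expectation are available behind flags.  Assay transforms (qPCR percent
expression, CRISPR viability/cytotoxicity) live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseMatrix", "CurveFit4PL", "SynergyScore", "AssayReadout",
    "fit_4pl", "bliss_score", "hsa_score", "sirna_pair_synergy",
    "qpcr_percent_expression", "crispr_viability_cytotoxicity",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseMatrix:
    """% inhibition over a concentration grid with single-agent margins.

    ``conc1`` indexes rows (drug 1), ``conc2`` columns (drug 2); both
    start at 0, so row 0 / column 0 are the single-agent margins and cell
    (0, 0) is untreated.  Values may exceed [0, 100] (assay noise).
    """

    drug1: str
    drug2: str
    conc1: np.ndarray
    conc2: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "conc1", np.asarray(self.conc1, dtype=float))
        object.__setattr__(self, "conc2", np.asarray(self.conc2, dtype=float))
        object.__setattr__(self, "inhibition",
                           np.asarray(self.inhibition, dtype=float))
        for name, c in (("conc1", self.conc1), ("conc2", self.conc2)):
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{name} not strictly increasing")
        if self.inhibition.shape != (len(self.conc1), len(self.conc2)):
            raise ValueError("inhibition grid does not match dose vectors")

    @property
    def margin1(self) -> np.ndarray:
        """Drug-1-alone % inhibition at each conc1 (column 0)."""
        return self.inhibition[:, 0]

    @property
    def margin2(self) -> np.ndarray:
        """Drug-2-alone % inhibition at each conc2 (row 0)."""
        return self.inhibition[0, :]

    def transposed(self) -> "DoseResponseMatrix":
        return DoseResponseMatrix(drug1=self.drug2, drug2=self.drug1,
                                  conc1=self.conc2, conc2=self.conc1,
                                  inhibition=self.inhibition.T)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseResponseMatrix):
            return NotImplemented
        return (self.drug1 == other.drug1 and self.drug2 == other.drug2
                and np.allclose(self.conc1, other.conc1)
                and np.allclose(self.conc2, other.conc2)
                and np.allclose(self.inhibition, other.inhibition))


@dataclass(frozen=True)
class CurveFit4PL:
    """Fitted four-parameter logistic y = L + (U - L) / (1 + (EC50/x)^s)."""

    lower: float
    upper: float
    slope: float
    ec50: float
    residual_norm: float
    fallback: bool = False
    _doses: np.ndarray | None = None
    _responses: np.ndarray | None = None

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.fallback:
            # monotone interpolation of the raw margin
            return np.interp(x, self._doses, self._responses)
        with np.errstate(divide="ignore"):
            out = self.lower + (self.upper - self.lower) / (
                1.0 + (self.ec50 / np.maximum(x, 1e-300)) ** self.slope)
        return np.where(x <= 0, self.lower, out)


@dataclass(frozen=True)
class SynergyScore:
    """A scored entity pair; score in percentage-inhibition units."""

    entity1: str
    entity2: str
    method: str  # bliss | hsa | sirna_multiplicative | timma_predicted
    score: float

    def __post_init__(self) -> None:
        if not self.method:
            raise ValueError("method tag required")


@dataclass(frozen=True)
class AssayReadout:
    """CellTiter-Glo / CellTox Green luminescence readouts."""

    ctg_day1: float
    ctg_day5: float
    ctx_day5: float = 0.0

    def __post_init__(self) -> None:
        if self.ctg_day1 <= 0 or self.ctg_day5 <= 0:
            raise ValueError("luminescence must be positive")


# ---------------------------------------------------------------------------
# 4PL curve fitting
# ---------------------------------------------------------------------------

def _four_pl(x, lower, upper, slope, ec50):
    return lower + (upper - lower) / (1.0 + (ec50 / x) ** slope)


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> CurveFit4PL:
    """Least-squares 4PL fit of % inhibition over nonzero doses.

    Bounds: L in [-20, 50], U in [0, 150], slope in (0, 10], EC50 within
    [min dose / 10, max dose * 10] — screening noise routinely exceeds
    [0, 100].  On non-convergence or a degenerate (flat) response the fit
    falls back to monotone interpolation of the raw margin with a logged
    warning.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct nonzero doses")

    def fallback() -> CurveFit4PL:
        logger.warning("fit_4pl: falling back to monotone interpolation")
        order = np.argsort(x)
        return CurveFit4PL(lower=float(y.min()), upper=float(y.max()),
                           slope=float("nan"), ec50=float("nan"),
                           residual_norm=0.0, fallback=True,
                           _doses=x[order], _responses=y[order])

    if np.ptp(y) < 1e-9:
        return fallback()

    lo = [-20.0, 0.0, 1e-6, x.min() / 10.0]
    hi = [50.0, 150.0, 10.0, x.max() * 10.0]
    # initializer: asymptotes from data, EC50 from log-linear midpoint crossing
    y_lo, y_hi = float(y.min()), float(y.max())
    mid = (y_lo + y_hi) / 2.0
    ec0 = float(np.exp(np.interp(mid, np.sort(y), np.log(x[np.argsort(y)]))))
    p0 = [np.clip(y_lo, lo[0], hi[0]), np.clip(y_hi, lo[1], hi[1]), 1.0,
          np.clip(ec0, lo[3], hi[3])]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_four_pl, x, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
    except (RuntimeError, ValueError):
        return fallback()
    resid = float(np.linalg.norm(_four_pl(x, *popt) - y))
    return CurveFit4PL(lower=float(popt[0]), upper=float(popt[1]),
                       slope=float(popt[2]), ec50=float(popt[3]),
                       residual_norm=resid)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def bliss_score(m: DoseResponseMatrix, use_fitted_margins: bool = True,
                literal_product: bool = False) -> SynergyScore:
    """Mean excess of observed inhibition over the Bliss expectation.

    Averaged over the nonzero-dose subgrid (7 x 7 for an 8 x 8 assay).
    Inhibition is handled as fractions internally and the score reported
    back in percentage points.  ``literal_product=True`` uses the plain
    product f1 * f2 as the expectation instead of the independence form
    f1 + f2 - f1 * f2.
    """
    n1, n2 = len(m.conc1) - 1, len(m.conc2) - 1
    if n1 < 2 or n2 < 2 or m.conc1[0] != 0 or m.conc2[0] != 0:
        raise ValueError("need a zero dose plus an n x m nonzero grid, n,m >= 2")
    d1, d2 = m.conc1[1:], m.conc2[1:]
    if use_fitted_margins:
        y1 = fit_4pl(m.conc1, m.margin1).predict(d1)
        y2 = fit_4pl(m.conc2, m.margin2).predict(d2)
    else:
        y1 = m.margin1[1:]
        y2 = m.margin2[1:]
    f1 = y1 / 100.0
    f2 = y2 / 100.0
    fc = m.inhibition[1:, 1:] / 100.0
    if literal_product:
        expected = np.outer(f1, f2)
    else:
        expected = f1[:, None] + f2[None, :] - np.outer(f1, f2)
    score = 100.0 * float(np.mean(fc - expected))
    return SynergyScore(entity1=m.drug1, entity2=m.drug2, method="bliss",
                        score=score)


def hsa_score(y_combination: float, y1: float, y2: float,
              entity1: str = "drug1", entity2: str = "drug2") -> SynergyScore:
    """Highest-single-agent synergy: y_comb - max(y1, y2), in % points."""
    return SynergyScore(entity1=entity1, entity2=entity2, method="hsa",
                        score=float(y_combination) - max(float(y1), float(y2)))


def sirna_pair_synergy(double_kd: Mapping[tuple[str, str], float],
                       singles: Mapping[str, float],
                       entity1: str = "drug1",
                       entity2: str = "drug2") -> SynergyScore:
    """Mean multiplicative excess over the cross-drug target pairs.

    Inputs are fractional inhibitions in [0, 1]; the mean of
    y_ij - y_i * y_j over all pairs is reported x100 (percentage points).
    """
    if not double_kd:
        raise ValueError("empty target-pair set")
    total = 0.0
    for (i, j), y_ij in double_kd.items():
        for g in (i, j):
            if g not in singles:
                raise KeyError(f"missing single-knockdown value for {g}")
        for v in (y_ij, singles[i], singles[j]):
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError("inhibition values must be fractions in [0, 1]")
        total += y_ij - singles[i] * singles[j]
    score = 100.0 * total / len(double_kd)
    return SynergyScore(entity1=entity1, entity2=entity2,
                        method="sirna_multiplicative", score=score)


def qpcr_percent_expression(cp1: float, cp2: float, cp3: float, cp4: float) -> float:
    """Housekeeping-corrected % expression after knock-down.

    100 * 0.5^(Cp1 - Cp2) / 0.5^(Cp3 - Cp4): Cp1/Cp2 are the target-gene
    cross points after/before knock-down, Cp3/Cp4 the housekeeping gene's.
    """
    for c in (cp1, cp2, cp3, cp4):
        if not np.isfinite(c):
            raise ValueError("cycle numbers must be finite")
    return 100.0 * 0.5 ** (cp1 - cp2) / 0.5 ** (cp3 - cp4)


def crispr_viability_cytotoxicity(readout: AssayReadout) -> dict[str, float]:
    """Day-5/day-1 viability ratio and cell-death-per-viability cytotoxicity."""
    viability = readout.ctg_day5 / readout.ctg_day1
    cytotoxicity = readout.ctx_day5 / viability
    return {"viability": float(viability), "cytotoxicity": float(cytotoxicity)}


def percent_inhibition_from_controls(value: float, negative: float,
                                     positive: float) -> float:
    """Normalize a viability readout to % inhibition between controls.

    ``negative`` (e.g. DMSO) maps to 0 % and ``positive`` (e.g. BzCl,
    full kill) to 100 %.
    """
    if negative == positive:
        raise ValueError("degenerate controls")
    return 100.0 * (negative - value) / (negative - positive)
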