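"""Readers and writers for every flat-file format the pipeline touches.

All tables travel as CSV (wide or long/tidy dialects), signed networks as
three-column SIF text (``source<TAB>sign<TAB>target`` with sign ``+``/``-``),
and fitted models/results as JSON.  Every reader validates and returns a
typed object; downstream modules never see raw frames.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SIGN_TOKENS = {"+": "activation", "-": "inhibition",
               "activation": "activation", "inhibition": "inhibition"}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KdMatrix:
    """Drug x kinase dissociation constants (nM).

    ``kd_nM`` is a drugs-by-kinases frame; NaN means the kinase was not
    bound at the assayed range (or not assayed) and is never a target.
    """

    kd_nM: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.kd_nM
        if df.empty:
            raise ValueError("empty Kd matrix")
        if df.index.duplicated().any():
            raise ValueError("duplicate drug labels in Kd matrix")
        if df.columns.duplicated().any():
            raise ValueError("duplicate kinase labels in Kd matrix")
        vals = df.to_numpy(dtype=float)
        if np.any(np.nan_to_num(vals, nan=1.0) <= 0):
            raise ValueError("non-positive Kd")
        if not np.isfinite(vals).any(axis=1).all():
            bad = df.index[~np.isfinite(vals).any(axis=1)].tolist()
            raise ValueError(f"drugs with no finite Kd: {bad}")

    @property
    def drugs(self) -> list[str]:
        return list(self.kd_nM.index)

    @property
    def kinases(self) -> list[str]:
        return list(self.kd_nM.columns)

    def row(self, drug: str) -> pd.Series:
        if drug not in self.kd_nM.index:
            raise KeyError(f"unknown drug: {drug}")
        return self.kd_nM.loc[drug]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KdMatrix):
            return NotImplemented
        a, b = self.kd_nM, other.kd_nM
        return (list(a.index) == list(b.index)
                and list(a.columns) == list(b.columns)
                and np.allclose(a.to_numpy(float), b.to_numpy(float),
                                equal_nan=True))


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-drug drug sensitivity scores, raw and min-max normalized.

    ``y`` lives in [0, 1]; higher = more sensitive.
    """

    dss_raw: pd.Series
    y: pd.Series

    def __post_init__(self) -> None:
        if (self.dss_raw < 0).any():
            raise ValueError("negative raw DSS")
        if ((self.y < -1e-12) | (self.y > 1 + 1e-12)).any():
            raise ValueError("normalized sensitivity outside [0, 1]")
        order = np.argsort(self.dss_raw.to_numpy())
        if np.any(np.diff(self.y.to_numpy()[order]) < -1e-9):
            raise ValueError("y not monotone in dss_raw")

    @property
    def drugs(self) -> list[str]:
        return list(self.dss_raw.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensitivityProfile):
            return NotImplemented
        return (list(self.dss_raw.index) == list(other.dss_raw.index)
                and np.allclose(self.dss_raw, other.dss_raw)
                and np.allclose(self.y, other.y))


@dataclass(frozen=True)
class ExpressionTable:
    """Per-gene log2 expression (unitless), optionally with RPKM."""

    log2_expression: pd.Series
    rpkm: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.log2_expression.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression table")
        if self.rpkm is not None and (self.rpkm.dropna() < 0).any():
            raise ValueError("negative RPKM")

    @property
    def genes(self) -> list[str]:
        return list(self.log2_expression.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        if list(self.log2_expression.index) != list(other.log2_expression.index):
            return False
        if not np.allclose(self.log2_expression, other.log2_expression):
            return False
        if (self.rpkm is None) != (other.rpkm is None):
            return False
        return self.rpkm is None or np.allclose(self.rpkm, other.rpkm,
                                                equal_nan=True)


@dataclass(frozen=True)
class SignedNetwork:
    """Signed directed edges (source, target, 'activation'|'inhibition')."""

    edges: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for src, dst, sign in self.edges:
            if not src or not dst:
                raise ValueError("empty gene symbol in signed edge")
            if sign not in ("activation", "inhibition"):
                raise ValueError(f"unknown sign token: {sign!r}")
            if (src, dst, sign) in seen:
                raise ValueError(f"duplicate edge {(src, dst, sign)}")
            seen.add((src, dst, sign))

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for src, dst, _ in self.edges:
            for g in (src, dst):
                if g not in out:
                    out.append(g)
        return out


# ---------------------------------------------------------------------------
# Kd matrices
# ---------------------------------------------------------------------------

def read_kd_matrix(path: str | Path, dialect: str = "wide") -> KdMatrix:
    """Read a drug-target Kd table.

    ``wide``: drugs in rows, kinases in columns, cells in nM (blank =
    not bound).  ``long``: three columns drug, kinase, kd_nM.
    Unparseable cells become missing with a logged warning count.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")
    if dialect == "wide":
        # pandas mangles duplicate header labels, so inspect the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        if len(header) != len(set(header)):
            raise ValueError("duplicate drug/kinase labels")
        raw = pd.read_csv(path, index_col=0, dtype=str)
        if raw.empty:
            raise ValueError(f"empty Kd table: {path}")
        if raw.index.duplicated().any() or raw.columns.duplicated().any():
            raise ValueError("duplicate drug/kinase labels")
        numeric = raw.apply(pd.to_numeric, errors="coerce")
        bad = int((numeric.isna() & raw.notna() & (raw != "")).to_numpy().sum())
        if bad:
            logger.warning("read_kd_matrix: %d unparseable Kd cells set to missing", bad)
        numeric.index = numeric.index.astype(str)
        numeric.columns = numeric.columns.astype(str)
        return KdMatrix(numeric.astype(float))
    if dialect == "long":
        raw = pd.read_csv(path)
        if raw.shape[1] < 3:
            raise ValueError("long dialect needs columns drug, kinase, kd")
        raw = raw.iloc[:, :3]
        raw.columns = ["drug", "kinase", "kd"]
        if raw.duplicated(["drug", "kinase"]).any():
            raise ValueError("duplicate (drug, kinase) rows in long Kd table")
        kd = pd.to_numeric(raw["kd"], errors="coerce")
        bad = int((kd.isna() & raw["kd"].notna()).sum())
        if bad:
            logger.warning("read_kd_matrix: %d unparseable Kd cells set to missing", bad)
        raw["kd"] = kd
        wide = raw.pivot(index="drug", columns="kinase", values="kd")
        wide.index = wide.index.astype(str)
        wide.columns = wide.columns.astype(str)
        wide.index.name = None
        wide.columns.name = None
        return KdMatrix(wide.astype(float))
    raise ValueError(f"unknown dialect: {dialect!r}")


def write_kd_matrix(kd: KdMatrix, path: str | Path) -> Path:
    path = Path(path)
    kd.kd_nM.to_csv(path, index_label="drug")
    return path


# ---------------------------------------------------------------------------
# Sensitivity / expression tables
# ---------------------------------------------------------------------------

def read_sensitivity(path: str | Path) -> SensitivityProfile:
    """Read a CSV with columns drug, dss_raw[, y]; renormalizes if y absent."""
    df = pd.read_csv(path)
    if "drug" not in df.columns or "dss_raw" not in df.columns:
        raise ValueError("sensitivity CSV needs columns drug, dss_raw")
    if df["drug"].duplicated().any():
        raise ValueError("duplicate drug labels in sensitivity table")
    idx = df["drug"].astype(str)
    dss = pd.Series(df["dss_raw"].to_numpy(float), index=idx, name="dss_raw")
    if "y" in df.columns:
        y = pd.Series(df["y"].to_numpy(float), index=idx, name="y")
    else:
        lo, hi = dss.min(), dss.max()
        if hi == lo:
            raise ValueError("degenerate screen: all DSS equal")
        y = ((dss - lo) / (hi - lo)).rename("y")
    return SensitivityProfile(dss, y)


def write_sensitivity(prof: SensitivityProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"drug": prof.drugs,
                  "dss_raw": prof.dss_raw.to_numpy(),
                  "y": prof.y.to_numpy()}).to_csv(path, index=False)
    return path


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a CSV with columns gene, log2_expression[, rpkm]."""
    df = pd.read_csv(path)
    if "gene" not in df.columns or "log2_expression" not in df.columns:
        raise ValueError("expression CSV needs columns gene, log2_expression")
    idx = df["gene"].astype(str)
    log2 = pd.Series(df["log2_expression"].to_numpy(float), index=idx,
                     name="log2_expression")
    rpkm = None
    if "rpkm" in df.columns:
        rpkm = pd.Series(df["rpkm"].to_numpy(float), index=idx, name="rpkm")
    return ExpressionTable(log2, rpkm)


def write_expression(expr: ExpressionTable, path: str | Path) -> Path:
    path = Path(path)
    cols = {"gene": expr.genes,
            "log2_expression": expr.log2_expression.to_numpy()}
    if expr.rpkm is not None:
        cols["rpkm"] = expr.rpkm.to_numpy()
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Signed networks (SIF)
# ---------------------------------------------------------------------------

def read_signed_network(path: str | Path) -> SignedNetwork:
    """Read SIF-style text: ``source<TAB>sign<TAB>target``, sign + or -."""
    edges: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        src, sign, dst = parts
        if sign not in SIGN_TOKENS:
            raise ValueError(f"{path}:{lineno}: unknown sign token {sign!r}")
        edges.append((src, dst, SIGN_TOKENS[sign]))
    return SignedNetwork(tuple(edges))


def write_signed_network(net: SignedNetwork, path: str | Path) -> Path:
    path = Path(path)
    sign_out = {"activation": "+", "inhibition": "-"}
    lines = [f"{s}\t{sign_out[sg]}\t{t}" for s, t, sg in net.edges]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Dose-response matrices
# ---------------------------------------------------------------------------

def read_dose_matrix(path: str | Path, drug1: str = "drug1",
                     drug2: str = "drug2"):
    """Read an n x m dose-response grid.

    Layout: first header cell is a label, remaining header cells are the
    column-drug concentrations (nM, starting at 0); the first column
    holds the row-drug concentrations; the body holds % inhibition.
    Row 0 / column 0 are the single-agent margins, cell (0, 0) untreated.
    """
    from polysynergy.synergy import DoseResponseMatrix

    df = pd.read_csv(path, index_col=0)
    conc2 = np.asarray([float(c) for c in df.columns])
    conc1 = df.index.to_numpy(dtype=float)
    grid = df.to_numpy(dtype=float)
    return DoseResponseMatrix(drug1=drug1, drug2=drug2,
                              conc1=conc1, conc2=conc2, inhibition=grid)


def write_dose_matrix(m, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(m.inhibition,
                      index=pd.Index(m.conc1, name="conc_nM"),
                      columns=[repr(float(c)) for c in m.conc2])
    df.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# Generic result plumbing
# ---------------------------------------------------------------------------

def write_results(obj, path: str | Path) -> Path:
    """Serialize any pipeline product so ``read(write(x)) == x``.

    Dispatch on type: tables go to CSV, models and nested results to JSON,
    signed networks to SIF.
    """
    from polysynergy.synergy import DoseResponseMatrix, SynergyScore
    from polysynergy.timma import TimmaModel

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, KdMatrix):
        return write_kd_matrix(obj, path)
    if isinstance(obj, SensitivityProfile):
        return write_sensitivity(obj, path)
    if isinstance(obj, ExpressionTable):
        return write_expression(obj, path)
    if isinstance(obj, SignedNetwork):
        return write_signed_network(obj, path)
    if isinstance(obj, DoseResponseMatrix):
        return write_dose_matrix(obj, path)
    if isinstance(obj, TimmaModel):
        path.write_text(obj.to_json())
        return path
    if isinstance(obj, list) and obj and isinstance(obj[0], SynergyScore):
        rows = [{"entity1": s.entity1, "entity2": s.entity2,
                 "method": s.method, "score": repr(float(s.score))}
                for s in obj]
        pd.DataFrame(rows).to_csv(path, index=False)
        return path
    if isinstance(obj, (dict, list)):
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        return path
    raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def read_results(path: str | Path, kind: str):
    """Inverse of :func:`write_results`; ``kind`` names the product type."""
    from polysynergy.synergy import SynergyScore
    from polysynergy.timma import TimmaModel

    path = Path(path)
    if kind == "kd_matrix":
        return read_kd_matrix(path, dialect="wide")
    if kind == "sensitivity":
        return read_sensitivity(path)
    if kind == "expression":
        return read_expression(path)
    if kind == "signed_network":
        return read_signed_network(path)
    if kind == "dose_matrix":
        return read_dose_matrix(path)
    if kind == "timma_model":
        return TimmaModel.from_json(path.read_text())
    if kind == "synergy_scores":
        df = pd.read_csv(path)
        return [SynergyScore(entity1=str(r.entity1), entity2=str(r.entity2),
                             method=str(r.method), score=float(r.score))
                for r in df.itertuples()]
    if kind == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown result kind: {kind!r}")
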