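"""Readers, writers, the bundled worked-example table, and reports.

The bundled fixture (:func:`fixture_table1`) is the published Pearson
correlation matrix of ten four-point depression-questionnaire items and
a binary gold-standard diagnosis, estimated from 242 patients.  Only
correlations were published (to two decimals), so the fixture is used in
standardized mode (unit SDs).

CSV schemas
-----------
Correlation structure: first column ``item``, one column per item label,
optional ``sd`` and ``r_crit`` columns.  Diagonal cells must be exactly
1; a file holding only the lower or upper triangle is mirrored
automatically.

Responses: a header of item labels plus ``criterion``; one respondent
per row, integer scores.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParseError
from .simulate import CriterionLink, ItemResponseData, SimulationDesign
from .structures import CorrelationStructure

_SYM_TOL = 1e-8

# Published 10-item example: lower triangle of the inter-item Pearson
# correlation matrix (row i lists correlations with items 1..i-1),
# the item-criterion (point-biserial) column, and — for reference only —
# the printed corrected item-total column, which was computed from raw
# data with unpublished item SDs and is NOT exactly reproducible from
# the correlations alone.
_TABLE1_LOWER = [
    [],
    [0.32],
    [0.27, 0.50],
    [0.41, 0.31, 0.31],
    [0.27, 0.32, 0.38, 0.34],
    [0.15, 0.42, 0.36, 0.15, 0.30],
    [0.22, 0.38, 0.27, 0.29, 0.31, 0.28],
    [0.36, 0.42, 0.44, 0.42, 0.49, 0.28, 0.44],
    [0.19, 0.19, 0.18, 0.10, 0.20, 0.10, 0.14, 0.33],
    [0.42, 0.46, 0.44, 0.57, 0.41, 0.27, 0.35, 0.55, 0.26],
]
_TABLE1_R_CRIT = [0.22, 0.21, 0.23, 0.28, 0.20, 0.22, 0.26, 0.25, 0.13, 0.35]
TABLE1_PRINTED_ITEM_TOTAL = {
    i + 1: v
    for i, v in enumerate([0.45, 0.59, 0.56, 0.51, 0.53, 0.40, 0.47, 0.67, 0.28, 0.68])
}
TABLE1_N_OBS = 242
#: full-scale (20-item) statistics printed alongside the example
FULL_SCALE_ALPHA = 0.93
FULL_SCALE_VALIDITY = 0.40


def fixture_table1() -> CorrelationStructure:
    """The bundled 10-item worked example, exactly as printed.

    Labels 1..10, unit SDs (standardized mode), item-criterion
    correlations, ``n_obs = 242``.
    """
    p = len(_TABLE1_LOWER)
    R = np.eye(p)
    for i, row in enumerate(_TABLE1_LOWER):
        for j, v in enumerate(row):
            R[i, j] = R[j, i] = v
    return CorrelationStructure(
        labels=tuple(range(1, p + 1)),
        R=R,
        sd=None,
        r_crit=np.array(_TABLE1_R_CRIT),
        n_obs=TABLE1_N_OBS,
    )


# -- label handling ----------------------------------------------------------


def _coerce_label(raw: str):
    raw = str(raw).strip()
    try:
        return int(raw)
    except ValueError:
        return raw


# -- correlation-structure CSV ----------------------------------------------


def read_structure(path) -> CorrelationStructure:
    """Read a correlation structure, mirroring triangle-only files."""
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "item":
        raise ParseError(f"{path}: first column must be named 'item'")
    labels = [_coerce_label(x) for x in df["item"]]
    extra = [c for c in df.columns[1:] if c not in ("sd", "r_crit")]
    if [_coerce_label(c) for c in extra] != labels:
        raise ParseError(
            f"{path}: item columns {extra!r} do not match the 'item' rows {labels!r}"
        )
    p = len(labels)
    raw = df[extra].to_numpy()
    M = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(p):
            cell = raw[i, j]
            if isinstance(cell, str):
                cell = cell.strip()
            if cell in (None, "") or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                M[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {labels[i]!r}, "
                    f"column {labels[j]!r}"
                ) from None
    R = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            a, b = M[i, j], M[j, i]
            if np.isnan(a) and np.isnan(b):
                raise ParseError(
                    f"{path}: missing correlation for pair "
                    f"({labels[i]!r}, {labels[j]!r})"
                )
            if not np.isnan(a) and not np.isnan(b):
                if abs(a - b) > _SYM_TOL:
                    raise ParseError(
                        f"{path}: asymmetric entries at ({labels[i]!r}, "
                        f"{labels[j]!r}): {a} vs {b}"
                    )
                R[i, j] = (a + b) / 2.0
            else:
                R[i, j] = a if not np.isnan(a) else b
    for i in range(p):
        if R[i, i] != 1.0:
            raise ParseError(
                f"{path}: diagonal cell at row {labels[i]!r} is {R[i, i]}, must be 1"
            )
    sd = df["sd"].astype(float).to_numpy() if "sd" in df.columns else None
    r_crit = df["r_crit"].astype(float).to_numpy() if "r_crit" in df.columns else None
    return CorrelationStructure(labels=tuple(labels), R=R, sd=sd, r_crit=r_crit)


def write_structure(structure: CorrelationStructure, path) -> None:
    """Write a full symmetric structure CSV (round-trips with the reader)."""
    cols = {"item": [str(lab) for lab in structure.labels]}
    for j, lab in enumerate(structure.labels):
        cols[str(lab)] = structure.R[:, j]
    if structure.sd is not None:
        cols["sd"] = structure.sd
    if structure.r_crit is not None:
        cols["r_crit"] = structure.r_crit
    pd.DataFrame(cols).to_csv(path, index=False)


# -- response CSV ------------------------------------------------------------


def read_responses(path) -> ItemResponseData:
    """Read respondent-by-item integer scores plus a ``criterion`` column."""
    df = pd.read_csv(path)
    if "criterion" not in df.columns:
        raise ParseError(f"{path}: a 'criterion' column is required")
    item_cols = [c for c in df.columns if c != "criterion"]
    if not item_cols:
        raise ParseError(f"{path}: no item columns found")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells are not supported")
    scores = df[item_cols].to_numpy()
    if not np.all(scores == scores.astype(int)):
        raise ParseError(f"{path}: item scores must be integers")
    return ItemResponseData(
        scores=scores.astype(int),
        criterion=df["criterion"].to_numpy(),
        labels=tuple(_coerce_label(c) for c in item_cols),
    )


def write_responses(data: ItemResponseData, path) -> None:
    df = pd.DataFrame(data.scores, columns=[str(lab) for lab in data.labels])
    df["criterion"] = data.criterion
    df.to_csv(path, index=False)


# -- simulation designs ------------------------------------------------------


def load_design(path) -> SimulationDesign:
    """Load a :class:`SimulationDesign` from YAML (or JSON) on disk."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    link = spec["crit_link"]
    return SimulationDesign(
        loadings=np.asarray(spec["loadings"], dtype=float),
        factor_corr=np.asarray(spec["factor_corr"], dtype=float),
        crit_link=CriterionLink(
            weights=np.asarray(link["weights"], dtype=float),
            noise_var=float(link["noise_var"]),
            prevalence=float(link["prevalence"]),
        ),
        n=int(spec["n"]),
        seed=int(spec.get("seed", 0)),
        thresholds=spec.get("thresholds"),
        labels=tuple(spec["labels"]) if "labels" in spec else None,
    )


# -- analysis reports --------------------------------------------------------


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


@dataclass(frozen=True)
class AnalysisReport:
    """Flat, JSON-serializable record of one analysis run.

    ``timestamp`` is excluded from equality so identical runs compare
    equal regardless of when they happened.
    """

    input: str
    mode: str
    operations: tuple
    results: dict
    warnings: tuple = ()
    version: str = ""
    seed: Optional[int] = None
    timestamp: Optional[str] = field(default=None, compare=False)

    def to_json(self) -> str:
        payload = {
            "input": self.input,
            "mode": self.mode,
            "operations": list(self.operations),
            "results": _jsonable(self.results),
            "warnings": list(self.warnings),
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(
            input=d["input"],
            mode=d["mode"],
            operations=tuple(d["operations"]),
            results=d["results"],
            warnings=tuple(d["warnings"]),
            version=d["version"],
            seed=d["seed"],
            timestamp=d.get("timestamp"),
        )


def write_report(report: AnalysisReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json() + "\n")


def rounded_pair(x: float, ndigits: int = 2) -> dict:
    """Report both full precision and the 2-dp headline convention."""
    return {"exact": float(x), "rounded": round(float(x), ndigits)}
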