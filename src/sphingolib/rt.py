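"""Segmented QSRR retention-time model.

Reverse-phase retention under a step-formed gradient is modelled by two
ordinary linear regressions on 2-D molecular descriptors, routed by XLogP:
the early-eluting segment ("A+B", isocratic and first gradient stage)
applies at XLogP <= 15.9, the late segment ("C", gentle gradient) at
XLogP >= 16.6, and the unweighted mean of both inside the open interval.
The published coefficient sets are shipped as the immutable ``paper-2017``
model; refitting (correlation prefilter + forward stepwise AIC selection)
is provided for new descriptor/RT datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "RTModel",
    "FitReport",
    "paper_2017",
    "predict_rt",
    "normalize_descriptor_name",
    "correlation_prefilter",
    "fit_stepwise",
    "split_by_segment",
]

# descriptor spellings tolerated on input (PaDEL vs. prose variants)
_DESCRIPTOR_SYNONYMS = {
    "atsc2 m": "ATSC2m",
    "atsc2m": "ATSC2m",
    "atsc2 v": "ATSC2v",
    "atsc2v": "ATSC2v",
    "xlogp": "XLogP",
    "sssch2": "SssCH2",
    "c2sp3": "C2SP3",
    "bic0": "BIC0",
    "lipoaffinityindex": "LipoaffinityIndex",
    "spmad_dzi": "SpMAD_Dzi",
}


def normalize_descriptor_name(name: str) -> str:
    """Canonical descriptor name: whitespace stripped, case-insensitive
    match against known synonyms (``'ATSC2 m'`` -> ``'ATSC2m'``)."""
    key = "".join(str(name).split()).lower()
    return _DESCRIPTOR_SYNONYMS.get(key, str(name).strip())


@dataclass(frozen=True)
class Segment:
    name: str
    descriptors: Tuple[str, ...]
    coefficients: Tuple[float, ...]
    intercept: float

    def predict(self, row: Mapping[str, float]) -> float:
        return self.intercept + sum(
            c * float(row[d]) for d, c in zip(self.descriptors, self.coefficients)
        )


@dataclass(frozen=True)
class RTModel:
    """Two-segment linear RT model with XLogP routing and boundary blending."""

    segments: Tuple[Segment, Segment]
    low_bound: float = 15.9
    high_bound: float = 16.6
    route_descriptor: str = "XLogP"

    @property
    def required_descriptors(self) -> Tuple[str, ...]:
        names: List[str] = [self.route_descriptor]
        for segment in self.segments:
            for d in segment.descriptors:
                if d not in names:
                    names.append(d)
        return tuple(names)

    def predict(self, descriptors: Mapping[str, float]) -> float:
        return predict_rt(descriptors, self)

    # -- JSON serialization ------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "low_bound": self.low_bound,
            "high_bound": self.high_bound,
            "route_descriptor": self.route_descriptor,
            "segments": [
                {
                    "name": s.name,
                    "descriptors": list(s.descriptors),
                    "coefficients": list(s.coefficients),
                    "intercept": s.intercept,
                }
                for s in self.segments
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RTModel":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        segments = tuple(
            Segment(
                name=s["name"],
                descriptors=tuple(s["descriptors"]),
                coefficients=tuple(float(c) for c in s["coefficients"]),
                intercept=float(s["intercept"]),
            )
            for s in payload["segments"]
        )
        return cls(
            segments=segments,  # type: ignore[arg-type]
            low_bound=float(payload["low_bound"]),
            high_bound=float(payload["high_bound"]),
            route_descriptor=payload["route_descriptor"],
        )


def paper_2017() -> RTModel:
    """The published coefficient sets (immutable builtin model).

    Early segment (XLogP <= 15.9):
        RT = -14 + 0.55 XLogP + 0.17 SssCH2 + 0.048 C2SP3 + 71 BIC0
             - 0.0022 ATSC2m + 0.00081 ATSC2v
    Late segment (XLogP >= 16.6):
        RT = 9.5 + 0.16 XLogP + 0.076 LipoaffinityIndex - 0.14 SpMAD_Dzi
             + 0.085 C2SP3
    """
    return RTModel(
        segments=(
            Segment(
                name="A+B",
                descriptors=("XLogP", "SssCH2", "C2SP3", "BIC0", "ATSC2m", "ATSC2v"),
                coefficients=(0.55, 0.17, 0.048, 71.0, -0.0022, 0.00081),
                intercept=-14.0,
            ),
            Segment(
                name="C",
                descriptors=("XLogP", "LipoaffinityIndex", "SpMAD_Dzi", "C2SP3"),
                coefficients=(0.16, 0.076, -0.14, 0.085),
                intercept=9.5,
            ),
        )
    )


BUILTIN_MODELS = {"paper-2017": paper_2017}


def predict_rt(descriptors: Mapping[str, float], model: Optional[RTModel] = None) -> float:
    """Predicted retention time in minutes for one descriptor row.

    Missing or non-finite required descriptors raise a ``ValueError`` that
    names them.  Predictions are not clamped to the gradient length.
    """
    model = model or paper_2017()
    row = {normalize_descriptor_name(k): v for k, v in dict(descriptors).items()}
    missing = [
        d
        for d in model.required_descriptors
        if d not in row or not math.isfinite(float(row[d]))
    ]
    if missing:
        raise ValueError(f"missing or non-finite descriptors: {', '.join(missing)}")
    xlogp = float(row[model.route_descriptor])
    early, late = model.segments
    if xlogp <= model.low_bound:
        return early.predict(row)
    if xlogp >= model.high_bound:
        return late.predict(row)
    return 0.5 * (early.predict(row) + late.predict(row))


# ---------------------------------------------------------------------------
# refitting pipeline
# ---------------------------------------------------------------------------


def correlation_prefilter(
    table: pd.DataFrame,
    rt: Sequence[float],
    threshold: float = 0.85,
) -> Tuple[List[str], Dict[str, List[str]]]:
    """Select descriptors with |Pearson r| >= threshold against RT.

    Constant ("uniform") columns and exact-duplicate ("redundant") columns
    are removed before correlation; the report lists both.  The absolute
    value is used because hydrophilicity descriptors anticorrelate with
    reverse-phase retention.
    """
    rt = np.asarray(rt, dtype=float)
    if len(table) < 3 or len(rt) < 3:
        raise ValueError("correlation prefilter needs at least 3 samples")
    if len(table) != len(rt):
        raise ValueError("descriptor table and RT vector differ in length")
    work = table.copy()
    work.columns = [normalize_descriptor_name(c) for c in work.columns]

    constant = [c for c in work.columns if work[c].nunique(dropna=False) <= 1]
    work = work.drop(columns=constant)
    duplicated_mask = work.T.duplicated()
    duplicate = list(work.columns[duplicated_mask])
    work = work.loc[:, ~duplicated_mask]

    selected: List[str] = []
    for column in work.columns:
        values = work[column].to_numpy(dtype=float)
        sd = values.std()
        if sd == 0:
            continue
        r = np.corrcoef(values, rt)[0, 1]
        if np.isfinite(r) and abs(r) >= threshold:
            selected.append(column)
    report = {"removed_constant": constant, "removed_duplicate": duplicate}
    return selected, report


@dataclass
class FitReport:
    """Outcome of a forward stepwise AIC fit for one segment."""

    selected: List[str]
    coefficients: Dict[str, float]  # includes "intercept"
    standard_errors: Dict[str, float]
    aic_trace: List[float]
    residual_sd: float
    n: int

    def to_segment(self, name: str) -> Segment:
        return Segment(
            name=name,
            descriptors=tuple(self.selected),
            coefficients=tuple(self.coefficients[d] for d in self.selected),
            intercept=self.coefficients["intercept"],
        )


def _ols_aic(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, float, float]:
    """OLS fit; returns (coefficients, RSS, AIC = n log(RSS/n) + 2p)."""
    n = len(y)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    p = X.shape[1]
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * p
    return beta, rss, aic


def fit_stepwise(table: pd.DataFrame, rt: Sequence[float]) -> FitReport:
    """Forward stepwise OLS with AIC selection (the R `step` convention).

    Starts from the intercept-only model; at each step the candidate whose
    addition minimises AIC (ties broken by descriptor name) is accepted,
    stopping when no addition lowers AIC.  The accepted AIC trace is
    strictly decreasing.
    """
    y = np.asarray(rt, dtype=float)
    n = len(y)
    if n <= 2:
        raise ValueError("stepwise fit needs more than 2 samples")
    work = table.copy()
    work.columns = [normalize_descriptor_name(c) for c in work.columns]
    candidates = sorted(work.columns)

    selected: List[str] = []
    X = np.ones((n, 1))
    _, rss, aic = _ols_aic(X, y)
    trace = [aic]
    while True:
        best: Optional[Tuple[float, str]] = None
        remaining = [c for c in candidates if c not in selected]
        if not remaining or n <= len(selected) + 2:
            break
        for name in remaining:
            X_try = np.column_stack([X, work[name].to_numpy(dtype=float)])
            _, _, aic_try = _ols_aic(X_try, y)
            if best is None or (aic_try, name) < best:
                best = (aic_try, name)
        if best is None or best[0] >= trace[-1]:
            break
        selected.append(best[1])
        X = np.column_stack([X, work[best[1]].to_numpy(dtype=float)])
        trace.append(best[0])

    import statsmodels.api as sm

    final = sm.OLS(y, X).fit()
    p = X.shape[1]
    dof = max(n - p, 1)
    residual_sd = math.sqrt(float(final.ssr) / dof)
    names = ["intercept"] + selected
    return FitReport(
        selected=selected,
        coefficients=dict(zip(names, (float(b) for b in final.params))),
        standard_errors=dict(zip(names, (float(s) for s in final.bse))),
        aic_trace=trace,
        residual_sd=residual_sd,
        n=n,
    )


def split_by_segment(
    table: pd.DataFrame,
    rt: Sequence[float],
    xlogp_ranges: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (5.0, 16.6),
        (15.9, 32.1),
    ),
) -> Tuple[Tuple[pd.DataFrame, np.ndarray], Tuple[pd.DataFrame, np.ndarray]]:
    """Split a training set into the two gradient segments by XLogP windows.

    The windows overlap by construction; rows inside the overlap appear in
    both subsets (narrow the ranges to assign them exclusively instead).
    The outer edges are open-ended: rows below the first window fall into
    the early segment, rows above the last into the late segment.
    """
    rt = np.asarray(rt, dtype=float)
    work = table.copy()
    work.columns = [normalize_descriptor_name(c) for c in work.columns]
    if "XLogP" not in work.columns:
        raise KeyError("descriptor table has no XLogP column")
    xlogp = work["XLogP"].to_numpy(dtype=float)
    (_, hi_early), (lo_late, _) = xlogp_ranges
    early = xlogp <= hi_early
    late = xlogp >= lo_late
    return (work.loc[early], rt[early]), (work.loc[late], rt[late])
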