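"""Library-based MS/MS identification.

Query features are gated by precursor m/z (and retention time when both the
query and the library record carry one), then scored against library spectra
with a cosine ("dot product") similarity on greedily paired peaks.  The
total score is the unweighted mean of the forward dot product, the reverse
dot product (query peaks unmatched by the library are ignored) and the
matched-diagnostic-ion fraction, each on a 0-100 scale; a feature is
accepted when the total reaches the cutoff (default 80).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .fragmentation import SpectrumRecord
from .rt import RTModel, predict_rt

__all__ = [
    "QueryFeature",
    "MatchConfig",
    "MatchResult",
    "dot_product_score",
    "identify",
    "attach_predicted_rt",
]


@dataclass
class QueryFeature:
    """One observed MS/MS feature: precursor, optional RT, and a peak list."""

    id: str
    precursor_mz: float
    polarity: str
    peaks: List[Tuple[float, float]]
    rt: Optional[float] = None


@dataclass(frozen=True)
class MatchConfig:
    ms1_tol: float = 0.01  # Da
    ms2_tol: float = 0.05  # Da
    rt_tol: float = 2.0  # minutes
    cutoff: float = 80.0  # percent

    def __post_init__(self) -> None:
        for name in ("ms1_tol", "ms2_tol", "rt_tol", "cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MatchResult:
    record_id: str
    class_code: str
    name: str
    dot_product: float
    reverse_dot_product: float
    matched_fraction: float
    precursor_error: float  # Da, query - library
    rt_error: Optional[float]  # minutes, query - library
    total_score: float
    accepted: bool


def _greedy_pairs(
    query: Sequence[Tuple[float, float]],
    library: Sequence[Tuple[float, float]],
    tol: float,
) -> List[Tuple[int, int]]:
    """Nearest-m/z greedy pairing within tolerance, each peak used once.

    Candidate pairs are taken in order of |delta m/z| with a symmetric,
    deterministic tie-break toward lower m/z.
    """
    candidates = []
    for qi, (qmz, _) in enumerate(query):
        for li, (lmz, _) in enumerate(library):
            delta = abs(qmz - lmz)
            if delta <= tol:
                candidates.append((delta, min(qmz, lmz), max(qmz, lmz), qi, li))
    candidates.sort()
    used_q, used_l, pairs = set(), set(), []
    for _, _, _, qi, li in candidates:
        if qi in used_q or li in used_l:
            continue
        used_q.add(qi)
        used_l.add(li)
        pairs.append((qi, li))
    return pairs


def _cosine(a: Sequence[float], b: Sequence[float]) -> float:
    num = sum(x * y for x, y in zip(a, b))
    norm = math.sqrt(sum(x * x for x in a)) * math.sqrt(sum(y * y for y in b))
    return num / norm if norm > 0 else 0.0


def dot_product_score(
    query_peaks: Sequence[Tuple[float, float]],
    library_peaks: Sequence[Tuple[float, float]],
    ms2_tol: float = 0.05,
) -> float:
    """Cosine similarity (0-100) over greedily paired peak intensities.

    Unpaired peaks on either side contribute zero-intensity counterparts,
    so the score is symmetric and reaches 100 only when paired intensities
    are proportional and nothing is unpaired.
    """
    if not query_peaks or not library_peaks:
        raise ValueError("peak lists must be non-empty")
    pairs = _greedy_pairs(query_peaks, library_peaks, ms2_tol)
    paired_q = {qi for qi, _ in pairs}
    paired_l = {li for _, li in pairs}
    a = [query_peaks[qi][1] for qi, li in pairs]
    b = [library_peaks[li][1] for qi, li in pairs]
    for qi, (_, intensity) in enumerate(query_peaks):
        if qi not in paired_q:
            a.append(intensity)
            b.append(0.0)
    for li, (_, intensity) in enumerate(library_peaks):
        if li not in paired_l:
            a.append(0.0)
            b.append(intensity)
    return 100.0 * _cosine(a, b)


def _reverse_dot_product(
    query_peaks: Sequence[Tuple[float, float]],
    library_peaks: Sequence[Tuple[float, float]],
    ms2_tol: float,
) -> Tuple[float, float]:
    """(reverse dot product 0-100, matched library-peak fraction 0-1)."""
    pairs = _greedy_pairs(query_peaks, library_peaks, ms2_tol)
    paired_l = {li for _, li in pairs}
    a = [query_peaks[qi][1] for qi, li in pairs]
    b = [library_peaks[li][1] for qi, li in pairs]
    for li, (_, intensity) in enumerate(library_peaks):
        if li not in paired_l:
            a.append(0.0)
            b.append(intensity)
    fraction = len(paired_l) / len(library_peaks) if library_peaks else 0.0
    return 100.0 * _cosine(a, b), fraction


def identify(
    query: QueryFeature,
    library: Iterable[SpectrumRecord],
    config: MatchConfig = MatchConfig(),
) -> List[MatchResult]:
    """Rank library records against one query feature.

    Records are prefiltered by polarity, precursor tolerance, and RT
    tolerance (only when both sides carry an RT); survivors are scored and
    sorted by total score (descending, ties by record id).  An empty result
    list means nothing passed the gates.
    """
    results: List[MatchResult] = []
    library_peaks_cache = {}
    for record in library:
        if record.polarity != query.polarity:
            continue
        precursor_error = query.precursor_mz - record.precursor_mz
        if abs(precursor_error) > config.ms1_tol:
            continue
        rt_error = None
        if query.rt is not None and record.rt is not None:
            rt_error = query.rt - record.rt
            if abs(rt_error) > config.rt_tol:
                continue
        lib_peaks = library_peaks_cache.get(id(record))
        if lib_peaks is None:
            lib_peaks = [(p.mz, float(p.intensity)) for p in record.peaks]
            library_peaks_cache[id(record)] = lib_peaks
        if not query.peaks or not lib_peaks:
            continue
        dot = dot_product_score(query.peaks, lib_peaks, config.ms2_tol)
        rev, fraction = _reverse_dot_product(query.peaks, lib_peaks, config.ms2_tol)
        total = (dot + rev + 100.0 * fraction) / 3.0
        results.append(
            MatchResult(
                record_id=record.record_id,
                class_code=record.class_code,
                name=record.name,
                dot_product=dot,
                reverse_dot_product=rev,
                matched_fraction=fraction,
                precursor_error=precursor_error,
                rt_error=rt_error,
                total_score=total,
                accepted=total >= config.cutoff,
            )
        )
    results.sort(key=lambda r: (-r.total_score, r.record_id))
    return results


def attach_predicted_rt(
    library: Sequence[SpectrumRecord],
    model: RTModel,
    descriptors: pd.DataFrame,
) -> List[SpectrumRecord]:
    """Attach model-predicted RTs to library records (in place).

    ``descriptors`` is indexed by species name (the record ``name`` field).
    Records without a row, or with missing/non-finite required descriptors,
    keep ``rt = None`` (with a warning) and will bypass the RT gate in
    :func:`identify`.
    """
    for record in library:
        if record.name not in descriptors.index:
            warnings.warn(f"no descriptor row for {record.name}; RT not attached")
            continue
        row: Mapping[str, float] = descriptors.loc[record.name].to_dict()
        try:
            record.rt = predict_rt(row, model)
        except ValueError as err:
            warnings.warn(f"{record.name}: {err}; RT not attached")
    return list(library)
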