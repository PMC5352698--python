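"""Deterministic synthetic test-input generators.

Noisy query spectra are drawn from library records with Gaussian m/z jitter,
multiplicative log-normal intensity noise and Bernoulli peak dropout; decoy
records shuffle m/z-to-intensity assignments while preserving the precursor.
RT training sets are standard-normal descriptor tables with a known linear
structure.  Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragmentation import Peak, SpectrumRecord
from .identification import QueryFeature

__all__ = ["perturb_spectrum", "synth_rt_dataset", "make_decoys"]


def perturb_spectrum(
    record: SpectrumRecord,
    mz_sigma: float = 0.002,
    intensity_cv: float = 0.2,
    dropout: float = 0.0,
    seed: int = 0,
) -> QueryFeature:
    """A noisy query drawn from a library record.

    m/z jitter is N(0, mz_sigma) per peak (precursor: mz_sigma/2); intensity
    noise is log-normal with the requested coefficient of variation; peaks
    drop out independently with probability ``dropout``, resampling the mask
    until at least one peak survives.
    """
    if mz_sigma < 0:
        raise ValueError("mz_sigma must be >= 0")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(record.peaks)
    if n == 0:
        raise ValueError("record has no peaks")
    keep = np.ones(n, dtype=bool)
    if dropout > 0:
        keep = rng.random(n) >= dropout
        while not keep.any():
            keep = rng.random(n) >= dropout
    sigma_log = math.sqrt(math.log(1.0 + intensity_cv**2)) if intensity_cv > 0 else 0.0
    peaks: List[Tuple[float, float]] = []
    for i, peak in enumerate(record.peaks):
        if not keep[i]:
            continue
        mz = peak.mz + rng.normal(0.0, mz_sigma) if mz_sigma > 0 else peak.mz
        intensity = float(peak.intensity)
        if sigma_log > 0:
            intensity *= math.exp(rng.normal(-0.5 * sigma_log**2, sigma_log))
        peaks.append((mz, intensity))
    precursor = record.precursor_mz
    if mz_sigma > 0:
        precursor += rng.normal(0.0, mz_sigma / 2.0)
    return QueryFeature(
        id=f"query:{record.record_id}",
        precursor_mz=precursor,
        polarity=record.polarity,
        rt=record.rt,
        peaks=peaks,
    )


def synth_rt_dataset(
    n: int,
    n_descriptors: int,
    true_coefficients: Dict[str, float],
    noise_sd: float,
    seed: int = 0,
    intercept: float = 0.0,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Descriptor table with known linear RT structure.

    Columns are the keys of ``true_coefficients`` followed by inert
    standard-normal filler descriptors up to ``n_descriptors``.
    ``rt = intercept + X @ beta + N(0, noise_sd)``.
    """
    if n_descriptors < len(true_coefficients):
        raise ValueError("n_descriptors smaller than the true coefficient count")
    if n <= n_descriptors + 2:
        raise ValueError(f"need n > {n_descriptors + 2} samples, got {n}")
    rng = np.random.default_rng(seed)
    names = list(true_coefficients) + [
        f"D{i:03d}" for i in range(n_descriptors - len(true_coefficients))
    ]
    X = rng.standard_normal((n, n_descriptors))
    table = pd.DataFrame(X, columns=names)
    beta = np.array([true_coefficients[name] for name in true_coefficients])
    rt = intercept + X[:, : len(beta)] @ beta
    if noise_sd > 0:
        rt = rt + rng.normal(0.0, noise_sd, size=n)
    return table, rt


def make_decoys(
    library: Sequence[SpectrumRecord], k: int, seed: int = 0
) -> List[SpectrumRecord]:
    """Precursor-preserving decoys: intensities cyclically reassigned among
    each record's m/z positions (a derangement for >= 2 peaks), flagged with
    ``comment['decoy'] = 'true'``."""
    if k > len(library):
        raise ValueError(f"k = {k} exceeds library size {len(library)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(library), size=k, replace=False) if k else []
    decoys: List[SpectrumRecord] = []
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        source = library[idx]
        n = len(source.peaks)
        # Sattolo shuffle: a uniform random cyclic permutation (no fixed points)
        perm = list(range(n))
        for i in range(n - 1, 0, -1):
            j = int(rng.integers(0, i))
            perm[i], perm[j] = perm[j], perm[i]
        peaks = [
            Peak(mz=source.peaks[i].mz, intensity=source.peaks[perm[i]].intensity)
            for i in range(n)
        ]
        decoys.append(
            replace(
                source,
                name=f"DECOY {source.name}",
                peaks=peaks,
                comment={**source.comment, "decoy": "true"},
                species=None,
            )
        )
    return decoys
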