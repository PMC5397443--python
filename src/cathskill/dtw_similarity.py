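"""Dynamic time warping repeatability of repeated recordings.

An operator repeats each cannulation task N times, giving N force (or
torque) recordings of different lengths.  Each recording is aligned by DTW
to the reference recording whose length is closest to the mean length, and
the mean of the N alignment costs is the operator's *average similarity
cost* for that task and channel — low cost means repeatable execution.

Alignment uses local cost |x_i - y_j|, the symmetric step set
{(1,0), (0,1), (1,1)} and a Sakoe–Chiba band of half-width
``ceil(band_fraction * max(len))``.  The accumulated cost is normalized by
the warping-path length by default so recordings of different durations
are comparable; the raw accumulated cost is also exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


__all__ = [
    "DTWAlignment",
    "RepeatabilityResult",
    "dtw_align",
    "select_reference",
    "average_similarity_cost",
]


class BandError(ValueError):
    """The Sakoe–Chiba band cannot connect the path corners."""


@dataclass(frozen=True)
class DTWAlignment:
    """A monotone warping path with its accumulated and normalized costs."""

    path: np.ndarray  # (K, 2) index pairs
    raw_cost: float
    normalized_cost: float


@dataclass(frozen=True)
class RepeatabilityResult:
    """Per-recording alignment costs C^i and their average (the
    repeatability measure); the reference aligns to itself at cost 0."""

    reference_index: int
    per_recording_costs: tuple[float, ...]
    average_cost: float
    channel: str


@njit(cache=False)
def _dtw_matrix(x: np.ndarray, y: np.ndarray, band: int) -> np.ndarray:
    n, m = x.shape[0], y.shape[0]
    D = np.full((n, m), np.inf)
    for i in range(n):
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band + 1
        if hi > m:
            hi = m
        for j in range(lo, hi):
            c = abs(x[i] - y[j])
            if i == 0 and j == 0:
                D[0, 0] = c
                continue
            best = np.inf
            if i > 0 and D[i - 1, j] < best:
                best = D[i - 1, j]
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            if i > 0 and j > 0 and D[i - 1, j - 1] < best:
                best = D[i - 1, j - 1]
            D[i, j] = c + best
    return D


def dtw_align(
    x: Sequence[float], y: Sequence[float], band_fraction: float = 0.1
) -> DTWAlignment:
    """Minimal-cost monotone alignment of two 1-D series.

    ``band_fraction`` in (0, 1] sets the Sakoe–Chiba half-width as a
    fraction of the longer series; the band must be at least as wide as
    the length difference, otherwise no path can reach the far corner.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("dtw_align requires non-empty series")
    if not (0 < band_fraction <= 1):
        raise ValueError("band_fraction must be in (0, 1]")
    n, m = x.size, y.size
    band = math.ceil(band_fraction * max(n, m))
    if band < abs(n - m):
        raise BandError(
            f"band half-width {band} cannot bridge length difference "
            f"{abs(n - m)}; increase band_fraction"
        )
    D = _dtw_matrix(x, y, band)
    # backtrack; ties prefer the diagonal step, then (i-1, j), then (i, j-1)
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((D[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((D[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((D[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
        path.append((i, j))
    path_arr = np.array(path[::-1], dtype=np.int64)
    raw = float(D[n - 1, m - 1])
    return DTWAlignment(
        path=path_arr, raw_cost=raw, normalized_cost=raw / path_arr.shape[0]
    )


def select_reference(recordings: Sequence[Sequence[float]]) -> int:
    """Index of the recording whose length is closest to the mean length;
    ties go to the lowest index."""
    if len(recordings) < 2:
        raise ValueError("select_reference needs at least 2 recordings")
    lengths = np.array([len(r) for r in recordings], dtype=float)
    return int(np.argmin(np.abs(lengths - lengths.mean())))


def average_similarity_cost(
    recordings: Sequence[Sequence[float]],
    channel: str = "force",
    band_fraction: float = 0.1,
    z_normalize: bool = False,
    normalized: bool = True,
) -> RepeatabilityResult:
    """Average DTW alignment cost of repeated recordings against the
    length-representative reference.

    ``z_normalize`` optionally standardizes each recording before
    alignment (off by default); ``normalized=False`` averages raw
    accumulated costs instead of path-length-normalized ones.

    Repeated runs can differ in length by more than the nominal band, in
    which case the band for that pair is widened to the minimum half-width
    that can connect the path corners.
    """
    ref = select_reference(recordings)
    series = [np.asarray(r, dtype=float) for r in recordings]
    if z_normalize:
        series = [
            (s - s.mean()) / sd if (sd := s.std()) > 0 else s - s.mean()
            for s in series
        ]
    costs = []
    for i, s in enumerate(series):
        if i == ref:
            costs.append(0.0)
            continue
        longer = max(s.size, series[ref].size)
        bf = max(band_fraction, (abs(s.size - series[ref].size) + 1) / longer)
        a = dtw_align(s, series[ref], min(bf, 1.0))
        costs.append(a.normalized_cost if normalized else a.raw_cost)
    return RepeatabilityResult(
        reference_index=ref,
        per_recording_costs=tuple(costs),
        average_cost=float(np.mean(costs)),
        channel=channel,
    )
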