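"""Weighted dependent dynamic time warping (DTW_D) with a Sakoe–Chiba band.

Dependent DTW aligns all nine angle channels along a *single* warping path,
appropriate when the channels are tightly coupled (as joint angles within one
limb are).  The local cost of matching sample ``i`` of cycle ``a`` to sample
``j`` of cycle ``b`` is the squared Euclidean distance between the weighted
channel vectors::

    c(i, j) = sum_m (w_m * (a_m[i] - b_m[j]))**2

Pelvis channels default to half the weight of the hip/knee/ankle/foot
channels so that shared pelvis kinematics do not dominate the between-side
dissimilarity.  The admissible region is a slope-corrected Sakoe–Chiba band

    |i * (M-1) - j * (N-1)| <= r * (N-1) * (M-1)

so that with ``r = 0.5`` the first sample of one cycle can only align with
samples in the first half of the other.  The band half-width is floored at
``max(N-1, M-1) / 2`` (the Bresenham bound), the smallest value for which
the corrected-diagonal corridor of lattice cells stays connected, so a path
always exists; for realistic cycle-length ratios this floor is inactive.
The returned distance is the raw accumulated cost along the optimal path:
no square root and no path-length normalization, which preserves duration
differences between cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .core_data import CHANNELS, DissimilarityMatrix, GaitCycle
from .preprocess import NormalizationStats, znormalize

#: Default channel weights: pelvis channels at half the distal-channel weight.
DEFAULT_WEIGHTS = np.array(
    [0.5 if ch.startswith("pelvis") else 1.0 for ch in CHANNELS]
)


@dataclass(frozen=True)
class DtwConfig:
    """Configuration of the dependent-DTW dissimilarity.

    Parameters
    ----------
    weights : ndarray, shape (9,)
        Per-channel weights applied to the series before squaring.
    window_fraction : float
        Sakoe–Chiba band half-width as a fraction of the (corrected) cycle
        length, in ``(0, 1]``.  1.0 disables the constraint for
        equal-length cycles.
    local_cost : str
        Only ``"squared_euclidean"`` is supported.
    """

    weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_WEIGHTS.copy()
    )
    window_fraction: float = 0.5
    local_cost: str = "squared_euclidean"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w <= 0):
            raise ValueError("all channel weights must be > 0")
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValueError("window_fraction must lie in (0, 1]")
        if self.local_cost != "squared_euclidean":
            raise ValueError(f"unsupported local cost {self.local_cost!r}")


def band_halfwidth(n: int, m: int, r: float) -> float:
    """Effective band half-width in cross-product units (see module doc)."""
    return max(r * (n - 1) * (m - 1), max(n - 1, m - 1) / 2.0) + 1e-9


@njit(cache=False)
def _banded_dtw(wa: np.ndarray, wb: np.ndarray, r: float) -> float:
    """Accumulate the DTW cost of two weighted series over the banded region.

    Local costs are computed cell-wise from the raw differences (exact zero
    for identical samples).  ``D(0,0) = c(0,0)``; steps are (1,0), (0,1),
    (1,1); out-of-band cells are +inf.
    """
    nch, n = wa.shape
    m = wb.shape[1]
    ni, mj = n - 1, m - 1
    R = r * ni * mj
    half = max(ni, mj) / 2.0
    if R < half:
        R = half
    R += 1e-9
    D = np.full((n, m), np.inf)
    for i in range(n):
        if ni == 0:
            jlo, jhi = 0, mj
        else:
            jlo = int(np.ceil((i * mj - R) / ni))
            jhi = int(np.floor((i * mj + R) / ni))
            if jlo < 0:
                jlo = 0
            if jhi > mj:
                jhi = mj
        for j in range(jlo, jhi + 1):
            c = 0.0
            for ch in range(nch):
                diff = wa[ch, i] - wb[ch, j]
                c += diff * diff
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
    return D[n - 1, m - 1]


def dtw_distance(
    a: np.ndarray,
    b: np.ndarray,
    weights: Sequence[float] | None = None,
    window_fraction: float = 0.5,
) -> float:
    """Dependent DTW distance between two multichannel series.

    ``a`` and ``b`` are arrays of shape (C, N) and (C, M) with a shared
    channel axis.  This is the channel-count-agnostic core used by
    :func:`dtw_dependent`; tests exercise it directly on 1–2 channel toys.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"channel mismatch: {a.shape[0]} vs {b.shape[0]} channels"
        )
    if weights is None:
        w = np.ones(a.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (a.shape[0],):
            raise ValueError("weights length must equal channel count")
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    return float(_banded_dtw(w[:, None] * a, w[:, None] * b, window_fraction))


def dtw_dependent(a: GaitCycle, b: GaitCycle, cfg: DtwConfig | None = None) -> float:
    """Dependent DTW distance between two (normalized) gait cycles."""
    if cfg is None:
        cfg = DtwConfig()
    return dtw_distance(a.angles, b.angles, cfg.weights, cfg.window_fraction)


def pairwise_matrix(
    cycles: Sequence[GaitCycle],
    stats: NormalizationStats,
    cfg: DtwConfig | None = None,
) -> DissimilarityMatrix:
    """All-pairs DTW_D dissimilarity matrix over Z-normalized iSCI cycles.

    Distances are computed for ``i < j`` only and mirrored across the
    diagonal (the cost and step pattern are symmetric); the diagonal is zero
    by construction.
    """
    if cfg is None:
        cfg = DtwConfig()
    cycles = list(cycles)
    if len(cycles) < 2:
        raise ValueError("need at least 2 cycles for a pairwise matrix")
    non_isci = [c.pattern_id for c in cycles if c.group != "iSCI"]
    if non_isci:
        raise ValueError(
            f"pairwise_matrix clusters iSCI cycles only; got control cycle(s) "
            f"{non_isci[:3]}"
        )
    ids = tuple(c.pattern_id for c in cycles)
    weighted = [
        cfg.weights[:, None] * znormalize(c, stats).angles for c in cycles
    ]
    n = len(cycles)
    values = np.zeros((n, n))
    r = cfg.window_fraction
    for i in range(n):
        for j in range(i + 1, n):
            d = _banded_dtw(weighted[i], weighted[j], r)
            values[i, j] = d
            values[j, i] = d
    return DissimilarityMatrix(pattern_ids=ids, values=values)
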