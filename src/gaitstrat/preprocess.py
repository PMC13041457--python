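"""Clinical-score quantization, weaker-leg assignment and Z-normalization.

Manual muscle test (MMT) grades carry "+"/"-" refinements that are mapped to
±0.5 around the base grade.  The weaker leg (WL) of a subject is the side
with the lower summed MMT score, with joint-wise tie-breaking in the order
hip, knee, ankle, hallux, and the right side as the final fallback.

Kinematic channels are Z-normalized with one global mean and standard
deviation per channel, pooled over every sample of every iSCI cycle (control
cycles contribute nothing to the statistics).  Normalization removes the
amplitude bias toward sagittal-plane channels before computing DTW
dissimilarities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    CHANNELS,
    MMT_JOINT_ORDER,
    MMT_MUSCLE_GROUPS,
    N_CHANNELS,
    GaitCycle,
    SubjectRecord,
)


class DegenerateChannelError(ValueError):
    """A channel is constant over the pooled data (zero variance)."""


_GRADE_RE = re.compile(r"^([0-5])([+-]?)$")


def quantize_mmt(grade: str) -> float:
    """Map an MMT grade string to a numeric score in [0, 5].

    The base digit carries the grade; a trailing ``+`` adds 0.5 and a
    trailing ``-`` subtracts 0.5 (so ``"3+"`` -> 3.5 and ``"3-"`` -> 2.5).
    Grades outside [0, 5] after refinement ("0-", "5+") are rejected.
    """
    m = _GRADE_RE.match(str(grade).strip())
    if m is None:
        raise ValueError(f"unparseable MMT grade: {grade!r}")
    score = float(m.group(1))
    if m.group(2) == "+":
        score += 0.5
    elif m.group(2) == "-":
        score -= 0.5
    if not 0.0 <= score <= 5.0:
        raise ValueError(f"MMT grade {grade!r} quantizes outside [0, 5]")
    return score


@dataclass(frozen=True)
class LegAssignment:
    """Weaker/stronger side of one subject with the per-side MMT sums."""

    subject_id: str
    weaker_side: str
    stronger_side: str
    sums: dict[str, float]

    def __post_init__(self) -> None:
        if self.weaker_side == self.stronger_side:
            raise ValueError("weaker and stronger side must differ")


def mmt_side_sum(s: SubjectRecord, side: str) -> float:
    """Summed quantized MMT score of one side (max 45 for 9 groups)."""
    grades = [g for (sd, _m), g in s.mmt_grades.items() if sd == side]
    return float(sum(quantize_mmt(g) for g in grades))


def mmt_joint_sum(s: SubjectRecord, side: str, joint: str) -> float:
    muscles = MMT_JOINT_ORDER[joint]
    return float(
        sum(
            quantize_mmt(g)
            for (sd, m), g in s.mmt_grades.items()
            if sd == side and m in muscles
        )
    )


def assign_weak_leg(s: SubjectRecord) -> LegAssignment:
    """Determine the weaker leg from summed MMT scores.

    The side with the strictly lower total sum is weaker.  On a tie, joint
    sums are compared in the order hip, knee, ankle, hallux and the first
    strict inequality decides; if every level ties, the right side is taken
    as the weaker leg.
    """
    for side in ("left", "right"):
        graded = {m for (sd, m) in s.mmt_grades if sd == side}
        if not graded:
            raise ValueError(f"subject {s.subject_id}: no MMT grades on {side}")
    sums = {side: mmt_side_sum(s, side) for side in ("left", "right")}
    if sums["left"] != sums["right"]:
        weaker = "left" if sums["left"] < sums["right"] else "right"
    else:
        weaker = "right"
        for joint in ("hip", "knee", "ankle", "hallux"):
            jl = mmt_joint_sum(s, "left", joint)
            jr = mmt_joint_sum(s, "right", joint)
            if jl != jr:
                weaker = "left" if jl < jr else "right"
                break
    stronger = "right" if weaker == "left" else "left"
    return LegAssignment(
        subject_id=s.subject_id, weaker_side=weaker,
        stronger_side=stronger, sums=sums,
    )


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel global mean/SD pooled over all iSCI samples.

    ``sigma`` uses the population (divide-by-N) convention; pooled sample
    counts are large enough that the distinction is negligible, but it is
    fixed here for exact reproducibility.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != (N_CHANNELS,) or sigma.shape != (N_CHANNELS,):
            raise ValueError("stats must hold exactly 9 (mu, sigma) pairs")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma))):
            raise ValueError("stats must be finite")
        if np.any(sigma <= 0):
            raise DegenerateChannelError("sigma must be > 0 for every channel")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(
            {"channel": CHANNELS, "mu": self.mu, "sigma": self.sigma}
        ).to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormalizationStats":
        df = pd.read_csv(path)
        df = df.set_index("channel").loc[list(CHANNELS)]
        return cls(mu=df["mu"].to_numpy(), sigma=df["sigma"].to_numpy())


def fit_normalization(cycles: Sequence[GaitCycle]) -> NormalizationStats:
    """Fit per-channel pooled mean/SD over iSCI cycles.

    Each cycle contributes all of its samples, so longer cycles weigh more
    (sample pooling, not an average of per-cycle means).  Control cycles are
    rejected: the reference statistics come from the patient group only.
    """
    isci = [c for c in cycles if c.group == "iSCI"]
    if not isci:
        raise ValueError("need at least one iSCI cycle to fit normalization")
    pooled = np.concatenate([c.angles for c in isci], axis=1)  # (9, total)
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 pooled samples per channel")
    mu = pooled.mean(axis=1)
    sigma = pooled.std(axis=1)  # population convention (ddof=0)
    if np.any(sigma == 0):
        bad = [CHANNELS[i] for i in np.flatnonzero(sigma == 0)]
        raise DegenerateChannelError(
            f"constant channel(s) in pooled data: {', '.join(bad)}"
        )
    return NormalizationStats(mu=mu, sigma=sigma)


def znormalize(c: GaitCycle, stats: NormalizationStats) -> GaitCycle:
    """Return a copy of the cycle with each channel mapped to (g - mu)/sigma."""
    z = (c.angles - stats.mu[:, None]) / stats.sigma[:, None]
    return replace(c, angles=z)


def znormalize_all(cycles: Iterable[GaitCycle],
                   stats: NormalizationStats) -> list[GaitCycle]:
    return [znormalize(c, stats) for c in cycles]
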