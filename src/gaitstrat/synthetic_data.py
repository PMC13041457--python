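"""Synthetic gait cohorts with planted cluster structure.

The generator emulates the study conditions this pipeline is built for: a
cohort of subjects with incomplete spinal cord injury (28 by default, two
sides each, five cycles per side = 280 cycles) plus a non-disabled control
group (21 subjects), with per-side archetypes planted so that every pipeline
stage — normalization, DTW clustering, feature discrimination, clinical
characterization, correlation recovery — can be tested end to end without
any real motion-capture data.

Each of the nine channels has a control template built as a low-order
harmonic series (offset plus a few sine/cosine terms) fitted through
canonical gait key points, with one non-harmonic element: a narrow pre-swing
plantarflexion burst on the ankle channel, whose depth is the natural handle
for the "reduced push-off" deviation shared by the slower archetypes.
Archetypes deviate from control through per-channel offsets and amplitude
scalings, a circular phase delay of the hip-flexion curve (late swing peak),
attenuation of the plantarflexion burst, and longer cycle durations.  The
magnitudes encode the qualitative orderings of the six cluster portraits
(e.g. the slowest archetype walks with persistent knee flexion, a strongly
delayed hip-flexion peak and cycles roughly three times as long as control);
matching any real cohort's medians is explicitly out of scope.

Clinical covariates (MMT grades, WISCI II, sex, walking aids, spasticity,
injury levels) are sampled from archetype-specific categorical
distributions, and walking speed and step length follow linear-plus-noise
couplings to the ankle plantarflexion angle at toe-off, calibrated by
simulation so that the pooled side-median rank correlation between
plantarflexion and speed lands near 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

from .core_data import (
    CHANNELS,
    GaitCycle,
    SubjectRecord,
    TemporospatialRecord,
)

# ---------------------------------------------------------------------------
# control templates: harmonic series through canonical key points
# ---------------------------------------------------------------------------

#: (cycle fraction, degrees) key points per channel; toe-off near 0.60.
_KEYPOINTS: Mapping[str, list[tuple[float, float]]] = {
    "pelvis_tilt": [(0.0, 12), (0.12, 11), (0.3, 13), (0.45, 11.5),
                    (0.62, 13), (0.8, 11), (0.9, 11.5)],
    "pelvis_obliquity": [(0.0, 0), (0.1, 3), (0.3, 1), (0.5, -3),
                         (0.6, -4), (0.8, 0), (0.92, 1)],
    "pelvis_rotation": [(0.0, 5), (0.25, 0), (0.5, -5), (0.75, 0),
                        (0.9, 3)],
    "hip_flexion": [(0.0, 30), (0.1, 25), (0.3, 5), (0.5, -8),
                    (0.55, -10), (0.65, 5), (0.85, 32), (0.95, 30)],
    "hip_adduction": [(0.0, 0), (0.15, 5), (0.45, 3), (0.6, -2),
                      (0.75, -5), (0.9, -1)],
    "hip_rotation": [(0.0, 0), (0.2, 3), (0.45, 3), (0.6, -1),
                     (0.75, -6), (0.9, -3)],
    "knee_flexion": [(0.0, 5), (0.15, 18), (0.4, 5), (0.55, 25),
                     (0.6, 38), (0.72, 65), (0.85, 30), (0.95, 6)],
    "ankle_dorsiflexion": [(0.0, 0), (0.1, -4), (0.3, 8), (0.5, 12),
                           (0.62, 8), (0.75, 2), (0.9, 1)],
    "foot_progression": [(0.0, -6), (0.2, -7), (0.4, -6.5), (0.6, -5),
                         (0.8, -6.5)],
}

_N_HARMONICS = {"hip_flexion": 3, "knee_flexion": 3}
_DEFAULT_HARMONICS = 2

#: Depth (degrees) of the control pre-swing plantarflexion burst.
PF_BURST_DEPTH = 20.0
#: Width of the burst as a fraction of the cycle.
PF_BURST_WIDTH = 0.06


def _fit_harmonics(points: Sequence[tuple[float, float]], n_harm: int) -> np.ndarray:
    u = np.array([p[0] for p in points])
    v = np.array([p[1] for p in points])
    cols = [np.ones_like(u)]
    for k in range(1, n_harm + 1):
        cols.append(np.cos(2 * np.pi * k * u))
        cols.append(np.sin(2 * np.pi * k * u))
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    return coef


_COEFFS = {
    ch: _fit_harmonics(pts, _N_HARMONICS.get(ch, _DEFAULT_HARMONICS))
    for ch, pts in _KEYPOINTS.items()
}


def _eval_harmonics(coef: np.ndarray, u: np.ndarray) -> np.ndarray:
    n_harm = (len(coef) - 1) // 2
    out = np.full_like(u, coef[0], dtype=float)
    for k in range(1, n_harm + 1):
        out += coef[2 * k - 1] * np.cos(2 * np.pi * k * u)
        out += coef[2 * k] * np.sin(2 * np.pi * k * u)
    return out


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted gait archetype: shape deviations plus covariate models.

    ``offsets`` add degrees to a channel; ``amp_scale`` scales a channel's
    excursion about its cycle mean; ``hip_peak_delay`` circularly delays the
    hip-flexion curve (fraction of cycle); ``pf_attenuation`` reduces the
    pre-swing plantarflexion burst depth (degrees).  ``speed`` and
    ``step_length`` follow ``a + b * (plantarflexion at toe-off) + noise``.
    MMT entries map muscle group -> [(grade string, probability), ...].
    """

    name: str
    offsets: Mapping[str, float] = field(default_factory=dict)
    amp_scale: Mapping[str, float] = field(default_factory=dict)
    hip_peak_delay: float = 0.0
    pf_attenuation: float = 0.0
    duration_mean: float = 1.05
    duration_sd: float = 0.05
    stance_fraction: float = 0.60
    speed_intercept: float = 1.07
    speed_slope: float = 0.015
    speed_sd: float = 0.08
    step_intercept: float = 0.58
    step_slope: float = 0.008
    step_sd: float = 0.04
    step_width_mean: float = 0.125
    step_width_sd: float = 0.02
    mmt: Mapping[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    wisci_choices: tuple[tuple[int, float], ...] = ((20, 1.0),)
    sex_p_female: float = 0.4
    aid_choices: tuple[tuple[str, float], ...] = (("barefoot", 1.0),)
    spasticity_p: float = 0.0
    mli_choices: tuple[tuple[str, float], ...] = (("thoracic", 1.0),)
    sli_choices: tuple[tuple[str, float], ...] = (("thoracic", 1.0),)

    def __post_init__(self) -> None:
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be > 0")
        if self.speed_slope < 0 or self.step_slope < 0:
            raise ValueError("temporospatial slopes must be >= 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")


_HIGH = (("5", 0.6), ("4+", 0.3), ("4", 0.1))
_MID = (("4", 0.4), ("3+", 0.3), ("3", 0.3))
_LOW = (("2", 0.5), ("2+", 0.3), ("3", 0.2))

_MMT_GROUPS = (
    "hip_flexion", "hip_extension", "hip_abduction", "hip_adduction",
    "knee_flexion", "knee_extension", "ankle_dorsiflexion",
    "ankle_plantarflexion", "hallux_extension",
)


def _mmt_profile(default, **overrides):
    prof = {g: default for g in _MMT_GROUPS}
    prof.update(overrides)
    return prof


#: Severity ordering used to pick the subject-level archetype of a subject
#: whose two sides carry different archetypes.
SEVERITY_ORDER = ("control", "green", "pink", "blue", "violet", "orange",
                  "cactus")


def default_archetypes() -> list[ArchetypeSpec]:
    """The control archetype plus six impaired gait archetypes.

    The impaired archetypes qualitatively mirror recurring post-injury gait
    portraits: mild internal hip rotation with slightly flexed knees
    (green); mildly reduced swing knee/ankle excursions (pink); absent hip
    extension with excess stance dorsiflexion and weak push-off (violet);
    reduced dorsiflexion range with a delayed hip-flexion peak (blue);
    severely restricted swing knee range and push-off, slow (orange); and
    persistent knee flexion with a strongly delayed hip-flexion peak over
    much longer cycles (cactus).
    """
    return [
        ArchetypeSpec(
            name="control",
            duration_mean=1.05, duration_sd=0.04,
            speed_intercept=1.07, speed_sd=0.07,
            step_intercept=0.59, step_sd=0.035,
            step_width_mean=0.125,
            mmt=_mmt_profile((("5", 1.0),)),
            sex_p_female=0.3,
            mli_choices=(("intact", 1.0),), sli_choices=(("intact", 1.0),),
        ),
        ArchetypeSpec(
            name="green",
            offsets={"hip_rotation": 10.0, "knee_flexion": 5.0},
            duration_mean=1.08, duration_sd=0.05,
            speed_intercept=0.97, speed_sd=0.08,
            step_intercept=0.56, step_sd=0.04,
            step_width_mean=0.13,
            mmt=_mmt_profile(_HIGH),
            wisci_choices=((20, 1.0),),
            sex_p_female=0.22,
            aid_choices=(("barefoot", 1.0),),
            spasticity_p=0.22,
            mli_choices=(("thoracic", 0.3), ("lumbar", 0.2),
                         ("sacral", 0.2), ("intact", 0.3)),
            sli_choices=(("thoracic", 0.6), ("lumbar", 0.3), ("sacral", 0.1)),
        ),
        ArchetypeSpec(
            name="pink",
            offsets={"foot_progression": 7.0, "pelvis_obliquity": -3.0},
            amp_scale={"knee_flexion": 0.8, "ankle_dorsiflexion": 0.8},
            duration_mean=1.14, duration_sd=0.05,
            speed_intercept=0.95, speed_sd=0.08,
            step_intercept=0.55, step_sd=0.04,
            step_width_mean=0.14,
            mmt=_mmt_profile(_HIGH),
            wisci_choices=((20, 1.0),),
            sex_p_female=0.77,
            aid_choices=(("barefoot", 1.0),),
            spasticity_p=0.23,
            mli_choices=(("thoracic", 0.3), ("lumbar", 0.2),
                         ("sacral", 0.2), ("intact", 0.3)),
            sli_choices=(("thoracic", 0.6), ("lumbar", 0.3), ("sacral", 0.1)),
        ),
        ArchetypeSpec(
            name="violet",
            offsets={"hip_flexion": 12.0, "knee_flexion": 8.0,
                     "ankle_dorsiflexion": 8.0, "pelvis_tilt": 5.0},
            pf_attenuation=7.0,
            duration_mean=1.35, duration_sd=0.06,
            speed_intercept=0.85, speed_sd=0.08,
            step_intercept=0.54, step_sd=0.04,
            step_width_mean=0.17,
            mmt=_mmt_profile(_MID, ankle_plantarflexion=_LOW),
            wisci_choices=((20, 0.6), (19, 0.4)),
            sex_p_female=0.10,
            aid_choices=(("barefoot", 0.8), ("shoes", 0.2)),
            spasticity_p=0.20,
            mli_choices=(("thoracic", 0.5), ("lumbar", 0.3), ("intact", 0.2)),
            sli_choices=(("thoracic", 0.7), ("lumbar", 0.3)),
        ),
        ArchetypeSpec(
            name="blue",
            amp_scale={"ankle_dorsiflexion": 0.62},
            hip_peak_delay=0.09,
            pf_attenuation=9.0,
            duration_mean=1.30, duration_sd=0.06,
            speed_intercept=0.73, speed_sd=0.08,
            step_intercept=0.50, step_sd=0.04,
            step_width_mean=0.155,
            mmt=_mmt_profile(
                _MID,
                ankle_plantarflexion=(("2", 0.3), ("2+", 0.2), ("3", 0.2),
                                      ("4", 0.2), ("5", 0.1)),
            ),
            wisci_choices=((20, 0.69), (19, 0.12), (16, 0.10), (13, 0.09)),
            sex_p_female=0.38,
            aid_choices=(("barefoot", 0.81), ("crutches+", 0.13),
                         ("walker+", 0.06)),
            spasticity_p=0.38,
            mli_choices=(("thoracic", 0.5), ("lumbar", 0.3), ("intact", 0.2)),
            sli_choices=(("cervical", 0.1), ("thoracic", 0.6),
                         ("lumbar", 0.3)),
        ),
        ArchetypeSpec(
            name="orange",
            offsets={"ankle_dorsiflexion": 6.0},
            amp_scale={"knee_flexion": 0.45, "ankle_dorsiflexion": 0.55,
                       "hip_flexion": 0.7},
            pf_attenuation=15.0,
            duration_mean=1.75, duration_sd=0.08,
            speed_intercept=0.73, speed_sd=0.08,
            step_intercept=0.50, step_sd=0.04,
            step_width_mean=0.11,
            mmt=_mmt_profile(_MID, ankle_plantarflexion=(("2", 0.7),
                                                         ("2+", 0.3))),
            wisci_choices=((20, 0.4), (19, 0.4), (13, 0.1), (12, 0.1)),
            sex_p_female=0.20,
            aid_choices=(("barefoot", 0.4), ("walker+", 0.6)),
            spasticity_p=0.0,
            mli_choices=(("thoracic", 0.6), ("lumbar", 0.4)),
            sli_choices=(("thoracic", 0.7), ("lumbar", 0.3)),
        ),
        ArchetypeSpec(
            name="cactus",
            offsets={"knee_flexion": 25.0, "hip_flexion": 20.0,
                     "pelvis_tilt": 6.0},
            amp_scale={"knee_flexion": 0.6, "hip_flexion": 0.6},
            hip_peak_delay=0.10,
            pf_attenuation=14.0,
            duration_mean=3.4, duration_sd=0.25,
            stance_fraction=0.65,
            speed_intercept=0.43, speed_sd=0.07,
            step_intercept=0.36, step_sd=0.035,
            step_width_mean=0.19,
            mmt=_mmt_profile(_LOW, ankle_plantarflexion=(("2", 1.0),)),
            wisci_choices=((20, 0.33), (12, 0.33), (9, 0.34)),
            sex_p_female=0.0,
            aid_choices=(("barefoot", 0.33), ("crutches", 0.67)),
            spasticity_p=1.0,
            mli_choices=(("thoracic", 0.7), ("lumbar", 0.3)),
            sli_choices=(("cervical", 0.2), ("thoracic", 0.8)),
        ),
    ]


#: Default per-side archetype layout for a 28-subject cohort: 21 symmetric
#: subjects plus 7 asymmetric ones, giving side counts blue 16, pink 13,
#: violet 10, green 9, orange 5, cactus 3 (56 sides, 280 cycles at 5/side).
_DEFAULT_PAIRS_28 = (
    [("blue", "blue")] * 6
    + [("pink", "pink")] * 5
    + [("violet", "violet")] * 4
    + [("green", "green")] * 3
    + [("orange", "orange")] * 2
    + [("cactus", "cactus")] * 1
    + [
        ("violet", "cactus"),
        ("blue", "violet"),
        ("blue", "green"),
        ("blue", "orange"),
        ("pink", "blue"),
        ("pink", "green"),
        ("pink", "green"),
    ]
)


def default_side_archetypes(n_subjects: int = 28) -> list[tuple[str, str]]:
    """(left, right) archetype names per subject, cycling the default layout."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    reps = -(-n_subjects // len(_DEFAULT_PAIRS_28))
    return (list(_DEFAULT_PAIRS_28) * reps)[:n_subjects]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings.

    Channel noise is low-pass-filtered Gaussian noise rescaled to
    ``noise_sd`` degrees; ``warp_strength`` bounds the deviation of the
    random monotone time warp from identity and also scales cycle-to-cycle
    duration variability, so setting noise and warp to zero makes all
    cycles of a side identical.
    """

    n_subjects: int = 28
    n_controls: int = 21
    cycles_per_side: int = 5
    sampling_rate: float = 100.0
    noise_sd: float = 1.5
    noise_cutoff_hz: float = 6.0
    warp_strength: float = 0.04
    side_offset_jitter_sd: float = 1.2
    side_amp_jitter_sd: float = 0.04
    pf_jitter_sd: float = 2.0
    seed: int = 0
    side_archetypes: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.cycles_per_side < 1:
            raise ValueError("n_subjects and cycles_per_side must be >= 1")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        if self.noise_sd < 0 or self.warp_strength < 0:
            raise ValueError("noise_sd and warp_strength must be >= 0")


@dataclass(frozen=True)
class Cohort:
    """Generated cohort: cycles, temporospatial records, subjects, labels."""

    cycles: tuple[GaitCycle, ...]
    temporospatial: tuple[TemporospatialRecord, ...]
    subjects: tuple[SubjectRecord, ...]
    planted: pd.DataFrame  # pattern_id, subject_id, side, archetype

    @property
    def isci_cycles(self) -> list[GaitCycle]:
        return [c for c in self.cycles if c.group == "iSCI"]

    @property
    def control_cycles(self) -> list[GaitCycle]:
        return [c for c in self.cycles if c.group == "control"]


def _sample(rng: np.random.Generator, choices) -> object:
    values = [v for v, _p in choices]
    probs = np.array([p for _v, p in choices], dtype=float)
    probs = probs / probs.sum()
    return values[rng.choice(len(values), p=probs)]


def _monotone_warp(rng: np.random.Generator, strength: float):
    """Random monotone map of [0,1] onto itself, ~``strength`` from identity."""
    if strength <= 0:
        return lambda u: u
    knots = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    jitter = rng.uniform(-strength, strength, size=3)
    inner = np.sort(knots[1:4] + jitter)
    inner = np.clip(inner, 0.02, 0.98)
    return PchipInterpolator(knots, np.concatenate(([0.0], inner, [1.0])))


def _lowpass_noise(rng, n, sd, cutoff, fs):
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    nyq = fs / 2.0
    wn = min(cutoff / nyq, 0.99)
    b, a = butter(2, wn)
    smooth = filtfilt(b, a, white)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def _evaluate_cycle(
    arch: ArchetypeSpec,
    u: np.ndarray,
    side_offsets: Mapping[str, float],
    side_amps: Mapping[str, float],
    pf_depth: float,
) -> np.ndarray:
    angles = np.empty((len(CHANNELS), len(u)))
    for m, ch in enumerate(CHANNELS):
        coef = _COEFFS[ch]
        uu = u
        if ch == "hip_flexion" and arch.hip_peak_delay:
            uu = (u - arch.hip_peak_delay) % 1.0
        base = _eval_harmonics(coef, uu)
        a0 = coef[0]
        amp = arch.amp_scale.get(ch, 1.0) * side_amps.get(ch, 1.0)
        val = a0 + amp * (base - a0)
        if ch == "ankle_dorsiflexion":
            depth = max(0.0, amp * pf_depth)
            val = val - depth * np.exp(
                -((u - arch.stance_fraction) / PF_BURST_WIDTH) ** 2
            )
        angles[m] = val + arch.offsets.get(ch, 0.0) + side_offsets.get(ch, 0.0)
    return angles


def generate_cohort(
    cfg: CohortConfig | None = None,
    archetypes: Sequence[ArchetypeSpec] | None = None,
) -> Cohort:
    """Generate a full synthetic cohort (deterministic given the seed)."""
    if cfg is None:
        cfg = CohortConfig()
    if archetypes is None:
        archetypes = default_archetypes()
    arch_by_name = {a.name: a for a in archetypes}
    pairs = (list(cfg.side_archetypes) if cfg.side_archetypes is not None
             else default_side_archetypes(cfg.n_subjects))
    if len(pairs) != cfg.n_subjects:
        raise ValueError("side_archetypes must list one pair per subject")
    rng = np.random.default_rng(cfg.seed)

    cycles: list[GaitCycle] = []
    ts: list[TemporospatialRecord] = []
    subjects: list[SubjectRecord] = []
    planted_rows: list[dict] = []

    def severity(name: str) -> int:
        return SEVERITY_ORDER.index(name) if name in SEVERITY_ORDER else 99

    def make_subject(sid: str, left: str, right: str, group: str):
        worse = max((left, right), key=severity)
        arch = arch_by_name[worse]
        grades = {}
        for side, name in (("left", left), ("right", right)):
            a = arch_by_name[name]
            for muscle, dist in a.mmt.items():
                grades[(side, muscle)] = str(_sample(rng, dist))
        subjects.append(SubjectRecord(
            subject_id=sid,
            sex="F" if rng.random() < arch.sex_p_female else "M",
            group=group,
            walking_aid=str(_sample(rng, arch.aid_choices)),
            spasticity_present=bool(rng.random() < arch.spasticity_p),
            wisci2=int(_sample(rng, arch.wisci_choices)),
            mli=str(_sample(rng, arch.mli_choices)),
            sli=str(_sample(rng, arch.sli_choices)),
            mmt_grades=grades,
        ))

    def make_side(sid: str, side: str, arch_name: str, group: str):
        arch = arch_by_name[arch_name]
        side_offsets = {
            ch: rng.normal(0.0, cfg.side_offset_jitter_sd) for ch in CHANNELS
        }
        side_amps = {
            ch: max(0.2, rng.normal(1.0, cfg.side_amp_jitter_sd))
            for ch in CHANNELS
        }
        pf_depth = max(
            0.0,
            PF_BURST_DEPTH - arch.pf_attenuation
            + rng.normal(0.0, cfg.pf_jitter_sd),
        )
        side_duration = max(0.4, rng.normal(arch.duration_mean,
                                            arch.duration_sd))
        for k in range(1, cfg.cycles_per_side + 1):
            dur = side_duration * (
                1.0 + 0.5 * cfg.warp_strength * rng.standard_normal()
            )
            T = max(40, int(round(dur * cfg.sampling_rate)))
            toe = int(np.clip(round(arch.stance_fraction * T), 1, T - 1))
            u = np.arange(T) / T
            warp = _monotone_warp(rng, cfg.warp_strength)
            angles = _evaluate_cycle(
                arch, np.asarray(warp(u)), side_offsets, side_amps, pf_depth
            )
            if cfg.noise_sd > 0:
                for m in range(len(CHANNELS)):
                    angles[m] += _lowpass_noise(
                        rng, T, cfg.noise_sd, cfg.noise_cutoff_hz,
                        cfg.sampling_rate,
                    )
            cyc = GaitCycle(
                subject_id=sid, side=side, cycle_index=k, angles=angles,
                toe_off_index=toe, sampling_rate=cfg.sampling_rate,
                group=group,
            )
            cycles.append(cyc)
            pf = -angles[CHANNELS.index("ankle_dorsiflexion")][toe]
            speed = max(0.05, arch.speed_intercept + arch.speed_slope * pf
                        + rng.normal(0.0, arch.speed_sd))
            step = max(0.05, arch.step_intercept + arch.step_slope * pf
                       + rng.normal(0.0, arch.step_sd))
            width = max(0.02, rng.normal(arch.step_width_mean,
                                         arch.step_width_sd))
            ts.append(TemporospatialRecord(
                subject_id=sid, side=side, cycle_index=k,
                walking_speed=speed, step_length=step, step_width=width,
            ))
            planted_rows.append({
                "pattern_id": cyc.pattern_id, "subject_id": sid,
                "side": side, "cycle_index": k, "archetype": arch_name,
            })

    for i, (left, right) in enumerate(pairs):
        sid = f"S{i + 1:02d}"
        for name in (left, right):
            if name not in arch_by_name:
                raise ValueError(f"unknown archetype {name!r}")
        make_subject(sid, left, right, "iSCI")
        make_side(sid, "left", left, "iSCI")
        make_side(sid, "right", right, "iSCI")

    for i in range(cfg.n_controls):
        sid = f"C{i + 1:02d}"
        make_subject(sid, "control", "control", "control")
        make_side(sid, "left", "control", "control")
        make_side(sid, "right", "control", "control")

    return Cohort(
        cycles=tuple(cycles), temporospatial=tuple(ts),
        subjects=tuple(subjects),
        planted=pd.DataFrame(planted_rows),
    )


def planted_correlation_check(cohort: Cohort) -> float:
    """Spearman rho between side-median plantarflexion at toe-off and speed.

    Computed over the impaired sides only, mirroring the correlation stage
    of the analysis pipeline.
    """
    from .stats import spearman

    rows = []
    ts_by_key = {r.keys: r for r in cohort.temporospatial}
    for c in cohort.isci_cycles:
        pf = -c.channel("ankle_dorsiflexion")[c.toe_off_index]
        speed = ts_by_key[(c.subject_id, c.side, c.cycle_index)].walking_speed
        rows.append({"subject_id": c.subject_id, "side": c.side,
                     "pf": pf, "speed": speed})
    df = pd.DataFrame(rows)
    med = df.groupby(["subject_id", "side"])[["pf", "speed"]].median()
    return spearman(med["pf"].to_numpy(), med["speed"].to_numpy()).rho
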