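"""Clinically meaningful kinematic features extracted per gait cycle.

Each feature is a (channel, statistic, phase) triple evaluated on the *raw*
angle channels in degrees (never on Z-normalized data).  Phases follow the
half-open stance/swing convention: stance = samples ``[0, toe_off)``, swing
= ``[toe_off, T)``.  Timing features are absolute seconds from the start of
the cycle, so cycle-duration differences show up in them directly.

The default registry has 27 features: the ten named descriptors that
dominate the cluster-vs-control explanations (e.g. ankle plantarflexion at
toe-off, time of maximum hip flexion in swing) padded with systematic
per-channel stance means, swing means and full-cycle ranges.  The registry
is file-overridable (YAML), so a different 27-feature catalogue can be
swapped in without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_data import CHANNELS, GaitCycle

logger = logging.getLogger(__name__)

STATISTICS = ("mean", "min", "max", "range", "value_at_event", "time_of_max")
PHASES = ("stance", "swing", "full_cycle", "toe_off")


@dataclass(frozen=True)
class FeatureDefinition:
    """One named scalar feature of a gait cycle.

    ``sign`` multiplies the extracted value; it is used only to report
    clinically conventional polarities (e.g. plantarflexion positive at
    toe-off while the channel stores dorsiflexion positive).
    """

    name: str
    channel: str
    statistic: str
    phase: str
    sign: float = 1.0
    note: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if (self.statistic == "value_at_event") != (self.phase == "toe_off"):
            raise ValueError(
                "value_at_event and phase 'toe_off' must be used together"
            )
        if self.statistic == "time_of_max" and self.phase == "toe_off":
            raise ValueError("time_of_max needs a window phase")


def _window(c: GaitCycle, phase: str) -> tuple[int, int]:
    if phase == "stance":
        return 0, c.toe_off_index
    if phase == "swing":
        return c.toe_off_index, c.n_samples
    if phase == "full_cycle":
        return 0, c.n_samples
    raise ValueError(f"phase {phase!r} has no window")


def extract_feature(c: GaitCycle, f: FeatureDefinition) -> float:
    """Evaluate one feature definition on one cycle (raw degrees/seconds)."""
    x = c.channel(f.channel)
    if f.statistic == "value_at_event":
        return float(f.sign * x[c.toe_off_index])
    lo, hi = _window(c, f.phase)
    if hi <= lo:
        raise ValueError(
            f"empty {f.phase} window for cycle {c.pattern_id}"
        )
    w = x[lo:hi]
    if f.statistic == "mean":
        v = w.mean()
    elif f.statistic == "min":
        v = w.min()
    elif f.statistic == "max":
        v = w.max()
    elif f.statistic == "range":
        v = w.max() - w.min()
    elif f.statistic == "time_of_max":
        # absolute sample index of the window max, in seconds from cycle start
        v = (lo + int(np.argmax(w))) / c.sampling_rate
    else:  # pragma: no cover - guarded by FeatureDefinition
        raise ValueError(f.statistic)
    return float(f.sign * v)


def extract_features(
    c: GaitCycle, registry: Sequence[FeatureDefinition]
) -> np.ndarray:
    """Feature vector for one cycle, ordered as the registry."""
    return np.array([extract_feature(c, f) for f in registry])


def default_registry() -> list[FeatureDefinition]:
    """The default 27-feature catalogue.

    The first ten entries are the named features that recur as the top
    cluster-vs-control discriminators; the remainder are systematic
    per-channel descriptors (stance mean, swing mean, full-cycle range)
    completing the set of 27.
    """
    named = [
        FeatureDefinition(
            "hip_rotation_mean_swing", "hip_rotation", "mean", "swing",
            note="mean hip internal rotation during swing"),
        FeatureDefinition(
            "hip_rotation_mean_stance", "hip_rotation", "mean", "stance",
            note="mean hip internal rotation during stance"),
        FeatureDefinition(
            "knee_flexion_min_stance", "knee_flexion", "min", "stance",
            note="minimum knee flexion during stance"),
        FeatureDefinition(
            "knee_flexion_range_swing", "knee_flexion", "range", "swing",
            note="range of knee flexion during swing"),
        FeatureDefinition(
            "foot_progression_mean_stance", "foot_progression", "mean",
            "stance", note="mean foot internal progression during stance"),
        FeatureDefinition(
            "ankle_dorsiflexion_range_cycle", "ankle_dorsiflexion", "range",
            "full_cycle", note="range of ankle dorsiflexion over the cycle"),
        FeatureDefinition(
            "ankle_plantarflexion_at_toe_off", "ankle_dorsiflexion",
            "value_at_event", "toe_off", sign=-1.0,
            note="plantarflexion positive: -dorsiflexion at toe-off"),
        FeatureDefinition(
            "hip_flexion_min_stance", "hip_flexion", "min", "stance",
            note="minimum hip flexion (peak extension) during stance"),
        FeatureDefinition(
            "ankle_dorsiflexion_max_stance", "ankle_dorsiflexion", "max",
            "stance", note="maximum ankle dorsiflexion during stance"),
        FeatureDefinition(
            "hip_flexion_time_of_max_swing", "hip_flexion", "time_of_max",
            "swing", note="time of maximum hip flexion in swing, seconds"),
    ]
    padding = []
    for ch in ("pelvis_tilt", "pelvis_obliquity", "pelvis_rotation",
               "hip_flexion", "hip_adduction"):
        padding += [
            FeatureDefinition(f"{ch}_mean_stance", ch, "mean", "stance"),
            FeatureDefinition(f"{ch}_mean_swing", ch, "mean", "swing"),
            FeatureDefinition(f"{ch}_range_cycle", ch, "range", "full_cycle"),
        ]
    padding += [
        FeatureDefinition("knee_flexion_range_cycle", "knee_flexion",
                          "range", "full_cycle"),
        FeatureDefinition("foot_progression_mean_swing", "foot_progression",
                          "mean", "swing"),
    ]
    registry = named + padding
    assert len(registry) == 27
    return registry


def save_registry(registry: Sequence[FeatureDefinition],
                  path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(
        [asdict(f) for f in registry], sort_keys=False))
    return path


def load_registry(path: str | Path) -> list[FeatureDefinition]:
    """Load a registry from YAML; lengths other than 27 are allowed but logged."""
    entries = yaml.safe_load(Path(path).read_text())
    registry = [FeatureDefinition(**e) for e in entries]
    names = [f.name for f in registry]
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    if len(registry) != 27:
        logger.warning(
            "feature registry has %d entries (the default catalogue has 27)",
            len(registry),
        )
    return registry


def build_feature_table(
    cluster_cycles: Iterable[GaitCycle],
    control_cycles: Iterable[GaitCycle],
    registry: Sequence[FeatureDefinition] | None = None,
) -> pd.DataFrame:
    """Labeled feature table for one cluster-vs-control problem.

    Rows are cycles (cluster of interest followed by controls), columns are
    the registry features in order plus a binary ``label`` column (1 =
    cluster, 0 = control).  The index holds pattern ids.
    """
    if registry is None:
        registry = default_registry()
    cluster_cycles = list(cluster_cycles)
    control_cycles = list(control_cycles)
    if not cluster_cycles or not control_cycles:
        raise ValueError("both the cluster and the control group must be nonempty")
    rows, index, labels = [], [], []
    for cyc, label in [(c, 1) for c in cluster_cycles] + [
        (c, 0) for c in control_cycles
    ]:
        try:
            rows.append(extract_features(cyc, registry))
        except ValueError as exc:
            raise ValueError(
                f"feature extraction failed for cycle {cyc.pattern_id}: {exc}"
            ) from exc
        index.append(cyc.pattern_id)
        labels.append(label)
    df = pd.DataFrame(rows, index=index, columns=[f.name for f in registry])
    df["label"] = labels
    return df
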