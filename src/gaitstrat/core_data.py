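"""Domain types and I/O for gait-cycle kinematics and pipeline products.

The unit of analysis is a *gait cycle* (one stride, initial contact to the
next ipsilateral initial contact) described by nine joint/segment angle
channels sampled at a fixed rate.  Cycles are deliberately kept on their raw
time base — they are never resampled to percent-gait — so that duration
differences remain visible to the downstream dissimilarity measure.

Sign conventions (positive direction) for the nine channels:
pelvis anterior tilt, pelvis upward obliquity, pelvis internal rotation,
hip flexion, hip adduction, hip internal rotation, knee flexion,
ankle dorsiflexion, foot internal progression.

Interchange formats are plain text: long-format CSV for cycle tables,
CSV for dissimilarity matrices, Newick for dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical ordered channel names for one gait cycle.
CHANNELS: tuple[str, ...] = (
    "pelvis_tilt",
    "pelvis_obliquity",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)

N_CHANNELS = len(CHANNELS)

SIDES = ("left", "right")
GROUPS = ("iSCI", "control")

#: Non-ordinal display names assigned to clusters by descending size.
CLUSTER_PALETTE = (
    "blue", "pink", "violet", "green", "orange", "cactus",
    "teal", "amber", "coral", "olive", "plum", "slate",
)


class SchemaError(ValueError):
    """A table is missing required columns or has malformed values."""


class IntegrityError(ValueError):
    """A record violates a domain-type invariant."""


@dataclass(frozen=True)
class GaitCycle:
    """One gait cycle: nine synchronized angle channels plus timing metadata.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    side : {"left", "right"}
        Which leg the cycle belongs to; sides are analysed independently.
    cycle_index : int
        1-based index of the cycle within its (subject, side).
    angles : ndarray, shape (9, T)
        Joint angles in degrees, rows ordered as :data:`CHANNELS`.
    toe_off_index : int
        Sample index of toe-off.  Stance is ``[0, toe_off_index)`` and swing
        ``[toe_off_index, T)`` (half-open, 0-based).
    sampling_rate : float
        Samples per second (default 100 Hz).
    group : {"iSCI", "control"}
    """

    subject_id: str
    side: str
    cycle_index: int
    angles: np.ndarray
    toe_off_index: int
    sampling_rate: float = 100.0
    group: str = "iSCI"

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", a)
        if self.side not in SIDES:
            raise IntegrityError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.group not in GROUPS:
            raise IntegrityError(f"group must be one of {GROUPS}, got {self.group!r}")
        if int(self.cycle_index) < 1:
            raise IntegrityError("cycle_index must be >= 1")
        if a.ndim != 2 or a.shape[0] != N_CHANNELS:
            raise IntegrityError(
                f"angles must have shape (9, T); got {a.shape}"
            )
        if a.shape[1] < 2:
            raise IntegrityError("cycles need at least 2 samples per channel")
        if not np.all(np.isfinite(a)):
            raise IntegrityError("angle values must be finite")
        if not (1 <= int(self.toe_off_index) < a.shape[1]):
            raise IntegrityError(
                f"toe_off_index {self.toe_off_index} outside (0, T={a.shape[1]})"
            )
        if not self.sampling_rate > 0:
            raise IntegrityError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.angles.shape[1]

    @property
    def duration(self) -> float:
        """Cycle duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def pattern_id(self) -> str:
        """Unique cycle identifier used throughout the pipeline."""
        return f"{self.subject_id}_{self.side}_c{self.cycle_index}"

    def channel(self, name: str) -> np.ndarray:
        return self.angles[CHANNELS.index(name)]


@dataclass(frozen=True)
class TemporospatialRecord:
    """Per-cycle walking speed (m/s), step length (m) and step width (m).

    Step width is the mediolateral distance between heel positions at
    initial contact.
    """

    subject_id: str
    side: str
    cycle_index: int
    walking_speed: float
    step_length: float
    step_width: float

    def __post_init__(self) -> None:
        for name in ("walking_speed", "step_length", "step_width"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise IntegrityError(f"{name} must be finite and >= 0, got {v}")

    @property
    def keys(self) -> tuple[str, str, int]:
        return (self.subject_id, self.side, self.cycle_index)


#: The nine muscle groups graded per side in the manual muscle test (MMT).
MMT_MUSCLE_GROUPS = (
    "hip_flexion",
    "hip_extension",
    "hip_abduction",
    "hip_adduction",
    "knee_flexion",
    "knee_extension",
    "ankle_dorsiflexion",
    "ankle_plantarflexion",
    "hallux_extension",
)

#: Joint aggregation order used to break ties when assigning the weaker leg.
MMT_JOINT_ORDER: Mapping[str, tuple[str, ...]] = {
    "hip": ("hip_flexion", "hip_extension", "hip_abduction", "hip_adduction"),
    "knee": ("knee_flexion", "knee_extension"),
    "ankle": ("ankle_dorsiflexion", "ankle_plantarflexion"),
    "hallux": ("hallux_extension",),
}

WALKING_AIDS = ("barefoot", "shoes", "crutches", "crutches+", "walker+")
INJURY_LEVELS = ("cervical", "thoracic", "lumbar", "sacral", "intact")


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical metadata for one subject.

    ``mmt_grades`` maps ``(side, muscle_group)`` to a raw manual-muscle-test
    grade string such as ``"3+"`` or ``"5"`` (quantized downstream).
    ``wisci2`` is the Walking Index for Spinal Cord Injury (0–20).  ``mli``
    and ``sli`` are motor and sensory injury levels.
    """

    subject_id: str
    sex: str
    group: str = "iSCI"
    walking_aid: str = "barefoot"
    spasticity_present: bool = False
    wisci2: int = 20
    mli: str = "thoracic"
    sli: str = "thoracic"
    mmt_grades: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise IntegrityError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.group not in GROUPS:
            raise IntegrityError(f"group must be one of {GROUPS}")
        if self.walking_aid not in WALKING_AIDS:
            raise IntegrityError(f"walking_aid must be one of {WALKING_AIDS}")
        if not (0 <= int(self.wisci2) <= 20):
            raise IntegrityError("wisci2 must lie in [0, 20]")
        for lvl_name in ("mli", "sli"):
            if getattr(self, lvl_name) not in INJURY_LEVELS:
                raise IntegrityError(f"{lvl_name} must be one of {INJURY_LEVELS}")
        per_side: dict[str, int] = {}
        for (side, muscle), _ in self.mmt_grades.items():
            if side not in SIDES:
                raise IntegrityError(f"unknown side {side!r} in mmt_grades")
            if muscle not in MMT_MUSCLE_GROUPS:
                raise IntegrityError(f"unknown muscle group {muscle!r}")
            per_side[side] = per_side.get(side, 0) + 1
        if any(n > len(MMT_MUSCLE_GROUPS) for n in per_side.values()):
            raise IntegrityError("more than 9 muscle-group grades on one side")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities over a fixed list of cycles."""

    pattern_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(self.pattern_ids)
        object.__setattr__(self, "pattern_ids", ids)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(ids)
        if len(set(ids)) != n:
            raise IntegrityError("pattern_ids must be unique")
        if v.shape != (n, n):
            raise IntegrityError(f"values must be {n}x{n}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise IntegrityError("matrix entries must be finite")
        if np.any(v < 0):
            raise IntegrityError("matrix entries must be nonnegative")
        if not np.allclose(v, v.T, rtol=0.0, atol=1e-9):
            raise IntegrityError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise IntegrityError("matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.pattern_ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree with pseudo-inertia merge heights.

    Clusters are numbered like scipy linkage: leaves are ``0..n-1`` (indices
    into ``leaf_ids``) and the cluster created by merge ``i`` is ``n + i``.
    Each merge is ``(cluster_a, cluster_b, height, merged_size)``.
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        ids = tuple(self.leaf_ids)
        merges = tuple(
            (int(a), int(b), float(h), int(s)) for a, b, h, s in self.merges
        )
        object.__setattr__(self, "leaf_ids", ids)
        object.__setattr__(self, "merges", merges)
        n = len(ids)
        if len(merges) != n - 1:
            raise IntegrityError(f"expected {n - 1} merges for {n} leaves")
        sizes = {i: 1 for i in range(n)}
        for k, (a, b, h, s) in enumerate(merges):
            if h < 0:
                raise IntegrityError("merge heights must be >= 0")
            if a not in sizes or b not in sizes or a == b:
                raise IntegrityError(f"merge {k} references invalid clusters")
            if s != sizes[a] + sizes[b]:
                raise IntegrityError(
                    f"merge {k}: size {s} != {sizes[a]} + {sizes[b]}"
                )
            sizes[n + k] = sizes.pop(a) + sizes.pop(b)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat cycle-level cluster labels plus size-ranked display names.

    ``labels`` maps pattern_id -> integer label, where label 0 is the largest
    cluster.  ``names`` maps each integer label to a non-ordinal colour-style
    display name.
    """

    labels: Mapping[str, int]
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        used = set(self.labels.values())
        if not used <= set(self.names):
            raise IntegrityError("every used label needs a display name")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def members(self, label: int) -> list[str]:
        return [p for p, l in self.labels.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern_id": list(self.labels),
                "label": list(self.labels.values()),
                "cluster": [self.names[l] for l in self.labels.values()],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CYCLE_META_COLS = ("subject_id", "side", "cycle_index", "frame", "toe_off_index")


def write_cycles(cycles: Iterable[GaitCycle], path: str | Path) -> Path:
    """Write cycles as a long-format CSV (one row per frame)."""
    frames = []
    for c in cycles:
        t = np.arange(c.n_samples)
        df = pd.DataFrame({
            "subject_id": c.subject_id,
            "side": c.side,
            "cycle_index": c.cycle_index,
            "frame": t,
            "toe_off_index": c.toe_off_index,
            "group": c.group,
            "sampling_rate": c.sampling_rate,
        })
        for m, name in enumerate(CHANNELS):
            df[name] = c.angles[m]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cycles(path: str | Path) -> list[GaitCycle]:
    """Read a long-format cycle table written by :func:`write_cycles`.

    Raises
    ------
    SchemaError
        If a required column (including any of the nine channels) is absent.
    IntegrityError
        If a cycle violates the :class:`GaitCycle` invariants, e.g. toe-off
        outside the cycle or unequal channel lengths.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CYCLE_META_COLS + CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"cycle table missing column(s): {', '.join(missing)}")
    if "group" not in df.columns:
        df["group"] = "iSCI"
    if "sampling_rate" not in df.columns:
        df["sampling_rate"] = 100.0

    cycles = []
    for (sid, side, idx), g in df.groupby(
        ["subject_id", "side", "cycle_index"], sort=True
    ):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise IntegrityError(
                f"cycle {sid}/{side}/{idx}: frames must be contiguous from 0"
            )
        toe_off = g["toe_off_index"].unique()
        if len(toe_off) != 1:
            raise IntegrityError(
                f"cycle {sid}/{side}/{idx}: inconsistent toe_off_index"
            )
        angles = np.vstack([g[name].to_numpy(dtype=float) for name in CHANNELS])
        if np.isnan(angles).any():
            raise IntegrityError(
                f"cycle {sid}/{side}/{idx}: missing or non-numeric angle values"
            )
        cycles.append(
            GaitCycle(
                subject_id=str(sid),
                side=str(side),
                cycle_index=int(idx),
                angles=angles,
                toe_off_index=int(toe_off[0]),
                sampling_rate=float(g["sampling_rate"].iloc[0]),
                group=str(g["group"].iloc[0]),
            )
        )
    return cycles


def write_matrix(m: DissimilarityMatrix, path: str | Path) -> Path:
    """Persist a dissimilarity matrix as CSV with id headers."""
    path = Path(path)
    df = pd.DataFrame(m.values, index=list(m.pattern_ids),
                      columns=list(m.pattern_ids))
    df.to_csv(path, float_format="%.17g")
    return path


def read_matrix(path: str | Path) -> DissimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Asymmetry beyond 1e-9 or negative entries raise :class:`IntegrityError`
    (via the type's own validation); values within tolerance are symmetrized
    so that round trips are exact to 1e-12.
    """
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise IntegrityError("matrix row and column ids disagree")
    v = df.to_numpy(dtype=float)
    if not np.allclose(v, v.T, rtol=0.0, atol=1e-9):
        raise IntegrityError("matrix file is asymmetric beyond tolerance")
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(pattern_ids=tuple(ids), values=v)


def export_dendrogram_newick(d: Dendrogram, path: str | Path) -> Path:
    """Export a dendrogram as Newick with branch lengths.

    The branch length of a node is its parent's merge height minus its own
    height (leaves have height 0), so root-to-leaf path lengths equal the
    root merge height.
    """
    n = d.n_leaves
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h, _s) in enumerate(d.merges):
        height[n + k] = h
        children[n + k] = (a, b)

    def fmt(node: int, parent_h: float) -> str:
        bl = parent_h - height[node]
        if node < n:
            return f"{_quote_newick(d.leaf_ids[node])}:{bl:.12g}"
        a, b = children[node]
        h = height[node]
        return f"({fmt(a, h)},{fmt(b, h)}):{bl:.12g}"

    root = n + len(d.merges) - 1 if d.merges else 0
    a, b = children[root]
    h = height[root]
    newick = f"({fmt(a, h)},{fmt(b, h)});"
    path = Path(path)
    path.write_text(newick + "\n")
    return path


def _quote_newick(name: str) -> str:
    if any(ch in name for ch in " (),:;'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def read_temporospatial(path: str | Path) -> list[TemporospatialRecord]:
    """Read per-cycle temporospatial parameters from CSV."""
    df = pd.read_csv(path)
    required = ("subject_id", "side", "cycle_index",
                "walking_speed", "step_length", "step_width")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"temporospatial table missing: {', '.join(missing)}")
    return [
        TemporospatialRecord(
            subject_id=str(r.subject_id), side=str(r.side),
            cycle_index=int(r.cycle_index),
            walking_speed=float(r.walking_speed),
            step_length=float(r.step_length),
            step_width=float(r.step_width),
        )
        for r in df.itertuples()
    ]


def write_temporospatial(records: Iterable[TemporospatialRecord],
                         path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([
        {
            "subject_id": r.subject_id, "side": r.side,
            "cycle_index": r.cycle_index, "walking_speed": r.walking_speed,
            "step_length": r.step_length, "step_width": r.step_width,
        }
        for r in records
    ]).to_csv(path, index=False, float_format="%.10g")
    return path


def write_subjects(subjects: Iterable[SubjectRecord], path: str | Path) -> Path:
    """Write clinical metadata; MMT grades become side_muscle columns."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "sex": s.sex, "group": s.group,
            "walking_aid": s.walking_aid,
            "spasticity_present": int(s.spasticity_present),
            "wisci2": s.wisci2, "mli": s.mli, "sli": s.sli,
        }
        for (side, muscle), grade in s.mmt_grades.items():
            row[f"mmt_{side}_{muscle}"] = grade
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = ("subject_id", "sex", "group", "walking_aid",
                "spasticity_present", "wisci2", "mli", "sli")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"subject table missing: {', '.join(missing)}")
    mmt_cols = [c for c in df.columns if c.startswith("mmt_")]
    subjects = []
    for r in df.itertuples():
        grades = {}
        for col in mmt_cols:
            val = getattr(r, col)
            if pd.isna(val):
                continue
            side, muscle = col[4:].split("_", 1)
            grades[(side, muscle)] = str(val)
        subjects.append(
            SubjectRecord(
                subject_id=str(r.subject_id), sex=str(r.sex),
                group=str(r.group), walking_aid=str(r.walking_aid),
                spasticity_present=bool(int(r.spasticity_present)),
                wisci2=int(r.wisci2), mli=str(r.mli), sli=str(r.sli),
                mmt_grades=grades,
            )
        )
    return subjects
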