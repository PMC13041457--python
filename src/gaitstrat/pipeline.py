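"""End-to-end pipeline drivers: full stratification run and ablation.

``run_pipeline`` chains the stages — Z-normalization fitted on the impaired
cycles, pairwise dependent-DTW dissimilarity, Ward-like clustering, cut,
side assignment, per-cluster feature tables with SMOTE + random-forest +
SHAP discrimination, and clinical characterization — writing every product
plus a manifest (seed, config hash, row counts, numeric-output hash) into a
run directory, so reruns with the same config and seed are verifiably
identical.

``run_ablation`` drops the highest-indexed cycle(s) of every side, repeats
the clustering, and reports the percentage of sides whose modal cluster
label is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_data, clustering, dtw, features, preprocess, stats
from .discriminate import SmoteConfig, explain_shap, smote_balance, train_rf_grid
from .synthetic_data import Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one full pipeline run.

    Either ``simulate`` is true (inputs are generated) or the three input
    paths must point at existing CSV tables.  Exactly one of ``cut_k`` /
    ``cut_threshold`` selects the dendrogram cut.
    """

    out_dir: str = "run"
    simulate: bool = True
    cycles_path: str | None = None
    temporospatial_path: str | None = None
    subjects_path: str | None = None
    n_subjects: int = 28
    n_controls: int = 21
    cycles_per_side: int = 5
    window_fraction: float = 0.5
    cut_k: int | None = 6
    cut_threshold: float | None = None
    discriminate: bool = False
    rf_grid_small: bool = True
    safe_resampling: bool = False
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cut_k is None) == (self.cut_threshold is None):
            raise ValueError("set exactly one of cut_k / cut_threshold")
        if not self.simulate:
            for p in (self.cycles_path, self.temporospatial_path,
                      self.subjects_path):
                if p is None:
                    raise ValueError(
                        "non-simulated runs need cycles/temporospatial/"
                        "subjects paths"
                    )
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


#: Reduced grid used when ``rf_grid_small`` is set: the full 54-point grid
#: is the replication default, but one forest per corner is enough for the
#: routine smoke runs the driver is meant for.
SMALL_RF_GRID = {
    "n_estimators": (200,),
    "max_features": ("sqrt",),
    "max_depth": (10, 20),
    "criterion": ("gini", "entropy"),
}


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        cohort = generate_cohort(CohortConfig(
            n_subjects=cfg.n_subjects, n_controls=cfg.n_controls,
            cycles_per_side=cfg.cycles_per_side, seed=cfg.seed,
        ))
        return (list(cohort.cycles), list(cohort.temporospatial),
                list(cohort.subjects), cohort.planted)
    cycles = core_data.read_cycles(cfg.cycles_path)
    ts = core_data.read_temporospatial(cfg.temporospatial_path)
    subjects = core_data.read_subjects(cfg.subjects_path)
    if not cycles:
        raise ValueError("no cycles found in input")
    return cycles, ts, subjects, None


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage and return the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []

    def stage(name: str, **info):
        stage_log.append({"stage": name, "elapsed_s": round(time.time() - t0, 2),
                          **info})
        logger.info("stage %s done (%.1fs)", name, time.time() - t0)

    cycles, ts, subjects, planted = _load_inputs(cfg)
    isci = [c for c in cycles if c.group == "iSCI"]
    controls = [c for c in cycles if c.group == "control"]
    if not isci:
        raise ValueError("pipeline requires at least one impaired cycle")
    stage("load", n_cycles=len(cycles), n_isci=len(isci),
          n_controls=len(controls))

    norm = preprocess.fit_normalization(isci)
    norm.to_csv(out / "normalization.csv")
    stage("normalize")

    dtw_cfg = dtw.DtwConfig(window_fraction=cfg.window_fraction)
    matrix = dtw.pairwise_matrix(isci, norm, dtw_cfg)
    core_data.write_matrix(matrix, out / "dissimilarity.csv")
    stage("dtw_matrix", n=matrix.n)

    dendro = clustering.hac_wardlike(matrix)
    core_data.export_dendrogram_newick(dendro, out / "dendrogram.nwk")
    pd.DataFrame(
        [{"cluster_a": a, "cluster_b": b, "height": h, "size": s}
         for a, b, h, s in dendro.merges]
    ).to_csv(out / "merges.csv", index=False)
    if cfg.cut_k is not None:
        assignment = clustering.cut_k(dendro, cfg.cut_k)
    else:
        assignment = clustering.cut_dendrogram(dendro, cfg.cut_threshold)
    assignment.to_frame().to_csv(out / "assignments.csv", index=False)
    sides = clustering.side_assignments(assignment, isci)
    sides.to_csv(out / "side_assignments.csv", index=False)
    stage("cluster", k=assignment.n_clusters)

    registry = features.default_registry()
    features.save_registry(registry, out / "feature_registry.yaml")
    feature_frames = {}
    if controls:
        for label in sorted(set(assignment.labels.values())):
            members = set(assignment.members(label))
            cluster_cycles = [c for c in isci if c.pattern_id in members]
            table = features.build_feature_table(cluster_cycles, controls,
                                                 registry)
            name = assignment.names[label]
            feature_frames[name] = table
            table.to_csv(out / f"features_{name}.csv")
    stage("features", n_tables=len(feature_frames))

    if cfg.discriminate and feature_frames:
        grid = SMALL_RF_GRID if cfg.rf_grid_small else None
        for name, table in feature_frames.items():
            smote_cfg = SmoteConfig(
                k_neighbors=min(cfg.smote_k,
                                max(1, int(table["label"].sum()) - 1)),
                seed=cfg.seed,
            )
            if cfg.safe_resampling:
                report, model = train_rf_grid(
                    table, seed=cfg.seed, grid=grid, safe_resampling=True,
                    smote_cfg=smote_cfg,
                )
                balanced = table
            else:
                balanced = smote_balance(table, smote_cfg)
                report, model = train_rf_grid(balanced, seed=cfg.seed,
                                              grid=grid)
            report.table.to_csv(out / f"grid_{name}.csv", index=False)
            summary = explain_shap(model, table)
            summary.top(10).to_csv(out / f"shap_top10_{name}.csv",
                                   index=False)
            summary.to_frame().to_csv(out / f"shap_local_{name}.csv",
                                      index=False)
        stage("discriminate", n_models=len(feature_frames))

    side_table = stats.side_medians(isci, ts, assignment)
    side_table.to_csv(out / "side_medians.csv", index=False)
    if side_table["cluster"].nunique() >= 2:
        report = stats.characterize_clusters(side_table, subjects)
        report.to_frame().to_csv(out / "characterization.csv", index=False)
        report.counts.to_csv(out / "cluster_counts.csv", index=False)
        for var, ph in report.posthoc.items():
            ph.to_csv(out / f"posthoc_{var}.csv", index=False)
    stage("characterize")

    if planted is not None:
        planted.to_csv(out / "planted_labels.csv", index=False)

    numeric_outputs = sorted(
        p for p in out.glob("*.csv") if p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": stage_log,
        "outputs": {p.name: _hash_file(p) for p in numeric_outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


@dataclass(frozen=True)
class AblationReport:
    """Side-level agreement between full and subsampled clusterings."""

    n_sides: int
    n_unchanged: int
    full_sides: pd.DataFrame = field(repr=False)
    sub_sides: pd.DataFrame = field(repr=False)

    @property
    def agreement(self) -> float:
        return self.n_unchanged / self.n_sides if self.n_sides else 1.0


def _match_labels(full: pd.DataFrame, sub: pd.DataFrame) -> int:
    """Count sides keeping their cluster, after greedily matching labels.

    Cluster labels are arbitrary between runs; labels are matched by maximal
    side overlap (greedy on the contingency table) before counting
    unchanged sides.
    """
    merged = full.merge(sub, on=["subject_id", "side"],
                        suffixes=("_full", "_sub"))
    tab = pd.crosstab(merged["label_full"], merged["label_sub"])
    mapping = {}
    t = tab.copy()
    while t.size and t.to_numpy().max() > 0:
        i, j = np.unravel_index(np.argmax(t.to_numpy()), t.shape)
        mapping[t.index[i]] = t.columns[j]
        t = t.drop(index=t.index[i], columns=t.columns[j])
    return int(sum(
        mapping.get(a) == b
        for a, b in zip(merged["label_full"], merged["label_sub"])
    ))


def run_ablation(
    cfg: PipelineConfig, drop_to: int, random_drop: bool = False
) -> AblationReport:
    """Re-cluster on ``drop_to`` cycles per side and report side agreement.

    By default the highest-indexed cycles are dropped (deterministic); with
    ``random_drop`` a seeded random subset is kept instead.
    """
    if drop_to < 1:
        raise ValueError("drop_to must be >= 1")
    cycles, _ts, _subjects, _planted = _load_inputs(cfg)
    isci = [c for c in cycles if c.group == "iSCI"]
    per_side = max(
        sum(1 for c in isci
            if (c.subject_id, c.side) == (d.subject_id, d.side))
        for d in isci
    )
    if drop_to >= per_side:
        raise ValueError(
            f"drop_to={drop_to} must be below cycles per side ({per_side})"
        )

    norm = preprocess.fit_normalization(isci)
    dtw_cfg = dtw.DtwConfig(window_fraction=cfg.window_fraction)

    def cluster_sides(cyc_list):
        m = dtw.pairwise_matrix(cyc_list, norm, dtw_cfg)
        dendro = clustering.hac_wardlike(m)
        if cfg.cut_k is not None:
            assignment = clustering.cut_k(dendro, cfg.cut_k)
        else:
            assignment = clustering.cut_dendrogram(dendro, cfg.cut_threshold)
        return clustering.side_assignments(assignment, cyc_list)

    full_sides = cluster_sides(isci)

    if random_drop:
        rng = np.random.default_rng(cfg.seed)
        keep = set()
        by_side: dict[tuple[str, str], list] = {}
        for c in isci:
            by_side.setdefault((c.subject_id, c.side), []).append(c)
        for key, group in sorted(by_side.items()):
            idx = rng.permutation(len(group))[:drop_to]
            keep.update(group[i].pattern_id for i in idx)
        sub = [c for c in isci if c.pattern_id in keep]
    else:
        sub = []
        by_side = {}
        for c in isci:
            by_side.setdefault((c.subject_id, c.side), []).append(c)
        for key, group in sorted(by_side.items()):
            group = sorted(group, key=lambda c: c.cycle_index)
            sub.extend(group[:drop_to])

    sub_sides = cluster_sides(sub)
    unchanged = _match_labels(full_sides, sub_sides)
    return AblationReport(
        n_sides=len(full_sides), n_unchanged=unchanged,
        full_sides=full_sides, sub_sides=sub_sides,
    )
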