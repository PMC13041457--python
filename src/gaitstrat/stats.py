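"""Nonparametric cluster characterization.

Sides, not subjects or cycles, are the unit of statistical analysis: each
(subject, side) is represented by the median of its cycles, and those side
medians are treated as independent observations.  Continuous and ordinal
variables are compared across clusters with Kruskal–Wallis followed by
Dunn's rank-based pairwise z-tests with Bonferroni correction (adjusted
p = min(1, raw p x number of pairs)); categorical variables use Pearson's
chi-squared without continuity correction; monotone association uses
Spearman's rank correlation with the t-approximation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import (
    MMT_MUSCLE_GROUPS,
    ClusterAssignment,
    GaitCycle,
    SubjectRecord,
    TemporospatialRecord,
)
from .clustering import side_assignments
from .preprocess import mmt_side_sum, quantize_mmt


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, df, raw and (optional) adjusted p."""

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    adjusted_p: float | None = None
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("p_value", "adjusted_p"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


def bonferroni(p: float, m: int) -> float:
    """Adjusted p = min(1, p * m)."""
    return min(1.0, p * m)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with midrank tie correction and chi2 reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        # all observations identical: no evidence of any difference
        return TestResult(
            method="kruskal_wallis", statistic=0.0, p_value=1.0,
            df=len(groups) - 1, n_per_group=tuple(len(g) for g in groups),
        )
    h, p = sps.kruskal(*groups)
    return TestResult(
        method="kruskal_wallis", statistic=float(h), p_value=float(p),
        df=len(groups) - 1, n_per_group=tuple(len(g) for g in groups),
    )


def posthoc_pairwise(
    groups: Sequence[Sequence[float]], method: str = "dunn_bonferroni"
) -> pd.DataFrame:
    """Pairwise post-hoc comparisons following Kruskal–Wallis.

    ``dunn_bonferroni`` (default) runs Dunn's z-tests on mean ranks with the
    tie correction, Bonferroni-adjusted over all C(g, 2) pairs;
    ``mannwhitney_bonferroni`` runs pairwise Mann–Whitney U tests instead.
    Returns a tidy frame with one row per pair.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need >= 2 groups")
    m = g * (g - 1) // 2
    rows = []
    if method == "dunn_bonferroni":
        pooled = np.concatenate(groups)
        n_total = len(pooled)
        ranks = sps.rankdata(pooled)
        sizes = [len(x) for x in groups]
        bounds = np.cumsum([0] + sizes)
        mean_ranks = [
            ranks[bounds[i]:bounds[i + 1]].mean() for i in range(g)
        ]
        _vals, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
        var_base = n_total * (n_total + 1) / 12.0 - tie_term
        for i, j in combinations(range(g), 2):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({
                "group_a": i, "group_b": j, "statistic": float(z),
                "p_value": float(p), "adjusted_p": bonferroni(float(p), m),
            })
    elif method == "mannwhitney_bonferroni":
        for i, j in combinations(range(g), 2):
            u, p = sps.mannwhitneyu(groups[i], groups[j],
                                    alternative="two-sided")
            rows.append({
                "group_a": i, "group_b": j, "statistic": float(u),
                "p_value": float(p), "adjusted_p": bonferroni(float(p), m),
            })
    else:
        raise ValueError(f"unknown post-hoc method {method!r}")
    return pd.DataFrame(rows)


def chi_squared(table: np.ndarray | Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-squared on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D nonnegative count matrix")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-squared requires positive row and column margins")
    stat, p, df, _exp = sps.chi2_contingency(t, correction=False)
    return TestResult(
        method="chi_squared", statistic=float(stat), p_value=float(p),
        df=float(df),
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    df: int

    def __str__(self) -> str:
        return f"r_s({self.df}) = {self.rho:.3f}, p = {self.p_value:.3g}"


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with midranks and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-D samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant variable")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), df=len(x) - 2)


# ---------------------------------------------------------------------------
# side-median representation and the characterization report
# ---------------------------------------------------------------------------


def side_medians(
    cycles: Sequence[GaitCycle],
    temporospatial: Sequence[TemporospatialRecord],
    assignment: ClusterAssignment,
    feature_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-(subject, side) medians of temporospatial (and feature) variables.

    Every cycle must have a temporospatial record; the cluster label is the
    side's modal label from :func:`gaitstrat.clustering.side_assignments`.
    """
    ts_by_key = {r.keys: r for r in temporospatial}
    rows = []
    for c in cycles:
        key = (c.subject_id, c.side, c.cycle_index)
        if key not in ts_by_key:
            raise ValueError(
                f"missing temporospatial record for cycle {c.pattern_id}"
            )
        r = ts_by_key[key]
        row = {
            "subject_id": c.subject_id, "side": c.side,
            "pattern_id": c.pattern_id,
            "walking_speed": r.walking_speed,
            "step_length": r.step_length,
            "step_width": r.step_width,
        }
        if feature_table is not None and c.pattern_id in feature_table.index:
            for col in feature_table.columns:
                if col != "label":
                    row[col] = feature_table.loc[c.pattern_id, col]
        rows.append(row)
    per_cycle = pd.DataFrame(rows)
    value_cols = [c for c in per_cycle.columns
                  if c not in ("subject_id", "side", "pattern_id")]
    med = (per_cycle.groupby(["subject_id", "side"], sort=True)[value_cols]
           .median().reset_index())
    sides = side_assignments(assignment, cycles)
    return med.merge(
        sides[["subject_id", "side", "label", "cluster", "n_cycles"]],
        on=["subject_id", "side"], how="left",
    )


#: Continuous/ordinal variables tested with Kruskal-Wallis + Dunn post-hoc.
KW_VARIABLES = (
    "mmt_sum", "mmt_hip_extension", "mmt_knee_flexion",
    "mmt_ankle_plantarflexion", "wisci2",
    "walking_speed", "step_length", "step_width",
)
#: Categorical variables tested with chi-squared.
CHI2_VARIABLES = ("sex", "walking_aid", "spasticity_present")


@dataclass(frozen=True)
class CharacterizationReport:
    """Cluster-characterization tables: omnibus tests, post-hocs, counts."""

    tests: Mapping[str, TestResult]
    posthoc: Mapping[str, pd.DataFrame]
    counts: pd.DataFrame
    side_table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, t in self.tests.items():
            rows.append({
                "variable": var, "method": t.method,
                "statistic": t.statistic, "df": t.df, "p_value": t.p_value,
            })
        return pd.DataFrame(rows)


def _clinical_side_columns(
    side_table: pd.DataFrame, subjects: Sequence[SubjectRecord]
) -> pd.DataFrame:
    by_id = {s.subject_id: s for s in subjects}
    t = side_table.copy()

    def grade(s: SubjectRecord, side: str, muscle: str) -> float:
        g = s.mmt_grades.get((side, muscle))
        return quantize_mmt(g) if g is not None else np.nan

    t["mmt_sum"] = [
        mmt_side_sum(by_id[r.subject_id], r.side) for r in t.itertuples()
    ]
    for muscle in ("hip_extension", "knee_flexion", "ankle_plantarflexion"):
        t[f"mmt_{muscle}"] = [
            grade(by_id[r.subject_id], r.side, muscle) for r in t.itertuples()
        ]
    t["wisci2"] = [by_id[r.subject_id].wisci2 for r in t.itertuples()]
    t["sex"] = [by_id[r.subject_id].sex for r in t.itertuples()]
    t["walking_aid"] = [by_id[r.subject_id].walking_aid for r in t.itertuples()]
    t["spasticity_present"] = [
        by_id[r.subject_id].spasticity_present for r in t.itertuples()
    ]
    return t


def characterize_clusters(
    side_table: pd.DataFrame, subjects: Sequence[SubjectRecord]
) -> CharacterizationReport:
    """Run the full cluster-characterization battery on side medians.

    ``side_table`` is the output of :func:`side_medians`.  Kruskal–Wallis
    (with Dunn/Bonferroni post-hocs) covers MMT sums and subscores, WISCI II
    and the temporospatial parameters; chi-squared covers sex, walking aid
    and spasticity.  Counts are reported both as sides and as cycles, since
    either can serve as the headline "n" of a cluster.
    """
    t = _clinical_side_columns(side_table, subjects)
    labels = sorted(t["cluster"].dropna().unique(),
                    key=lambda c: (-(t["cluster"] == c).sum(), c))
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters to characterize")

    tests: dict[str, TestResult] = {}
    posthoc: dict[str, pd.DataFrame] = {}
    for var in KW_VARIABLES:
        groups = [
            t.loc[(t["cluster"] == lab) & t[var].notna(), var].to_numpy()
            for lab in labels
        ]
        groups = [g for g in groups if len(g) > 0]
        tests[var] = kruskal_wallis(groups)
        ph = posthoc_pairwise(groups)
        ph["group_a"] = [labels[i] for i in ph["group_a"]]
        ph["group_b"] = [labels[i] for i in ph["group_b"]]
        posthoc[var] = ph
    for var in CHI2_VARIABLES:
        counts = pd.crosstab(t["cluster"], t[var])
        counts = counts.loc[[l for l in labels if l in counts.index]]
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        tests[var] = chi_squared(counts.to_numpy())

    count_rows = []
    for lab in labels:
        sub = t[t["cluster"] == lab]
        count_rows.append({
            "cluster": lab,
            "n_sides": len(sub),
            "n_cycles": int(sub["n_cycles"].sum()),
        })
    return CharacterizationReport(
        tests=tests, posthoc=posthoc,
        counts=pd.DataFrame(count_rows), side_table=t,
    )
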