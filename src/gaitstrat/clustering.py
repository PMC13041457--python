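"""Ward-like hierarchical agglomerative clustering on a dissimilarity matrix.

Classical Ward linkage minimizes the increase of within-cluster variance and
is defined for Euclidean coordinates.  The Ward-like generalization used here
works directly on an arbitrary dissimilarity matrix: the within-cluster
"pseudo-inertia" of a cluster C is defined from pairwise dissimilarities,

    I(C) = (1 / n_C) * sum_{i<j in C} d(i, j)**2,

and each agglomeration step merges the pair of clusters whose union increases
total pseudo-inertia the least.  Merge costs are maintained with the
Lance–Williams recurrence for Ward's method applied to the cost

    S(A, B) = I(A u B) - I(A) - I(B),      S({i}, {j}) = d(i, j)**2 / 2,

    S(A u B, K) = [(n_A + n_K) S(A, K) + (n_B + n_K) S(B, K)
                   - n_K S(A, B)] / (n_A + n_B + n_K).

Merge heights are the pseudo-inertia increases themselves; on Euclidean
inputs they coincide with classical Ward (scipy heights h relate as
``S = h**2 / 2``).  The DTW dissimilarities enter squared, which makes
heights interpretable as inertia on the DTW scale.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    CLUSTER_PALETTE,
    ClusterAssignment,
    Dendrogram,
    DissimilarityMatrix,
    GaitCycle,
)

logger = logging.getLogger(__name__)


def hac_wardlike(m: DissimilarityMatrix) -> Dendrogram:
    """Agglomerate a dissimilarity matrix with Ward-like linkage.

    Ties in the merge cost are broken by the lexicographically smallest
    ``(cluster_id_a, cluster_id_b)`` pair, where leaves are numbered
    ``0..n-1`` in input order and the cluster created by merge ``i`` is
    ``n + i``.
    """
    n = m.n
    if n < 2:
        raise ValueError("need at least 2 patterns to cluster")
    # S[p, q] = current Ward merge cost between active clusters in slots p, q
    S = (m.values.astype(float) ** 2) / 2.0
    np.fill_diagonal(S, np.inf)
    sizes = np.ones(n)
    ids = np.arange(n)          # cluster id occupying each slot
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float, int]] = []
    prev_h = -np.inf
    monotone = True
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = S[np.ix_(sub, sub)]
        h = block.min()
        # lexicographic tie-break on sorted cluster-id pairs
        cand = np.argwhere(np.isclose(block, h, rtol=0.0, atol=0.0))
        pairs = []
        for a_i, b_i in cand:
            if a_i < b_i:
                ia, ib = ids[sub[a_i]], ids[sub[b_i]]
                pairs.append((min(ia, ib), max(ia, ib), sub[a_i], sub[b_i]))
        ida, idb, pa, pb = min(pairs)
        na, nb = sizes[pa], sizes[pb]
        if h < prev_h - 1e-12:
            monotone = False
        prev_h = max(prev_h, h)
        merges.append((int(ida), int(idb), float(h), int(na + nb)))
        # Lance-Williams update of merge costs against every other cluster
        others = sub[(sub != pa) & (sub != pb)]
        if others.size:
            nk = sizes[others]
            s_new = (
                (na + nk) * S[pa, others]
                + (nb + nk) * S[pb, others]
                - nk * h
            ) / (na + nb + nk)
            S[pa, others] = s_new
            S[others, pa] = s_new
        sizes[pa] = na + nb
        ids[pa] = n + step
        active[pb] = False
    if not monotone:
        logger.warning(
            "non-monotone merge heights encountered; the input dissimilarity "
            "may not be metric-like"
        )
    return Dendrogram(leaf_ids=m.pattern_ids, merges=tuple(merges))


def _components(d: Dendrogram, kept_merges: int) -> ClusterAssignment:
    """Flat assignment from the first ``kept_merges`` merges (union-find)."""
    n = d.n_leaves
    parent = list(range(n + kept_merges))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k in range(kept_merges):
        a, b, _h, _s = d.merges[k]
        node = n + k
        parent[find(a)] = node
        parent[find(b)] = node

    roots = [find(i) for i in range(n)]
    # order clusters by descending size, ties by smallest leaf index
    by_root: dict[int, list[int]] = {}
    for leaf, r in enumerate(roots):
        by_root.setdefault(r, []).append(leaf)
    ordered = sorted(by_root.values(), key=lambda ls: (-len(ls), ls[0]))
    labels = {}
    for lab, leaves in enumerate(ordered):
        for leaf in leaves:
            labels[d.leaf_ids[leaf]] = lab
    names = {
        lab: (CLUSTER_PALETTE[lab] if lab < len(CLUSTER_PALETTE)
              else f"cluster{lab + 1}")
        for lab in range(len(ordered))
    }
    return ClusterAssignment(labels=labels, names=names)


def cut_dendrogram(d: Dendrogram, threshold: float) -> ClusterAssignment:
    """Cut at a pseudo-inertia height: drop merges with height > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = sum(1 for (_a, _b, h, _s) in d.merges if h <= threshold)
    # heights are monotone for valid input, so the kept merges are a prefix;
    # guard against non-monotone height sequences by keeping the prefix only
    prefix = 0
    for _a, _b, h, _s in d.merges:
        if h <= threshold:
            prefix += 1
        else:
            break
    return _components(d, min(kept, prefix))


def cut_k(d: Dendrogram, k: int) -> ClusterAssignment:
    """Cut into exactly ``k`` clusters by undoing the last ``k-1`` merges."""
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    return _components(d, n - k)


def suggest_threshold(d: Dendrogram) -> float:
    """Largest-relative-gap cut heuristic (extension for unattended runs).

    The study this pipeline models selected its cut by visual inspection of
    the dendrogram; this helper returns the midpoint of the largest relative
    gap between consecutive merge heights in the upper half of the tree.
    """
    h = np.sort(d.heights)
    upper = h[len(h) // 2:]
    if len(upper) < 2:
        return float(h[-1]) if len(h) else 0.0
    ratios = (upper[1:] + 1e-30) / (upper[:-1] + 1e-30)
    i = int(np.argmax(ratios))
    return float(0.5 * (upper[i] + upper[i + 1]))


def side_assignments(
    a: ClusterAssignment, cycles: Sequence[GaitCycle]
) -> pd.DataFrame:
    """Side-level modal cluster labels with a consistency flag.

    Returns one row per (subject, side) with the modal cycle label, its
    display name, the number of cycles, and ``consistent`` True when all
    cycles of the side share one label (otherwise the side is "mixed").
    """
    rows = []
    by_side: dict[tuple[str, str], list[int]] = {}
    for c in cycles:
        if c.pattern_id not in a.labels:
            raise ValueError(f"cycle {c.pattern_id} has no cluster label")
        by_side.setdefault((c.subject_id, c.side), []).append(
            a.labels[c.pattern_id]
        )
    for (sid, side), labs in sorted(by_side.items()):
        counts = pd.Series(labs).value_counts()
        top = counts.max()
        modal = min(l for l, c in counts.items() if c == top)
        rows.append({
            "subject_id": sid,
            "side": side,
            "label": int(modal),
            "cluster": a.names[int(modal)],
            "n_cycles": len(labs),
            "consistent": len(counts) == 1,
        })
    return pd.DataFrame(rows)
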