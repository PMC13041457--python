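"""Path-dependent Shapley value attributions for tree ensembles.

Computes exact Shapley values for a tree's prediction under the
path-dependent feature-perturbation value function: when a coalition does
not contain the feature split on at a node, the recursion descends both
children weighted by their training cover, i.e. the conditional expectation
implied by the tree's own training distribution.  The polynomial-time
algorithm maintains, along each root-to-leaf traversal, the set of features
encountered and a compact summary of the permutation weights of every
coalition size ("the path"), extending it at each split and unwinding it
when a feature repeats.

For a random-forest classifier the explained output is the positive-class
probability; attributions of the member trees average, so for every row

    base_value + sum_f phi[f] = predict_proba(x)[1]

holds to numerical precision (local accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


def _extend(d: list, z: list, o: list, w: list,
            pz: float, po: float, pi: int) -> None:
    """Append a feature to the path and update coalition-size weights."""
    l = len(d)
    d.append(pi)
    z.append(pz)
    o.append(po)
    w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        w[i + 1] += po * w[i] * (i + 1) / (l + 1)
        w[i] = pz * w[i] * (l - i) / (l + 1)


def _unwind(d: list, z: list, o: list, w: list, i: int) -> None:
    """Undo the extension that introduced path element ``i`` (in place)."""
    l = len(d) - 1
    n = w[l]
    oi, zi = o[i], z[i]
    for j in range(l - 1, -1, -1):
        if oi != 0.0:
            t = w[j]
            w[j] = n * (l + 1) / ((j + 1) * oi)
            n = t - w[j] * zi * (l - j) / (l + 1)
        else:
            w[j] = w[j] * (l + 1) / (zi * (l - j))
    for j in range(i, l):
        d[j], z[j], o[j] = d[j + 1], z[j + 1], o[j + 1]
    del d[l], z[l], o[l], w[l]


def _unwound_sum(z: list, o: list, w: list, i: int) -> float:
    """Sum of path weights after hypothetically unwinding element ``i``."""
    l = len(z) - 1
    oi, zi = o[i], z[i]
    total = 0.0
    if oi != 0.0:
        n = w[l]
        for j in range(l - 1, -1, -1):
            t = n * (l + 1) / ((j + 1) * oi)
            total += t
            n = w[j] - t * zi * (l - j) / (l + 1)
    else:
        for j in range(l - 1, -1, -1):
            total += w[j] * (l + 1) / (zi * (l - j))
    return total


def _tree_shap_single(
    x: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    cover: np.ndarray,
    value: np.ndarray,
    phi: np.ndarray,
) -> None:
    """Accumulate one tree's Shapley values for sample ``x`` into ``phi``."""

    def recurse(node: int, d: list, z: list, o: list, w: list,
                pz: float, po: float, pi: int) -> None:
        d, z, o, w = d.copy(), z.copy(), o.copy(), w.copy()
        _extend(d, z, o, w, pz, po, pi)
        if left[node] < 0:  # leaf
            v = value[node]
            for i in range(1, len(d)):
                s = _unwound_sum(z, o, w, i)
                phi[d[i]] += s * (o[i] - z[i]) * v
            return
        f = feature[node]
        if x[f] <= threshold[node]:
            hot, cold = left[node], right[node]
        else:
            hot, cold = right[node], left[node]
        iz = io = 1.0
        for k in range(1, len(d)):
            if d[k] == f:
                iz, io = z[k], o[k]
                _unwind(d, z, o, w, k)
                break
        recurse(hot, d, z, o, w, iz * cover[hot] / cover[node], io, f)
        recurse(cold, d, z, o, w, iz * cover[cold] / cover[node], 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)


def _tree_arrays(est) -> tuple:
    t = est.tree_
    val = t.value[:, 0, :]
    totals = val.sum(axis=1)
    # per-node positive-class probability (works for counts or proportions)
    v = val[:, 1] / np.where(totals > 0, totals, 1.0)
    return (
        t.children_left, t.children_right, t.feature, t.threshold,
        t.weighted_n_node_samples.astype(float), v,
    )


def _tree_expected(left, right, cover, value) -> float:
    """Cover-weighted expectation of the tree output (the leaf average)."""
    leaves = left < 0
    return float(np.sum(cover[leaves] * value[leaves]) / cover[0])


def forest_shap_values(
    model: RandomForestClassifier, X: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-row Shapley attributions and base value for a fitted forest.

    Returns ``(phi, base)`` where ``phi`` has shape (n_rows, n_features) and
    ``base`` is the ensemble's cover-weighted expected positive-class
    probability, so ``base + phi.sum(axis=1)`` equals
    ``model.predict_proba(X)[:, 1]``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"X must be 2-D with {model.n_features_in_} feature columns"
        )
    n, p = X.shape
    trees = [_tree_arrays(est) for est in model.estimators_]
    phi = np.zeros((n, p))
    base = 0.0
    for left, right, feat, thr, cover, value in trees:
        base += _tree_expected(left, right, cover, value)
        tree_phi = np.zeros(p)
        for i in range(n):
            tree_phi[:] = 0.0
            _tree_shap_single(X[i], left, right, feat, thr, cover, value,
                              tree_phi)
            phi[i] += tree_phi
    k = len(trees)
    return phi / k, base / k


@dataclass(frozen=True)
class ShapSummary:
    """Global and local Shapley attribution summary for one model.

    ``global_impact`` is the mean absolute attribution per feature; ``local``
    the per-row signed attributions; ``ranking`` the feature names in
    descending order of global impact.
    """

    feature_names: tuple[str, ...]
    local: np.ndarray
    base_value: float

    @property
    def global_impact(self) -> np.ndarray:
        return np.abs(self.local).mean(axis=0)

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-self.global_impact, kind="stable")
        return [self.feature_names[i] for i in order]

    def top(self, k: int = 10) -> pd.DataFrame:
        imp = self.global_impact
        order = np.argsort(-imp, kind="stable")[:k]
        return pd.DataFrame({
            "feature": [self.feature_names[i] for i in order],
            "mean_abs_shap": imp[order],
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.local, columns=list(self.feature_names))
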