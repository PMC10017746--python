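"""Ordinal tau staging from network measures.

Two routes to a stage:

1. ``threshold_stage`` applies the published fixed decision tree: limbic
   strength <= 14.463 splits stages 1-2 from 3-4; within the low branch
   limbic <= 9.867 separates stage 1 from 2; within the high branch global
   efficiency <= 0.901 separates stage 3 from 4. Splits send values equal
   to the threshold to the lower branch.

2. ``fit_stage_tree`` learns such a tree from data with a simplified
   conditional-inference procedure: at each node every feature's
   association with the response is scored by a rank (Spearman-type)
   statistic whose two-sided p-value comes from a seeded permutation test,
   Bonferroni-corrected over features; if no feature is significant at
   ``alpha`` (or the node is too small) the node becomes a leaf, otherwise
   the winning feature is split at the cutpoint maximizing a standardized
   two-sample rank statistic. This follows the unbiased-recursive-
   partitioning recipe in spirit but is deliberately simplified and is not
   bit-identical to the R partykit implementation. Leaves are numbered into
   stages 1..K by ascending mean of the first feature (tau severity order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkMeasures

__all__ = [
    "StageThresholds",
    "DEFAULT_THRESHOLDS",
    "StageModel",
    "StageNode",
    "StageAssignment",
    "threshold_stage",
    "default_stage_model",
    "fit_stage_tree",
    "stage_summary",
]


@dataclass(frozen=True)
class StageThresholds:
    """The fixed staging cutpoints (SUVR-difference units)."""

    limbic_high: float = 14.463  # stages 1-2 vs 3-4
    limbic_low: float = 9.867  # stage 1 vs 2
    efficiency: float = 0.901  # stage 3 vs 4


DEFAULT_THRESHOLDS = StageThresholds()


@dataclass
class StageNode:
    """One node of an axis-aligned binary threshold tree."""

    variable: str | None = None
    threshold: float | None = None
    left: "StageNode | None" = None  # taken when value <= threshold
    right: "StageNode | None" = None
    stage: int | None = None  # set on leaves
    n: int = 0
    p_value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"stage": self.stage, "n": self.n}
        return {
            "variable": self.variable,
            "threshold": self.threshold,
            "p_value": self.p_value,
            "n": self.n,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class StageModel:
    root: StageNode
    feature_names: list[str]

    @property
    def n_stages(self) -> int:
        return max(leaf.stage for leaf in self._leaves())

    def _leaves(self) -> list[StageNode]:
        out: list[StageNode] = []

        def walk(node: StageNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def predict_one(self, row: dict[str, float]) -> int:
        node = self.root
        while not node.is_leaf:
            value = row[node.variable]
            if not np.isfinite(value):
                raise ValueError(f"non-finite value for {node.variable!r}")
            node = node.left if value <= node.threshold else node.right
        return int(node.stage)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return np.array(
            [self.predict_one(row) for row in features.to_dict("records")], dtype=int
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"features": self.feature_names, "tree": self.root.to_dict()}, indent=2
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class StageAssignment:
    subject_id: str
    stage: int


def default_stage_model(thresholds: StageThresholds = DEFAULT_THRESHOLDS) -> StageModel:
    """The published two-level tree as a StageModel."""
    root = StageNode(
        variable="limbic_strength",
        threshold=thresholds.limbic_high,
        left=StageNode(
            variable="limbic_strength",
            threshold=thresholds.limbic_low,
            left=StageNode(stage=1),
            right=StageNode(stage=2),
        ),
        right=StageNode(
            variable="global_efficiency",
            threshold=thresholds.efficiency,
            left=StageNode(stage=3),
            right=StageNode(stage=4),
        ),
    )
    return StageModel(root=root, feature_names=["limbic_strength", "global_efficiency"])


def threshold_stage(
    measures: NetworkMeasures | dict,
    subject_id: str = "",
    thresholds: StageThresholds = DEFAULT_THRESHOLDS,
) -> StageAssignment:
    """Assign an ordinal stage 1-4 from limbic strength and global efficiency."""
    if isinstance(measures, NetworkMeasures):
        limbic = measures.limbic_strength
        eff = measures.global_efficiency
    else:
        limbic = measures.get("limbic_strength")
        eff = measures.get("global_efficiency")
    if limbic is None or eff is None:
        raise ValueError("staging requires limbic_strength and global_efficiency")
    model = default_stage_model(thresholds)
    stage = model.predict_one(
        {"limbic_strength": float(limbic), "global_efficiency": float(eff)}
    )
    return StageAssignment(subject_id=subject_id, stage=stage)


# ---------------------------------------------------------------------------
# simplified conditional-inference tree learner


def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks (midranks for ties)."""
    from scipy.stats import rankdata

    return rankdata(a)


def _association_pvalue(
    x: np.ndarray, y_ranks: np.ndarray, rng: np.random.Generator, n_perm: int
) -> float:
    """Two-sided permutation p for the rank correlation of x with y.

    Uses the +1-corrected permutation estimator, which is a valid (slightly
    conservative) p-value at any permutation count.
    """
    xr = _rank(x)
    xr = xr - xr.mean()
    yr = y_ranks - y_ranks.mean()
    if np.allclose(xr, 0) or np.allclose(yr, 0):
        return 1.0
    t_obs = abs(float(xr @ yr))
    perms = rng.permuted(np.tile(yr, (n_perm, 1)), axis=1)
    t_perm = np.abs(perms @ xr)
    return float((1 + np.sum(t_perm >= t_obs - 1e-12)) / (n_perm + 1))


def _best_cut(x: np.ndarray, y_ranks: np.ndarray, min_node: int) -> float | None:
    """Cutpoint maximizing the standardized two-sample rank statistic.

    The statistic at a candidate cut is |sum of response ranks left of the
    cut − its expectation| / sd under random assignment; both branches must
    keep at least ``min_node`` rows. Ties in the criterion break toward the
    smallest cut value.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    ys = y_ranks[order]
    n = xs.size
    csum = np.cumsum(ys)
    total = csum[-1]
    ybar = total / n
    yvar = np.mean((ys - ybar) ** 2)
    if yvar <= 0:
        return None
    best_stat, best_cut = -np.inf, None
    for k in range(min_node, n - min_node + 1):
        if k < n and xs[k - 1] == xs[k]:
            continue  # cannot cut inside a tie group
        m = k
        mean_k = m * ybar
        var_k = m * (n - m) / (n - 1) * yvar
        stat = abs(csum[k - 1] - mean_k) / np.sqrt(var_k)
        if stat > best_stat + 1e-12:
            best_stat, best_cut = stat, float(xs[k - 1])
    return best_cut


def fit_stage_tree(
    features: pd.DataFrame,
    response: Sequence[float],
    alpha: float = 0.05,
    min_node: int = 20,
    n_perm: int = 9999,
    seed: int = 0,
) -> StageModel:
    """Learn an axis-aligned threshold tree by recursive rank-based splitting.

    Parameters
    ----------
    features : DataFrame of numeric columns (e.g. limbic strength, global
        efficiency).
    response : numeric vector (or integer-coded categories) driving the
        splits.
    alpha : significance level for the Bonferroni-corrected permutation
        p-value required to split a node.
    min_node : minimum rows per branch; a node smaller than ``2*min_node``
        becomes a leaf.
    n_perm : permutations per association test.
    seed : seed for the permutation generator (the fit is deterministic
        given it).
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    X = features.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("response length must match feature rows")
    if X.shape[0] < 2 * min_node:
        raise ValueError(f"need at least {2 * min_node} rows (2*min_node)")
    names = list(features.columns)
    rng = np.random.default_rng(seed)
    skipped: list[str] = []

    def grow(idx: np.ndarray) -> StageNode:
        node = StageNode(n=idx.size)
        ysub = y[idx]
        if idx.size < 2 * min_node or np.all(ysub == ysub[0]):
            return node
        y_ranks = _rank(ysub)
        pvals = []
        for j, name in enumerate(names):
            xj = X[idx, j]
            if np.all(xj == xj[0]):
                if name not in skipped:
                    skipped.append(name)
                pvals.append(1.0)
                continue
            pvals.append(_association_pvalue(xj, y_ranks, rng, n_perm))
        corrected = np.minimum(1.0, np.asarray(pvals) * len(names))
        j_best = int(np.argmin(corrected))
        if corrected[j_best] > alpha:
            return node
        cut = _best_cut(X[idx, j_best], y_ranks, min_node)
        if cut is None:
            return node
        go_left = X[idx, j_best] <= cut
        if not go_left.any() or go_left.all():
            return node
        node.variable = names[j_best]
        node.threshold = cut
        node.p_value = float(corrected[j_best])
        node.left = grow(idx[go_left])
        node.right = grow(idx[~go_left])
        return node

    root = grow(np.arange(X.shape[0]))
    model = StageModel(root=root, feature_names=names)
    _number_leaves(model, X, names)
    if skipped:
        model.skipped_features = skipped  # type: ignore[attr-defined]
    return model


def _number_leaves(model: StageModel, X: np.ndarray, names: list[str]) -> None:
    """Number leaves into stages by ascending mean of the first feature."""
    leaves: list[StageNode] = []
    first = X[:, 0]
    frame = pd.DataFrame(X, columns=names)

    def leaf_of(row: dict[str, float]) -> StageNode:
        node = model.root
        while not node.is_leaf:
            node = node.left if row[node.variable] <= node.threshold else node.right
        return node

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for i, row in enumerate(frame.to_dict("records")):
        leaf = leaf_of(row)
        key = id(leaf)
        if key not in sums:
            leaves.append(leaf)
            sums[key] = 0.0
            counts[key] = 0
        sums[key] += first[i]
        counts[key] += 1
    leaves.sort(key=lambda lf: sums[id(lf)] / max(counts[id(lf)], 1))
    for stage, leaf in enumerate(leaves, start=1):
        leaf.stage = stage


def stage_summary(
    profiles: Sequence,
    strengths: Sequence[np.ndarray],
    assignments: Sequence[StageAssignment],
    n_stages: int | None = None,
) -> pd.DataFrame:
    """Per-stage mean regional profile and mean nodal-strength vector.

    Empty stages are reported as all-NaN rows rather than dropped, so a
    four-stage model always yields four rows.
    """
    if not (len(profiles) == len(strengths) == len(assignments)):
        raise ValueError("profiles, strengths and assignments must align")
    stages = np.array([a.stage for a in assignments], dtype=int)
    if n_stages is None:
        n_stages = int(stages.max()) if stages.size else 0
    node_ids = list(profiles[0].node_ids) if profiles else []
    rows = []
    for stage in range(1, n_stages + 1):
        members = np.flatnonzero(stages == stage)
        row: dict[str, float] = {"stage": stage, "n": members.size}
        if members.size:
            prof_mean = np.mean([profiles[i].values for i in members], axis=0)
            str_mean = np.mean([np.asarray(strengths[i]) for i in members], axis=0)
        else:
            prof_mean = np.full(len(node_ids), np.nan)
            str_mean = np.full(len(node_ids), np.nan)
        for rid, pv, sv in zip(node_ids, prof_mean, str_mean):
            row[f"profile_{rid}"] = pv
            row[f"strength_{rid}"] = sv
        rows.append(row)
    return pd.DataFrame(rows)
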