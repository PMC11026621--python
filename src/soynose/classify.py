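"""Decision-tree and KNN classification of water-stress status.

The water-stress question is binary — was the plant irrigated or not —
and the published detector is a shallow axis-parallel decision tree over
min-max-normalised e-nose and chamber features.  This module provides

* :func:`reference_tree` — the fixed three-split tree reported for the
  reference experiment,
* :func:`train_tree` — a C4.5-style learner (information-gain ratio over
  midpoint thresholds, depth / min-leaf / purity stopping),
* :func:`knn_classify` — a k-nearest-neighbour baseline on normalised
  features,
* row-normalised confusion-matrix evaluation with grouped
  leave-plants-out splitting, so that replicate samples of one plant never
  straddle the train/test boundary.

Ties anywhere resolve toward "irrigated": misreporting a watered plant as
stressed is the less harmful error, so ambiguity never hides true stress
by accident of ordering.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("irrigated", "non_irrigated")

_EPS = 1e-12


@dataclass
class TreeNode:
    """Internal split (feature, threshold, left<=, right>) or class leaf."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: str | None = None

    def __post_init__(self) -> None:
        if self.klass is None:
            if self.feature is None or self.threshold is None or self.left is None or self.right is None:
                raise ValueError("internal node needs feature, threshold and both children")
            if not np.isfinite(self.threshold):
                raise ValueError("threshold must be finite")
        elif self.feature is not None or self.left is not None or self.right is not None:
            raise ValueError("leaf cannot carry a split")

    @property
    def is_leaf(self) -> bool:
        return self.klass is not None

    def predict(self, features: Mapping[str, float]) -> str:
        node = self
        while not node.is_leaf:
            if node.feature not in features:
                raise KeyError(f"feature {node.feature!r} missing from input")
            node = node.left if features[node.feature] <= node.threshold else node.right
        return node.klass  # type: ignore[return-value]

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())  # type: ignore[union-attr]

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()  # type: ignore[union-attr]

    # -- plain-text serialization (JSON-compatible, human-diffable) --------

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),    # type: ignore[union-attr]
            "right": self.right.to_dict(),  # type: ignore[union-attr]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreeNode":
        if "class" in d:
            return cls(klass=str(d["class"]))
        return cls(
            feature=str(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TreeNode":
        return cls.from_dict(json.loads(Path(path).read_text()))


def reference_tree() -> TreeNode:
    """The fixed three-split water-stress tree from the reference experiment.

    Features are min-max normalised to [0,1]:

    * root: ``regression_max_sensor_6 <= 0.829849`` (trend of the PA/2
      peak magnitude across days),
    * left child: ``max_sensor_6 <= 0.315273`` — yes: irrigated, no:
      non-irrigated,
    * right child: ``regression_temperature_int <= 0.714568`` — yes:
      irrigated, no: non-irrigated.
    """
    return TreeNode(
        feature="regression_max_sensor_6",
        threshold=0.829849,
        left=TreeNode(
            feature="max_sensor_6",
            threshold=0.315273,
            left=TreeNode(klass="irrigated"),
            right=TreeNode(klass="non_irrigated"),
        ),
        right=TreeNode(
            feature="regression_temperature_int",
            threshold=0.714568,
            left=TreeNode(klass="irrigated"),
            right=TreeNode(klass="non_irrigated"),
        ),
    )


def _majority(labels: Sequence[str]) -> str:
    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(k for k, v in counts.items() if v == top)
    if len(tied) > 1 and "irrigated" in tied:
        return "irrigated"
    return tied[0]


def _entropy_from_counts(pos: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Binary entropy (bits) given positive counts and totals (vectorised)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, pos / np.maximum(n, 1), 0.0)
        h = np.zeros_like(p, dtype=float)
        for q in (p, 1.0 - p):
            term = np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
            h = h + term
    return h


def _best_split(
    X: np.ndarray,
    ybin: np.ndarray,
    feature_names: Sequence[str],
    min_leaf: int,
) -> tuple[str, float] | None:
    """Best (feature, midpoint threshold) by information-gain ratio.

    Ties (within 1e-12 of the best ratio) break by feature name then by
    threshold value, making training invariant to row order.
    """
    n = ybin.size
    pos_total = float(ybin.sum())
    parent_h = float(_entropy_from_counts(np.array([pos_total]), np.array([n]))[0])
    best: tuple[float, str, float] | None = None  # (ratio, name, threshold)
    order_names = np.argsort(feature_names)
    for j in order_names:
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        vs = col[order]
        ys = ybin[order]
        cum_pos = np.cumsum(ys)
        idx = np.nonzero(vs[:-1] < vs[1:])[0]  # split after position i
        if idx.size == 0:
            continue
        n_left = idx + 1.0
        n_right = n - n_left
        valid = (n_left >= min_leaf) & (n_right >= min_leaf)
        if not valid.any():
            continue
        idx = idx[valid]
        n_left = n_left[valid]
        n_right = n_right[valid]
        pos_left = cum_pos[idx].astype(float)
        pos_right = pos_total - pos_left
        h_left = _entropy_from_counts(pos_left, n_left)
        h_right = _entropy_from_counts(pos_right, n_right)
        gain = parent_h - (n_left * h_left + n_right * h_right) / n
        pl = n_left / n
        split_info = -(pl * np.log2(pl) + (1.0 - pl) * np.log2(1.0 - pl))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(split_info > 0, gain / split_info, 0.0)
        ratio = np.where(gain > _EPS, ratio, -np.inf)
        if not np.any(np.isfinite(ratio)):
            continue
        k = int(np.argmax(ratio))  # first occurrence = smallest threshold on ties
        if ratio[k] == -np.inf:
            continue
        thr = 0.5 * (vs[idx[k]] + vs[idx[k] + 1])
        name = feature_names[j]
        if best is None or ratio[k] > best[0] + _EPS:
            best = (float(ratio[k]), name, float(thr))
        # equal ratios: earlier feature name wins (iteration is name-sorted)
    if best is None:
        return None
    return best[1], best[2]


def train_tree(
    X: pd.DataFrame,
    y: Sequence[str],
    *,
    max_depth: int | None = 5,
    min_leaf: int = 5,
) -> TreeNode:
    """Recursive-partitioning tree maximising the information-gain ratio.

    Candidate thresholds are midpoints between consecutive distinct sorted
    feature values; recursion stops on purity, ``max_depth``, or when no
    split leaves ``min_leaf`` rows on each side.  Leaves take the majority
    class, ties resolving to ``"irrigated"``.  Training is deterministic
    and invariant to row permutations.
    """
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    labels = np.asarray(list(y), dtype=object)
    if labels.size == 0:
        raise ValueError("empty training data")
    if len(X) != labels.size:
        raise ValueError("X and y length mismatch")
    if X.shape[1] == 0:
        raise ValueError("need at least one feature")
    if labels.size < min_leaf:
        raise ValueError(f"need at least min_leaf={min_leaf} rows")
    feature_names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    classes = sorted(set(labels.tolist()))
    if len(classes) > 2:
        raise ValueError("binary classification only")
    positive = classes[-1]
    ybin = (labels == positive).astype(float)
    depth_cap = np.inf if max_depth is None else max_depth

    def grow(rows: np.ndarray, depth: int) -> TreeNode:
        ys = labels[rows]
        if depth >= depth_cap or rows.size < 2 * min_leaf or len(set(ys.tolist())) == 1:
            return TreeNode(klass=_majority(ys.tolist()))
        found = _best_split(Xv[rows], ybin[rows], feature_names, min_leaf)
        if found is None:
            return TreeNode(klass=_majority(ys.tolist()))
        name, thr = found
        col = Xv[rows, feature_names.index(name)]
        left_rows = rows[col <= thr]
        right_rows = rows[col > thr]
        return TreeNode(
            feature=name,
            threshold=thr,
            left=grow(left_rows, depth + 1),
            right=grow(right_rows, depth + 1),
        )

    return grow(np.arange(labels.size), 0)


def training_accuracy(tree: TreeNode, X: pd.DataFrame, y: Sequence[str]) -> float:
    preds = [tree.predict(row) for row in X.to_dict(orient="records")]
    return float(np.mean([p == t for p, t in zip(preds, y)]))


def exhaustive_tree_accuracy(X: pd.DataFrame, y: Sequence[str]) -> float:
    """Training accuracy of the best possible (depth-unbounded) axis tree.

    With unlimited depth an axis-parallel tree can isolate every distinct
    feature vector, so the optimum is the majority count within each group
    of identical rows — an exact brute-force-equivalent oracle.
    """
    labels = list(y)
    groups: dict[tuple, Counter] = {}
    for row, lab in zip(X.to_numpy(dtype=float), labels):
        groups.setdefault(tuple(row), Counter()).update([lab])
    correct = sum(max(c.values()) for c in groups.values())
    return correct / len(labels)


def knn_classify(
    train_X: pd.DataFrame | np.ndarray,
    train_y: Sequence[str],
    query: Mapping[str, float] | Sequence[float],
    k: int,
) -> str:
    """Majority vote among the k nearest training rows (Euclidean).

    Vote ties break toward the tied class with the smaller summed distance
    within the neighbourhood, then toward "irrigated".  Features should be
    normalised to comparable scales before calling.
    """
    if isinstance(train_X, pd.DataFrame):
        cols = list(train_X.columns)
        Xv = train_X.to_numpy(dtype=float)
        if isinstance(query, Mapping):
            q = np.array([float(query[c]) for c in cols])
        else:
            q = np.asarray(query, dtype=float)
    else:
        Xv = np.asarray(train_X, dtype=float)
        if isinstance(query, Mapping):
            raise TypeError("mapping query requires a DataFrame training set")
        q = np.asarray(query, dtype=float)
    labels = list(train_y)
    if Xv.shape[0] == 0:
        raise ValueError("empty training set")
    if not 1 <= k <= Xv.shape[0]:
        raise ValueError(f"k must be in 1..{Xv.shape[0]}")
    d = np.sqrt(np.sum((Xv - q) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[:k]
    votes = Counter(labels[i] for i in order)
    top = max(votes.values())
    tied = [c for c, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    sums = {c: float(sum(d[i] for i in order if labels[i] == c)) for c in tied}
    best = min(sums.values())
    closest = sorted(c for c, s in sums.items() if s <= best + _EPS)
    if "irrigated" in closest:
        return "irrigated"
    return closest[0]


@dataclass
class ConfusionMatrix:
    """2x2 counts, true class in rows, predicted in columns."""

    counts: np.ndarray
    labels: tuple[str, str] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts shape must match labels")

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        labels: tuple[str, str] = CLASSES,
    ) -> "ConfusionMatrix":
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            if t not in index:
                raise ValueError(f"true label {t!r} not in {labels}")
            if p not in index:
                raise ValueError(f"predicted label {p!r} not in {labels}")
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, labels)

    @property
    def row_percent(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    @property
    def accuracy_pct(self) -> float:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty confusion matrix")
        return 100.0 * float(np.trace(self.counts)) / float(total)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.row_percent if percent else self.counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))

    def summary(self) -> str:
        pct = self.row_percent
        width = max(len(l) for l in self.labels) + 2
        header = " " * width + "".join(f"{l:>16}" for l in self.labels)
        lines = [header]
        for i, lab in enumerate(self.labels):
            cells = "".join(
                f"{pct[i, j]:15.1f}%" if np.isfinite(pct[i, j]) else f"{'-':>16}"
                for j in range(len(self.labels))
            )
            lines.append(f"{lab:<{width}}" + cells)
        lines.append(f"accuracy: {self.accuracy_pct:.1f}%")
        return "\n".join(lines)


Model = TreeNode | Callable[[Mapping[str, float]], str]


def evaluate(
    model: Model,
    X: pd.DataFrame,
    y: Sequence[str],
    labels: tuple[str, str] = CLASSES,
) -> tuple[ConfusionMatrix, float]:
    """Row-normalised confusion matrix and overall accuracy (%) on a test set."""
    if len(X) == 0:
        raise ValueError("empty test set")
    predict = model.predict if isinstance(model, TreeNode) else model
    preds = [predict(row) for row in X.to_dict(orient="records")]
    cm = ConfusionMatrix.from_predictions(list(y), preds, labels)
    return cm, cm.accuracy_pct


def split_by_plants(
    plant_ids: Sequence[int],
    n_test: int = 3,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[int], list[int]]:
    """Grouped leave-plants-out split: whole plants go to train or test."""
    plants = sorted(set(int(p) for p in plant_ids))
    if not 1 <= n_test < len(plants):
        raise ValueError(f"n_test must be in 1..{len(plants) - 1}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    test = sorted(rng.choice(plants, size=n_test, replace=False).tolist())
    train = [p for p in plants if p not in test]
    return train, test
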