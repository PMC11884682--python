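"""Centrality random forest (c-rf): the permutation-importance baseline.

ROI-pair features are scored with Breiman-style out-of-bag (OOB) permutation
importance from a random forest classifier, the top-k pairs (k = 200 by
default) define the ROI network, and node centralities rank individual ROIs.

The forest itself is scikit-learn's ``RandomForestClassifier`` with its
conventional classification defaults apart from the tree count.  The OOB
permutation importance is computed here: for every tree, the OOB samples'
accuracy drop is measured after permuting each feature the tree actually
splits on (features a tree never uses contribute an exact zero), and the
drops are averaged over all trees.  The per-tree evaluation runs in a
jit-compiled kernel so 5000-tree forests stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datasets import CorrelationDataset
from .netrank import CentralityScores, build_pair_network, centrality
from .npdr import apply_threshold

__all__ = ["RFConfig", "rf_pair_importance", "crf_rank_rois"]


@dataclass
class RFConfig:
    """Random-forest baseline parameters (5000 trees, top-200 pair cutoff)."""

    n_trees: int = 5000
    top_k: int = 200
    seed: int = 0
    importance_type: str = field(default="permutation")

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.importance_type != "permutation":
            raise ValueError("only permutation importance is supported")


@njit(cache=True)
def _tree_oob_importance(
    left, right, feat, thresh, leaf_class, x_oob, y_oob, used, perm, imp
):
    """Accuracy drop per used feature for one tree, accumulated into imp.

    ``perm`` is a permutation of the OOB rows; permuting feature f is realized
    by reading column f from row perm[s] instead of row s during traversal.
    """
    n = x_oob.shape[0]
    base_correct = 0
    for s in range(n):
        node = 0
        while left[node] != -1:
            if x_oob[s, feat[node]] <= thresh[node]:
                node = left[node]
            else:
                node = right[node]
        if leaf_class[node] == y_oob[s]:
            base_correct += 1
    base_acc = base_correct / n
    for k in range(used.shape[0]):
        f = used[k]
        correct = 0
        for s in range(n):
            node = 0
            while left[node] != -1:
                fnode = feat[node]
                if fnode == f:
                    v = x_oob[perm[s], fnode]
                else:
                    v = x_oob[s, fnode]
                if v <= thresh[node]:
                    node = left[node]
                else:
                    node = right[node]
            if leaf_class[node] == y_oob[s]:
                correct += 1
        imp[f] += base_acc - correct / n
    return base_acc


def rf_pair_importance(dataset: CorrelationDataset, config: RFConfig | None = None) -> pd.DataFrame:
    """Out-of-bag permutation importance of every ROI-pair feature.

    Returns an importance table (``feature_id, importance, selected``) sorted
    in feature order; the forest's OOB classification accuracy is attached as
    ``table.attrs["oob_accuracy"]`` as a diagnostic, and the tree
    hyperparameters as ``table.attrs["rf_params"]``.  Importances on pure
    noise are seed-dependent and centered at zero; rankings should only be
    interpreted jointly with the OOB accuracy.
    """
    from sklearn.ensemble import RandomForestClassifier

    config = config or RFConfig()
    y = dataset.phenotype
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("phenotype must contain at least two samples of each class")

    x = np.ascontiguousarray(dataset.feature_matrix, dtype=np.float32)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, oob_score=True, random_state=config.seed, n_jobs=1
    )
    rf.fit(x, y)

    n, p = x.shape
    imp = np.zeros(p)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    all_idx = np.arange(n)
    for est, sampled in zip(rf.estimators_, rf.estimators_samples_):
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        oob = all_idx[mask]
        if len(oob) == 0:
            continue
        tree = est.tree_
        used = np.unique(tree.feature[tree.feature >= 0])
        if len(used) == 0:
            continue
        leaf_class = rf.classes_[np.argmax(tree.value[:, 0, :], axis=1)].astype(np.int64)
        x_oob = np.ascontiguousarray(x[oob])
        y_oob = y[oob].astype(np.int64)
        perm = rng.permutation(len(oob))
        _tree_oob_importance(
            tree.children_left,
            tree.children_right,
            tree.feature,
            tree.threshold,
            leaf_class,
            x_oob,
            y_oob,
            used,
            perm,
            imp,
        )
    imp /= config.n_trees

    table = pd.DataFrame({"feature_id": dataset.pair_labels, "importance": imp})
    table["selected"] = table["feature_id"].isin(
        apply_threshold(table, "top_k", k=config.top_k)
    )
    table.attrs["oob_accuracy"] = float(rf.oob_score_)
    table.attrs["rf_params"] = {
        "n_estimators": config.n_trees,
        "criterion": rf.criterion,
        "max_features": rf.max_features,
        "max_depth": rf.max_depth,
        "min_samples_split": rf.min_samples_split,
        "min_samples_leaf": rf.min_samples_leaf,
        "bootstrap": rf.bootstrap,
        "random_state": config.seed,
    }
    return table


def crf_rank_rois(
    dataset: CorrelationDataset,
    config: RFConfig | None = None,
    centrality_method: str = "degree",
    *,
    importance_table: pd.DataFrame | None = None,
) -> CentralityScores:
    """Rank ROIs by centrality on the network of the top-k RF pairs.

    Composition: permutation importance -> top-k threshold -> pair network ->
    centrality.  A precomputed importance table may be passed to reuse one
    forest across several centralities.
    """
    config = config or RFConfig()
    if importance_table is None:
        importance_table = rf_pair_importance(dataset, config)
    top = apply_threshold(importance_table, "top_k", k=config.top_k)
    net = build_pair_network(top, dataset.roi_names)
    return centrality(net, centrality_method)
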