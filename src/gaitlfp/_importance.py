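"""Out-of-bag permutation importance for sklearn random forests.

ranger-style variable importance: for every tree, classify its out-of-bag
rows, then re-classify them with one feature's values permuted among the
OOB rows; the importance of a feature is the mean accuracy drop across
trees.  Implemented as a numba kernel over the forest's exported node
arrays so that thousands of candidate-band features stay tractable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _predict_row(row_idx, perm_feature, perm_value, X,
                 children_left, children_right, feature, threshold, leaf_class):
    node = 0
    while children_left[node] != -1:
        f = feature[node]
        v = perm_value if f == perm_feature else X[row_idx, f]
        node = children_left[node] if v <= threshold[node] else children_right[node]
    return leaf_class[node]


@njit(cache=True)
def _oob_importance_kernel(X, y, oob_mask, node_offsets,
                           children_left, children_right, feature, threshold,
                           leaf_class, seed):
    n_trees = oob_mask.shape[0]
    n_features = X.shape[1]
    imp = np.zeros(n_features)
    n_used = 0
    np.random.seed(seed)
    for t in range(n_trees):
        off = node_offsets[t]
        cl = children_left[off:node_offsets[t + 1]]
        cr = children_right[off:node_offsets[t + 1]]
        ft = feature[off:node_offsets[t + 1]]
        th = threshold[off:node_offsets[t + 1]]
        lc = leaf_class[off:node_offsets[t + 1]]
        oob = np.flatnonzero(oob_mask[t])
        n_oob = oob.size
        if n_oob < 2:
            continue
        n_used += 1
        base = 0.0
        for i in range(n_oob):
            if _predict_row(oob[i], -1, 0.0, X, cl, cr, ft, th, lc) == y[oob[i]]:
                base += 1.0
        base /= n_oob
        # permuting a feature this tree never splits on cannot change its
        # predictions, so only the tree's own split features need scoring
        used = np.unique(ft[ft >= 0])
        for k in range(used.size):
            f = used[k]
            perm = np.random.permutation(n_oob)
            correct = 0.0
            for i in range(n_oob):
                v = X[oob[perm[i]], f]
                if _predict_row(oob[i], f, v, X, cl, cr, ft, th, lc) == y[oob[i]]:
                    correct += 1.0
            imp[f] += base - correct / n_oob
    if n_used > 0:
        imp /= n_used
    return imp


def oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray,
                               seed: int = 0) -> np.ndarray:
    """Per-feature OOB permutation importance of a fitted sklearn forest."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    # map labels onto the forest's internal class indices
    y = np.searchsorted(forest.classes_, np.asarray(y)).astype(np.int64)
    n = X.shape[0]
    oob_mask = np.ones((len(forest.estimators_), n), dtype=np.bool_)
    for t, sampled in enumerate(forest.estimators_samples_):
        oob_mask[t, sampled] = False
    offsets = [0]
    cl, cr, ft, th, lc = [], [], [], [], []
    for est in forest.estimators_:
        tree = est.tree_
        cl.append(tree.children_left)
        cr.append(tree.children_right)
        ft.append(tree.feature)
        th.append(tree.threshold)
        counts = tree.value[:, 0, :] if tree.value.ndim == 3 else tree.value
        lc.append(np.argmax(counts, axis=1).astype(np.int64))
        offsets.append(offsets[-1] + tree.node_count)
    return _oob_importance_kernel(
        X, y, oob_mask, np.asarray(offsets, dtype=np.int64),
        np.concatenate(cl).astype(np.int64), np.concatenate(cr).astype(np.int64),
        np.concatenate(ft).astype(np.int64), np.concatenate(th).astype(np.float64),
        np.concatenate(lc), seed,
    )
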