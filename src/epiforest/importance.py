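"""Out-of-bag permutation importance.

For tree j with OOB set of size N_j, the contribution of SNP A is the drop in
the number of correctly classified OOB individuals after permuting A's
genotypes among the OOB individuals only, divided by N_j; the importance
I(A) is the average of these contributions over all T trees (trees with no
OOB individuals contribute 0 but still enter the 1/T average).  One
permutation is drawn per (tree, SNP).  SNPs never used by a tree are skipped:
their predictions, and hence their contribution from that tree, are exactly
unchanged by the permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._kernels import tree_importance_kernel
from .forest import EpistasisForest

__all__ = ["importance_scores", "importance_table"]


def importance_scores(forest: EpistasisForest, X, y, random_state: int | None = None,
                      _identity_permutation: bool = False) -> np.ndarray:
    """Permutation importance I(A) of every SNP; shape (n_snps,).

    ``_identity_permutation`` is a test hook that replaces every permutation
    by the identity, in which case all scores are exactly 0.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if not hasattr(forest, "trees_"):
        raise ValueError("forest is not fitted")
    if X.shape[1] != forest.n_features_in_ or X.shape[0] != forest.inbag_count_.shape[1]:
        raise ValueError("forest and dataset shapes do not match")
    T = len(forest.trees_)
    m = forest.n_features_in_
    ss = np.random.SeedSequence(random_state)
    streams = ss.spawn(T)
    totals = np.zeros(m, dtype=np.float64)
    oob_mask = forest.inbag_count_ == 0
    for j, tree in enumerate(forest.trees_):
        oob = np.flatnonzero(oob_mask[j]).astype(np.int64)
        nj = oob.size
        if nj == 0:
            continue
        used = tree.used_snps().astype(np.int64)
        if used.size == 0:
            continue
        rng = np.random.Generator(np.random.PCG64(streams[j]))
        permvals = np.empty((used.size, nj), dtype=np.int8)
        for u, s in enumerate(used):
            if _identity_permutation:
                permvals[u] = X[oob, s]
            else:
                permvals[u] = X[oob[rng.permutation(nj)], s]
        base, corr = tree_importance_kernel(
            tree.feature_a, tree.feature_b, tree.left_mask,
            tree.children_left, tree.children_right, tree.leaf_class,
            X, y, oob, used, permvals,
        )
        totals[used] += (base - corr) / nj
    return totals / T


def importance_table(forest: EpistasisForest, X, y, snp_ids=None,
                     random_state: int | None = None) -> pd.DataFrame:
    """Importance scores as a ranked table (snp_id, importance, rank)."""
    scores = importance_scores(forest, X, y, random_state=random_state)
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(scores.size)]
    df = pd.DataFrame({"snp_id": list(snp_ids), "importance": scores})
    df["rank"] = df["importance"].rank(ascending=False, method="min").astype(int)
    return df.sort_values("rank", kind="stable").reset_index(drop=True)
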