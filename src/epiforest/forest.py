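"""Random forest over categorical SNP genotypes with paired-SNP node splits.

Each tree is grown on a bootstrap sample (N draws with replacement from the N
individuals).  At every node, ``mtry`` candidate split variables are drawn
uniformly without replacement from the union of all single SNPs and all
unordered SNP pairs; the candidate and bipartition with the largest Gini
decrease is chosen.  Allowing pair variables is what lets loci with no
marginal effect reach the root of trees, which both the permutation
importance and the branch co-occurrence interaction score rely on.

Stopping rules (the growth procedure is otherwise unbounded): a node becomes
a leaf when it is class-pure, holds fewer than ``min_node_size`` individuals,
or no sampled candidate yields a positive Gini decrease.  Ties at equal
decrease prefer fewer SNPs, then smaller SNP indices (a parsimony bias
against spurious pair splits), realized by scanning candidates in sorted
order with strict improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._kernels import node_cells, predict_kernel, sample_and_best_split
from .splitting import SplitRule, SplitVariable, n_candidate_variables

__all__ = ["Tree", "EpistasisForest", "build_forest", "grow_tree", "predict_tree"]

#: numerical guard against splitting on floating-point dust
_MIN_GAIN = 1e-12


@dataclass
class Tree:
    """One classification tree in flat-array form.

    ``feature_b[i] == -1`` marks a single-SNP split; ``leaf_class[i] == -1``
    marks an internal node.  ``left_mask`` is the canonical cell bitmask of
    the rule (bit c set == cell c routes left).  ``n0``/``n1`` are the in-bag
    control/case counts at each node and ``decrease`` the realized Gini
    decrease of internal nodes (0 at leaves).
    """

    feature_a: np.ndarray
    feature_b: np.ndarray
    left_mask: np.ndarray
    children_left: np.ndarray
    children_right: np.ndarray
    leaf_class: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    decrease: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature_a.size

    @property
    def n_internal(self) -> int:
        return int((self.leaf_class < 0).sum())

    def used_snps(self) -> np.ndarray:
        """Distinct SNP indices appearing in this tree's split variables."""
        internal = self.leaf_class < 0
        labels = np.concatenate([
            self.feature_a[internal],
            self.feature_b[internal][self.feature_b[internal] >= 0],
        ])
        return np.unique(labels)

    def rule(self, node: int) -> SplitRule:
        a = int(self.feature_a[node])
        b = int(self.feature_b[node])
        var = SplitVariable((a,) if b < 0 else (a, b))
        return SplitRule.from_mask(var, int(self.left_mask[node]))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.int8)
        rows = np.arange(X.shape[0], dtype=np.int64)
        return predict_kernel(
            self.feature_a, self.feature_b, self.left_mask,
            self.children_left, self.children_right, self.leaf_class, X, rows,
        )

    def to_dict(self) -> dict:
        return {
            "feature_a": self.feature_a.tolist(),
            "feature_b": self.feature_b.tolist(),
            "left_mask": self.left_mask.tolist(),
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "leaf_class": self.leaf_class.tolist(),
            "n0": self.n0.tolist(),
            "n1": self.n1.tolist(),
            "decrease": self.decrease.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Tree":
        return cls(
            feature_a=np.asarray(d["feature_a"], np.int32),
            feature_b=np.asarray(d["feature_b"], np.int32),
            left_mask=np.asarray(d["left_mask"], np.int64),
            children_left=np.asarray(d["children_left"], np.int32),
            children_right=np.asarray(d["children_right"], np.int32),
            leaf_class=np.asarray(d["leaf_class"], np.int8),
            n0=np.asarray(d["n0"], np.int64),
            n1=np.asarray(d["n1"], np.int64),
            decrease=np.asarray(d["decrease"], np.float64),
        )


def grow_tree(rng: np.random.Generator, X, y, *, mtry: int, max_combo_order: int = 2,
              min_node_size: int = 8, bootstrap=None) -> Tree:
    """Grow one tree on the given bootstrap multiset of row indices.

    ``bootstrap=None`` uses every row once (no resampling), which is handy for
    deterministic toy examples.  Candidates are resampled independently at
    every node.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    n, m = X.shape
    if bootstrap is None:
        bootstrap = np.arange(n, dtype=np.int64)
    else:
        bootstrap = np.asarray(bootstrap, dtype=np.int64)
    if bootstrap.size == 0:
        raise ValueError("bootstrap sample must be nonempty")

    fa, fb, mask, cl, cr, leafc, n0s, n1s, decs = [], [], [], [], [], [], [], [], []

    def new_node():
        for lst, val in ((fa, -1), (fb, -1), (mask, 0), (cl, -1), (cr, -1),
                         (leafc, -1), (n0s, 0), (n1s, 0), (decs, 0.0)):
            lst.append(val)
        return len(fa) - 1

    root = new_node()
    # LIFO stack, right child pushed first => preorder node numbering
    stack = [(root, bootstrap)]
    while stack:
        node, idx = stack.pop()
        yn = y[idx]
        n1 = int(yn.sum())
        n0 = idx.size - n1
        n0s[node], n1s[node] = n0, n1
        make_leaf = n0 == 0 or n1 == 0 or idx.size < min_node_size
        best = (-1, -1, 0, 0.0)
        if not make_leaf:
            node_seed = np.uint64(rng.integers(0, 2 ** 63))
            best = sample_and_best_split(X, y, idx, m, mtry, max_combo_order,
                                         node_seed, _MIN_GAIN)
            if best[0] < 0:
                make_leaf = True
        if make_leaf:
            leafc[node] = 1 if n1 > n0 else 0  # tie -> control
            continue
        a, b, rule_mask, dec = int(best[0]), int(best[1]), int(best[2]), float(best[3])
        cells = node_cells(X, idx, a, b)
        left_sel = ((rule_mask >> cells) & 1).astype(bool)
        fa[node], fb[node], mask[node], decs[node] = a, b, rule_mask, dec
        left = new_node()
        right = new_node()
        cl[node], cr[node] = left, right
        stack.append((right, idx[~left_sel]))
        stack.append((left, idx[left_sel]))

    return Tree(
        feature_a=np.asarray(fa, np.int32),
        feature_b=np.asarray(fb, np.int32),
        left_mask=np.asarray(mask, np.int64),
        children_left=np.asarray(cl, np.int32),
        children_right=np.asarray(cr, np.int32),
        leaf_class=np.asarray(leafc, np.int8),
        n0=np.asarray(n0s, np.int64),
        n1=np.asarray(n1s, np.int64),
        decrease=np.asarray(decs, np.float64),
    )


def predict_tree(tree: Tree, genotype_row) -> int:
    """Class predicted by one tree for a single genotype row."""
    row = np.ascontiguousarray(np.atleast_2d(genotype_row), dtype=np.int8)
    return int(tree.predict(row)[0])


class EpistasisForest(ClassifierMixin, BaseEstimator):
    """Random-forest classifier with single-SNP and SNP-pair node splits.

    Parameters
    ----------
    n_trees : int
        Number of trees grown on bootstrap samples.
    mtry : int or None
        Candidate split variables sampled per node, without replacement from
        the union of all singles and all unordered pairs.  None uses ~10% of
        that universe (the convention used for the simulation benchmark).
    max_combo_order : {1, 2}
        1 restricts candidates to single SNPs (the classical categorical
        random forest); 2 adds all unordered SNP pairs.
    min_node_size : int
        Nodes smaller than this become leaves.  The default 8 keeps roughly
        one sample per genotype cell at the smallest pair-splittable node.
    random_state : int or None
        Master seed; per-tree substreams are spawned from it so forests are
        reproducible and trees independent.

    Attributes
    ----------
    trees_ : list of Tree
    inbag_count_ : ndarray (n_trees, n_samples)
        Bootstrap multiplicities; ``inbag_count_ == 0`` is the OOB indicator.
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 max_combo_order: int = 2, min_node_size: int = 8,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.max_combo_order = max_combo_order
        self.min_node_size = min_node_size
        self.random_state = random_state

    # -- fitting -------------------------------------------------------
    def _validate_X(self, X) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.int8)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d genotype matrix")
        if X.size and (X.min() < 0 or X.max() > 2):
            raise ValueError("genotype codes must be 0, 1 or 2")
        return X

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must contain 0/1 labels")
        y = y.astype(np.int8)
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_combo_order not in (1, 2):
            raise ValueError("max_combo_order must be 1 or 2")
        n, m = X.shape
        universe = n_candidate_variables(m, self.max_combo_order)
        mtry = self.mtry if self.mtry is not None else max(1, round(0.1 * universe))
        mtry = min(mtry, universe)
        if mtry < 1:
            raise ValueError("mtry must be >= 1")

        ss = np.random.SeedSequence(self.random_state)
        children = ss.spawn(self.n_trees)
        self.classes_ = np.array([0, 1], dtype=np.int8)
        self.n_features_in_ = m
        self.mtry_ = mtry
        trees = []
        inbag = np.zeros((self.n_trees, n), dtype=np.uint16)
        for j in range(self.n_trees):
            rng = np.random.Generator(np.random.PCG64(children[j]))
            boot = rng.integers(0, n, size=n)
            np.add.at(inbag[j], boot, 1)
            trees.append(grow_tree(
                rng, X, y, mtry=mtry, max_combo_order=self.max_combo_order,
                min_node_size=self.min_node_size, bootstrap=boot,
            ))
        self.trees_ = trees
        self.inbag_count_ = inbag
        return self

    # -- inference -----------------------------------------------------
    @property
    def oob_indicator_(self) -> np.ndarray:
        """t_ij matrix: 1 when individual i is out-of-bag for tree j (trees x individuals)."""
        return (self.inbag_count_ == 0).astype(np.int8)

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of SNPs than the fitted forest")
        votes = np.zeros(X.shape[0], dtype=np.int64)
        for tree in self.trees_:
            votes += tree.predict(X)
        p1 = votes / len(self.trees_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(np.int8)

    # -- serialization -------------------------------------------------
    def to_json(self, path=None):
        """Serialize the fitted forest (topology, rules, bootstraps) to JSON."""
        d = {
            "params": self.get_params(),
            "n_features_in": int(self.n_features_in_),
            "mtry_used": int(self.mtry_),
            "inbag_count": self.inbag_count_.tolist(),
            "trees": [t.to_dict() for t in self.trees_],
        }
        if path is None:
            return d
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, source) -> "EpistasisForest":
        if isinstance(source, dict):
            d = source
        else:
            with open(source) as fh:
                d = json.load(fh)
        est = cls(**d["params"])
        est.classes_ = np.array([0, 1], dtype=np.int8)
        est.n_features_in_ = int(d["n_features_in"])
        est.mtry_ = int(d["mtry_used"])
        est.inbag_count_ = np.asarray(d["inbag_count"], dtype=np.uint16)
        est.trees_ = [Tree.from_dict(t) for t in d["trees"]]
        return est


def build_forest(X, y, *, n_trees: int, mtry: int | None = None,
                 max_combo_order: int = 2, min_node_size: int = 8,
                 random_state: int | None = None) -> EpistasisForest:
    """Functional wrapper: fit an :class:`EpistasisForest` on (X, y)."""
    return EpistasisForest(
        n_trees=n_trees, mtry=mtry, max_combo_order=max_combo_order,
        min_node_size=min_node_size, random_state=random_state,
    ).fit(X, y)
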