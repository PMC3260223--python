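"""Branch co-occurrence interaction scores with a randomization null.

Every root-to-leaf path ("branch") of every tree contributes the set of
distinct SNPs split on along it; the raw interaction score of a SNP
combination G counts its simultaneous appearances in branches over the
forest.  To avoid bias towards combinations near the top of a branch —
which would otherwise be counted once for every leaf below them — each
combination is counted at most once per tree by default
(``count_scope='tree'``); counting once per branch instead
(``count_scope='branch'``) is available and satisfies the exact
conservation identity sum_G inter(G) = sum_branches C(|set|, 2), but a
single spurious shallow pair-split then contributes as many counts as there
are leaves below it, which the label-randomization baseline of a
moderately-sized forest cannot match (see the methods note).

The null distribution is obtained by shuffling the SNP labels
over the split-variable slots of the forest while keeping tree topology and
per-SNP usage counts fixed, and recounting; the normalized score is

    INTER(G) = (raw(G) - mean_random(G)) / sd_random(G)

and a combination is called when INTER exceeds ``threshold_sigma`` (default
25, strict inequality).  Combinations never observed in any randomization
have mean 0 and an undefined sd; their sd is floored (see
``InteractionConfig.sd_floor``) so a handful of chance co-occurrences cannot
masquerade as overwhelming evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import branch_sets_kernel, count_combos, emit_combos_kernel, tree_depth_leaves
from .forest import EpistasisForest, Tree

__all__ = [
    "InteractionConfig",
    "branch_snp_sets",
    "raw_interaction_scores",
    "randomize_forest_labels",
    "normalized_scores",
    "call_interactions",
    "write_interactions",
]


@dataclass
class InteractionConfig:
    """Scoring configuration.

    combo_sizes: which combination orders to score (subset of {2, 3}).
    n_randomizations: label shuffles used to build the baseline (>= 2).
    threshold_sigma: detection threshold on the normalized score (strict >).
    sd_floor: lower bound on the baseline sd, in co-occurrence counts.
    scope: 'forest' permutes labels across the whole forest at once
        (preserves forest-wide SNP usage); 'tree' permutes within each tree.
    count_scope: 'tree' counts a combination at most once per tree (default;
        removes the bias towards combinations near the root); 'branch'
        counts once per branch.
    """

    combo_sizes: tuple[int, ...] = (2,)
    n_randomizations: int = 100
    threshold_sigma: float = 25.0
    sd_floor: float = 1.0
    scope: str = "forest"
    count_scope: str = "tree"

    def __post_init__(self):
        self.combo_sizes = tuple(sorted(set(int(s) for s in self.combo_sizes)))
        if not self.combo_sizes or any(s not in (2, 3) for s in self.combo_sizes):
            raise ValueError("combo_sizes must be a nonempty subset of {2, 3}")
        if self.n_randomizations < 2:
            raise ValueError("n_randomizations must be >= 2 (sd undefined otherwise)")
        if self.threshold_sigma <= 0:
            raise ValueError("threshold_sigma must be positive")
        if self.scope not in ("forest", "tree"):
            raise ValueError("scope must be 'forest' or 'tree'")
        if self.count_scope not in ("tree", "branch"):
            raise ValueError("count_scope must be 'tree' or 'branch'")


def _tree_labels(tree: Tree):
    internal = tree.leaf_class < 0
    return tree.feature_a.copy(), tree.feature_b.copy(), internal


def _tree_branch_arrays(tree: Tree, la, lb):
    """(flat, ptr, n_branches) of one tree under the given label arrays."""
    depth, nleaf = tree_depth_leaves(tree.children_left, tree.children_right, tree.leaf_class)
    flat = np.empty(max(1, nleaf * 2 * max(depth, 1)), dtype=np.int64)
    ptr = np.zeros(nleaf + 1, dtype=np.int64)
    nb = branch_sets_kernel(tree.children_left, tree.children_right, tree.leaf_class,
                            la, lb, flat, ptr)
    return flat, ptr, nb


def branch_snp_sets(forest: EpistasisForest) -> list[list[np.ndarray]]:
    """Per tree, the distinct-SNP set of every branch (one per leaf).

    A pair-split node contributes both its SNPs; a SNP appearing in several
    nodes of the same path is counted once.  Leaf-only trees yield branches
    with empty sets.
    """
    out = []
    for tree in forest.trees_:
        la, lb, _ = _tree_labels(tree)
        flat, ptr, nb = _tree_branch_arrays(tree, la, lb)
        out.append([np.sort(flat[ptr[i]:ptr[i + 1]]) for i in range(nb)])
    return out


def _encode_forest_combos(forest: EpistasisForest, labels, combo_size: int, m: int,
                          count_scope: str = "tree") -> np.ndarray:
    """Encoded combos of all branches of the forest under per-tree labels.

    ``count_scope='tree'`` deduplicates combos within each tree, so a combo's
    multiplicity in the result is the number of trees containing it.
    """
    chunks = []
    for tree, (la, lb) in zip(forest.trees_, labels):
        flat, ptr, nb = _tree_branch_arrays(tree, la, lb)
        total = count_combos(ptr, nb, combo_size)
        if total == 0:
            continue
        out = np.empty(total, dtype=np.int64)
        npos = emit_combos_kernel(flat, ptr, nb, combo_size, m, out)
        emitted = out[:npos]
        if count_scope == "tree":
            emitted = np.unique(emitted)
        chunks.append(emitted)
    if not chunks:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chunks)


def _decode(code: int, combo_size: int, m: int) -> tuple[int, ...]:
    if combo_size == 2:
        return (code // m, code % m)
    c = code % m
    rest = code // m
    return (rest // m, rest % m, c)


def raw_interaction_scores(forest: EpistasisForest, combo_size: int = 2,
                           count_scope: str = "tree") -> dict[tuple[int, ...], int]:
    """inter(G): branch co-occurrence counts of every combination with raw > 0.

    With ``count_scope='tree'`` (default) a combination appearing in several
    branches of one tree counts once for that tree; with ``'branch'`` every
    branch containing it counts.
    """
    if combo_size not in (2, 3):
        raise ValueError("combo_size must be 2 or 3")
    if count_scope not in ("tree", "branch"):
        raise ValueError("count_scope must be 'tree' or 'branch'")
    m = forest.n_features_in_
    labels = [_tree_labels(t)[:2] for t in forest.trees_]
    enc = _encode_forest_combos(forest, labels, combo_size, m, count_scope)
    keys, counts = np.unique(enc, return_counts=True)
    return {_decode(int(k), combo_size, m): int(c) for k, c in zip(keys, counts)}


def randomize_forest_labels(forest: EpistasisForest, rng: np.random.Generator,
                            scope: str = "forest") -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled per-tree (feature_a, feature_b) label arrays.

    All SNP-label slots of all split nodes (a pair node holds two slots) are
    permuted by one uniform permutation — forest-wide by default, or within
    each tree with ``scope='tree'`` — leaving topology, rule cell-partitions
    and per-SNP usage multiplicities unchanged.  A pair node may receive two
    identical labels; it then contributes a single SNP to its branches.
    """
    per_tree = []
    for tree in forest.trees_:
        la, lb, internal = _tree_labels(tree)
        slots_a = np.flatnonzero(internal)
        slots_b = np.flatnonzero(internal & (lb >= 0))
        per_tree.append((la, lb, slots_a, slots_b))
    if scope == "tree":
        for la, lb, sa, sb in per_tree:
            vals = np.concatenate([la[sa], lb[sb]])
            vals = rng.permutation(vals)
            la[sa] = vals[: sa.size]
            lb[sb] = vals[sa.size:]
        return [(la, lb) for la, lb, _, _ in per_tree]
    vals = np.concatenate([np.concatenate([la[sa], lb[sb]]) for la, lb, sa, sb in per_tree]) \
        if per_tree else np.empty(0, dtype=np.int64)
    vals = rng.permutation(vals)
    pos = 0
    out = []
    for la, lb, sa, sb in per_tree:
        la[sa] = vals[pos: pos + sa.size]
        pos += sa.size
        lb[sb] = vals[pos: pos + sb.size]
        pos += sb.size
        out.append((la, lb))
    return out


def normalized_scores(forest: EpistasisForest, config: InteractionConfig | None = None,
                      random_state: int | None = None) -> pd.DataFrame:
    """Raw, baseline and normalized interaction scores for the fitted forest.

    Only combinations observed in the original forest (raw > 0) are
    materialized; no other combination can be called.  The baseline for each
    of them is its co-occurrence count distribution over
    ``config.n_randomizations`` label shuffles (zero counts included).
    """
    if config is None:
        config = InteractionConfig()
    if not hasattr(forest, "trees_"):
        raise ValueError("forest is not fitted")
    m = forest.n_features_in_
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(random_state)))
    frames = []
    for size in config.combo_sizes:
        labels0 = [_tree_labels(t)[:2] for t in forest.trees_]
        enc = _encode_forest_combos(forest, labels0, size, m, config.count_scope)
        keys, raw = np.unique(enc, return_counts=True)
        ssum = np.zeros(keys.size)
        ssq = np.zeros(keys.size)
        for _ in range(config.n_randomizations):
            labels = randomize_forest_labels(forest, rng, scope=config.scope)
            enc_r = _encode_forest_combos(forest, labels, size, m, config.count_scope)
            if enc_r.size and keys.size:
                pos = np.searchsorted(keys, enc_r)
                pos[pos == keys.size] = 0
                hit = keys[pos] == enc_r
                cnt = np.bincount(pos[hit], minlength=keys.size)
            else:
                cnt = np.zeros(keys.size, dtype=np.int64)
            ssum += cnt
            ssq += cnt.astype(np.float64) ** 2
        R = config.n_randomizations
        mean = ssum / R
        var = np.maximum(ssq - R * mean ** 2, 0.0) / (R - 1)
        sd = np.maximum(np.sqrt(var), config.sd_floor)
        norm = (raw - mean) / sd
        frames.append(pd.DataFrame({
            "snps": [_decode(int(k), size, m) for k in keys],
            "combo_size": size,
            "raw": raw.astype(int),
            "baseline_mean": mean,
            "baseline_sd": sd,
            "normalized": norm,
            "called": norm > config.threshold_sigma,
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["snps", "combo_size", "raw", "baseline_mean", "baseline_sd",
                 "normalized", "called"])
    return table.sort_values("normalized", ascending=False, kind="stable").reset_index(drop=True)


def call_interactions(table: pd.DataFrame, config: InteractionConfig | None = None) -> pd.DataFrame:
    """Called combinations (normalized > threshold), sorted descending.

    When both pairs and triples are scored, a called triple suppresses its
    sub-pairs only where the triple's normalized score exceeds each
    sub-pair's.
    """
    if config is None:
        config = InteractionConfig()
    called = table[table["normalized"] > config.threshold_sigma].copy()
    called = called.sort_values("normalized", ascending=False, kind="stable")
    if {2, 3} <= set(called["combo_size"].unique()):
        norm_of = {tuple(s): v for s, v in zip(called["snps"], called["normalized"])}
        drop = set()
        for snps, v in norm_of.items():
            if len(snps) != 3:
                continue
            subs = [(snps[0], snps[1]), (snps[0], snps[2]), (snps[1], snps[2])]
            present = [p for p in subs if p in norm_of]
            if present and all(v > norm_of[p] for p in present):
                drop.update(present)
        if drop:
            called = called[[tuple(s) not in drop for s in called["snps"]]]
    return called.reset_index(drop=True)


def write_interactions(table: pd.DataFrame, path, snp_ids=None) -> None:
    """Write an interaction table as TSV, optionally mapping indices to ids."""
    out = table.copy()
    if snp_ids is not None:
        out["snps"] = [",".join(snp_ids[i] for i in s) for s in out["snps"]]
    else:
        out["snps"] = [",".join(map(str, s)) for s in out["snps"]]
    out.to_csv(path, sep="\t", index=False)
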