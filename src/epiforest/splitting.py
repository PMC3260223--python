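"""Node-splitting machinery: Gini impurity, bipartitions of genotype cells,
candidate sampling over single SNPs and unordered SNP pairs.

A split variable of n SNPs (n in {1, 2}) takes one of 3**n categorical values
("cells"); a splitting rule is a bipartition of those cells, of which there
are 2**(3**n - 1) - 1 distinct ones (a subset and its complement describe the
same rule).  Rules are kept canonical: the "left" cell set always contains
cell 0, i.e. genotype (0,) or (0, 0).

The best rule for a candidate is found with the classical two-class Gini
shortcut: order the nonempty cells by their case fraction and scan only the
contiguous prefixes of that order, which provably contain an optimal
bipartition.  The full enumeration (`enumerate_bipartitions`) is retained both
as part of the public surface and as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._kernels import best_split_kernel, node_cells

__all__ = [
    "SplitVariable",
    "SplitRule",
    "SplitEvaluation",
    "gini",
    "gini_decrease",
    "enumerate_bipartitions",
    "n_candidate_variables",
    "sample_candidates",
    "evaluate_candidate",
]


@dataclass(frozen=True)
class SplitVariable:
    """A single SNP or an unordered pair of distinct SNPs (column indices)."""

    snps: tuple[int, ...]

    def __post_init__(self):
        snps = tuple(sorted(int(s) for s in self.snps))
        object.__setattr__(self, "snps", snps)
        if len(snps) not in (1, 2):
            raise ValueError("split variables contain 1 or 2 SNPs")
        if len(set(snps)) != len(snps):
            raise ValueError("split variable SNP indices must be distinct")
        if snps[0] < 0:
            raise ValueError("SNP indices must be non-negative")

    @property
    def order(self) -> int:
        return len(self.snps)

    @property
    def n_cells(self) -> int:
        return 3 ** self.order


@dataclass(frozen=True)
class SplitRule:
    """A bipartition of a split variable's genotype cells.

    ``left_cells`` is the canonical cell subset routed left; it always
    contains cell 0 and is a proper nonempty subset of the 3**n cells.
    """

    variable: SplitVariable
    left_cells: frozenset[int]

    def __post_init__(self):
        cells = frozenset(int(c) for c in self.left_cells)
        object.__setattr__(self, "left_cells", cells)
        nc = self.variable.n_cells
        if not cells or len(cells) == nc:
            raise ValueError("left_cells must be a nonempty proper subset of the cells")
        if any(c < 0 or c >= nc for c in cells):
            raise ValueError("cell index out of range")
        if 0 not in cells:
            raise ValueError("canonical rules route cell 0 left")

    @property
    def mask(self) -> int:
        return sum(1 << c for c in self.left_cells)

    @classmethod
    def from_mask(cls, variable: SplitVariable, mask: int) -> "SplitRule":
        cells = frozenset(c for c in range(variable.n_cells) if (mask >> c) & 1)
        return cls(variable, cells)


@dataclass(frozen=True)
class SplitEvaluation:
    """One evaluated rule: parent/child impurities and the Gini decrease."""

    rule: SplitRule
    gini_parent: float
    gini_left: float
    gini_right: float
    frac_left: float
    frac_right: float
    decrease: float


def gini(n_controls: int, n_cases: int) -> float:
    """Gini impurity 1 - f0**2 - f1**2 of a node with the given class counts."""
    total = n_controls + n_cases
    if total < 1:
        raise ValueError("Gini impurity of an empty node is undefined")
    f0 = n_controls / total
    f1 = n_cases / total
    return 1.0 - f0 * f0 - f1 * f1


def gini_decrease(parent_counts, left_counts, right_counts) -> SplitEvaluation:
    """Impurity decrease of a split, as an evaluation without an attached rule.

    ``decrease = gini(parent) - f_left * gini(left) - f_right * gini(right)``
    with f_left/f_right the fractions of parent samples in each child.
    """
    p0, p1 = parent_counts
    l0, l1 = left_counts
    r0, r1 = right_counts
    if l0 + l1 == 0 or r0 + r1 == 0:
        raise ValueError("both children must be nonempty")
    if (l0 + r0, l1 + r1) != (p0, p1):
        raise ValueError("child counts do not sum to parent counts")
    ntot = p0 + p1
    fl = (l0 + l1) / ntot
    fr = (r0 + r1) / ntot
    gp, gl, gr = gini(p0, p1), gini(l0, l1), gini(r0, r1)
    return SplitEvaluation(
        rule=None, gini_parent=gp, gini_left=gl, gini_right=gr,
        frac_left=fl, frac_right=fr, decrease=gp - fl * gl - fr * gr,
    )


def enumerate_bipartitions(n_snps_in_variable: int) -> list[int]:
    """All canonical bipartitions of the 3**n genotype cells, as bitmasks.

    Exactly 2**(3**n - 1) - 1 rules: 3 for a single SNP, 255 for a pair.
    Canonical form keeps cell 0 in the (left) subset, so no subset and its
    complement are both listed.
    """
    if n_snps_in_variable not in (1, 2):
        raise ValueError("only split variables of 1 or 2 SNPs are supported")
    ncells = 3 ** n_snps_in_variable
    full = (1 << ncells) - 1
    # odd masks contain cell 0; exclude the full set
    return list(range(1, full, 2))


def n_candidate_variables(n_snps: int, max_combo_order: int = 2) -> int:
    """Size of the candidate universe: singles plus (optionally) all pairs."""
    if max_combo_order == 1:
        return n_snps
    return n_snps + n_snps * (n_snps - 1) // 2


@lru_cache(maxsize=8)
def _pair_offsets(m: int) -> np.ndarray:
    """offsets[a] = number of lexicographic pairs (a', b') with a' < a."""
    a = np.arange(m, dtype=np.int64)
    return a * (2 * m - a - 1) // 2


def _decode_candidates(u: np.ndarray, m: int):
    """Decode sorted universe indices into (first, second) SNP arrays."""
    u = np.asarray(u, dtype=np.int64)
    cand_a = np.empty(u.size, dtype=np.int32)
    cand_b = np.full(u.size, -1, dtype=np.int32)
    singles = u < m
    cand_a[singles] = u[singles]
    v = u[~singles] - m
    if v.size:
        offs = _pair_offsets(m)
        a = np.searchsorted(offs, v, side="right") - 1
        b = a + 1 + (v - offs[a])
        cand_a[~singles] = a
        cand_b[~singles] = b
    return cand_a, cand_b


def _sample_candidate_arrays(rng: np.random.Generator, n_snps: int, mtry: int,
                             max_combo_order: int = 2):
    """mtry distinct candidates, uniform without replacement over the universe.

    Returned sorted (singles ascending, then pairs lexicographic): the growth
    kernel's strict-improvement scan then realizes the fewest-SNPs-first,
    smallest-indices tie-break.
    """
    universe = n_candidate_variables(n_snps, max_combo_order)
    if mtry > universe:
        raise ValueError(f"mtry={mtry} exceeds the candidate universe ({universe})")
    if mtry == universe:
        return _decode_candidates(np.arange(universe, dtype=np.int64), n_snps)
    # first-mtry-distinct values of an iid uniform stream == uniform sample
    # without replacement
    got = np.empty(0, dtype=np.int64)
    while got.size < mtry:
        need = mtry - got.size
        draw = rng.integers(0, universe, size=need + need // 8 + 16)
        stream = np.concatenate([got, draw])
        _, first = np.unique(stream, return_index=True)
        got = stream[np.sort(first)][:mtry]
    return _decode_candidates(np.sort(got), n_snps)


def sample_candidates(rng: np.random.Generator, n_snps: int, mtry: int,
                      max_combo_order: int = 2) -> list[SplitVariable]:
    """Sample ``mtry`` distinct split-variable candidates for one node."""
    cand_a, cand_b = _sample_candidate_arrays(rng, n_snps, mtry, max_combo_order)
    return [
        SplitVariable((int(a),) if b < 0 else (int(a), int(b)))
        for a, b in zip(cand_a, cand_b)
    ]


def evaluate_candidate(variable: SplitVariable, node_sample, X, y) -> SplitEvaluation | None:
    """Best rule (maximal Gini decrease) for one variable on a node sample.

    Returns None when the variable is genotype-constant over the node, i.e.
    every rule leaves one child empty ("no valid split").  Cells with zero
    in-node individuals are folded onto the side containing cell 0; they do
    not affect the decrease.
    """
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    idx = np.asarray(node_sample, dtype=np.int64)
    if idx.size == 0:
        raise ValueError("node sample must be nonempty")
    snps = variable.snps
    cand_a = np.array([snps[0]], dtype=np.int32)
    cand_b = np.array([snps[1] if len(snps) == 2 else -1], dtype=np.int32)
    best_c, mask, dec = best_split_kernel(X, y, idx, cand_a, cand_b, -np.inf)
    if best_c < 0:
        return None
    rule = SplitRule.from_mask(variable, int(mask))
    cells = node_cells(X, idx, cand_a[0], cand_b[0])
    left = ((int(mask) >> cells) & 1).astype(bool)
    yl = y[idx[left]]
    yr = y[idx[~left]]
    ev = gini_decrease(
        (int((y[idx] == 0).sum()), int((y[idx] == 1).sum())),
        (int((yl == 0).sum()), int((yl == 1).sum())),
        (int((yr == 0).sum()), int((yr == 1).sum())),
    )
    return SplitEvaluation(
        rule=rule, gini_parent=ev.gini_parent, gini_left=ev.gini_left,
        gini_right=ev.gini_right, frac_left=ev.frac_left,
        frac_right=ev.frac_right, decrease=ev.decrease,
    )
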