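"""Synthetic case-control panels for benchmarking epistasis detection.

Disease models
--------------
* Pure epistasis: random 3x3 penetrance tables double-centered under
  Hardy-Weinberg genotype weights so both single-locus marginal penetrances
  are constant (no marginal effect), then rescaled to a target broad-sense
  heritability h^2 = sum_ij g_i g_j (f_ij - K)^2 / (K (1 - K)) at baseline
  prevalence K.  This reproduces the defining properties (pure epistasis at
  a stated h^2 and MAF) of the classical zero-marginal model family without
  transcribing any external table.
* Weak-marginal two-locus models (additive / multiplicative / threshold) in
  the odds parameterization: odds(i,j) = a(1+t)^(i+j), a(1+t)^(i*j) and
  a(1+t)^[i>=1 and j>=1] respectively, with t calibrated so each locus's
  marginal odds ratio (genotype 1 vs 0) equals 1 + lambda and a set to hit
  the target prevalence.  An LD parameter r^2 < 1 replaces each causal locus
  by a genotyped marker in incomplete LD with it.
* Three-locus amplifier model: a moderate pure-epistasis pair extended by a
  third, weaker locus whose genotype scales the pair's penetrance deviations
  by increasing factors; all three single-locus marginals stay flat.

Sampling is retrospective: fixed numbers of cases and controls, causal
genotypes drawn exactly from the Bayes posterior P(genotypes | status), and
independent HWE noise SNPs with MAFs uniform over ``noise_maf_range``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data import Dataset

__all__ = [
    "PenetranceTable",
    "SimulationSpec",
    "ModelAssignment",
    "hwe_genotype_freqs",
    "heritability",
    "pure_epistasis_penetrance",
    "marchini_odds_table",
    "three_snp_model",
    "three_snp_penetrance",
    "ld_marker",
    "sample_case_control",
    "simulate_null",
]


def hwe_genotype_freqs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies ((1-p)^2, 2p(1-p), p^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


@dataclass
class PenetranceTable:
    """P(disease | genotypes) over 2 or 3 loci, with the generating MAFs.

    ``prevalence`` is K = sum_g g_weights * f under HWE; for pure-epistasis
    tables every locus's HWE-weighted marginal penetrance equals K.
    """

    values: np.ndarray
    mafs: tuple[float, ...]
    prevalence: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mafs = tuple(float(m) for m in self.mafs)
        if self.values.shape not in ((3, 3), (3, 3, 3)):
            raise ValueError("penetrance table must be 3x3 or 3x3x3")
        if len(self.mafs) != self.values.ndim:
            raise ValueError("one MAF per locus is required")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.values.ndim

    def genotype_weights(self) -> np.ndarray:
        """Joint HWE genotype frequencies, same shape as ``values``."""
        w = hwe_genotype_freqs(self.mafs[0])
        for maf in self.mafs[1:]:
            w = np.multiply.outer(w, hwe_genotype_freqs(maf))
        return w

    def recompute_prevalence(self) -> float:
        return float((self.genotype_weights() * self.values).sum())

    def marginal_penetrance(self, locus: int) -> np.ndarray:
        """HWE-weighted penetrance of one locus, averaged over the others."""
        w = self.genotype_weights()
        axes = tuple(a for a in range(self.values.ndim) if a != locus)
        num = (w * self.values).sum(axis=axes)
        den = w.sum(axis=axes)
        return num / den


def heritability(table: PenetranceTable) -> float:
    """Broad-sense h^2 = sum_g g (f - K)^2 / (K (1 - K)) of a table."""
    K = table.recompute_prevalence()
    w = table.genotype_weights()
    return float((w * (table.values - K) ** 2).sum() / (K * (1 - K)))


#: prevalence ladder scanned when no baseline prevalence is requested; the
#: penetrance floor f >= 0 caps negative deviations at -K, so high-h^2
#: zero-marginal tables only exist at appreciable prevalence
_PREVALENCE_LADDER = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)


def pure_epistasis_penetrance(h2_target: float, maf: float,
                              prevalence: float | None = None,
                              rng: np.random.Generator | None = None,
                              max_tries: int = 10_000) -> PenetranceTable:
    """Random two-locus penetrance table with no marginal effects.

    A random 3x3 matrix is double-centered under HWE weights (both weighted
    row and column means zero), scaled so the heritability hits
    ``h2_target`` exactly, and shifted to prevalence K; draws whose entries
    leave [0, 1] are rejected and retried.  With ``prevalence=None`` the
    smallest feasible K on a fixed ladder is used (the [0, 1] bounds make
    high-heritability zero-marginal tables infeasible at low prevalence).
    """
    if not 0.0 < h2_target <= 0.5:
        raise ValueError("h2_target must be in (0, 0.5]")
    rng = np.random.default_rng() if rng is None else rng
    g = hwe_genotype_freqs(maf)
    W = np.outer(g, g)
    ladder = _PREVALENCE_LADDER if prevalence is None else (prevalence,)
    tries_per_level = max_tries if prevalence is not None else max(500, max_tries // len(ladder))
    for K in ladder:
        scale = h2_target * K * (1 - K)
        for _ in range(tries_per_level):
            M = rng.normal(size=(3, 3))
            rowm = (M * g[None, :]).sum(axis=1)
            colm = (g[:, None] * M).sum(axis=0)
            grand = float((W * M).sum())
            D = M - rowm[:, None] - colm[None, :] + grand
            var = float((W * D * D).sum())
            if var < 1e-12:
                continue
            f = K + np.sqrt(scale / var) * D
            if (f >= 0).all() and (f <= 1).all():
                return PenetranceTable(f, (maf, maf), K)
    raise RuntimeError(
        f"no valid zero-marginal table found for h2={h2_target}, maf={maf}, "
        f"K={prevalence} after {max_tries} tries; a larger prevalence gives "
        "more room for the required penetrance deviations"
    )


def _odds_exponent(kind: str) -> np.ndarray:
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    if kind == "additive":
        return (i + j).astype(float)
    if kind == "multiplicative":
        return (i * j).astype(float)
    if kind == "threshold":
        return ((i >= 1) & (j >= 1)).astype(float)
    raise ValueError("kind must be 'additive', 'multiplicative' or 'threshold'")


def _marchini_table(kind: str, alpha: float, theta: float) -> np.ndarray:
    odds = alpha * (1.0 + theta) ** _odds_exponent(kind)
    return odds / (1.0 + odds)


def _marginal_or(values: np.ndarray, g: np.ndarray) -> float:
    """Odds ratio of genotype 1 vs 0 in one locus's marginal penetrance."""
    marg = (values * g[None, :]).sum(axis=1)
    o = marg / (1.0 - marg)
    return float(o[1] / o[0])


def marchini_odds_table(kind: str, lam: float = 0.5, maf: float = 0.2,
                        prevalence: float = 0.02) -> PenetranceTable:
    """Two-locus weak-marginal interaction model in the odds parameterization.

    Calibrated numerically so that (i) the population prevalence under HWE at
    the given MAF equals ``prevalence`` and (ii) each locus's marginal
    per-allele odds ratio (genotype 1 vs 0) equals ``1 + lam``.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    g = hwe_genotype_freqs(maf)
    W = np.outer(g, g)

    def alpha_for(theta: float) -> float:
        def prev_gap(log_alpha):
            return float((W * _marchini_table(kind, np.exp(log_alpha), theta)).sum()) - prevalence
        return float(np.exp(brentq(prev_gap, -30.0, 10.0, xtol=1e-14)))

    if lam == 0:
        alpha = alpha_for(0.0)
        return PenetranceTable(_marchini_table(kind, alpha, 0.0), (maf, maf), prevalence)

    def or_gap(theta):
        alpha = alpha_for(theta)
        return _marginal_or(_marchini_table(kind, alpha, theta), g) - (1.0 + lam)

    try:
        theta = brentq(or_gap, 1e-9, 200.0, xtol=1e-12)
    except ValueError as exc:
        raise RuntimeError(
            f"marginal-effect calibration failed for kind={kind}, lam={lam}, "
            f"maf={maf}, K={prevalence}"
        ) from exc
    alpha = alpha_for(theta)
    return PenetranceTable(_marchini_table(kind, alpha, theta), (maf, maf), prevalence)


def three_snp_model(base: PenetranceTable, amplification=(0.5, 1.0, 2.0),
                    maf3: float | None = None) -> PenetranceTable:
    """Extend a zero-marginal pair table with a third amplifying locus.

    f(i, j, k) = K + c_k (f2(i, j) - K), with the amplification factors c_k
    increasing in k and normalized so their HWE-weighted mean is 1: the third
    locus then has a flat marginal penetrance of exactly K and collapsing
    over it recovers the base table, while the full-table heritability
    exceeds the base heritability (weighted mean of c_k^2 > 1).
    """
    if base.n_loci != 2:
        raise ValueError("base table must be a two-locus table")
    c = np.asarray(amplification, dtype=np.float64)
    if c.shape != (3,) or not (np.diff(c) > 0).all() or (c < 0).any():
        raise ValueError("amplification must be 3 non-negative increasing factors")
    maf3 = base.mafs[0] if maf3 is None else maf3
    g3 = hwe_genotype_freqs(maf3)
    c = c / float((g3 * c).sum())
    K = base.prevalence
    dev = base.values - K
    f = K + dev[:, :, None] * c[None, None, :]
    if (f < 0).any() or (f > 1).any():
        raise ValueError("amplified penetrances leave [0, 1]; retry with a new base table")
    return PenetranceTable(f, (*base.mafs, maf3), K)


def three_snp_penetrance(h2_base: float = 0.2, maf: float = 0.4,
                         prevalence: float | None = None,
                         amplification=(0.5, 1.0, 2.0), rng: np.random.Generator | None = None,
                         max_tries: int = 10_000) -> PenetranceTable:
    """Draw base pair tables until the three-locus extension is valid.

    The amplified deviations need more [0, 1] headroom than the base table,
    so with ``prevalence=None`` every ladder level from the base-feasible one
    upward is tried in turn.
    """
    rng = np.random.default_rng() if rng is None else rng
    ladder = _PREVALENCE_LADDER if prevalence is None else (prevalence,)
    # base draws are microseconds, and the amplified [0, 1] bounds reject
    # most bases, so the per-level budget is generous
    tries_per_level = max(5000, max_tries // len(ladder))
    for K in ladder:
        for _ in range(tries_per_level):
            try:
                base = pure_epistasis_penetrance(h2_base, maf, K, rng, max_tries=200)
            except RuntimeError:
                break  # base itself infeasible at this K; move up the ladder
            try:
                return three_snp_model(base, amplification=amplification, maf3=maf)
            except ValueError:
                continue
    raise RuntimeError("no valid three-locus table found; increase prevalence")


def ld_marker(causal_genotypes: np.ndarray, maf: float, r2: float,
              rng: np.random.Generator | None = None) -> np.ndarray:
    """Genotypes of a marker in LD (r^2) with a causal locus of equal MAF.

    Marker alleles are drawn per causal allele from the two-locus haplotype
    frequencies with D = r p (1 - p) (r = sqrt(r2)), the largest D consistent
    with equal allele frequencies; r2 = 1 returns an identical copy.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must be in (0, 1]")
    causal = np.asarray(causal_genotypes, dtype=np.int8)
    if r2 == 1.0:
        return causal.copy()
    rng = np.random.default_rng() if rng is None else rng
    p = maf
    r = np.sqrt(r2)
    p_m_given_c1 = p + r * (1 - p)
    p_m_given_c0 = p * (1 - r)
    a1 = (causal >= 1).astype(np.int8)
    a2 = (causal == 2).astype(np.int8)
    out = np.zeros_like(causal)
    for allele in (a1, a2):
        prob = np.where(allele == 1, p_m_given_c1, p_m_given_c0)
        out += (rng.random(causal.shape) < prob).astype(np.int8)
    return out


@dataclass
class ModelAssignment:
    """A penetrance model planted on specific SNP columns.

    ``slots`` are the genotyped column indices of the causal combination (or
    of the LD markers when ``r2 < 1``); ``subpopulation`` assigns the model
    to one half of a heterogeneous panel (None elsewhere).
    """

    table: PenetranceTable
    slots: tuple[int, ...]
    r2: float = 1.0
    subpopulation: int | None = None

    def __post_init__(self):
        self.slots = tuple(int(s) for s in self.slots)
        if len(self.slots) != self.table.n_loci:
            raise ValueError("one slot per causal locus is required")
        if len(set(self.slots)) != len(self.slots):
            raise ValueError("causal slots must be distinct")


@dataclass
class SimulationSpec:
    """Full description of one simulated case-control panel."""

    n_cases: int
    n_controls: int
    n_snps: int
    models: list[ModelAssignment] = field(default_factory=list)
    composition: str = "single"  # single | hybrid | heterogeneous | null
    noise_maf_range: tuple[float, float] = (0.05, 0.5)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1 or self.n_snps < 1:
            raise ValueError("counts must be positive")
        if self.composition not in ("single", "hybrid", "heterogeneous", "null"):
            raise ValueError(f"unknown composition {self.composition!r}")
        if self.composition == "null" and self.models:
            raise ValueError("null panels have no causal models")
        if self.composition == "heterogeneous":
            subs = sorted({m.subpopulation for m in self.models})
            if subs != [0, 1]:
                raise ValueError("heterogeneous panels need models in subpopulations 0 and 1")
        taken = [s for m in self.models for s in m.slots]
        if len(set(taken)) != len(taken):
            raise ValueError("causal slots overlap between models")
        if taken and (min(taken) < 0 or max(taken) >= self.n_snps):
            raise ValueError("causal slot out of range")


def _sample_from_table(table: PenetranceTable, status: int, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Causal genotypes drawn from P(genotypes | status) under the model."""
    w = table.genotype_weights().ravel()
    f = table.values.ravel()
    post = w * (f if status == 1 else (1.0 - f))
    total = post.sum()
    if total <= 0:
        raise RuntimeError("degenerate penetrance table: requested status has probability 0")
    cells = rng.choice(post.size, size=size, p=post / total)
    return np.stack(np.unravel_index(cells, table.values.shape), axis=1).astype(np.int8)


def sample_case_control(spec: SimulationSpec, rng: np.random.Generator | None = None) -> Dataset:
    """Simulate a case-control panel according to ``spec``.

    Every causal model's genotypes are drawn conditional on the case/control
    label (models are conditionally independent given the label, which is the
    column-wise mixing construction for hybrid panels); all remaining SNPs
    are independent HWE noise with MAFs uniform over ``noise_maf_range``.
    For heterogeneous panels the cases and controls are split evenly between
    two subpopulations and each model is causal only in its own half, its
    slots being plain noise in the other half.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.rng_seed))) \
        if rng is None else rng
    n = spec.n_cases + spec.n_controls
    m = spec.n_snps
    lo, hi = spec.noise_maf_range
    mafs = rng.uniform(lo, hi, size=m)
    G = rng.binomial(2, mafs[None, :], size=(n, m)).astype(np.int8)
    y = np.concatenate([
        np.ones(spec.n_cases, dtype=np.int8),
        np.zeros(spec.n_controls, dtype=np.int8),
    ])

    if spec.composition == "heterogeneous":
        half_case = spec.n_cases // 2
        half_ctrl = spec.n_controls // 2
        subpop = np.concatenate([
            np.zeros(half_case, np.int8), np.ones(spec.n_cases - half_case, np.int8),
            np.zeros(half_ctrl, np.int8), np.ones(spec.n_controls - half_ctrl, np.int8),
        ])
    else:
        subpop = np.zeros(n, np.int8)

    for model in spec.models:
        member = np.ones(n, bool) if model.subpopulation is None \
            else subpop == model.subpopulation
        for status in (1, 0):
            rows = np.flatnonzero(member & (y == status))
            if rows.size == 0:
                continue
            causal = _sample_from_table(model.table, status, rows.size, rng)
            for locus, slot in enumerate(model.slots):
                col = causal[:, locus]
                if model.r2 < 1.0:
                    col = ld_marker(col, model.table.mafs[locus], model.r2, rng)
                G[rows, slot] = col

    snp_ids = [f"snp{i:04d}" for i in range(m)]
    ind_ids = [f"case{i:04d}" for i in range(spec.n_cases)] + \
              [f"ctrl{i:04d}" for i in range(spec.n_controls)]
    truth = [tuple(snp_ids[s] for s in sorted(mdl.slots)) for mdl in spec.models] or None
    return Dataset(G, snp_ids, ind_ids, y, truth=truth)


def simulate_null(n_cases: int, n_controls: int, n_snps: int, rng_seed: int = 0) -> Dataset:
    """Panel with no disease-associated SNPs (all independent HWE noise)."""
    spec = SimulationSpec(n_cases=n_cases, n_controls=n_controls, n_snps=n_snps,
                          composition="null", rng_seed=rng_seed)
    return sample_case_control(spec)
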