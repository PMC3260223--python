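"""Benchmark harness: per-pair power / false-positive accounting and the
single-locus chi-square reference test.

Power for a model setting is the fraction of planted combinations (over all
simulated datasets of that setting) that are called exactly — set equality of
SNP ids; a called pair that is merely a subset of a planted triple counts as
a false positive unless the relaxation is requested explicitly.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import Dataset
from .forest import EpistasisForest
from .interaction import InteractionConfig, call_interactions, normalized_scores
from .simulate import SimulationSpec, sample_case_control

__all__ = [
    "score_dataset",
    "chi_square_single_locus",
    "BenchmarkSetting",
    "run_benchmark",
    "detect_interactions",
]

logger = logging.getLogger("epiforest")


def score_dataset(called, truth, allow_subset_of_triple: bool = False) -> tuple[int, int]:
    """(true positives, false positives) of one dataset's calls.

    ``called`` and ``truth`` are iterables of SNP-id (or index) tuples; a call
    matches a planted combination only by exact set equality.
    """
    called_sets = {frozenset(c) for c in called}
    truth_sets = [frozenset(t) for t in truth]
    tp = sum(t in called_sets for t in truth_sets)
    fp = 0
    for c in called_sets:
        if c in truth_sets:
            continue
        if allow_subset_of_triple and any(c < t for t in truth_sets):
            continue
        fp += 1
    return tp, fp


def chi_square_single_locus(dataset: Dataset) -> pd.DataFrame:
    """Per-SNP 3x2 genotype-by-status chi-square test (df = 2).

    Returns snp_id, statistic, pvalue and a Bonferroni-corrected significance
    flag at family level 0.1.  SNPs with an empty genotype margin are skipped
    (NaN) with a warning.
    """
    G = dataset.genotypes
    y = dataset.phenotype
    n, m = G.shape
    # counts[s, g, c]: individuals with genotype g and status c at SNP s
    counts = np.zeros((m, 3, 2), dtype=np.int64)
    for c in (0, 1):
        rows = G[y == c]
        flat = (np.arange(m, dtype=np.int64) * 3)[None, :] + rows
        counts[:, :, c] = np.bincount(flat.ravel(), minlength=3 * m).reshape(m, 3)
    row_marg = counts.sum(axis=2)  # (m, 3)
    col_marg = counts.sum(axis=1)  # (m, 2)
    total = n
    expected = row_marg[:, :, None] * col_marg[:, None, :] / total
    ok = (row_marg > 0).all(axis=1)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} SNP(s) skipped in chi-square test: empty genotype margin",
            stacklevel=2,
        )
    stat = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (counts - expected) ** 2 / expected
    stat[ok] = np.nansum(contrib[ok], axis=(1, 2))
    pval = np.where(np.isnan(stat), np.nan, chi2.sf(stat, df=2))
    alpha = 0.1 / m  # Bonferroni at the liberal family level 0.1
    return pd.DataFrame({
        "snp_id": dataset.snp_ids,
        "statistic": stat,
        "pvalue": pval,
        "significant_bonferroni": pval < alpha,
    })


def detect_interactions(dataset: Dataset, forest_params: dict,
                        interaction_config: InteractionConfig | None = None,
                        random_state: int | None = None) -> pd.DataFrame:
    """simulate-free pipeline: fit the forest and call interactions by SNP id."""
    forest = EpistasisForest(random_state=random_state, **forest_params)
    forest.fit(dataset.X, dataset.y)
    table = normalized_scores(forest, interaction_config, random_state=random_state)
    called = call_interactions(table, interaction_config)
    called = called.copy()
    called["snp_ids"] = [tuple(dataset.snp_ids[i] for i in s) for s in called["snps"]]
    return called


@dataclass
class BenchmarkSetting:
    """One model setting: several dataset specs scored under shared configs."""

    label: str
    specs: list[SimulationSpec]
    forest_params: dict = field(default_factory=dict)
    interaction_config: InteractionConfig | None = None
    allow_subset_of_triple: bool = False


def run_benchmark(settings: list[BenchmarkSetting], random_state: int | None = None) -> pd.DataFrame:
    """simulate -> fit -> score -> call -> count TP/FP for every setting.

    Deterministic given the specs' seeds and ``random_state`` (which seeds
    the forest and the randomization null per dataset).
    """
    ss = np.random.SeedSequence(random_state)
    rows = []
    for setting in settings:
        tp_total = fp_total = truth_total = 0
        for spec in setting.specs:
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            t0 = time.perf_counter()
            ds = sample_case_control(spec)
            called = detect_interactions(
                ds, setting.forest_params, setting.interaction_config, random_state=seed,
            )
            tp, fp = score_dataset(
                list(called["snp_ids"]), ds.truth or [],
                allow_subset_of_triple=setting.allow_subset_of_triple,
            )
            tp_total += tp
            fp_total += fp
            truth_total += len(ds.truth or [])
            logger.info(
                "%s seed=%d: tp=%d fp=%d (%.1fs)",
                setting.label, spec.rng_seed, tp, fp, time.perf_counter() - t0,
            )
        rows.append({
            "label": setting.label,
            "n_datasets": len(setting.specs),
            "n_truth": truth_total,
            "true_positives": tp_total,
            "false_positives": fp_total,
            "power": tp_total / truth_total if truth_total else np.nan,
        })
    return pd.DataFrame(rows)
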