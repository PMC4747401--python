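"""Rank-product differential expression with permutation significance.

The pairwise (unpaired two-class) form of the rank product: for every
class-A sample paired with every class-B sample, genes are ranked by the
pairwise expression difference, and each gene's statistic is the geometric
mean of its ranks across all pairs (``rp_up`` ranks the largest A-minus-B
difference first, ``rp_down`` the smallest).  Because only within-pair
ranks enter the statistic, any per-sample constant shift and — when pairs
are restricted to samples from the same dataset — any per-dataset per-gene
shift cancels, which is what makes the method robust to batch effects when
cohorts from several studies are pooled.

Significance is assessed by permutation of the class labels (within each
dataset, preserving per-dataset class counts, so the batch structure of
the null matches the observed statistic): each round reassigns samples to
classes, recomputes the rank product, and a gene's one-sided tail count
gives ``p = (1 + #{null rp <= observed rp}) / (n_permutations + 1)``.
Permuting whole samples — rather than gene values within pairs — keeps
the null faithful to the correlation between pairs that share a sample,
which is what makes the reported p-values calibrated at small cohort
sizes.  The per-gene ``p`` column is two-sided (the smaller one-sided
p-value doubled, capped at 1) with ``direction`` taken from the smaller
side.  The Breitling "percentage of false positives" (pfp), estimated
from the pooled null distribution, is emitted as an alternative
error-rate column.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .matrix import LOG2, ExpressionMatrix
from .ranking import DOWN, UP, DirectionalGeneSet

#: Columns of the rank-product results table (a "DEG table"), indexed by
#: gene_id: rp_up, rp_down, p_up, p_down, p, direction, fdr, pfp.
DEG_TABLE_COLUMNS = ["rp_up", "rp_down", "p_up", "p_down", "p", "direction", "fdr", "pfp"]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pair_indices(
    labels: np.ndarray, datasets: np.ndarray, cross_dataset: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays (a_idx, b_idx) of admissible class-A x class-B pairs."""
    a_all = np.where(labels)[0]
    b_all = np.where(~labels)[0]
    ai, bi = np.meshgrid(a_all, b_all, indexing="ij")
    ai, bi = ai.ravel(), bi.ravel()
    if not cross_dataset:
        keep = datasets[ai] == datasets[bi]
        ai, bi = ai[keep], bi[keep]
    return ai, bi


def _log_rank_products(
    x: np.ndarray, ai: np.ndarray, bi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    diffs = x[:, ai] - x[:, bi]
    log_up = np.log(rankdata(-diffs, axis=0, method="average")).mean(axis=1)
    log_down = np.log(rankdata(diffs, axis=0, method="average")).mean(axis=1)
    return log_up, log_down


def rank_product(
    matrix: ExpressionMatrix,
    class_a: Sequence[str],
    class_b: Sequence[str],
    n_permutations: int = 1000,
    seed: int | None = None,
    cross_dataset: bool = False,
) -> pd.DataFrame:
    """Rank-product DEG table for class A vs class B (log2-scale matrix).

    Parameters
    ----------
    class_a, class_b
        Sample ids of the two classes ("up" means higher in class A).
    n_permutations
        Gene-label permutations for the null; p-values are bounded below
        by 1/(n_permutations + 1).
    seed
        Mandatory RNG seed; the output is bit-identical across runs.
    cross_dataset
        If False (default), only sample pairs from the same ``dataset_id``
        contribute, preserving batch resistance when datasets are pooled.

    Returns
    -------
    DataFrame indexed by gene_id with :data:`DEG_TABLE_COLUMNS`; ``p`` is
    the smaller of the two one-sided p-values, ``direction`` the
    corresponding side, and ``fdr`` the BH adjustment of ``p`` within each
    direction.
    """
    if matrix.scale != LOG2:
        raise ValueError("rank_product expects a log2-scale matrix")
    if seed is None:
        raise ValueError("a seed is required for the permutation null")
    class_a, class_b = list(class_a), list(class_b)
    if len(class_a) < 2 or len(class_b) < 2:
        warnings.warn("fewer than 2 samples in a class: degenerate power", stacklevel=2)
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} is low; p-value resolution is "
            f"{1 / (n_permutations + 1):.3g}",
            stacklevel=2,
        )
    sample_ids = class_a + class_b
    x = matrix.values[sample_ids].to_numpy()
    n_genes = matrix.n_genes
    labels = np.array([True] * len(class_a) + [False] * len(class_b))
    datasets = matrix.samples.loc[sample_ids, "dataset_id"].to_numpy()
    if cross_dataset:
        datasets = np.zeros(len(sample_ids), dtype=int)
    ai, bi = _pair_indices(labels, datasets, cross_dataset)
    if ai.size == 0:
        raise ValueError(
            "no admissible sample pairs (classes may not share a dataset; "
            "set cross_dataset=True to pair across datasets)"
        )
    if ai.size == 1:
        warnings.warn("single-pair design: degenerate power", stacklevel=2)
    log_rp_up, log_rp_down = _log_rank_products(x, ai, bi)

    rng = np.random.default_rng(seed)
    group_indices = [np.where(datasets == ds)[0] for ds in np.unique(datasets)]
    count_up = np.zeros(n_genes, dtype=np.int64)
    count_down = np.zeros(n_genes, dtype=np.int64)
    pooled_up = np.zeros(n_genes, dtype=np.float64)
    pooled_down = np.zeros(n_genes, dtype=np.float64)
    for _ in range(n_permutations):
        perm_labels = labels.copy()
        for idx in group_indices:  # shuffle class labels within each dataset
            perm_labels[idx] = perm_labels[idx][rng.permutation(idx.size)]
        pai, pbi = _pair_indices(perm_labels, datasets, cross_dataset)
        null_up, null_down = _log_rank_products(x, pai, pbi)
        count_up += null_up <= log_rp_up
        count_down += null_down <= log_rp_down
        pooled_up += np.searchsorted(np.sort(null_up), log_rp_up, side="right")
        pooled_down += np.searchsorted(np.sort(null_down), log_rp_down, side="right")

    p_up = (1.0 + count_up) / (n_permutations + 1.0)
    p_down = (1.0 + count_down) / (n_permutations + 1.0)
    # Breitling pfp: expected false positives at each gene's cutoff over its
    # observed-rank position.
    exp_fp_up = pooled_up / n_permutations
    exp_fp_down = pooled_down / n_permutations
    obs_rank_up = rankdata(log_rp_up, method="average")
    obs_rank_down = rankdata(log_rp_down, method="average")
    pfp_up = np.minimum(exp_fp_up / obs_rank_up, 1.0)
    pfp_down = np.minimum(exp_fp_down / obs_rank_down, 1.0)

    up_wins = np.where(
        p_up != p_down, p_up < p_down, log_rp_up <= log_rp_down
    )
    table = pd.DataFrame(
        {
            "rp_up": np.exp(log_rp_up),
            "rp_down": np.exp(log_rp_down),
            "p_up": p_up,
            "p_down": p_down,
            # two-sided: smaller one-sided tail doubled, capped at 1
            "p": np.minimum(2.0 * np.where(up_wins, p_up, p_down), 1.0),
            "direction": np.where(up_wins, UP, DOWN),
            "pfp": np.where(up_wins, pfp_up, pfp_down),
        },
        index=matrix.values.index,
    )
    table.index.name = "gene_id"
    fdr = np.empty(n_genes)
    for direction in (UP, DOWN):
        mask = (table["direction"] == direction).to_numpy()
        if mask.any():
            fdr[mask] = bh_adjust(table.loc[mask, "p"])
    table["fdr"] = fdr
    return table[DEG_TABLE_COLUMNS]


def deg_filter(
    table: pd.DataFrame,
    fdr_max: float | None = None,
    p_max: float | None = None,
    label: str = "DEG",
) -> DirectionalGeneSet:
    """Genes passing the stated threshold(s), with their directions.

    Thresholds are inclusive; pass ``fdr_max`` and/or ``p_max`` in (0, 1].
    """
    for name, thr in (("fdr_max", fdr_max), ("p_max", p_max)):
        if thr is not None and not (0 < thr <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")
    if fdr_max is None and p_max is None:
        raise ValueError("provide at least one of fdr_max, p_max")
    mask = pd.Series(True, index=table.index)
    if fdr_max is not None:
        mask &= table["fdr"] <= fdr_max
    if p_max is not None:
        mask &= table["p"] <= p_max
    chosen = table[mask]
    return DirectionalGeneSet(
        label, dict(zip(chosen.index.astype(str), chosen["direction"]))
    )
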