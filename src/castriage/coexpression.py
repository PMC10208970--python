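"""Developmental-brain co-expression statistics with a Monte-Carlo null.

The gene-set statistic is the median absolute pairwise Spearman correlation
over the set's gene pairs, computed on a genes x samples expression matrix.
Significance is an empirical (add-one) Monte-Carlo p-value against
same-size gene sets drawn uniformly from an expression-eligible universe.
The co-expression network connects gene pairs whose |rho| reaches the
genome-wide top-quantile threshold (top 5% by default).

All statistics are rank-based and therefore invariant under strictly
monotone transforms of the expression values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .types import ExpressionMatrix

DEFAULT_QUANTILE = 0.95
DEFAULT_N_ITER = 5000
DEFAULT_MAX_PAIRS = 2_000_000
DEFAULT_DETECTION_FRACTION = 0.5


def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    """Row-wise average-tie ranks, centred and scaled so that Z @ Z.T is the
    Spearman correlation matrix. Constant rows become all-NaN."""
    ranks = rankdata(values, axis=1).astype(float)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ranks / norm
    z[np.squeeze(norm, axis=1) == 0.0, :] = np.nan
    return z


def spearman_matrix(m: ExpressionMatrix, genes: Optional[list[str]] = None) -> pd.DataFrame:
    """Pairwise Spearman rho (average-rank ties) with unit diagonal.

    Pairs involving a constant expression vector are undefined and recorded
    as NaN (the diagonal of a constant gene is still 1).
    """
    sub = m if genes is None else m.subset(list(genes))
    if sub.n_samples < 3:
        raise ValueError(f"need >= 3 samples for correlation, have {sub.n_samples}")
    z = _standardized_ranks(sub.values.to_numpy())
    rho = np.clip(z @ z.T, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=sub.genes, columns=sub.genes)


def eligible_universe(m: ExpressionMatrix, detection_fraction: float = DEFAULT_DETECTION_FRACTION,
                      floor: float = 0.0) -> list[str]:
    """Genes detected (expression > floor) in at least ``detection_fraction``
    of samples — the universe from which null gene sets are drawn."""
    frac = (m.values.to_numpy() > floor).mean(axis=1)
    return [g for g, f in zip(m.genes, frac) if f >= detection_fraction]


def _quantile_lookup(values: np.ndarray, quantile: float) -> float:
    """Sorted-value lookup: smallest value with at least ``quantile`` of the
    distribution at or below it (the minimum at quantile 0)."""
    srt = np.sort(values)
    k = max(0, int(np.ceil(quantile * srt.size)) - 1)
    return float(srt[k])


def genome_wide_threshold(m: ExpressionMatrix, quantile: float = DEFAULT_QUANTILE,
                          max_pairs: int = DEFAULT_MAX_PAIRS,
                          seed: Optional[int] = None) -> tuple[float, str]:
    """Top-quantile cutoff on |rho| over gene pairs genome-wide.

    Exact over all pairs when their count is at most ``max_pairs``;
    otherwise estimated over ``max_pairs`` pairs sampled uniformly without
    replacement. Returns (threshold, method) with method 'exact' or
    'sampled'. Pairs with undefined rho are excluded.
    """
    if not 0.0 <= quantile < 1.0:
        raise ValueError(f"quantile must lie in [0, 1), got {quantile}")
    n = m.n_genes
    n_pairs = comb(n, 2)
    if n_pairs == 0:
        raise ValueError("need at least two genes for a pair threshold")
    z = _standardized_ranks(m.values.to_numpy())
    if n_pairs <= max_pairs:
        rho = z @ z.T
        vals = np.abs(rho[np.triu_indices(n, k=1)])
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_pairs, size=max_pairs, replace=False)
        # unrank the pair index k -> (i, j), i < j, row-major upper triangle
        i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(np.int64)
        j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(np.int64)
        vals = np.empty(max_pairs)
        chunk = 262_144  # bound the temporary row-gather memory
        for lo in range(0, max_pairs, chunk):
            hi = min(lo + chunk, max_pairs)
            vals[lo:hi] = np.abs(np.einsum("ij,ij->i", z[i[lo:hi]], z[j[lo:hi]]))
        method = "sampled"
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all gene pairs have undefined correlation")
    return _quantile_lookup(np.minimum(vals, 1.0), quantile), method


@dataclass
class SetStatistic:
    value: float  # median |rho| over defined pairs
    n_pairs: int  # C(k, 2)
    n_missing: int  # pairs with undefined rho, excluded from the median


def set_coexpression_statistic(rho: pd.DataFrame, gene_set: Iterable[str]) -> SetStatistic:
    """Median |rho| over the unordered pairs of ``gene_set``.

    Pairs with undefined rho (constant genes) are excluded from the median
    and counted in ``n_missing``.
    """
    genes = list(gene_set)
    missing = [g for g in genes if g not in rho.index]
    if missing:
        raise KeyError(f"genes absent from correlation matrix: {missing}")
    sub = rho.loc[genes, genes].to_numpy()
    iu = np.triu_indices(len(genes), k=1)
    vals = np.abs(sub[iu])
    defined = vals[~np.isnan(vals)]
    value = float(np.median(defined)) if defined.size else float("nan")
    return SetStatistic(value=value, n_pairs=vals.size, n_missing=int(np.isnan(vals).sum()))


def _set_stat_from_z(z: np.ndarray, idx: np.ndarray) -> float:
    sub = z[idx] @ z[idx].T
    iu = np.triu_indices(len(idx), k=1)
    vals = np.abs(sub[iu])
    vals = vals[~np.isnan(vals)]
    return float(np.median(vals)) if vals.size else float("nan")


@dataclass
class MonteCarloResult:
    observed: float
    mc_p: float
    n_iter: int
    seed: Optional[int]
    null_statistics: np.ndarray = field(repr=False)
    universe_size: int = 0


def monte_carlo_test(m: ExpressionMatrix, gene_set: Iterable[str],
                     n_iter: int = DEFAULT_N_ITER, seed: Optional[int] = None,
                     eligible: Optional[list[str]] = None) -> MonteCarloResult:
    """Empirical p for the gene set's median |rho| against random same-size sets.

    Null sets are drawn uniformly without replacement within a draw from the
    eligible universe (by default, genes detected in at least half the
    samples; the observed genes remain drawable, but a draw identical to the
    observed set is rejected). The add-one estimator
    ``(1 + #{null >= observed}) / (n_iter + 1)`` keeps p strictly positive;
    its resolution floor is 1 / (n_iter + 1).
    """
    genes = list(gene_set)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing}")
    if eligible is None:
        eligible = eligible_universe(m)
    universe = sorted(set(eligible) | set(genes))
    if len(universe) < len(genes) + 1:
        raise ValueError(
            f"eligible universe ({len(universe)}) must exceed the gene set size ({len(genes)})"
        )
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    z = _standardized_ranks(m.values.to_numpy())
    obs_idx = np.array(sorted(gene_pos[g] for g in genes))
    observed = _set_stat_from_z(z, obs_idx)
    universe_idx = np.array([gene_pos[g] for g in universe])
    obs_key = set(obs_idx.tolist())
    rng = np.random.default_rng(seed)
    k = len(genes)
    null = np.empty(n_iter)
    for it in range(n_iter):
        while True:
            draw = rng.choice(universe_idx, size=k, replace=False)
            if set(draw.tolist()) != obs_key:
                break
        null[it] = _set_stat_from_z(z, draw)
    mc_p = (1.0 + float(np.sum(null >= observed))) / (n_iter + 1.0)
    return MonteCarloResult(observed=observed, mc_p=mc_p, n_iter=n_iter, seed=seed,
                            null_statistics=null, universe_size=len(universe))


def build_network(rho: pd.DataFrame, gene_sets: Optional[dict[str, set[str]]] = None,
                  threshold: float = 0.0) -> nx.Graph:
    """Co-expression graph: an edge wherever |rho| >= threshold.

    Edge attributes: ``rho`` and ``sign`` (+1 positive, -1 negative
    correlation). Node attribute ``sources`` lists the provenance labels of
    every gene set containing the gene.
    """
    g = nx.Graph()
    genes = list(rho.index)
    for gene in genes:
        sources = sorted(
            name for name, members in (gene_sets or {}).items() if gene in members
        )
        g.add_node(gene, sources=sources)
    arr = rho.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    for i, j in zip(iu, ju):
        r = arr[i, j]
        if not np.isnan(r) and abs(r) >= threshold:
            g.add_edge(genes[i], genes[j], rho=float(r), sign=1 if r >= 0 else -1)
    return g


def cluster_order(rho: pd.DataFrame, gene_set: Optional[list[str]] = None) -> list[str]:
    """Display order from agglomerative clustering, median linkage, on the
    distance 1 - rho. Undefined correlations are treated as distance 1."""
    genes = list(gene_set) if gene_set is not None else list(rho.index)
    if len(genes) <= 1:
        return genes
    sub = rho.loc[genes, genes].to_numpy().copy()
    np.fill_diagonal(sub, 1.0)
    dist = 1.0 - np.nan_to_num(sub, nan=0.0)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    link = linkage(squareform(dist, checks=False), method="median")
    return [genes[i] for i in leaves_list(link)]


@dataclass
class CoexpressionResult:
    """Bundle of one full co-expression analysis of a gene set."""

    gene_set: list[str]
    rho: pd.DataFrame = field(repr=False)
    threshold: float = float("nan")
    threshold_method: str = ""
    set_statistic: float = float("nan")
    n_pairs: int = 0
    n_missing_pairs: int = 0
    n_pairs_above_threshold: int = 0
    mc_p: float = float("nan")
    n_iter: int = 0
    seed: Optional[int] = None
    edges: list[tuple] = field(default_factory=list)
    display_order: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_genes": len(self.gene_set),
            "n_pairs": self.n_pairs,
            "n_missing_pairs": self.n_missing_pairs,
            "median_abs_rho": self.set_statistic,
            "threshold": self.threshold,
            "threshold_method": self.threshold_method,
            "n_pairs_above_threshold": self.n_pairs_above_threshold,
            "mc_p": self.mc_p,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def analyze_gene_set(m: ExpressionMatrix, gene_set: Iterable[str],
                     n_iter: int = DEFAULT_N_ITER, seed: Optional[int] = None,
                     quantile: float = DEFAULT_QUANTILE,
                     max_pairs: int = DEFAULT_MAX_PAIRS,
                     detection_fraction: float = DEFAULT_DETECTION_FRACTION,
                     gene_sets: Optional[dict[str, set[str]]] = None) -> CoexpressionResult:
    """Full analysis: set rho matrix, genome-wide threshold, set statistic,
    Monte-Carlo p, network edges and a clustering display order."""
    genes = list(gene_set)
    rho = spearman_matrix(m, genes)
    threshold, method = genome_wide_threshold(m, quantile=quantile,
                                              max_pairs=max_pairs, seed=seed)
    stat = set_coexpression_statistic(rho, genes)
    mc = monte_carlo_test(
        m, genes, n_iter=n_iter, seed=seed,
        eligible=eligible_universe(m, detection_fraction=detection_fraction),
    )
    net = build_network(rho, gene_sets=gene_sets, threshold=threshold)
    edges = sorted(
        (a, b, d["rho"], d["sign"]) if a <= b else (b, a, d["rho"], d["sign"])
        for a, b, d in net.edges(data=True)
    )
    return CoexpressionResult(
        gene_set=genes,
        rho=rho,
        threshold=threshold,
        threshold_method=method,
        set_statistic=stat.value,
        n_pairs=stat.n_pairs,
        n_missing_pairs=stat.n_missing,
        n_pairs_above_threshold=len(edges),
        mc_p=mc.mc_p,
        n_iter=n_iter,
        seed=seed,
        edges=edges,
        display_order=cluster_order(rho, genes),
    )
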