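"""Connectivity-score prioritization of candidate genes with FDR control.

A candidate gene's connectivity to a seed set of implicated genes is the
sum of its absolute Spearman correlations to the seeds (self-pairs
excluded), so the score lies in [0, |seeds|]. Significance is empirical:
the candidate's score is compared to the scores of genes drawn uniformly
from the expression-eligible universe, and Benjamini-Hochberg adjustment
controls the false discovery rate over each candidate batch (q < 0.1 by
default flags a gene as prioritized).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coexpression import _standardized_ranks, eligible_universe
from .types import ExpressionMatrix

DEFAULT_FDR = 0.1


@dataclass
class ConnectivityScore:
    gene: str
    score: float
    n_missing_terms: int = 0  # seed correlations undefined, contributed 0
    mc_p: float = float("nan")
    q: float = float("nan")
    prioritized: bool = False


@dataclass
class CnvRegion:
    """A copy-number-variant region and the genes it spans.

    Genes may belong to several overlapping regions; each region is scored
    as its own batch.
    """

    label: str
    chrom: str
    start: int
    end: int
    member_genes: list[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"region {self.label!r} has no member genes")
        if self.start > self.end:
            raise ValueError(f"region {self.label!r}: start > end")


def connectivity(gene: str, seed_set: Iterable[str], rho: pd.DataFrame) -> ConnectivityScore:
    """Sum of |rho(gene, seed)| over the seed set, excluding the gene itself.

    Undefined correlations (constant genes) contribute 0 and are counted.
    """
    seeds = [s for s in sorted(set(seed_set)) if s != gene]
    missing = [g for g in [gene] + seeds if g not in rho.index]
    if missing:
        raise KeyError(f"genes absent from correlation matrix: {missing}")
    vals = rho.loc[gene, seeds].to_numpy(dtype=float)
    nan_mask = np.isnan(vals)
    score = float(np.abs(vals[~nan_mask]).sum())
    return ConnectivityScore(gene=gene, score=score, n_missing_terms=int(nan_mask.sum()))


def _scores_against_seeds(z: np.ndarray, gene_idx: np.ndarray, seed_idx: np.ndarray,
                          self_exclude: bool = True) -> np.ndarray:
    """Vectorized connectivity: for each row of ``gene_idx``, the sum of
    |rho| to the seeds, with NaN terms contributing 0."""
    corr = np.abs(z[gene_idx] @ z[seed_idx].T)
    if self_exclude:
        seed_col = {s: c for c, s in enumerate(seed_idx)}
        for r, g in enumerate(gene_idx):
            if g in seed_col:
                corr[r, seed_col[g]] = np.nan
    return np.nansum(corr, axis=1)


def prioritize_genes(candidates: Iterable[str], seed_set: Iterable[str], m: ExpressionMatrix,
                     n_iter: int = 5000, seed: Optional[int] = None, fdr: float = DEFAULT_FDR,
                     universe: Optional[list[str]] = None,
                     _null_scores: Optional[np.ndarray] = None) -> list[ConnectivityScore]:
    """Score one candidate batch against the seed set, with empirical p and
    Benjamini-Hochberg q over the batch.

    Null scores come from ``n_iter`` genes drawn uniformly (with
    replacement across draws) from the eligible universe minus the seed
    set. Candidates identical to a seed gene are rejected. Returns scores
    sorted descending.
    """
    cands = sorted(set(candidates))
    seeds = sorted(set(seed_set))
    if not cands:
        return []
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    overlap = set(cands) & set(seeds)
    if overlap:
        raise ValueError(f"candidate gene(s) identical to seed gene(s): {sorted(overlap)}")
    missing = [g for g in cands + seeds if g not in m.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    z = _standardized_ranks(m.values.to_numpy())
    seed_idx = np.array([gene_pos[g] for g in seeds])
    cand_idx = np.array([gene_pos[g] for g in cands])
    cand_corr = np.abs(z[cand_idx] @ z[seed_idx].T)
    n_missing = np.isnan(cand_corr).sum(axis=1)
    cand_scores = np.nansum(cand_corr, axis=1)
    if _null_scores is None:
        _null_scores = draw_null_scores(m, seeds, n_iter=n_iter, seed=seed, universe=universe)
    mc_p = (1.0 + (_null_scores[None, :] >= cand_scores[:, None]).sum(axis=1)) / (
        len(_null_scores) + 1.0
    )
    q = multipletests(mc_p, method="fdr_bh")[1]
    out = [
        ConnectivityScore(
            gene=g, score=float(s), n_missing_terms=int(nm),
            mc_p=float(p), q=float(qv), prioritized=bool(qv < fdr),
        )
        for g, s, nm, p, qv in zip(cands, cand_scores, n_missing, mc_p, q)
    ]
    out.sort(key=lambda c: (-c.score, c.gene))
    return out


def draw_null_scores(m: ExpressionMatrix, seed_set: Iterable[str], n_iter: int,
                     seed: Optional[int] = None,
                     universe: Optional[list[str]] = None) -> np.ndarray:
    """Connectivity scores of ``n_iter`` random universe genes to the seeds."""
    seeds = sorted(set(seed_set))
    if universe is None:
        universe = eligible_universe(m)
    pool = [g for g in universe if g not in set(seeds)]
    if not pool:
        raise ValueError("eligible universe contains only seed genes")
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    z = _standardized_ranks(m.values.to_numpy())
    seed_idx = np.array([gene_pos[g] for g in seeds])
    rng = np.random.default_rng(seed)
    draw = rng.choice(np.array([gene_pos[g] for g in pool]), size=n_iter, replace=True)
    return _scores_against_seeds(z, draw, seed_idx, self_exclude=False)


@dataclass
class RegionReport:
    region: CnvRegion
    scores: list[ConnectivityScore] = field(default_factory=list)

    @property
    def prioritized(self) -> list[ConnectivityScore]:
        return [s for s in self.scores if s.prioritized]

    @property
    def empty(self) -> bool:
        return not self.prioritized


def prioritize_regions(regions: list[CnvRegion], seed_set: Iterable[str], m: ExpressionMatrix,
                       n_iter: int = 5000, seed: Optional[int] = None,
                       fdr: float = DEFAULT_FDR,
                       universe: Optional[list[str]] = None) -> list[RegionReport]:
    """Run the candidate prioritization per CNV region (one FDR batch each).

    Null draws come from the full eligible universe, not from within the
    region, and are shared across regions so a gene spanning overlapping
    regions receives identical score and p in each. Region members absent
    from the matrix or coinciding with seeds are skipped. Scores within a
    region are sorted descending.
    """
    seeds = sorted(set(seed_set))
    null = draw_null_scores(m, seeds, n_iter=n_iter, seed=seed, universe=universe)
    reports = []
    for region in regions:
        members = [
            g for g in sorted(set(region.member_genes))
            if g in m.values.index and g not in seeds
        ]
        scores = prioritize_genes(members, seeds, m, n_iter=n_iter, fdr=fdr,
                                  _null_scores=null) if members else []
        reports.append(RegionReport(region=region, scores=scores))
    return reports


def read_regions_bed(regions_path, gene_coords_path) -> list[CnvRegion]:
    """Assemble CNV regions from a BED of regions (4th column = label) and a
    BED of gene coordinates (4th column = symbol).

    BED inputs are 0-based half-open and converted to 1-based inclusive. A
    gene is a member of every region its span overlaps.
    """

    def read_bed(path):
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, name = line.split("\t")[:4]
                rows.append((chrom, int(start) + 1, int(end), name))
        return rows

    genes = read_bed(gene_coords_path)
    regions = []
    for chrom, start, end, label in read_bed(regions_path):
        members = [
            g for gc, gs, ge, g in genes if gc == chrom and gs <= end and ge >= start
        ]
        regions.append(CnvRegion(label=label, chrom=chrom, start=start, end=end,
                                 member_genes=sorted(set(members))))
    return regions
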