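"""End-to-end orchestration: filter -> classify -> co-express -> prioritize.

Every stage writes plain TSV/JSON so any stage can be re-run or inspected
independently; re-running with an identical configuration and seed
reproduces byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as vio
from .classify import CandidateCall, GenePanelSet, apply_review, shortlist, summarize_cohort
from .coexpression import analyze_gene_set
from .filtering import FilterConfig, PoolVariant, apply_filters, filter_sv
from .prioritize import prioritize_genes, prioritize_regions, read_regions_bed


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Paths and settings for a full run; unset optional inputs skip their
    stages (variant-only and expression-only runs are both valid)."""

    out_dir: str
    variants: Optional[str] = None
    pedigree: Optional[str] = None
    panels_dir: Optional[str] = None
    review: Optional[str] = None
    sv_calls: Optional[str] = None
    expression: Optional[str] = None
    expression_metadata: Optional[str] = None
    coexpr_genes: Optional[str] = None
    seeds: Optional[str] = None
    prioritize_candidates: Optional[str] = None
    regions_bed: Optional[str] = None
    gene_coords_bed: Optional[str] = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_iter: int = 5000
    seed: int = 0
    quantile: float = 0.95
    detection_fraction: float = 0.5
    fdr: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fcfg = FilterConfig(**(data.pop("filter", None) or {}))
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown run config key(s): {sorted(unknown)}")
        cfg = cls(filter=fcfg, **data)
        for name in ("variants", "pedigree", "panels_dir", "review", "sv_calls",
                     "expression", "expression_metadata", "coexpr_genes", "seeds",
                     "prioritize_candidates", "regions_bed", "gene_coords_bed"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {name}={p!r} does not exist")
        return cfg


def load_panels(panels_dir) -> GenePanelSet:
    """Every *.txt in the directory is one panel named by its file stem."""
    panels = {}
    for path in sorted(Path(panels_dir).glob("*.txt")):
        panels[path.stem] = vio.read_gene_list(path)
    return GenePanelSet(panels=panels, provenance={n: str(Path(panels_dir) / f"{n}.txt")
                                                   for n in panels})


def pool_to_frame(pool: list[PoolVariant]) -> pd.DataFrame:
    rows = []
    for pv in pool:
        v = pv.variant
        rows.append(
            {"family": v.family_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "gene": v.gene, "transcript": v.transcript,
             "consequence": ",".join(sorted(v.consequence)),
             "inheritance": pv.inheritance.model,
             "x_linked": pv.inheritance.x_linked,
             "phenotype_consistent_model": pv.inheritance.consistent_with_phenotype}
        )
    return pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "ref", "alt", "gene", "transcript",
                       "consequence", "inheritance", "x_linked",
                       "phenotype_consistent_model"],
    )


def candidates_to_frame(calls: list[CandidateCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {"family": v.family_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "gene": v.gene, "transcript": v.transcript,
             "deleterious_class": c.deleterious_class,
             "criteria_met": ";".join(c.criteria_met),
             "stage": c.stage, "inheritance": c.inheritance.model,
             "acmg_class": c.acmg_class,
             "phenotype_consistent": c.phenotype_consistent, "tier": c.tier}
        )
    return pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "ref", "alt", "gene", "transcript",
                       "deleterious_class", "criteria_met", "stage", "inheritance",
                       "acmg_class", "phenotype_consistent", "tier"],
    )


def run_all(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the summary report dict.

    Outputs under ``cfg.out_dir``: pool.tsv, attrition.tsv, candidates.tsv,
    sv_kept.tsv, coexpression.json, edges.tsv, prioritization.tsv and
    report.json. Any stage failure raises :class:`StageError` naming the
    stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": {**cfg.filter.to_dict(),
                                   "n_iter": cfg.n_iter, "seed": cfg.seed,
                                   "quantile": cfg.quantile,
                                   "detection_fraction": cfg.detection_fraction,
                                   "fdr": cfg.fdr},
                    "stages_run": []}

    calls: list[CandidateCall] = []
    if cfg.variants is not None:
        if cfg.pedigree is None:
            raise StageError("filter: a pedigree is required with a variant table")
        try:
            variants = vio.read_annotated_variants(cfg.variants)
            ped = vio.read_pedigree(cfg.pedigree)
            pool, attrition = apply_filters(variants, ped, cfg.filter)
        except (vio.ParseError, ValueError) as exc:
            raise StageError(f"filter: {exc}") from exc
        pool_to_frame(pool).to_csv(out / "pool.tsv", sep="\t", index=False)
        attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
        report["stages_run"].append("filter")
        report["n_variants_in"] = len(variants)
        report["n_pool"] = len(pool)
        dropped = attrition[attrition["stage"] != ""]
        report["attrition_by_stage"] = (
            dropped.groupby("stage").size().sort_index().to_dict()
        )

        try:
            panels = load_panels(cfg.panels_dir) if cfg.panels_dir else GenePanelSet(panels={})
            calls = shortlist(pool, panels)
            review = vio.read_review_table(cfg.review) if cfg.review else None
            calls = apply_review(calls, review)
        except (vio.ParseError, ValueError, KeyError) as exc:
            raise StageError(f"classify: {exc}") from exc
        candidates_to_frame(calls).to_csv(out / "candidates.tsv", sep="\t", index=False)
        report["stages_run"].append("classify")
        n_probands = len(ped.family_ids)
        report["cohort_summary"] = summarize_cohort(calls, n_probands)

    if cfg.sv_calls is not None:
        try:
            svs = vio.read_sv_calls(cfg.sv_calls)
            kept = filter_sv(svs, cfg.filter)
        except (vio.ParseError, ValueError) as exc:
            raise StageError(f"sv_filter: {exc}") from exc
        vio.write_sv_calls(kept, out / "sv_kept.tsv")
        report["stages_run"].append("sv_filter")
        report["n_sv_in"] = len(svs)
        report["n_sv_kept"] = len(kept)

    matrix = None
    if cfg.expression is not None:
        try:
            matrix = vio.read_expression_matrix(cfg.expression, cfg.expression_metadata)
        except (vio.ParseError, ValueError) as exc:
            raise StageError(f"expression: {exc}") from exc

    if matrix is not None and cfg.coexpr_genes is not None:
        gene_set = sorted(vio.read_gene_list(cfg.coexpr_genes))
        try:
            res = analyze_gene_set(
                matrix, gene_set, n_iter=cfg.n_iter, seed=cfg.seed,
                quantile=cfg.quantile, detection_fraction=cfg.detection_fraction,
            )
        except (KeyError, ValueError) as exc:
            raise StageError(f"coexpression: {exc}") from exc
        with open(out / "coexpression.json", "w") as fh:
            json.dump(res.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(res.edges, columns=["gene_i", "gene_j", "rho", "sign"]).to_csv(
            out / "edges.tsv", sep="\t", index=False)
        report["stages_run"].append("coexpression")
        report["coexpression"] = res.summary()

    if matrix is not None and cfg.seeds is not None and (
            cfg.prioritize_candidates is not None or cfg.regions_bed is not None):
        seed_set = sorted(vio.read_gene_list(cfg.seeds))
        rows = []
        try:
            if cfg.prioritize_candidates is not None:
                cands = sorted(vio.read_gene_list(cfg.prioritize_candidates))
                for s in prioritize_genes(cands, seed_set, matrix, n_iter=cfg.n_iter,
                                          seed=cfg.seed, fdr=cfg.fdr):
                    rows.append({"batch": "candidates", "gene": s.gene, "score": s.score,
                                 "mc_p": s.mc_p, "q": s.q, "prioritized": s.prioritized})
            if cfg.regions_bed is not None:
                if cfg.gene_coords_bed is None:
                    raise ValueError("regions_bed requires gene_coords_bed")
                regions = read_regions_bed(cfg.regions_bed, cfg.gene_coords_bed)
                for rep in prioritize_regions(regions, seed_set, matrix,
                                              n_iter=cfg.n_iter, seed=cfg.seed,
                                              fdr=cfg.fdr):
                    for s in rep.scores:
                        rows.append({"batch": rep.region.label, "gene": s.gene,
                                     "score": s.score, "mc_p": s.mc_p, "q": s.q,
                                     "prioritized": s.prioritized})
        except (KeyError, ValueError) as exc:
            raise StageError(f"prioritize: {exc}") from exc
        prior = pd.DataFrame(rows, columns=["batch", "gene", "score", "mc_p", "q",
                                            "prioritized"])
        prior.to_csv(out / "prioritization.tsv", sep="\t", index=False)
        report["stages_run"].append("prioritize")
        report["n_prioritized"] = int(prior["prioritized"].sum()) if len(prior) else 0
        report["connectivity_formula"] = "sum of |rho(gene, seed)| over the seed set"

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
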