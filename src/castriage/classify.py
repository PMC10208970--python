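"""Deleteriousness classification, two-stage shortlisting and tier assignment.

Two rule-based classifiers operate on VEP-style annotations:

* predicted loss of function — LoF consequence, in a LoF-intolerant gene
  (pLI >= 0.9 or LoFtool < 0.1), and either CADD Phred >= 20 or a splice
  impact (AdaBoost or random-forest splice score >= 0.6). Frameshifts are
  exempt from the third clause: intolerance alone suffices.
* predicted damaging missense — at least three of: PolyPhen-2 probably or
  possibly damaging; SIFT deleterious (incl. low confidence); CADD Phred
  >= 20; regional missense tolerance ratio significantly different from 1
  (FDR < 0.05). A missing annotation never counts toward the three.

Shortlisting is two-stage per family: candidates in the collated
genes-of-interest union first; a genome-wide, gene-agnostic pass only when
the panel stage yields nothing reviewable. Clinical ACMG classes and
phenotype-consistency judgements are review inputs, never computed here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .filtering import InheritanceCall, PoolVariant
from .types import AnnotatedVariant, LOF_CONSEQUENCES

PLI_MIN = 0.9
LOFTOOL_MAX = 0.1
CADD_MIN = 20.0
SPLICE_SCORE_MIN = 0.6
MTR_FDR_MAX = 0.05
MISSENSE_CRITERIA_REQUIRED = 3


@dataclass
class GenePanelSet:
    """Named gene panels and their union (the genes-of-interest list).

    Membership queries are case-normalized to upper case.
    """

    panels: dict[str, set[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.panels = {name: {g.upper() for g in genes} for name, genes in self.panels.items()}

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.panels.values():
            out |= genes
        return out

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.union

    def panels_for(self, gene: str) -> list[str]:
        g = gene.upper()
        return sorted(name for name, genes in self.panels.items() if g in genes)


@dataclass
class CandidateCall:
    """A shortlisted variant with its classification and review tier."""

    variant: AnnotatedVariant
    deleterious_class: str  # lof | damaging_missense | none
    criteria_met: list[str]
    inheritance: InheritanceCall
    stage: Optional[str] = None  # panel | genome_wide
    acmg_class: Optional[int] = None  # review input, 1-5
    phenotype_consistent: Optional[bool] = None  # review input
    tier: str = "excluded"  # high_confidence | low_confidence | excluded


def classify_lof(v: AnnotatedVariant) -> tuple[bool, list[str]]:
    """Apply the three-clause predicted-LoF rule; returns (is_lof, criteria)."""
    criteria: list[str] = []
    lof_terms = v.consequence & LOF_CONSEQUENCES
    if not lof_terms:
        return False, criteria
    criteria.append("lof_consequence")
    intolerant = False
    if v.pli is not None and v.pli >= PLI_MIN:
        intolerant = True
        criteria.append("pli>=0.9")
    if v.loftool is not None and v.loftool < LOFTOOL_MAX:
        intolerant = True
        criteria.append("loftool<0.1")
    if not intolerant:
        return False, criteria
    frameshift = "frameshift_variant" in v.consequence
    damaging = False
    if frameshift:
        damaging = True
        criteria.append("frameshift_exemption")
    if v.cadd_phred is not None and v.cadd_phred >= CADD_MIN:
        damaging = True
        criteria.append("cadd>=20")
    if v.ada_score is not None and v.ada_score >= SPLICE_SCORE_MIN:
        damaging = True
        criteria.append("ada>=0.6")
    if v.rf_score is not None and v.rf_score >= SPLICE_SCORE_MIN:
        damaging = True
        criteria.append("rf>=0.6")
    return damaging, criteria


def classify_missense(v: AnnotatedVariant) -> tuple[bool, list[str]]:
    """At-least-three-of-four damaging-missense rule; returns (is_damaging, criteria)."""
    if "missense_variant" not in v.consequence:
        return False, []
    criteria: list[str] = []
    if v.polyphen_call in ("probably_damaging", "possibly_damaging"):
        criteria.append("polyphen_damaging")
    if v.sift_call in ("deleterious", "deleterious_low_confidence"):
        criteria.append("sift_deleterious")
    if v.cadd_phred is not None and v.cadd_phred >= CADD_MIN:
        criteria.append("cadd>=20")
    if v.mtr_fdr is not None and v.mtr_fdr < MTR_FDR_MAX:
        criteria.append("mtr_fdr<0.05")
    return len(criteria) >= MISSENSE_CRITERIA_REQUIRED, criteria


def classify_variant(v: AnnotatedVariant) -> tuple[str, list[str]]:
    """LoF takes precedence over missense; returns (class, criteria)."""
    is_lof, crit = classify_lof(v)
    if is_lof:
        return "lof", crit
    is_mis, crit = classify_missense(v)
    if is_mis:
        return "damaging_missense", crit
    return "none", []


def collapse_transcripts(pool: list[PoolVariant]) -> list[PoolVariant]:
    """Most-severe-transcript rule: one record per allele per family.

    An allele qualifies if any overlapping transcript's annotation
    qualifies; the qualifying (first, by severity lof > missense > none)
    transcript is the one reported.
    """
    rank = {"lof": 0, "damaging_missense": 1, "none": 2}
    best: dict[tuple, PoolVariant] = {}
    for pv in pool:
        key = (pv.variant.family_id,) + pv.variant.allele_key
        cls, _ = classify_variant(pv.variant)
        prev = best.get(key)
        if prev is None or rank[cls] < rank[classify_variant(prev.variant)[0]]:
            best[key] = pv
    return [best[k] for k in sorted(best)]


def shortlist(pool: list[PoolVariant], panels: GenePanelSet) -> list[CandidateCall]:
    """Two-stage candidate shortlisting per family.

    Stage 1 keeps deleterious candidates whose gene is in the panel union;
    stage 2 (genome-wide) is evaluated only for families where stage 1
    produced no reviewable candidate. A variant is never in both stages.
    """
    collapsed = collapse_transcripts(pool)
    by_family: dict[str, list] = {}
    for pv in collapsed:
        cls, crit = classify_variant(pv.variant)
        if cls == "none":
            continue
        by_family.setdefault(pv.variant.family_id, []).append((pv, cls, crit))
    calls: list[CandidateCall] = []
    for fam in sorted(by_family):
        items = by_family[fam]
        panel_items = [it for it in items if it[0].variant.gene in panels]
        staged = (
            [(it, "panel") for it in panel_items]
            if panel_items
            else [(it, "genome_wide") for it in items]
        )
        for (pv, cls, crit), stage in staged:
            calls.append(
                CandidateCall(
                    variant=pv.variant,
                    deleterious_class=cls,
                    criteria_met=crit,
                    inheritance=pv.inheritance,
                    stage=stage,
                )
            )
    return calls


def assign_tier(call: CandidateCall) -> str:
    """Confidence tier from the supplied ACMG class and phenotype fit.

    High confidence: pathogenic (5) or likely pathogenic (4) with a
    consistent phenotype. Low confidence: uncertain significance (3), or
    likely pathogenic without phenotype fit. Everything else is excluded.
    """
    if call.deleterious_class == "none":
        return "excluded"
    cls, consistent = call.acmg_class, bool(call.phenotype_consistent)
    if cls in (4, 5) and consistent:
        return "high_confidence"
    if cls == 3 or (cls == 4 and not consistent):
        return "low_confidence"
    return "excluded"


def apply_review(calls: list[CandidateCall], review: Optional[pd.DataFrame]) -> list[CandidateCall]:
    """Merge clinical review (ACMG class, phenotype consistency) and tier.

    Candidates without a review row default to uncertain significance
    (class 3) — unreviewed variants can never reach high confidence.
    """
    table: dict[tuple, tuple[int, bool]] = {}
    if review is not None:
        for row in review.itertuples(index=False):
            table[(row.family, row.chrom, int(row.pos), row.ref, row.alt)] = (
                int(row.acmg_class), bool(row.phenotype_consistent),
            )
    for call in calls:
        v = call.variant
        cls, consistent = table.get((v.family_id,) + v.allele_key, (3, False))
        call.acmg_class = cls
        call.phenotype_consistent = consistent
        call.tier = assign_tier(call)
    return calls


def yield_percent(n_solved: int, n_probands: int, decimals: int = 0) -> float:
    """Diagnostic yield as a percentage (rounded; int percent at decimals=0)."""
    pct = round(100.0 * n_solved / n_probands, decimals if decimals else None)
    return float(pct)


def summarize_cohort(calls: list[CandidateCall], n_probands: int) -> dict:
    """Cohort-level report: solved probands, per-tier counts, yields."""
    high = [c for c in calls if c.tier == "high_confidence"]
    low = [c for c in calls if c.tier == "low_confidence"]
    solved_families = sorted({c.variant.family_id for c in high})
    low_families = sorted({c.variant.family_id for c in low})
    return {
        "n_probands": n_probands,
        "n_solved": len(solved_families),
        "solved_families": solved_families,
        "n_high_confidence_variants": len(high),
        "n_low_confidence_variants": len(low),
        "n_low_confidence_families": len(low_families),
        "diagnostic_yield_percent": yield_percent(len(solved_families), n_probands),
        "low_confidence_percent": yield_percent(len(low_families), n_probands, decimals=1),
    }
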