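"""Site QC, genotype QC, population-frequency and inheritance filtering.

The filters reproduce a GATK-style short-variant triage for trio designs:
variants flagged by recalibration or violating hard site-quality cutoffs are
removed, genotype support is required in the proband and every sequenced
relative, and rarity plus an inheritance model consistent with the pedigree
is demanded before a variant enters the analyzable pool.

All inequalities are strict exactly as configured: DP > 10 means a depth of
11 passes and 10 fails. Missing site-QC metrics never trigger a drop — only
explicit violations and explicit recalibration-failure flags do.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd
import yaml

from .types import AnnotatedVariant, Pedigree, StructuralVariantCall


@dataclass
class FilterConfig:
    """Hard thresholds for site, genotype, frequency and SV filters.

    SNV and indel site thresholds differ (indel strand/position cutoffs are
    laxer); the mapping-quality rank-sum cutoff applies to SNVs only.
    """

    # SNV site thresholds
    qd_min: float = 2.0
    fs_max: float = 60.0
    sor_max: float = 3.0
    mq_rank_sum_min: float = -12.6
    read_pos_rank_sum_min: float = -8.0
    # indel site thresholds (QD cutoff shared with SNVs)
    indel_fs_max: float = 200.0
    indel_sor_max: float = 10.0
    indel_read_pos_rank_sum_min: float = -20.0
    excess_het_z_max: float = 4.5
    # genotype thresholds
    dp_min: int = 10
    gq_min: int = 20
    # frequency thresholds
    ac_max: int = 2
    comphet_af_max: float = 0.0005
    # structural variants
    sv_families_max: int = 2
    sv_af_max: float = 0.0005

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown filter config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FilterDecision:
    keep: bool
    reason: Optional[str] = None  # first violated rule, None when kept

    def __bool__(self) -> bool:
        return self.keep


@dataclass
class InheritanceCall:
    """Inferred transmission model for one proband variant.

    ``consistent_with_phenotype`` marks whether the model supports
    candidacy: de novo and recessive models always do; inherited dominant
    models only when the transmitting parent is affected, with maternal
    transmission on X to a male proband exempted (unaffected carrier
    females are expected under X-linked inheritance).
    """

    model: str  # de_novo | inherited_maternal | inherited_paternal |
    #             homozygous_recessive | compound_het | unknown
    x_linked: bool = False
    partner: Optional[tuple] = None  # allele key of the trans variant (compound het)
    consistent_with_phenotype: bool = False


KEEP = FilterDecision(True)


def filter_site_qc(v: AnnotatedVariant, cfg: FilterConfig) -> FilterDecision:
    """Drop recalibration failures and hard site-quality violations.

    A missing metric cannot violate its threshold; the returned reason names
    the first rule violated in a fixed check order.
    """
    qc = v.site_qc

    def bad(value, limit, below: bool) -> bool:
        if value is None:
            return False
        return value < limit if below else value > limit

    if qc.vqsr_fail:
        return FilterDecision(False, "VQSR")
    if bad(qc.excess_het_z, cfg.excess_het_z_max, below=False):
        return FilterDecision(False, "ExcessHet")
    if bad(qc.qd, cfg.qd_min, below=True):
        return FilterDecision(False, "QD")
    indel = qc.variant_class == "indel"
    if bad(qc.fs, cfg.indel_fs_max if indel else cfg.fs_max, below=False):
        return FilterDecision(False, "FS")
    if bad(qc.sor, cfg.indel_sor_max if indel else cfg.sor_max, below=False):
        return FilterDecision(False, "SOR")
    if not indel and bad(qc.mq_rank_sum, cfg.mq_rank_sum_min, below=True):
        return FilterDecision(False, "MQRankSum")
    if bad(qc.read_pos_rank_sum,
           cfg.indel_read_pos_rank_sum_min if indel else cfg.read_pos_rank_sum_min,
           below=True):
        return FilterDecision(False, "ReadPosRankSum")
    return KEEP


def filter_genotype_qc(v: AnnotatedVariant, ped: Pedigree, cfg: FilterConfig) -> FilterDecision:
    """Require DP and GQ strictly above threshold in the proband and every
    sequenced relative with a non-missing call at this site."""
    proband = ped.proband(v.family_id)
    pg = v.genotypes.get(proband.sample_id)
    if pg is None or pg.genotype == "missing":
        return FilterDecision(False, "proband_genotype_missing")
    for member in ped.sequenced_members(v.family_id):
        g = v.genotypes.get(member.sample_id)
        if g is None or g.genotype == "missing":
            if member.sample_id == proband.sample_id:
                return FilterDecision(False, "proband_genotype_missing")
            continue  # unsequenced-at-this-site relative: nothing to check
        if g.depth is None or g.depth <= cfg.dp_min:
            return FilterDecision(False, f"DP({member.sample_id})")
        if g.quality is None or g.quality <= cfg.gq_min:
            return FilterDecision(False, f"GQ({member.sample_id})")
    return KEEP


def filter_frequency(v: AnnotatedVariant, cfg: FilterConfig,
                     mode: str = "dominant_denovo") -> FilterDecision:
    """Population rarity filter.

    dominant_denovo: absent from gnomAD or allele count <= ac_max (all
    populations). compound_het: absent or mean allele frequency strictly
    below comphet_af_max.
    """
    if mode == "dominant_denovo":
        if v.gnomad_ac is None or v.gnomad_ac <= cfg.ac_max:
            return KEEP
        return FilterDecision(False, "gnomAD_AC")
    if mode == "compound_het":
        if v.gnomad_af is None or v.gnomad_af < cfg.comphet_af_max:
            return KEEP
        return FilterDecision(False, "gnomAD_AF")
    raise ValueError(f"unknown frequency mode {mode!r}")


def build_cohort_index(variants: list[AnnotatedVariant], ped: Pedigree) -> dict:
    """Map exact allele key -> set of family ids in which an *unaffected*
    individual carries the allele."""
    unaffected = ped.unaffected_ids()
    index: dict[tuple, set[str]] = {}
    for v in variants:
        for sid, g in v.genotypes.items():
            if sid in unaffected and g.carries_alt:
                index.setdefault(v.allele_key, set()).add(ped.individual(sid).family_id)
    return index


def filter_cohort_recurrence(v: AnnotatedVariant, cohort_index: dict) -> FilterDecision:
    """Drop alleles carried by unaffected individuals elsewhere in the cohort.

    The match is exact on (chrom, pos, ref, alt). Carriage by the variant's
    own family members is not counted here: transmission within the family
    is the province of the inheritance model (reported low-confidence
    variants can be inherited from an unaffected parent).
    """
    fams = cohort_index.get(v.allele_key, set()) - {v.family_id}
    if fams:
        return FilterDecision(False, "cohort_unaffected")
    return KEEP


def infer_inheritance(v: AnnotatedVariant, ped: Pedigree) -> InheritanceCall:
    """Classify transmission from parental genotypes.

    De novo requires both sequenced parents homozygous reference; single
    transmitting parents give the corresponding inherited model; proband
    homozygous-alternate with two heterozygous parents is the recessive
    model. Duos and singletons where transmission cannot be resolved return
    ``unknown``. On X the call is flagged x_linked with sex-aware zygosity.
    """
    proband = ped.proband(v.family_id)
    pg = v.genotypes.get(proband.sample_id)
    if pg is None or pg.genotype == "missing":
        raise ValueError(f"proband genotype missing for {v.chrom}:{v.pos} in {v.family_id}")
    x = v.is_x and (
        (proband.sex == "male" and pg.genotype in ("hemi_alt", "hom_alt"))
        or (proband.sex != "male" and pg.genotype in ("het", "hom_alt"))
    )
    if not pg.carries_alt:
        return InheritanceCall("unknown", x_linked=False)

    father, mother = ped.parents(proband.sample_id)

    def parent_gt(parent):
        if parent is None or not parent.sequenced:
            return None
        g = v.genotypes.get(parent.sample_id)
        if g is None or g.genotype == "missing":
            return None
        return g

    fg, mg = parent_gt(father), parent_gt(mother)
    f_carries = fg.carries_alt if fg else None
    m_carries = mg.carries_alt if mg else None

    if f_carries is False and m_carries is False:
        return InheritanceCall("de_novo", x_linked=x, consistent_with_phenotype=True)
    if pg.genotype == "hom_alt" and fg and mg and fg.genotype == "het" and mg.genotype == "het":
        return InheritanceCall("homozygous_recessive", x_linked=x, consistent_with_phenotype=True)
    if f_carries and m_carries:
        return InheritanceCall("unknown", x_linked=x)
    if m_carries:
        consistent = mother.affected == "affected" or (x and proband.sex == "male")
        return InheritanceCall("inherited_maternal", x_linked=x,
                               consistent_with_phenotype=consistent)
    if f_carries:
        return InheritanceCall("inherited_paternal", x_linked=x,
                               consistent_with_phenotype=father.affected == "affected")
    # at least one parent unresolvable and the other non-carrier (or none)
    return InheritanceCall("unknown", x_linked=x)


def pair_compound_hets(variants: list[AnnotatedVariant], ped: Pedigree,
                       calls: Optional[dict] = None) -> list[tuple]:
    """All in-trans heterozygous pairs within one gene of one proband.

    Phase is inferred from parental genotypes only: a pair requires one
    maternally and one paternally transmitted het. Returns
    ``[(maternal_variant, paternal_variant), ...]``.
    """
    if calls is None:
        calls = {id(v): infer_inheritance(v, ped) for v in variants}
    maternal, paternal = [], []
    for v in variants:
        proband = ped.proband(v.family_id)
        pg = v.genotypes.get(proband.sample_id)
        if pg is None or pg.genotype != "het":
            continue
        model = calls[id(v)].model
        if model == "inherited_maternal":
            maternal.append(v)
        elif model == "inherited_paternal":
            paternal.append(v)
    return [(m, p) for m in maternal for p in paternal]


def filter_sv(calls: list[StructuralVariantCall], cfg: FilterConfig) -> list[StructuralVariantCall]:
    """Drop SVs recurrent in more than ``sv_families_max`` cohort families
    or with population frequency above ``sv_af_max``."""
    kept = []
    for c in calls:
        if c.families_observed > cfg.sv_families_max:
            continue
        if c.sv_af is not None and c.sv_af > cfg.sv_af_max:
            continue
        kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Pipeline stage: run all short-variant filters and log attrition


@dataclass
class PoolVariant:
    """A filter-surviving variant plus its inheritance call."""

    variant: AnnotatedVariant
    inheritance: InheritanceCall


def _sort_key(v: AnnotatedVariant):
    return (v.family_id, v.chrom, v.pos, v.ref, v.alt, v.transcript)


def apply_filters(variants: list[AnnotatedVariant], ped: Pedigree,
                  cfg: Optional[FilterConfig] = None) -> tuple[list[PoolVariant], pd.DataFrame]:
    """Run site QC -> genotype QC -> frequency -> cohort recurrence ->
    inheritance, in order, recording the first failing stage per variant.

    A variant failing the dominant allele-count rule is retained if its
    population frequency still admits a compound-heterozygous model and it
    actually forms an in-trans pair; otherwise it is dropped as too common.
    Inherited dominant models require an affected transmitting parent.

    Returns the surviving pool (sorted, order-independent) and a per-variant
    attrition table with columns family, chrom, pos, ref, alt, transcript,
    gene, stage, reason (stage/reason empty for survivors).
    """
    if cfg is None:
        cfg = FilterConfig()
    for v in variants:
        unknown_samples = set(v.genotypes) - {i.sample_id for i in ped.individuals}
        if unknown_samples:
            raise ValueError(
                f"genotype sample(s) absent from pedigree at {v.chrom}:{v.pos}: "
                f"{sorted(unknown_samples)}"
            )
    cohort_index = build_cohort_index(variants, ped)
    rows = []
    survivors: list[PoolVariant] = []
    comphet_only: list[tuple[AnnotatedVariant, InheritanceCall]] = []

    def log(v, stage, reason):
        rows.append(
            {"family": v.family_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "transcript": v.transcript, "gene": v.gene,
             "stage": stage, "reason": reason}
        )

    for v in sorted(variants, key=_sort_key):
        d = filter_site_qc(v, cfg)
        if not d:
            log(v, "site_qc", d.reason)
            continue
        d = filter_genotype_qc(v, ped, cfg)
        if not d:
            log(v, "genotype_qc", d.reason)
            continue
        dominant_ok = filter_frequency(v, cfg, "dominant_denovo")
        comphet_ok = filter_frequency(v, cfg, "compound_het")
        if not dominant_ok and not comphet_ok:
            log(v, "frequency", dominant_ok.reason)
            continue
        d = filter_cohort_recurrence(v, cohort_index)
        if not d:
            log(v, "recurrence", d.reason)
            continue
        inh = infer_inheritance(v, ped)
        proband = ped.proband(v.family_id)
        carries = v.genotypes[proband.sample_id].carries_alt
        if not carries:
            log(v, "inheritance", "proband_not_carrier")
            continue
        if not dominant_ok:
            # too common for dominant/de novo; eligible only via compound het
            comphet_only.append((v, inh))
            continue
        if inh.model in ("inherited_maternal", "inherited_paternal") and not inh.consistent_with_phenotype:
            # keep open for a compound-het pairing before declaring a drop
            comphet_only.append((v, inh))
            continue
        log(v, "", "")
        survivors.append(PoolVariant(v, inh))

    # resolve compound-het candidates per (family, gene)
    by_gene: dict[tuple, list] = {}
    for v, inh in comphet_only:
        by_gene.setdefault((v.family_id, v.gene), []).append((v, inh))
    pool_hets = {pv.variant.allele_key: pv for pv in survivors}
    for (fam, gene), items in sorted(by_gene.items()):
        gene_variants = [v for v, _ in items] + [
            pv.variant for pv in survivors
            if pv.variant.family_id == fam and pv.variant.gene == gene
        ]
        calls = {}
        for gv in gene_variants:
            match = next((i for v2, i in items if v2 is gv), None)
            calls[id(gv)] = match if match is not None else pool_hets[gv.allele_key].inheritance
        pairs = pair_compound_hets(gene_variants, ped, calls)
        paired_keys = {v.allele_key for pair in pairs for v in pair}
        for v, inh in items:
            if v.allele_key in paired_keys:
                partner = None
                for m, p in pairs:
                    if m is v:
                        partner = p.allele_key
                        break
                    if p is v:
                        partner = m.allele_key
                        break
                log(v, "", "")
                survivors.append(
                    PoolVariant(
                        v,
                        InheritanceCall("compound_het", x_linked=inh.x_linked,
                                        partner=partner, consistent_with_phenotype=True),
                    )
                )
            elif not filter_frequency(v, cfg, "dominant_denovo"):
                log(v, "frequency", "gnomAD_AC")
            else:
                log(v, "inheritance", "inherited_from_unaffected")

    survivors.sort(key=lambda pv: _sort_key(pv.variant))
    attrition = pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "ref", "alt", "transcript",
                       "gene", "stage", "reason"],
    ).sort_values(["family", "chrom", "pos", "ref", "alt", "transcript"]).reset_index(drop=True)
    return survivors, attrition
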