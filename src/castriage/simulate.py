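"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover every external input: a trio cohort with planted
causal variants and benign background variants (each constructed to fail a
named filter), a developmental-brain expression matrix with planted
co-expression blocks, and gene panels with a prescribed overlap structure.
Every generated variant appears exactly once in a truth table recording its
expected pipeline disposition, so recovery is checkable end to end.

Identical spec + seed give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    AnnotatedVariant,
    ExpressionMatrix,
    GenotypeCall,
    Individual,
    Pedigree,
    SiteQCMetrics,
)
from .classify import GenePanelSet

TRUTH_COLUMNS = [
    "family", "chrom", "pos", "gene", "category", "inheritance",
    "expected_tier", "expected_failure_filter",
]

PLANT_CATEGORIES = ("lof", "damaging_missense", "benign")
PLANT_INHERITANCE = (
    "de_novo", "maternal", "paternal", "compound_het_pair", "x_linked_de_novo",
)
#: benign variants are constructed to fail exactly one of these stages
BENIGN_FAILURE_MODES = (
    "site_qc", "genotype_qc", "frequency", "recurrence", "inheritance", "classifier",
)

_LOF_CHOICES = (
    "stop_gained", "frameshift_variant", "splice_acceptor_variant",
    "splice_donor_variant", "start_lost", "stop_lost",
)
_BASES = ("A", "C", "G", "T")


@dataclass
class PlantedVariant:
    family_index: int
    gene: str
    category: str = "lof"
    inheritance: str = "de_novo"
    chrom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in PLANT_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.inheritance not in PLANT_INHERITANCE:
            raise ValueError(f"unknown inheritance {self.inheritance!r}")


@dataclass
class PanelSimSpec:
    panel_sizes: dict[str, int]
    n_overlap_memberships: int = 0
    universe_size: int = 5000
    seed: int = 0


@dataclass
class CohortSimSpec:
    n_families: int
    seed: int = 0
    planted_variants: list[PlantedVariant] = field(default_factory=list)
    background_rate: float = 20.0  # expected benign variants per family
    panel_spec: Optional[PanelSimSpec] = None
    family_structures: dict[int, str] = field(default_factory=dict)  # index -> trio|duo|singleton

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for pv in self.planted_variants:
            if not 0 <= pv.family_index < self.n_families:
                raise ValueError(f"family_index {pv.family_index} out of range")
            structure = self.family_structures.get(pv.family_index, "trio")
            if pv.inheritance == "compound_het_pair" and structure != "trio":
                raise ValueError(
                    f"compound het planting requires a trio, family {pv.family_index} "
                    f"is a {structure}"
                )


@dataclass
class ExpressionSimSpec:
    n_genes: int
    n_samples: int = 280
    n_donors: int = 24
    module_assignments: dict[str, int] = field(default_factory=dict)  # gene -> block, 0 = none
    within_block_correlation: float = 0.65
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")
        if not 0.0 <= self.within_block_correlation < 1.0:
            raise ValueError(
                "within_block_correlation must lie in [0, 1) for a positive-definite "
                f"block covariance, got {self.within_block_correlation}"
            )


# ---------------------------------------------------------------------------
# cohort


def _clean_site_qc(rng, indel: bool) -> SiteQCMetrics:
    return SiteQCMetrics(
        filter_flags=frozenset({"PASS"}),
        qd=round(rng.uniform(10, 35), 2),
        fs=round(rng.uniform(0, 20), 2),
        sor=round(rng.uniform(0.3, 2.0), 2),
        mq_rank_sum=round(rng.normal(0, 1.5), 2),
        read_pos_rank_sum=round(rng.normal(0, 1.5), 2),
        excess_het_z=round(rng.uniform(-2, 2), 2),
        variant_class="indel" if indel else "snv",
    )


def _good_call(rng, sample: str, genotype: str) -> GenotypeCall:
    return GenotypeCall(sample_id=sample, genotype=genotype,
                        depth=int(rng.integers(20, 60)), quality=int(rng.integers(50, 100)))


def _alleles(rng, indel: bool) -> tuple[str, str]:
    ref = str(rng.choice(_BASES))
    if indel:
        ins = ref + "".join(rng.choice(_BASES, size=int(rng.integers(1, 4))))
        return (ref, ins) if rng.random() < 0.5 else (ins, ref)
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    return ref, alt


class _CohortBuilder:
    def __init__(self, spec: CohortSimSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.variants: list[AnnotatedVariant] = []
        self.truth_rows: list[dict] = []
        self.pos_counter = 1_000_000
        self.families = [f"FAM{i + 1:04d}" for i in range(spec.n_families)]
        self.individuals: list[Individual] = []
        self.members: dict[str, dict[str, Optional[str]]] = {}
        self._build_pedigree()

    def _build_pedigree(self) -> None:
        # sexes drawn up front; families with X-linked plantings get a
        # female proband so a de novo X het is representable
        forced_female = {
            pv.family_index for pv in self.spec.planted_variants
            if pv.inheritance == "x_linked_de_novo"
        }
        affected_parent: dict[int, str] = {}
        for pv in self.spec.planted_variants:
            if pv.inheritance in ("maternal", "paternal") and pv.category != "benign":
                affected_parent[pv.family_index] = pv.inheritance
        for i, fam in enumerate(self.families):
            structure = self.spec.family_structures.get(i, "trio")
            sex = "female" if i in forced_female else ("male" if self.rng.random() < 0.75 else "female")
            proband = f"{fam}_P"
            father = f"{fam}_F" if structure == "trio" or structure == "duo" else None
            mother = f"{fam}_M" if structure == "trio" else None
            self.members[fam] = {"proband": proband, "father": father, "mother": mother}
            self.individuals.append(
                Individual(sample_id=proband, family_id=fam, father_id=father,
                           mother_id=mother, sex=sex, affected="affected")
            )
            if father:
                self.individuals.append(
                    Individual(sample_id=father, family_id=fam, sex="male",
                               affected="affected" if affected_parent.get(i) == "paternal"
                               else "unaffected")
                )
            if mother:
                self.individuals.append(
                    Individual(sample_id=mother, family_id=fam, sex="female",
                               affected="affected" if affected_parent.get(i) == "maternal"
                               else "unaffected")
                )

    def _next_pos(self) -> int:
        self.pos_counter += int(self.rng.integers(500, 5000))
        return self.pos_counter

    def _trio_genotypes(self, fam: str, proband_gt: str, father_gt: str,
                        mother_gt: str) -> dict[str, GenotypeCall]:
        calls = {}
        m = self.members[fam]
        calls[m["proband"]] = _good_call(self.rng, m["proband"], proband_gt)
        if m["father"]:
            calls[m["father"]] = _good_call(self.rng, m["father"], father_gt)
        if m["mother"]:
            calls[m["mother"]] = _good_call(self.rng, m["mother"], mother_gt)
        return calls

    def _lof_annotations(self) -> dict:
        consequence = str(self.rng.choice(_LOF_CHOICES))
        ann = {
            "consequence": frozenset({consequence}),
            "pli": round(float(self.rng.uniform(0.9, 1.0)), 3),
            "loftool": round(float(self.rng.uniform(0.001, 0.099)), 4),
        }
        if consequence == "frameshift_variant":
            # intolerance alone suffices; CADD may be absent
            if self.rng.random() < 0.5:
                ann["cadd_phred"] = round(float(self.rng.uniform(20, 45)), 1)
        elif consequence in ("splice_acceptor_variant", "splice_donor_variant"):
            ann["ada_score"] = round(float(self.rng.uniform(0.6, 1.0)), 3)
            ann["rf_score"] = round(float(self.rng.uniform(0.6, 1.0)), 3)
            ann["cadd_phred"] = round(float(self.rng.uniform(20, 45)), 1)
        else:
            ann["cadd_phred"] = round(float(self.rng.uniform(20, 45)), 1)
        return ann

    def _missense_annotations(self, damaging: bool) -> dict:
        if damaging:
            # satisfy at least three of the four criteria
            drop = int(self.rng.integers(0, 5))  # 4 = drop none
            ann = {"consequence": frozenset({"missense_variant"})}
            if drop != 0:
                ann.update(polyphen_call="probably_damaging",
                           polyphen_score=round(float(self.rng.uniform(0.9, 1.0)), 3))
            if drop != 1:
                ann.update(sift_call="deleterious",
                           sift_score=round(float(self.rng.uniform(0.0, 0.05)), 3))
            if drop != 2:
                ann["cadd_phred"] = round(float(self.rng.uniform(20, 40)), 1)
            if drop != 3:
                ann["mtr_fdr"] = round(float(self.rng.uniform(0.0, 0.049)), 4)
            return ann
        return {
            "consequence": frozenset({"missense_variant"}),
            "polyphen_call": "benign",
            "polyphen_score": round(float(self.rng.uniform(0.0, 0.3)), 3),
            "sift_call": "tolerated",
            "sift_score": round(float(self.rng.uniform(0.2, 1.0)), 3),
            "cadd_phred": round(float(self.rng.uniform(0, 15)), 1),
            "mtr_fdr": round(float(self.rng.uniform(0.2, 1.0)), 4),
        }

    def _emit(self, fam: str, chrom: str, pos: int, ref: str, alt: str, gene: str,
              ann: dict, genotypes: dict, qc: SiteQCMetrics,
              gnomad_ac=None, gnomad_af=None) -> AnnotatedVariant:
        v = AnnotatedVariant(
            family_id=fam, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            transcript=f"ENST{pos:011d}",
            gnomad_ac=gnomad_ac, gnomad_af=gnomad_af,
            site_qc=qc, genotypes=genotypes, **ann,
        )
        self.variants.append(v)
        return v

    def _truth(self, v: AnnotatedVariant, category: str, inheritance: str,
               expected_tier: str, expected_failure: str) -> None:
        self.truth_rows.append(
            {"family": v.family_id, "chrom": v.chrom, "pos": v.pos, "gene": v.gene,
             "category": category, "inheritance": inheritance,
             "expected_tier": expected_tier, "expected_failure_filter": expected_failure}
        )

    def plant(self, pv: PlantedVariant) -> None:
        fam = self.families[pv.family_index]
        chrom = pv.chrom or ("X" if pv.inheritance == "x_linked_de_novo"
                             else str(self.rng.integers(1, 23)))
        if pv.category == "benign":
            self._plant_benign(fam, chrom, pv.gene)
            return
        ann = self._lof_annotations() if pv.category == "lof" else self._missense_annotations(True)
        indel = "frameshift_variant" in ann["consequence"]
        if pv.inheritance == "compound_het_pair":
            for parent_gt in (("het", "hom_ref"), ("hom_ref", "het")):
                ref, alt = _alleles(self.rng, indel)
                genotypes = self._trio_genotypes(fam, "het", *parent_gt)
                v = self._emit(fam, chrom, self._next_pos(), ref, alt, pv.gene,
                               ann, genotypes, _clean_site_qc(self.rng, indel),
                               gnomad_af=round(float(self.rng.uniform(0, 0.0004)), 6),
                               gnomad_ac=int(self.rng.integers(3, 10)))
                self._truth(v, pv.category, "compound_het_pair", "high_confidence", "none")
                ann = dict(ann)  # second variant of the pair reuses annotations
            return
        ref, alt = _alleles(self.rng, indel)
        if pv.inheritance in ("de_novo", "x_linked_de_novo"):
            genotypes = self._trio_genotypes(fam, "het", "hom_ref", "hom_ref")
        elif pv.inheritance == "maternal":
            genotypes = self._trio_genotypes(fam, "het", "hom_ref", "het")
        else:  # paternal
            genotypes = self._trio_genotypes(fam, "het", "het", "hom_ref")
        gnomad_ac = None if self.rng.random() < 0.5 else int(self.rng.integers(0, 3))
        v = self._emit(fam, chrom, self._next_pos(), ref, alt, pv.gene, ann, genotypes,
                       _clean_site_qc(self.rng, indel), gnomad_ac=gnomad_ac)
        self._truth(v, pv.category, pv.inheritance, "high_confidence", "none")

    def _plant_benign(self, fam: str, chrom: str, gene: str,
                      mode: Optional[str] = None) -> None:
        if mode is None:
            mode = str(self.rng.choice(BENIGN_FAILURE_MODES))
        indel = bool(self.rng.random() < 0.2)
        ref, alt = _alleles(self.rng, indel)
        pos = self._next_pos()
        qc = _clean_site_qc(self.rng, indel)
        genotypes = self._trio_genotypes(fam, "het", "hom_ref", "hom_ref")
        ann = self._lof_annotations() if self.rng.random() < 0.3 else self._missense_annotations(True)
        gnomad_ac: Optional[int] = None
        expected_failure = mode
        if mode == "site_qc":
            failures = {
                "qd": round(float(self.rng.uniform(0, 1.9)), 2),
                "fs": round(float(self.rng.uniform(61, 300) if not indel
                                  else self.rng.uniform(201, 400)), 1),
                "sor": round(float(self.rng.uniform(3.1, 8) if not indel
                                   else self.rng.uniform(10.1, 20)), 2),
                "excess_het_z": round(float(self.rng.uniform(4.6, 9)), 2),
                "vqsr": None,
            }
            which = str(self.rng.choice(sorted(failures)))
            if which == "vqsr":
                qc = SiteQCMetrics(filter_flags=frozenset({"VQSRTrancheSNP99.70to100.00"}),
                                   variant_class=qc.variant_class)
            else:
                kwargs = {k: getattr(qc, k) for k in
                          ("qd", "fs", "sor", "mq_rank_sum", "read_pos_rank_sum",
                           "excess_het_z")}
                kwargs[which] = failures[which]
                qc = SiteQCMetrics(filter_flags=frozenset({"PASS"}),
                                   variant_class=qc.variant_class, **kwargs)
        elif mode == "genotype_qc":
            target = self.members[fam]["proband"]
            genotypes[target] = GenotypeCall(
                sample_id=target, genotype="het",
                depth=int(self.rng.integers(1, 11)), quality=int(self.rng.integers(50, 99)),
            )
        elif mode == "frequency":
            gnomad_ac = int(self.rng.integers(3, 200))
        elif mode == "recurrence":
            # same allele carried by an unaffected parent of another family;
            # the carrier genotype rides on this record (the cohort index is
            # built from genotypes across all records)
            affected = {i.sample_id for i in self.individuals if i.affected == "affected"}
            carrier_parent = None
            start = self.families.index(fam)
            for step in range(1, len(self.families)):
                other = self.families[(start + step) % len(self.families)]
                for role in ("father", "mother"):
                    cand = self.members[other][role]
                    if cand is not None and cand not in affected:
                        carrier_parent = cand
                        break
                if carrier_parent:
                    break
            if carrier_parent is None:
                self._plant_benign(fam, chrom, gene, mode="frequency")
                return
            genotypes[carrier_parent] = _good_call(self.rng, carrier_parent, "het")
        elif mode == "inheritance":
            # inherited from an unaffected parent within the family
            affected = {i.sample_id for i in self.individuals if i.affected == "affected"}
            which = None
            for role in ("father", "mother"):
                cand = self.members[fam][role]
                if cand is not None and cand not in affected:
                    which = role
                    break
            if which is None:  # singleton or both parents affected: fall back
                self._plant_benign(fam, chrom, gene, mode="frequency")
                return
            genotypes = self._trio_genotypes(
                fam, "het",
                "het" if which == "father" else "hom_ref",
                "het" if which == "mother" else "hom_ref",
            )
        elif mode == "classifier":
            ann = self._missense_annotations(damaging=False)
        else:
            raise ValueError(f"unknown benign failure mode {mode!r}")
        v = self._emit(fam, chrom, pos, ref, alt, gene, ann, genotypes, qc,
                       gnomad_ac=gnomad_ac)
        self._truth(v, "benign", "none", "excluded", expected_failure)

    def build(self) -> tuple[list[AnnotatedVariant], Pedigree, pd.DataFrame]:
        for pv in self.spec.planted_variants:
            self.plant(pv)
        n_bg = self.rng.poisson(self.spec.background_rate, size=self.spec.n_families)
        bg_counter = 0
        for i, fam in enumerate(self.families):
            for _ in range(int(n_bg[i])):
                # one synthetic gene per background variant: spurious
                # same-gene compound-het pairings are not part of the design
                gene = f"BGENE{bg_counter:05d}"
                bg_counter += 1
                self._plant_benign(fam, str(self.rng.integers(1, 23)), gene)
        ped = Pedigree(self.individuals)
        truth = pd.DataFrame(self.truth_rows, columns=TRUTH_COLUMNS)
        truth = truth.sort_values(["family", "chrom", "pos"]).reset_index(drop=True)
        return self.variants, ped, truth


def simulate_cohort(spec: CohortSimSpec) -> tuple[list[AnnotatedVariant], Pedigree, pd.DataFrame]:
    """Generate (annotated variants, pedigree, truth table) for one cohort.

    Planted lof / damaging_missense variants satisfy every QC, frequency and
    inheritance rule plus the respective classifier; benign background
    variants fail exactly one stage, sampled uniformly over failure modes
    and recorded in ``expected_failure_filter``.
    """
    return _CohortBuilder(spec).build()


def make_review_table(truth: pd.DataFrame, variants: list[AnnotatedVariant]) -> pd.DataFrame:
    """Clinical-review stand-in derived from the truth table: expected
    high-tier variants get ACMG class 5 with a consistent phenotype,
    everything else class 3."""
    key_to_variant = {}
    for v in variants:
        key_to_variant.setdefault((v.family_id, v.chrom, v.pos), v)
    rows = []
    for row in truth.itertuples(index=False):
        v = key_to_variant.get((row.family, str(row.chrom), int(row.pos)))
        if v is None:
            continue
        high = row.expected_tier == "high_confidence"
        rows.append(
            {"family": v.family_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
             "alt": v.alt, "acmg_class": 5 if high else 3,
             "phenotype_consistent": high}
        )
    return pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "ref", "alt", "acmg_class",
                       "phenotype_consistent"],
    )


# ---------------------------------------------------------------------------
# expression

_STAGES = [
    ("8pcw", 8.0, "pcw"), ("12pcw", 12.0, "pcw"), ("16pcw", 16.0, "pcw"),
    ("21pcw", 21.0, "pcw"), ("26pcw", 26.0, "pcw"), ("37pcw", 37.0, "pcw"),
    ("4mo", 4.0, "mo"), ("10mo", 10.0, "mo"),
]


def simulate_expression(spec: ExpressionSimSpec) -> ExpressionMatrix:
    """Log-normal expression with block-equicorrelated latent structure.

    Genes in block b > 0 share a per-sample latent factor giving a target
    pairwise (Pearson, on the log scale) correlation of
    ``within_block_correlation``; block 0 and unassigned genes are
    independent. The exponential link keeps values RPKM-like and positive
    without changing any rank statistic.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    c = spec.within_block_correlation
    blocks: dict[int, list[int]] = {}
    for i, g in enumerate(genes):
        b = spec.module_assignments.get(g, 0)
        blocks.setdefault(b, []).append(i)
    latent = rng.standard_normal((spec.n_genes, spec.n_samples))
    for b, idx in blocks.items():
        if b == 0:
            continue
        common = rng.standard_normal(spec.n_samples)
        latent[idx] = np.sqrt(c) * common + np.sqrt(1.0 - c) * latent[idx]
    mu = rng.normal(2.0, 1.0, size=(spec.n_genes, 1))
    values = np.exp(mu + spec.noise_sd * latent)
    samples = [f"S{i + 1:04d}" for i in range(spec.n_samples)]
    donors = [f"D{(i % spec.n_donors) + 1:03d}" for i in range(spec.n_samples)]
    stages = [_STAGES[i % len(_STAGES)] for i in range(spec.n_samples)]
    metadata = pd.DataFrame(
        {
            "donor_id": donors,
            "stage_label": [s[0] for s in stages],
            "age_value": [s[1] for s in stages],
            "age_unit": [s[2] for s in stages],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), metadata)


# ---------------------------------------------------------------------------
# panels


def simulate_panels(spec: PanelSimSpec) -> GenePanelSet:
    """Gene panels with exact sizes and exactly ``n_overlap_memberships``
    redundant memberships, so the union size is the size sum minus the
    overlap count."""
    total = sum(spec.panel_sizes.values())
    union_target = total - spec.n_overlap_memberships
    if spec.n_overlap_memberships < 0:
        raise ValueError("n_overlap_memberships must be >= 0")
    if union_target > spec.universe_size:
        raise ValueError(
            f"union of {union_target} genes exceeds universe of {spec.universe_size}"
        )
    if union_target < max(spec.panel_sizes.values(), default=0):
        raise ValueError("overlap too large: union smaller than the largest panel")
    rng = np.random.default_rng(spec.seed)
    universe = [f"GENE{i + 1:05d}" for i in range(spec.universe_size)]
    order = rng.permutation(spec.universe_size)
    fresh = iter(universe[i] for i in order)
    panels: dict[str, set[str]] = {}
    used: list[str] = []
    remaining_overlap = spec.n_overlap_memberships
    names = list(spec.panel_sizes)
    for k, name in enumerate(names):
        size = spec.panel_sizes[name]
        # leave enough overlap capacity for later panels, greedily dup here
        later_capacity = sum(spec.panel_sizes[n] for n in names[k + 1:])
        n_dup = min(remaining_overlap, size, len(used))
        n_dup = max(n_dup, remaining_overlap - later_capacity)
        if n_dup > min(size, len(used)):
            raise ValueError("infeasible overlap structure")
        dup = [used[i] for i in rng.choice(len(used), size=n_dup, replace=False)] if n_dup else []
        new = [next(fresh) for _ in range(size - n_dup)]
        panels[name] = set(dup) | set(new)
        if len(panels[name]) != size:
            raise ValueError("infeasible overlap structure")
        used.extend(new)
        remaining_overlap -= n_dup
    if remaining_overlap:
        raise ValueError("infeasible overlap structure")
    gps = GenePanelSet(panels=panels, provenance={n: "simulated" for n in names})
    assert len(gps.union) == union_target
    return gps
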