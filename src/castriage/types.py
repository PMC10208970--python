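"""Core data model for trio variant triage.

All genomic coordinates are 1-based inclusive (VCF convention); BED-style
inputs are converted at the parsing boundary. A missing annotation is
``None`` and is never conflated with zero — a variant absent from gnomAD
is not the same as a variant with allele count 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: VEP-style consequence terms counted as predicted loss of function.
LOF_CONSEQUENCES = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "start_lost",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

#: Consequence vocabulary the parsers recognise without warning.
KNOWN_CONSEQUENCES = LOF_CONSEQUENCES | {
    "missense_variant",
    "synonymous_variant",
    "splice_region_variant",
    "intron_variant",
    "inframe_deletion",
    "inframe_insertion",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
    "non_coding_transcript_exon_variant",
}

SIFT_CALLS = frozenset({"deleterious", "deleterious_low_confidence", "tolerated"})
POLYPHEN_CALLS = frozenset({"probably_damaging", "possibly_damaging", "benign"})
GENOTYPES = frozenset({"hom_ref", "het", "hom_alt", "hemi_alt", "missing"})

_X_NAMES = frozenset({"X", "chrX", "x", "23"})


def is_x_chrom(chrom: str) -> bool:
    """True for any conventional spelling of the X chromosome."""
    return chrom in _X_NAMES


def _check_unit(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass
class SiteQCMetrics:
    """Caller-side site quality annotations consumed (never recomputed) here.

    Any metric may be missing; a missing metric cannot violate a threshold.
    ``filter_flags`` carries the VCF FILTER column — anything other than
    PASS / '.' is treated as a recalibration failure.
    """

    filter_flags: frozenset = frozenset({"PASS"})
    qd: Optional[float] = None
    fs: Optional[float] = None
    sor: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    excess_het_z: Optional[float] = None
    variant_class: str = "snv"

    def __post_init__(self) -> None:
        if self.variant_class not in ("snv", "indel"):
            raise ValueError(f"variant_class must be snv|indel, got {self.variant_class!r}")
        self.filter_flags = frozenset(self.filter_flags)

    @property
    def vqsr_fail(self) -> bool:
        return bool(self.filter_flags - {"PASS", "."})


@dataclass
class GenotypeCall:
    """One sample's call at one site: genotype class plus DP/GQ."""

    sample_id: str
    genotype: str = "missing"
    depth: Optional[int] = None
    quality: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.quality is not None and self.quality < 0:
            raise ValueError("quality must be >= 0")

    @property
    def carries_alt(self) -> bool:
        return self.genotype in ("het", "hom_alt", "hemi_alt")


@dataclass
class AnnotatedVariant:
    """One alternate allele at one site for one family, per transcript.

    Functional annotation follows the VEP vocabulary; in-silico scores and
    population frequencies may all be missing independently.
    """

    family_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: frozenset = frozenset()
    gnomad_ac: Optional[int] = None
    gnomad_af: Optional[float] = None
    pli: Optional[float] = None
    loftool: Optional[float] = None
    cadd_phred: Optional[float] = None
    sift_call: Optional[str] = None
    sift_score: Optional[float] = None
    polyphen_call: Optional[str] = None
    polyphen_score: Optional[float] = None
    mtr_fdr: Optional[float] = None
    ada_score: Optional[float] = None
    rf_score: Optional[float] = None
    site_qc: SiteQCMetrics = field(default_factory=SiteQCMetrics)
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref ({self.ref!r}) at {self.chrom}:{self.pos}")
        self.consequence = frozenset(self.consequence)
        for name in ("pli", "loftool", "sift_score", "polyphen_score", "mtr_fdr", "ada_score", "rf_score", "gnomad_af"):
            _check_unit(name, getattr(self, name))
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be nonnegative")
        if self.gnomad_ac is not None and self.gnomad_ac < 0:
            raise ValueError("gnomad_ac must be nonnegative")
        if self.sift_call is not None and self.sift_call not in SIFT_CALLS:
            raise ValueError(f"unknown SIFT call {self.sift_call!r}")
        if self.polyphen_call is not None and self.polyphen_call not in POLYPHEN_CALLS:
            raise ValueError(f"unknown PolyPhen call {self.polyphen_call!r}")

    @property
    def allele_key(self) -> tuple:
        """Exact-allele identity used cohort-wide (no fuzzy indel matching)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def is_x(self) -> bool:
        return is_x_chrom(self.chrom)


@dataclass
class StructuralVariantCall:
    """A CNV/SV region call with cohort recurrence and population frequency."""

    family_id: str
    chrom: str
    start: int
    end: int
    sv_type: str
    caller_label: str = ""
    sv_af: Optional[float] = None
    families_observed: int = 1

    _CNV_TYPES = frozenset({"DEL", "DUP", "INV"})
    MAX_CNV_LENGTH = 5_000_000

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "DUP", "INS", "INV", "BND"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.start > self.end:
            raise ValueError(f"start > end ({self.start} > {self.end})")
        if self.sv_type in self._CNV_TYPES and self.length > self.MAX_CNV_LENGTH:
            raise ValueError(f"CNV span {self.length} exceeds {self.MAX_CNV_LENGTH} bp")
        _check_unit("sv_af", self.sv_af)
        if self.families_observed < 0:
            raise ValueError("families_observed must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Individual:
    sample_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affected: str = "unknown"
    sequenced: bool = True
    twin_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male|female|unknown, got {self.sex!r}")
        if self.affected not in ("affected", "unaffected", "unknown"):
            raise ValueError(f"affected must be affected|unaffected|unknown, got {self.affected!r}")


class Pedigree:
    """Family structures with sex and affection status.

    Supports trios, parent-child duos, singletons and extended families.
    Monozygotic twins may be annotated with ``twin_of``; the twin pair is
    collapsed to a single analysis proband (the twin that is the annotation
    target, or the lexicographically first).
    """

    def __init__(self, individuals: list[Individual]):
        ids = [i.sample_id for i in individuals]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sample id(s): {sorted(dupes)}")
        self._by_id = {i.sample_id: i for i in individuals}
        self._families: dict[str, list[Individual]] = {}
        for ind in individuals:
            self._families.setdefault(ind.family_id, []).append(ind)
        self._validate()

    def _validate(self) -> None:
        for ind in self._by_id.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise ValueError(f"{ind.sample_id}: dangling parent id {pid!r}")
        # No ancestry cycles (a sample can never be its own ancestor).
        for ind in self._by_id.values():
            seen: set[str] = set()
            stack = [ind.sample_id]
            while stack:
                sid = stack.pop()
                if sid in seen:
                    raise ValueError(f"pedigree cycle involving {sid!r}")
                seen.add(sid)
                cur = self._by_id[sid]
                stack.extend(p for p in (cur.father_id, cur.mother_id) if p is not None)

    @property
    def individuals(self) -> list[Individual]:
        return list(self._by_id.values())

    @property
    def family_ids(self) -> list[str]:
        return list(self._families)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def individual(self, sample_id: str) -> Individual:
        return self._by_id[sample_id]

    def members(self, family_id: str) -> list[Individual]:
        return list(self._families[family_id])

    def proband(self, family_id: str) -> Individual:
        """The single affected analysis proband of one family unit.

        Probands are affected individuals that are not a parent of anyone in
        the family; MZ twin pairs collapse to one proband.
        """
        members = self._families[family_id]
        parent_ids = {p for m in members for p in (m.father_id, m.mother_id) if p}
        cands = [m for m in members if m.affected == "affected" and m.sample_id not in parent_ids]
        if len(cands) > 1:
            cand_ids = {c.sample_id for c in cands}
            twins = [c for c in cands if c.twin_of in cand_ids]
            if twins:
                keep = sorted(cand_ids - {t.sample_id for t in twins} | {min(t.twin_of for t in twins)})
                cands = [c for c in cands if c.sample_id in keep]
        if not cands:
            raise ValueError(f"family {family_id!r} has no affected proband")
        if len(cands) > 1:
            raise ValueError(
                f"family {family_id!r} has {len(cands)} proband candidates: "
                f"{sorted(c.sample_id for c in cands)}"
            )
        return cands[0]

    def parents(self, sample_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        """(father, mother), either None when absent from the pedigree."""
        ind = self._by_id[sample_id]
        father = self._by_id.get(ind.father_id) if ind.father_id else None
        mother = self._by_id.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def sequenced_members(self, family_id: str) -> list[Individual]:
        return [m for m in self._families[family_id] if m.sequenced]

    def unaffected_ids(self) -> set[str]:
        return {i.sample_id for i in self._by_id.values() if i.affected == "unaffected"}


class ExpressionMatrix:
    """Genes x samples expression with per-sample developmental metadata.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns; metadata (optional) has one row per sample, indexed by
    sample id, with at least donor id and developmental stage.
    """

    def __init__(self, values: pd.DataFrame, metadata: Optional[pd.DataFrame] = None):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbol(s): {dupes}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(arr).any():
            raise ValueError("expression values must not contain NaN")
        if (arr < 0).any():
            raise ValueError("expression values must be nonnegative")
        if metadata is not None:
            missing = set(values.columns) - set(metadata.index)
            extra = set(metadata.index) - set(values.columns)
            if missing or extra:
                raise ValueError(
                    f"metadata/sample mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
                )
            metadata = metadata.loc[values.columns]
        self.values = values
        self.metadata = metadata

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, genes: list[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes], self.metadata)
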