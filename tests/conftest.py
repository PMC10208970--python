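"""Shared fixtures: hand-built trios and small synthetic datasets."""
from __future__ import annotations

import pytest

from castriage.types import (
    AnnotatedVariant,
    GenotypeCall,
    Individual,
    Pedigree,
    SiteQCMetrics,
)


def make_trio_ped(family_id: str = "FAM1", proband_sex: str = "male",
                  father_affected: bool = False, mother_affected: bool = False,
                  duo_missing: str | None = None) -> Pedigree:
    """A single trio (or duo when one parent is dropped)."""
    inds = [
        Individual(sample_id="P1", family_id=family_id,
                   father_id=None if duo_missing == "father" else "F1",
                   mother_id=None if duo_missing == "mother" else "M1",
                   sex=proband_sex, affected="affected"),
    ]
    if duo_missing != "father":
        inds.append(Individual(sample_id="F1", family_id=family_id, sex="male",
                               affected="affected" if father_affected else "unaffected"))
    if duo_missing != "mother":
        inds.append(Individual(sample_id="M1", family_id=family_id, sex="female",
                               affected="affected" if mother_affected else "unaffected"))
    return Pedigree(inds)


def gt(sample: str, genotype: str, dp: int = 40, gq: int = 80) -> GenotypeCall:
    return GenotypeCall(sample_id=sample, genotype=genotype, depth=dp, quality=gq)


def make_variant(chrom: str = "1", pos: int = 1000, ref: str = "A", alt: str = "T",
                 family_id: str = "FAM1", gene: str = "GENE1",
                 transcript: str = "ENST1", consequence=("missense_variant",),
                 genotypes: dict | None = None, site_qc: SiteQCMetrics | None = None,
                 **scores) -> AnnotatedVariant:
    if genotypes is None:
        genotypes = {"P1": gt("P1", "het"), "F1": gt("F1", "hom_ref"),
                     "M1": gt("M1", "hom_ref")}
    if site_qc is None:
        site_qc = SiteQCMetrics(variant_class="snv" if len(ref) == len(alt) else "indel")
    return AnnotatedVariant(
        family_id=family_id, chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=transcript, consequence=frozenset(consequence),
        site_qc=site_qc, genotypes=genotypes, **scores,
    )


@pytest.fixture
def trio_ped() -> Pedigree:
    return make_trio_ped()
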