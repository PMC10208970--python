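"""Readers and writers for every external format the pipeline touches.

The tab-separated annotated-variant dialect is the canonical format; VCF
(4.x with a VEP-style CSQ INFO field) is supported through a thin adapter.
Empty strings denote missing values throughout — a missing gnomAD allele
count is parsed as ``None``, never as 0.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional

import pandas as pd

from .types import (
    AnnotatedVariant,
    ExpressionMatrix,
    GenotypeCall,
    Individual,
    KNOWN_CONSEQUENCES,
    Pedigree,
    SiteQCMetrics,
    StructuralVariantCall,
)

VARIANT_COLUMNS = [
    "family", "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
    "gnomad_ac", "gnomad_af", "pli", "loftool", "cadd_phred", "sift", "polyphen",
    "mtr_fdr", "ada_score", "rf_score", "qd", "fs", "sor", "mq_rank_sum",
    "read_pos_rank_sum", "excess_het_z", "filter",
]

_SIFT_ALIASES = {
    "del": "deleterious",
    "deleterious": "deleterious",
    "dellowconf": "deleterious_low_confidence",
    "deleterious_low_confidence": "deleterious_low_confidence",
    "tolerated": "tolerated",
    "tol": "tolerated",
}
_POLYPHEN_ALIASES = {
    "dam": "probably_damaging",
    "probdam": "probably_damaging",
    "probably_damaging": "probably_damaging",
    "posdam": "possibly_damaging",
    "possibly_damaging": "possibly_damaging",
    "ben": "benign",
    "benign": "benign",
}


class ParseError(ValueError):
    """Malformed input row; message names the offending line."""


def _opt_float(s: str) -> Optional[float]:
    return None if s == "" else float(s)


def _opt_int(s: str) -> Optional[int]:
    return None if s == "" else int(s)


def parse_prediction(text: str, aliases: dict) -> tuple[Optional[str], Optional[float]]:
    """Parse a VEP-style ``Call(score)`` string, a bare call, or empty.

    Accepts e.g. ``Del(0)``, ``ProbDam(0.998)``, ``deleterious(0.01)``,
    ``tolerated``. Returns (canonical call, score).
    """
    text = text.strip()
    if not text:
        return None, None
    call, score = text, None
    if text.endswith(")") and "(" in text:
        call, rest = text.split("(", 1)
        score = float(rest[:-1])
    key = call.strip().lower().replace(" ", "_").replace("-", "_")
    if key not in aliases:
        raise ValueError(f"unrecognised prediction call {call!r}")
    return aliases[key], score


def format_prediction(call: Optional[str], score: Optional[float]) -> str:
    if call is None:
        return ""
    return call if score is None else f"{call}({score:g})"


def _parse_genotype(sample: str, gt: str, dp: str, gq: str) -> GenotypeCall:
    return GenotypeCall(
        sample_id=sample,
        genotype=gt if gt else "missing",
        depth=_opt_int(dp),
        quality=_opt_int(gq),
    )


def _sample_names(header: list[str]) -> list[str]:
    """Per-sample triplet columns SAMPLE.gt / SAMPLE.dp / SAMPLE.gq."""
    tail = header[len(VARIANT_COLUMNS):]
    if len(tail) % 3:
        raise ParseError("sample columns must come in gt/dp/gq triplets")
    names = []
    for i in range(0, len(tail), 3):
        gt, dp, gq = tail[i: i + 3]
        if not (gt.endswith(".gt") and dp.endswith(".dp") and gq.endswith(".gq")):
            raise ParseError(f"malformed sample column triplet: {tail[i:i+3]}")
        base = gt[:-3]
        if dp[:-3] != base or gq[:-3] != base:
            raise ParseError(f"sample column triplet names disagree: {tail[i:i+3]}")
        names.append(base)
    return names


def read_annotated_variants(path, dialect: str = "tsv") -> list[AnnotatedVariant]:
    """Read annotated variants from the TSV dialect or a VEP-annotated VCF.

    One record is emitted per (site, alt allele, transcript). Unknown
    consequence terms trigger a warning but are retained verbatim.
    """
    if dialect == "vcf":
        return read_annotated_vcf(path)
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    records: list[AnnotatedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header required") from None
        if header[: len(VARIANT_COLUMNS)] != VARIANT_COLUMNS:
            raise ParseError(f"{path}: header does not match the annotated-variant dialect")
        samples = _sample_names(header)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0]):
                continue
            try:
                records.append(_row_to_variant(row, header, samples))
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def _row_to_variant(row: list[str], header: list[str], samples: list[str]) -> AnnotatedVariant:
    if len(row) != len(header):
        raise ValueError(f"expected {len(header)} fields, got {len(row)}")
    d = dict(zip(header, row))
    consequence = frozenset(t for t in d["consequence"].split(",") if t)
    unknown = consequence - KNOWN_CONSEQUENCES
    if unknown:
        warnings.warn(f"unknown consequence term(s) retained: {sorted(unknown)}", stacklevel=3)
    sift_call, sift_score = parse_prediction(d["sift"], _SIFT_ALIASES)
    poly_call, poly_score = parse_prediction(d["polyphen"], _POLYPHEN_ALIASES)
    ref, alt = d["ref"], d["alt"]
    site_qc = SiteQCMetrics(
        filter_flags=frozenset(f for f in d["filter"].split(",") if f) or frozenset({"PASS"}),
        qd=_opt_float(d["qd"]),
        fs=_opt_float(d["fs"]),
        sor=_opt_float(d["sor"]),
        mq_rank_sum=_opt_float(d["mq_rank_sum"]),
        read_pos_rank_sum=_opt_float(d["read_pos_rank_sum"]),
        excess_het_z=_opt_float(d["excess_het_z"]),
        variant_class="snv" if len(ref) == len(alt) else "indel",
    )
    genotypes = {}
    for s in samples:
        gt, dp, gq = d[f"{s}.gt"], d[f"{s}.dp"], d[f"{s}.gq"]
        if gt in ("", "missing") and dp == "" and gq == "":
            continue  # sample not assayed for this record
        genotypes[s] = _parse_genotype(s, gt, dp, gq)
    return AnnotatedVariant(
        family_id=d["family"],
        chrom=d["chrom"],
        pos=int(d["pos"]),
        ref=ref,
        alt=alt,
        gene=d["gene"],
        transcript=d["transcript"],
        consequence=consequence,
        gnomad_ac=_opt_int(d["gnomad_ac"]),
        gnomad_af=_opt_float(d["gnomad_af"]),
        pli=_opt_float(d["pli"]),
        loftool=_opt_float(d["loftool"]),
        cadd_phred=_opt_float(d["cadd_phred"]),
        sift_call=sift_call,
        sift_score=sift_score,
        polyphen_call=poly_call,
        polyphen_score=poly_score,
        mtr_fdr=_opt_float(d["mtr_fdr"]),
        ada_score=_opt_float(d["ada_score"]),
        rf_score=_opt_float(d["rf_score"]),
        site_qc=site_qc,
        genotypes=genotypes,
    )


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:g}"
    return str(x)


def write_annotated_variants(variants: list[AnnotatedVariant], path) -> None:
    """Write the canonical TSV dialect; inverse of :func:`read_annotated_variants`."""
    samples = sorted({s for v in variants for s in v.genotypes})
    header = VARIANT_COLUMNS + [f"{s}.{k}" for s in samples for k in ("gt", "dp", "gq")]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for v in variants:
            row = [
                v.family_id, v.chrom, v.pos, v.ref, v.alt, v.gene, v.transcript,
                ",".join(sorted(v.consequence)),
                _fmt(v.gnomad_ac), _fmt(v.gnomad_af), _fmt(v.pli), _fmt(v.loftool),
                _fmt(v.cadd_phred),
                format_prediction(v.sift_call, v.sift_score),
                format_prediction(v.polyphen_call, v.polyphen_score),
                _fmt(v.mtr_fdr), _fmt(v.ada_score), _fmt(v.rf_score),
                _fmt(v.site_qc.qd), _fmt(v.site_qc.fs), _fmt(v.site_qc.sor),
                _fmt(v.site_qc.mq_rank_sum), _fmt(v.site_qc.read_pos_rank_sum),
                _fmt(v.site_qc.excess_het_z),
                ",".join(sorted(v.site_qc.filter_flags)),
            ]
            for s in samples:
                g = v.genotypes.get(s)
                if g is None:
                    row += ["missing", "", ""]
                else:
                    row += [g.genotype, _fmt(g.depth), _fmt(g.quality)]
            w.writerow(row)


# ---------------------------------------------------------------------------
# VCF adapter


def read_annotated_vcf(path) -> list[AnnotatedVariant]:
    """Thin VCF adapter: VCF 4.x with a VEP-style CSQ INFO field.

    CSQ subfields are pipe-delimited and named in the header Description
    (``Format: gene|transcript|consequence|...``) using the same field names
    as the TSV dialect; FORMAT must carry GT:DP:GQ. The family id is taken
    from the INFO key ``FAMILY`` (one family per VCF otherwise via filename
    stem).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    csq_header = vf.header.info.get("CSQ")
    if csq_header is None:
        raise ParseError(f"{path}: no CSQ INFO field in header")
    desc = csq_header.description
    fields = desc.split("Format:", 1)[1].strip().split("|") if "Format:" in desc else desc.split("|")
    fields = [f.strip() for f in fields]
    default_family = Path(str(path)).stem
    records: list[AnnotatedVariant] = []
    declared_info = set(vf.header.info.keys())

    def info_get(rec, key):
        return rec.info.get(key) if key in declared_info else None

    for rec in vf:
        family = info_get(rec, "FAMILY") or default_family
        filt = frozenset(rec.filter.keys()) or frozenset({"PASS"})
        for alt_i, alt in enumerate(rec.alts or ()):
            genotypes = {}
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    cls = "missing"
                elif len(gt) == 1:
                    cls = "hemi_alt" if gt[0] == alt_i + 1 else "hom_ref"
                else:
                    n_alt = sum(1 for a in gt if a == alt_i + 1)
                    cls = {0: "hom_ref", 1: "het", 2: "hom_alt"}[n_alt]
                genotypes[sample] = GenotypeCall(
                    sample_id=sample, genotype=cls,
                    depth=call.get("DP"), quality=call.get("GQ"),
                )
            ref = rec.ref
            site_qc = SiteQCMetrics(
                filter_flags=filt,
                qd=info_get(rec, "QD"),
                fs=info_get(rec, "FS"),
                sor=info_get(rec, "SOR"),
                mq_rank_sum=info_get(rec, "MQRankSum"),
                read_pos_rank_sum=info_get(rec, "ReadPosRankSum"),
                excess_het_z=info_get(rec, "ExcessHetZ"),
                variant_class="snv" if len(ref) == len(alt) else "indel",
            )
            for csq in rec.info.get("CSQ", ()):  # one entry per transcript
                d = dict(zip(fields, csq.split("|")))
                consequence = frozenset(
                    t for t in d.get("consequence", "").replace("&", ",").split(",") if t
                )
                unknown = consequence - KNOWN_CONSEQUENCES
                if unknown:
                    warnings.warn(f"unknown consequence term(s) retained: {sorted(unknown)}")
                sift_call, sift_score = parse_prediction(d.get("sift", ""), _SIFT_ALIASES)
                poly_call, poly_score = parse_prediction(d.get("polyphen", ""), _POLYPHEN_ALIASES)
                records.append(
                    AnnotatedVariant(
                        family_id=str(family),
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=ref,
                        alt=alt,
                        gene=d.get("gene", ""),
                        transcript=d.get("transcript", ""),
                        consequence=consequence,
                        gnomad_ac=_opt_int(d.get("gnomad_ac", "")),
                        gnomad_af=_opt_float(d.get("gnomad_af", "")),
                        pli=_opt_float(d.get("pli", "")),
                        loftool=_opt_float(d.get("loftool", "")),
                        cadd_phred=_opt_float(d.get("cadd_phred", "")),
                        sift_call=sift_call,
                        sift_score=sift_score,
                        polyphen_call=poly_call,
                        polyphen_score=poly_score,
                        mtr_fdr=_opt_float(d.get("mtr_fdr", "")),
                        ada_score=_opt_float(d.get("ada_score", "")),
                        rf_score=_opt_float(d.get("rf_score", "")),
                        site_qc=site_qc,
                        genotypes=genotypes,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# PED


_SEX = {"1": "male", "2": "female"}
_PHENO = {"1": "unaffected", "2": "affected"}


def read_pedigree(path) -> Pedigree:
    """Standard 6-column PED (FID IID PAT MAT SEX PHENO), whitespace-delimited.

    An optional 7th column annotates monozygotic twins as ``MZ:<co-twin id>``
    (``.`` for none). '0' parent ids mean the parent is absent/unavailable.
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 columns, got {len(parts)}")
            fid, iid, pat, mat, sex, pheno = parts[:6]
            twin = None
            if len(parts) >= 7 and parts[6] not in (".", "0", ""):
                if not parts[6].startswith("MZ:"):
                    raise ParseError(f"{path}:{lineno}: malformed twin annotation {parts[6]!r}")
                twin = parts[6][3:]
            if iid in (pat, mat):
                raise ParseError(f"{path}:{lineno}: sample {iid!r} lists itself as a parent")
            individuals.append(
                Individual(
                    sample_id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX.get(sex, "unknown"),
                    affected=_PHENO.get(pheno, "unknown"),
                    twin_of=twin,
                )
            )
    return Pedigree(individuals)


def write_pedigree(ped: Pedigree, path) -> None:
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    pheno_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for ind in ped.individuals:
            cols = [
                ind.family_id, ind.sample_id,
                ind.father_id or "0", ind.mother_id or "0",
                sex_code[ind.sex], pheno_code[ind.affected],
            ]
            if ind.twin_of:
                cols.append(f"MZ:{ind.twin_of}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix

METADATA_COLUMNS = ["sample_id", "donor_id", "stage_label", "age_value", "age_unit"]


def read_expression_matrix(path, metadata_path=None) -> ExpressionMatrix:
    """Genes x samples TSV (first column gene symbol) plus sample metadata."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell ({exc})") from exc
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t")
        missing_cols = set(METADATA_COLUMNS) - set(metadata.columns)
        if missing_cols:
            raise ParseError(f"{metadata_path}: missing metadata column(s) {sorted(missing_cols)}")
        metadata = metadata.set_index("sample_id")
    return ExpressionMatrix(values, metadata)


def write_expression_matrix(m: ExpressionMatrix, path, metadata_path=None) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")
    if metadata_path is not None and m.metadata is not None:
        m.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Structural variants, panels, review files

SV_COLUMNS = ["family", "chrom", "start", "end", "sv_type", "caller", "sv_af", "families_observed"]


def read_sv_calls(path) -> list[StructuralVariantCall]:
    """BED-derived SV TSV; start/end are 1-based inclusive in this dialect."""
    calls: list[StructuralVariantCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != SV_COLUMNS:
            raise ParseError(f"{path}: header does not match the SV dialect")
        for lineno, d in enumerate(reader, start=2):
            try:
                calls.append(
                    StructuralVariantCall(
                        family_id=d["family"],
                        chrom=d["chrom"],
                        start=int(d["start"]),
                        end=int(d["end"]),
                        sv_type=d["sv_type"],
                        caller_label=d["caller"],
                        sv_af=_opt_float(d["sv_af"]),
                        families_observed=int(d["families_observed"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return calls


def write_sv_calls(calls: list[StructuralVariantCall], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SV_COLUMNS)
        for c in calls:
            w.writerow(
                [c.family_id, c.chrom, c.start, c.end, c.sv_type, c.caller_label,
                 _fmt(c.sv_af), c.families_observed]
            )


def read_gene_list(path) -> set[str]:
    """One symbol per line; '#' comments and blank lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line.upper())
    return genes


def read_review_table(path) -> pd.DataFrame:
    """Clinical review file: family, chrom, pos, ref, alt, acmg_class, phenotype_consistent."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"family": str, "chrom": str, "pos": int, "ref": str, "alt": str},
    )
    required = {"family", "chrom", "pos", "ref", "alt", "acmg_class", "phenotype_consistent"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing review column(s) {sorted(missing)}")
    df["acmg_class"] = df["acmg_class"].astype(int)
    df["phenotype_consistent"] = df["phenotype_consistent"].map(
        lambda x: str(x).strip().lower() in ("1", "true", "yes", "y")
    )
    return df
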