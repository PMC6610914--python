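"""Reading annotated cohort VCFs and writing tabular variant output.

The reader accepts either one multi-sample VCF or a list of per-subject
VCFs (merged allele-exactly on (chrom, pos, ref, alt)).  Multi-allelic
sites are decomposed into one :class:`~varprio.model.VariantRecord` per ALT
allele before anything downstream runs.  Expected annotation keys (all
optional per record; a missing key is recorded as absent, never as 0):

INFO  GENE, CDS, SIFT, PPH, GRD, SAAF, HRUN, CNVCONF, PVAL and the
      membership flags DBSNP, UCSCC, DGV, EX5K, COSMIC.
FORMAT  GT, DP.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

from .model import (
    CohortCallSet,
    VariantAnnotations,
    VariantRecord,
    classify_variant_type,
)


class VcfFormatError(ValueError):
    """Unreadable or inconsistent VCF input."""


def _per_allele(value, allele_idx: int, n_alt: int):
    """Pick the value for one ALT allele from a Number=A or scalar INFO field."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        if allele_idx < len(value):
            return value[allele_idx]
        return None
    if isinstance(value, str) and n_alt > 1 and "," in value:
        parts = value.split(",")
        return parts[allele_idx] if allele_idx < len(parts) else None
    return value


def _opt_float(v):
    if v is None or v == ".":
        return None
    # htslib stores INFO floats as 32-bit; quantize to 6 significant digits
    # to shed the representation noise (0.05 would otherwise read back as
    # 0.050000000745, 35.04 as 35.040001).
    return float(f"{float(v):.6g}")


def _opt_int(v):
    if v is None or v == ".":
        return None
    return int(round(float(v)))


def _records_from_file(path: Path) -> tuple[list[str], list[VariantRecord]]:
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"{path}: cannot open as VCF: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for line_no, var in enumerate(vcf, start=1):
        try:
            records.extend(_decompose(var, samples))
        except VcfFormatError:
            raise
        except Exception as exc:
            raise VcfFormatError(
                f"{path}: record {line_no} ({var.CHROM}:{var.POS}): {exc}"
            ) from exc
    vcf.close()
    return samples, records


def _decompose(var, samples: Sequence[str]) -> list[VariantRecord]:
    n_alt = len(var.ALT)
    dp = var.format("DP")
    depths_raw = []
    for i in range(len(samples)):
        if dp is None:
            depths_raw.append(0)
        else:
            d = int(dp[i][0]) if dp[i][0] is not None else 0
            depths_raw.append(max(d, 0))
    info = var.INFO
    out = []
    for k, alt in enumerate(var.ALT):
        genotypes: dict[str, bool] = {}
        depths: dict[str, int] = {}
        for i, s in enumerate(samples):
            alleles = var.genotypes[i][:-1]  # last element is phasing flag
            genotypes[s] = (k + 1) in alleles
            depths[s] = depths_raw[i]
        gene = _per_allele(info.get("GENE"), k, n_alt)
        cds = _per_allele(info.get("CDS"), k, n_alt)
        ann = VariantAnnotations(
            sift=_opt_float(_per_allele(info.get("SIFT"), k, n_alt)),
            polyphen=_opt_float(_per_allele(info.get("PPH"), k, n_alt)),
            grantham=_opt_int(_per_allele(info.get("GRD"), k, n_alt)),
            exac_saaf=_opt_float(_per_allele(info.get("SAAF"), k, n_alt)),
            in_dbsnp=bool(info.get("DBSNP")),
            in_ucsc_common=bool(info.get("UCSCC")),
            in_dgv=bool(info.get("DGV")),
            in_5000exomes=bool(info.get("EX5K")),
            in_cosmic=bool(info.get("COSMIC")),
            homopolymer_len=_opt_int(_per_allele(info.get("HRUN"), k, n_alt)),
            cnv_confidence=_opt_float(_per_allele(info.get("CNVCONF"), k, n_alt)),
        )
        out.append(VariantRecord(
            chrom=var.CHROM,
            pos=var.POS,
            ref_allele=var.REF,
            alt_allele=alt,
            subject_depths=depths,
            genotypes=genotypes,
            caller_p=_opt_float(info.get("PVAL")),
            variant_type=classify_variant_type(var.REF, alt),
            gene=str(gene) if gene is not None else "",
            cds_change=str(cds) if cds is not None else "",
            annotations=ann,
        ))
    return out


def read_cohort_vcf(
    paths: str | Path | Sequence[str | Path],
    case_id: str,
) -> CohortCallSet:
    """Read one multi-sample VCF, or several per-subject VCFs, into a cohort.

    Per-subject files are merged allele-exactly: records sharing
    (chrom, pos, ref, alt) become one record whose genotype/depth maps span
    all subjects (annotations from the first file seen win); subjects absent
    from a site get a no-call with depth 0.

    Raises
    ------
    VcfFormatError
        On unreadable input or when ``case_id`` is not among the samples.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_subjects: list[str] = []
    merged: dict[tuple, VariantRecord] = {}
    for path in paths:
        samples, records = _records_from_file(Path(path))
        for s in samples:
            if s not in all_subjects:
                all_subjects.append(s)
        for rec in records:
            prev = merged.get(rec.key)
            if prev is None:
                merged[rec.key] = rec
            else:
                prev.subject_depths = {**prev.subject_depths, **rec.subject_depths}
                prev.genotypes = {**prev.genotypes, **rec.genotypes}
    if case_id not in all_subjects:
        raise VcfFormatError(
            f"case_id {case_id!r} not among samples {all_subjects}")
    records = list(merged.values())
    for rec in records:
        depths = dict(rec.subject_depths)
        genos = dict(rec.genotypes)
        for s in all_subjects:
            depths.setdefault(s, 0)
            genos.setdefault(s, False)
        rec.subject_depths = depths
        rec.genotypes = genos
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
    return CohortCallSet(subjects=all_subjects, case_id=case_id, records=records)


TABLE_COLUMNS = ["subject", "gene", "chrom", "pos", "ref", "alt", "type",
                 "effect", "sift", "polyphen", "grantham"]


def write_variant_table(records: Iterable[VariantRecord],
                        destination: str | Path) -> pd.DataFrame:
    """Write records as a UTF-8 TSV, one row per (record, called subject).

    Rows are sorted by (chrom, pos, alt, subject); absent values are written
    as ".".  A record with no called subject contributes one row with
    subject ".".  Returns the DataFrame that was written.
    """
    rows = []
    for rec in records:
        subjects = rec.called_subjects() or ["."]
        for s in subjects:
            rows.append({
                "subject": s,
                "gene": rec.gene or ".",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref_allele,
                "alt": rec.alt_allele,
                "type": rec.variant_type.value,
                "effect": rec.effect or ".",
                "sift": rec.annotations.sift,
                "polyphen": rec.annotations.polyphen,
                "grantham": rec.annotations.grantham,
            })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["chrom", "pos", "alt", "subject"],
                            kind="mergesort").reset_index(drop=True)
    df.to_csv(destination, sep="\t", index=False, na_rep=".")
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_variant_table` ("." -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
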