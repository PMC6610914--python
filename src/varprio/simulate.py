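"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the study conditions the pipeline targets: one case
subject plus a small control group (default 3), ~10,000 annotated exome
variants over a toy 10-gene genome, a handful of planted case-exclusive
deleterious variants that pass every filter stage, and distractor classes
each engineered to be removed by exactly one named stage:

============================  =========================================
truth class                   designated removal point
============================  =========================================
true_exclusive                none (survives the whole pipeline)
common_dbsnp                  SNV chain, common_snp stage (dbSNP/UCSC)
population_saaf               exac_saaf stage
benign_scores                 sift stage (tolerated SIFT score)
known_cosmic                  cosmic stage
structural_dgv                CNV chain, dgv stage
shared_with_control           exclusivity step (called in a control)
low_coverage                  exclusivity step (case depth < 100x)
============================  =========================================

Knowledge bases, the coding-sequence FASTA, and the expression table are
generated consistently with the planted labels, so end-to-end recovery of
the true-exclusive set is exact by construction.  CDS coordinates agree
between the VCF and the FASTA (each gene is a contiguous forward-strand
CDS), so consequence annotation runs end-to-end on the fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .consequence import CodingSequence, write_cds_fasta
from .knowledge import ExpressionTable, KnowledgeBase, compute_grantham_matrix
from .model import (
    CohortCallSet,
    VariantAnnotations,
    VariantRecord,
    VariantType,
)

TRUE_CLASS = "true_exclusive"
DISTRACTOR_CLASSES = (
    "common_dbsnp",
    "population_saaf",
    "benign_scores",
    "known_cosmic",
    "shared_with_control",
    "low_coverage",
    "structural_dgv",
)
ALL_CLASSES = (TRUE_CLASS,) + DISTRACTOR_CLASSES

#: Filter-chain stage (or exclusivity reason) that must remove each class.
DESIGNATED_STAGE = {
    "common_dbsnp": "common_snp",
    "population_saaf": "exac_saaf",
    "benign_scores": "sift",
    "known_cosmic": "cosmic",
    "structural_dgv": "dgv",
    "shared_with_control": "in_control",
    "low_coverage": "low_depth",
}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODON_TABLE = {}  # filled lazily from Bio via consequence translation


def _codon_aa(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate the targeted cohort shape: 1 case + 3 controls, 10,000
    called variants, 4 planted true exclusives.  ``class_fractions`` splits
    the non-true variants over the distractor classes (default: equal
    sevenths; integer remainders go to common_dbsnp).  Per-sample depth is
    negative-binomial with the given mean/dispersion; case depth for planted
    passing variants is redrawn until it clears 100x (a truncated draw, so
    the floor holds with probability 1).
    """

    n_controls: int = 3
    n_variants_total: int = 10_000
    n_true_exclusive: int = 4
    class_fractions: Optional[dict[str, float]] = None
    depth_mean: float = 180.0
    depth_dispersion: float = 8.0
    seed: int = 0
    n_genes: int = 10
    cds_codons: int = 2499  # sense codons; a TAA stop is appended
    min_case_depth: int = 100

    def __post_init__(self) -> None:
        if self.n_controls < 1:
            raise ValueError("need at least one control")
        if self.n_true_exclusive > self.n_variants_total:
            raise ValueError("n_true_exclusive exceeds n_variants_total")
        if self.class_fractions:
            unknown = set(self.class_fractions) - set(DISTRACTOR_CLASSES)
            if unknown:
                raise ValueError(f"unknown distractor classes: {sorted(unknown)}")
            if any(f < 0 for f in self.class_fractions.values()):
                raise ValueError("class fractions must be non-negative")
            if sum(self.class_fractions.values()) > 1 + 1e-9:
                raise ValueError("class fractions sum above 1")


@dataclass
class SyntheticTruth:
    """Planted class label for every generated variant key."""

    labels: dict[tuple, str] = field(default_factory=dict)

    def keys_of(self, cls: str) -> set[tuple]:
        return {k for k, c in self.labels.items() if c == cls}

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in ALL_CLASSES}
        for c in self.labels.values():
            counts[c] += 1
        return counts


@dataclass
class GeneratedCohort:
    """Everything :func:`generate_cohort` produces, ready for the pipeline."""

    cohort: CohortCallSet
    knowledge_bases: dict[str, KnowledgeBase]
    expression: ExpressionTable
    coding_sequences: dict[str, CodingSequence]
    truth: SyntheticTruth
    params: SimulationParams


def _class_counts(params: SimulationParams) -> dict[str, int]:
    remaining = params.n_variants_total - params.n_true_exclusive
    fracs = params.class_fractions or {
        c: 1.0 / len(DISTRACTOR_CLASSES) for c in DISTRACTOR_CLASSES}
    counts = {c: int(math.floor(fracs.get(c, 0.0) * remaining))
              for c in DISTRACTOR_CLASSES}
    leftover = remaining - sum(counts.values())
    if leftover < 0:
        raise ValueError("class fractions allocate more than the variant budget")
    counts["common_dbsnp"] += leftover
    return counts


class _Genome:
    """Toy genome: one contiguous forward-strand CDS per gene per chromosome."""

    CDS_START = 1_000_001

    def __init__(self, rng: np.random.Generator, n_genes: int, cds_codons: int):
        sense = [b1 + b2 + b3 for b1 in _BASES for b2 in _BASES for b3 in _BASES
                 if b1 + b2 + b3 not in _STOPS]
        self.genes: list[str] = [f"GENE{i + 1:02d}" for i in range(n_genes)]
        self.chrom_of = {g: f"chr{i + 1}" for i, g in enumerate(self.genes)}
        self.cds: dict[str, CodingSequence] = {}
        self.cds_len = 3 * (cds_codons + 1)
        for g in self.genes:
            codons = rng.choice(sense, size=cds_codons)
            self.cds[g] = CodingSequence(g, "".join(codons) + "TAA")
        self._used: dict[str, set[int]] = {g: set() for g in self.genes}

    def sample_free(self, rng: np.random.Generator, gene: str, width: int) -> int:
        """Draw an unused CDS span of ``width`` bases (1-based start, kept
        clear of the terminal stop codon) without reserving it."""
        hi = self.cds_len - 3 - width + 1
        used = self._used[gene]
        for _ in range(10_000):
            pos = int(rng.integers(1, hi + 1))
            if not any(p in used for p in range(pos, pos + width)):
                return pos
        raise ValueError(f"CDS of {gene} is saturated; lower n_variants_total")

    def reserve(self, gene: str, pos: int, width: int) -> None:
        self._used[gene].update(range(pos, pos + width))

    def take_span(self, rng: np.random.Generator, gene: str, width: int) -> int:
        """Reserve and return an unused CDS span of ``width`` bases."""
        pos = self.sample_free(rng, gene, width)
        self.reserve(gene, pos, width)
        return pos

    def genomic_pos(self, cds_pos: int) -> int:
        return self.CDS_START + cds_pos - 1


def _grantham_window_values():
    gm = compute_grantham_matrix()
    return gm


def _deleterious_snv(rng: np.random.Generator, genome: _Genome, gene: str,
                     gm) -> tuple[int, str, str, int]:
    """Find a single-base substitution whose amino-acid change has a
    Grantham distance in the deleterious window [101, 215]."""
    seq = genome.cds[gene].sequence
    for _ in range(10_000):
        pos = genome.sample_free(rng, gene, 1)
        codon_i = (pos + 2) // 3
        codon = seq[3 * codon_i - 3:3 * codon_i]
        ref_aa = _codon_aa(codon)
        off = (pos - 1) % 3
        ref_base = seq[pos - 1]
        alts = [b for b in _BASES if b != ref_base]
        for i in rng.permutation(len(alts)):
            alt = alts[int(i)]
            new_codon = codon[:off] + alt + codon[off + 1:]
            alt_aa = _codon_aa(new_codon)
            if alt_aa in ("*", ref_aa):
                continue
            d = gm.distance(ref_aa, alt_aa)
            if 101 <= d <= 215:
                genome.reserve(gene, pos, 1)
                return pos, ref_base, alt, d
        # position stays free; try another one
    raise ValueError("could not place a deleterious substitution")


def _deleterious_mnv(rng: np.random.Generator, genome: _Genome, gene: str,
                     gm) -> tuple[int, str, str, int]:
    """A 2-base length-preserving substitution within one codon whose single
    amino-acid change lies in the Grantham window."""
    seq = genome.cds[gene].sequence
    for _ in range(10_000):
        pos = genome.sample_free(rng, gene, 2)
        codon_i = (pos + 2) // 3
        if codon_i != (pos + 3) // 3:  # must not straddle codons
            continue
        codon = seq[3 * codon_i - 3:3 * codon_i]
        ref_aa = _codon_aa(codon)
        off = (pos - 1) % 3
        ref2 = seq[pos - 1:pos + 1]
        pairs = [(a, b) for a in _BASES for b in _BASES]
        for i in rng.permutation(len(pairs)):
            a, b = pairs[int(i)]
            alt2 = a + b
            if alt2 == ref2:
                continue
            if alt2[0] == ref2[0] or alt2[1] == ref2[1]:
                continue  # keep it a genuine 2-base MNV
            new_codon = codon[:off] + alt2 + codon[off + 2:]
            alt_aa = _codon_aa(new_codon)
            if alt_aa in ("*", ref_aa):
                continue
            d = gm.distance(ref_aa, alt_aa)
            if 101 <= d <= 215:
                genome.reserve(gene, pos, 2)
                return pos, ref2, alt2, d
    raise ValueError("could not place a deleterious MNV")


def _nbinom_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def generate_cohort(params: SimulationParams) -> GeneratedCohort:
    """Generate a fully-annotated synthetic cohort with planted truth.

    Deterministic for a fixed seed.  Every variant is labeled with exactly
    one truth class; knowledge bases, expression table and coding sequences
    are consistent with the labels (e.g. common_dbsnp variants really are in
    the dbSNP store, true-exclusive genes carry liver level 3).
    """
    rng = np.random.default_rng(params.seed)
    gm = _grantham_window_values()
    genome = _Genome(rng, params.n_genes, params.cds_codons)
    subjects = ["CASE"] + [f"CTRL{i + 1:02d}" for i in range(params.n_controls)]
    case = subjects[0]
    controls = subjects[1:]
    counts = _class_counts(params)

    kbs = {name: KnowledgeBase(name=name)
           for name in ("dbsnp", "ucsc_common", "dgv", "exomes5000",
                        "exac_saaf", "cosmic")}
    truth = SyntheticTruth()
    records: list[VariantRecord] = []

    def depths(case_min: Optional[int] = None,
               case_range: Optional[tuple[int, int]] = None,
               controls_min: Optional[int] = None) -> dict[str, int]:
        out = {}
        for s in subjects:
            d = _nbinom_depth(rng, params.depth_mean, params.depth_dispersion)
            floor = None
            if s == case and case_min is not None:
                floor = case_min
            if s != case and controls_min is not None:
                floor = controls_min
            if floor is not None:
                while d < floor:
                    d = _nbinom_depth(rng, params.depth_mean,
                                      params.depth_dispersion)
            if s == case and case_range is not None:
                d = int(rng.integers(case_range[0], case_range[1] + 1))
            out[s] = d
        return out

    def genos(called: list[str]) -> dict[str, bool]:
        return {s: s in called for s in subjects}

    def passing_scores(sift_hi=False) -> dict:
        return {
            "caller_p": round(float(rng.uniform(0.0, 0.01)), 4),
            "sift": (round(float(rng.uniform(0.2, 1.0)), 4) if sift_hi
                     else round(float(rng.uniform(0.0, 0.05)), 4)),
            "polyphen": round(float(rng.uniform(0.85, 1.0)), 4),
        }

    def gene_cycle(i: int) -> str:
        return genome.genes[i % len(genome.genes)]

    # --- planted true exclusives -----------------------------------------
    for i in range(params.n_true_exclusive):
        gene = gene_cycle(i)
        chrom = genome.chrom_of[gene]
        if i == 1:  # one MNV among the planted set exercises the MNV chain
            cds_pos, ref, alt, grd = _deleterious_mnv(rng, genome, gene, gm)
            vtype = VariantType.MNV
            cds_change = f"c.{cds_pos}_{cds_pos + 1}del{ref}ins{alt}"
        else:
            cds_pos, ref, alt, grd = _deleterious_snv(rng, genome, gene, gm)
            vtype = VariantType.SNV
            cds_change = f"c.{cds_pos}{ref}>{alt}"
        sc = passing_scores()
        rec = VariantRecord(
            chrom=chrom, pos=genome.genomic_pos(cds_pos),
            ref_allele=ref, alt_allele=alt,
            subject_depths=depths(case_min=params.min_case_depth,
                                  controls_min=params.min_case_depth),
            genotypes=genos([case]),
            caller_p=sc["caller_p"], variant_type=vtype,
            gene=gene, cds_change=cds_change,
            annotations=VariantAnnotations(
                sift=sc["sift"], polyphen=sc["polyphen"], grantham=grd),
        )
        records.append(rec)
        truth.labels[rec.key] = TRUE_CLASS

    # --- distractors ------------------------------------------------------
    gene_i = params.n_true_exclusive
    for cls in DISTRACTOR_CLASSES:
        for j in range(counts[cls]):
            gene = gene_cycle(gene_i)
            gene_i += 1
            chrom = genome.chrom_of[gene]

            if cls == "structural_dgv":
                cds_pos = genome.take_span(rng, gene, 1)
                gpos = genome.genomic_pos(cds_pos)
                ref = genome.cds[gene].sequence[cds_pos - 1]
                alt = "<DEL>" if rng.random() < 0.5 else "<DUP>"
                kbs["dgv"].add_interval(chrom, gpos - 1, gpos)
                rec = VariantRecord(
                    chrom=chrom, pos=gpos, ref_allele=ref, alt_allele=alt,
                    subject_depths=depths(case_min=params.min_case_depth),
                    genotypes=genos([case]),
                    caller_p=round(float(rng.uniform(0.0, 0.01)), 4),
                    variant_type=VariantType.CNV, gene=gene,
                    annotations=VariantAnnotations(
                        in_dgv=True,
                        cnv_confidence=round(float(rng.uniform(5.0, 50.0)), 2)),
                )
                records.append(rec)
                truth.labels[rec.key] = cls
                continue

            if cls == "shared_with_control" and j % 3 == 2:
                # every third shared variant is a frameshift insertion that
                # passes the INDEL chain and dies only at exclusivity
                cds_pos = genome.take_span(rng, gene, 1)
                gpos = genome.genomic_pos(cds_pos)
                ref = genome.cds[gene].sequence[cds_pos - 1]
                ins = _BASES[int(rng.integers(0, 4))]
                rec = VariantRecord(
                    chrom=chrom, pos=gpos, ref_allele=ref,
                    alt_allele=ref + ins,
                    subject_depths=depths(case_min=params.min_case_depth),
                    genotypes=genos([case, controls[j % len(controls)]]),
                    caller_p=round(float(rng.uniform(0.0, 0.01)), 4),
                    variant_type=VariantType.INDEL, gene=gene,
                    cds_change=f"c.{cds_pos}_{cds_pos + 1}ins{ins}",
                    annotations=VariantAnnotations(homopolymer_len=2),
                )
                records.append(rec)
                truth.labels[rec.key] = cls
                continue

            # all remaining classes ride a genuinely deleterious substitution
            # so that only the designated stage removes them
            cds_pos, ref, alt, grd = _deleterious_snv(rng, genome, gene, gm)
            sc = passing_scores(sift_hi=(cls == "benign_scores"))
            gpos = genome.genomic_pos(cds_pos)
            key = (chrom, gpos, ref, alt)
            ann_kwargs: dict = {}
            called = [case]
            case_min: Optional[int] = params.min_case_depth
            case_range = None
            if cls == "common_dbsnp":
                kbs["dbsnp"].sites.add(key)
                if j % 2 == 0:
                    kbs["ucsc_common"].sites.add(key)
                ann_kwargs.update(in_dbsnp=True, in_ucsc_common=(j % 2 == 0))
            elif cls == "population_saaf":
                af = round(float(rng.uniform(0.01, 0.25)), 4)
                kbs["exac_saaf"].frequencies[key] = af
                ann_kwargs.update(exac_saaf=af)
            elif cls == "known_cosmic":
                kbs["cosmic"].sites.add(key)
                ann_kwargs.update(in_cosmic=True)
            elif cls == "shared_with_control":
                called = [case, controls[j % len(controls)]]
            elif cls == "low_coverage":
                case_min = None
                case_range = (10, params.min_case_depth - 1)
            rec = VariantRecord(
                chrom=chrom, pos=gpos, ref_allele=ref, alt_allele=alt,
                subject_depths=depths(case_min=case_min, case_range=case_range),
                genotypes=genos(called),
                caller_p=sc["caller_p"], variant_type=VariantType.SNV,
                gene=gene, cds_change=f"c.{cds_pos}{ref}>{alt}",
                annotations=VariantAnnotations(
                    sift=sc["sift"], polyphen=sc["polyphen"], grantham=grd,
                    **ann_kwargs),
            )
            records.append(rec)
            truth.labels[rec.key] = cls

    # --- background catalog entries away from the cohort's variants ------
    for name in ("dbsnp", "ucsc_common", "cosmic"):
        for _ in range(50):
            chrom = genome.chrom_of[gene_cycle(int(rng.integers(0, params.n_genes)))]
            pos = int(rng.integers(2_500_000, 2_600_000))
            ref = _BASES[int(rng.integers(0, 4))]
            alt = rng.choice([b for b in _BASES if b != ref])
            kbs[name].sites.add((chrom, pos, ref, str(alt)))
    for name in ("exac_saaf", "exomes5000"):
        for _ in range(50):
            chrom = genome.chrom_of[gene_cycle(int(rng.integers(0, params.n_genes)))]
            pos = int(rng.integers(2_500_000, 2_600_000))
            ref = _BASES[int(rng.integers(0, 4))]
            alt = rng.choice([b for b in _BASES if b != ref])
            kbs[name].frequencies[(chrom, pos, ref, str(alt))] = round(
                float(rng.uniform(0.001, 0.5)), 4)
    for g in genome.genes:  # background structural variation off the genes
        kbs["dgv"].add_interval(genome.chrom_of[g], 3_000_000, 3_010_000)

    # --- expression table -------------------------------------------------
    true_genes = sorted({records[i].gene for i in range(params.n_true_exclusive)})
    entries: dict[tuple[str, str], int] = {}
    other_level = [0, 1, 2]
    for i, g in enumerate(genome.genes):
        if g in true_genes:
            entries[(g, "liver")] = 3
        else:
            entries[(g, "liver")] = other_level[i % 3]
        entries[(g, "kidney")] = int(rng.integers(0, 4))
        entries[(g, "brain")] = int(rng.integers(0, 4))
    expression = ExpressionTable(entries=entries)

    records.sort(key=lambda r: (int(r.chrom[3:]), r.pos, r.alt_allele))
    cohort = CohortCallSet(subjects=subjects, case_id=case, records=records)
    return GeneratedCohort(
        cohort=cohort, knowledge_bases=kbs, expression=expression,
        coding_sequences=genome.cds, truth=truth, params=params,
    )


# ---------------------------------------------------------------------------
# Fixture bundle writer
# ---------------------------------------------------------------------------

_VCF_INFO_HEADER = """\
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=CDS,Number=A,Type=String,Description="HGVS coding change">
##INFO=<ID=SIFT,Number=A,Type=Float,Description="SIFT score">
##INFO=<ID=PPH,Number=A,Type=Float,Description="PolyPhen score">
##INFO=<ID=GRD,Number=A,Type=Integer,Description="Grantham distance">
##INFO=<ID=SAAF,Number=A,Type=Float,Description="ExAC South Asian allele frequency">
##INFO=<ID=HRUN,Number=A,Type=Integer,Description="Homopolymer run length">
##INFO=<ID=CNVCONF,Number=A,Type=Float,Description="CNV confidence">
##INFO=<ID=PVAL,Number=1,Type=Float,Description="Variant caller p-value">
##INFO=<ID=DBSNP,Number=0,Type=Flag,Description="Present in dbSNP">
##INFO=<ID=UCSCC,Number=0,Type=Flag,Description="Present in UCSC common SNPs">
##INFO=<ID=DGV,Number=0,Type=Flag,Description="Overlaps a DGV interval">
##INFO=<ID=EX5K,Number=0,Type=Flag,Description="Present in 5000Exomes">
##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Present in COSMIC">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _fmt(v: float) -> str:
    return repr(round(float(v), 6))


def _info_field(rec: VariantRecord) -> str:
    ann = rec.annotations
    parts = []
    if rec.gene:
        parts.append(f"GENE={rec.gene}")
    if rec.cds_change:
        parts.append(f"CDS={rec.cds_change}")
    if ann.sift is not None:
        parts.append(f"SIFT={_fmt(ann.sift)}")
    if ann.polyphen is not None:
        parts.append(f"PPH={_fmt(ann.polyphen)}")
    if ann.grantham is not None:
        parts.append(f"GRD={ann.grantham}")
    if ann.exac_saaf is not None:
        parts.append(f"SAAF={_fmt(ann.exac_saaf)}")
    if ann.homopolymer_len is not None:
        parts.append(f"HRUN={ann.homopolymer_len}")
    if ann.cnv_confidence is not None:
        parts.append(f"CNVCONF={_fmt(ann.cnv_confidence)}")
    if rec.caller_p is not None:
        parts.append(f"PVAL={_fmt(rec.caller_p)}")
    for flag, name in ((ann.in_dbsnp, "DBSNP"), (ann.in_ucsc_common, "UCSCC"),
                       (ann.in_dgv, "DGV"), (ann.in_5000exomes, "EX5K"),
                       (ann.in_cosmic, "COSMIC")):
        if flag:
            parts.append(name)
    return ";".join(parts) if parts else "."


def write_cohort_vcf(cohort: CohortCallSet, path: str | Path,
                     seed: Optional[int] = None) -> None:
    """Write the cohort as a sorted multi-sample VCF 4.2 text file."""
    chroms = sorted({r.chrom for r in cohort.records},
                    key=lambda c: int(c[3:]) if c[3:].isdigit() else 10**6)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        src = "##source=varprio-simulate"
        if seed is not None:
            src += f" seed={seed}"
        fh.write(src + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=5000000>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.subjects) + "\n")
        for rec in cohort.records:
            samples = []
            for s in cohort.subjects:
                gt = "0/1" if rec.genotypes.get(s, False) else "0/0"
                samples.append(f"{gt}:{rec.subject_depths.get(s, 0)}")
            fh.write("\t".join([
                rec.chrom, str(rec.pos), ".", rec.ref_allele, rec.alt_allele,
                "100", "PASS", _info_field(rec), "GT:DP", *samples]) + "\n")


def _write_site_kb(kb: KnowledgeBase, path: Path) -> None:
    with_af = bool(kb.frequencies)
    header = "chrom\tpos\tref\talt" + ("\taf" if with_af else "")
    rows = []
    for key in sorted(kb.sites):
        rows.append("\t".join(map(str, key)))
    for key in sorted(kb.frequencies):
        rows.append("\t".join(map(str, key)) + f"\t{kb.frequencies[key]}")
    path.write_text("\n".join([header, *rows]) + "\n")


def _write_bed(kb: KnowledgeBase, path: Path) -> None:
    lines = []
    for chrom in sorted(kb.intervals,
                        key=lambda c: int(c[3:]) if c[3:].isdigit() else 10**6):
        for iv in sorted(kb.intervals[chrom]):
            lines.append(f"{chrom}\t{iv.begin}\t{iv.end}")
    path.write_text("\n".join(lines) + "\n")


def write_fixture_bundle(generated: GeneratedCohort,
                         directory: str | Path) -> dict[str, Path]:
    """Write the full fixture set: cohort VCF, knowledge bases, expression
    TSV, CDS FASTA, truth TSV, and a ready-to-run pipeline config.

    Returns the mapping of logical name -> written path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["vcf"] = directory / "cohort.vcf"
    write_cohort_vcf(generated.cohort, paths["vcf"], seed=generated.params.seed)

    for name, kb in generated.knowledge_bases.items():
        if name == "dgv":
            paths[name] = directory / "kb_dgv.bed"
            _write_bed(kb, paths[name])
        else:
            paths[name] = directory / f"kb_{name}.tsv"
            _write_site_kb(kb, paths[name])

    paths["expression"] = directory / "expression.tsv"
    rows = ["gene\ttissue\tlevel"]
    for (gene, tissue) in sorted(generated.expression.entries):
        rows.append(f"{gene}\t{tissue}\t{generated.expression.entries[(gene, tissue)]}")
    paths["expression"].write_text("\n".join(rows) + "\n")

    paths["cds_fasta"] = directory / "cds.fasta"
    write_cds_fasta(generated.coding_sequences, paths["cds_fasta"])

    paths["truth"] = directory / "truth.tsv"
    rows = ["chrom\tpos\tref\talt\tclass"]
    for key in sorted(generated.truth.labels,
                      key=lambda k: (int(k[0][3:]), k[1], k[3])):
        rows.append("\t".join(map(str, key)) + f"\t{generated.truth.labels[key]}")
    paths["truth"].write_text("\n".join(rows) + "\n")

    config = {
        "inputs": {
            "vcf": "cohort.vcf",
            "case_id": generated.cohort.case_id,
            "cds_fasta": "cds.fasta",
            "expression": "expression.tsv",
            "knowledge_bases": {
                name: paths[name].name for name in generated.knowledge_bases},
        },
        "filters": {
            "saaf_threshold": 0.0,
            "cnv_confidence_min": 5.0,
            "homopolymer_max": 6,
        },
        "selection": {"min_depth": generated.params.min_case_depth,
                      "strict_controls": False},
        "expression": {"tissue": "liver", "min_level": 1, "top_k": 4},
        "output": {"dir": "results"},
    }
    paths["config"] = directory / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
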