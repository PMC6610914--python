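"""Core data model for annotated exome variant calls.

A :class:`VariantRecord` is one called variant for one ALT allele, carrying
per-subject genotype/depth information and the annotation block that the
filter chains consume.  Multi-allelic VCF sites are decomposed into one
record per ALT allele before anything downstream sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class VariantType(str, Enum):
    """Four-way variant classification used to route filter chains."""

    SNV = "SNV"
    MNV = "MNV"
    INDEL = "INDEL"
    CNV = "CNV"


#: Symbolic ALT alleles accepted for copy-number variants.
SYMBOLIC_ALTS = {"<DEL>", "<DUP>"}


class NotAVariantError(ValueError):
    """REF and ALT alleles are identical."""


def classify_variant_type(ref_allele: str, alt_allele: str) -> VariantType:
    """Classify an allele pair as SNV, MNV, INDEL or CNV.

    SNV: both alleles length 1 and different.  MNV: equal lengths > 1 with at
    least one differing position.  INDEL: unequal lengths.  CNV: symbolic ALT
    (``<DEL>`` or ``<DUP>``).  Complex substitutions with unequal allele
    lengths are treated as INDEL so that the four classes partition all valid
    allele pairs.

    Raises
    ------
    NotAVariantError
        If the alleles are identical.
    ValueError
        On empty alleles or an unrecognized symbolic ALT.
    """
    if not ref_allele or not alt_allele:
        raise ValueError("alleles must be non-empty")
    if alt_allele.startswith("<"):
        if alt_allele in SYMBOLIC_ALTS:
            return VariantType.CNV
        raise ValueError(f"unknown symbolic allele {alt_allele!r}")
    if ref_allele == alt_allele:
        raise NotAVariantError(f"not a variant: {ref_allele!r} == {alt_allele!r}")
    if len(ref_allele) == len(alt_allele):
        return VariantType.SNV if len(ref_allele) == 1 else VariantType.MNV
    return VariantType.INDEL


@dataclass
class VariantAnnotations:
    """Annotation block consumed by the filter chains.

    ``None`` means the annotation is absent, which is distinct from any
    numeric value (a SIFT score of 0 is highly deleterious, not missing).
    """

    sift: Optional[float] = None
    polyphen: Optional[float] = None
    grantham: Optional[int] = None
    exac_saaf: Optional[float] = None
    in_dbsnp: bool = False
    in_ucsc_common: bool = False
    in_dgv: bool = False
    in_5000exomes: bool = False
    in_cosmic: bool = False
    homopolymer_len: Optional[int] = None
    cnv_confidence: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen", "exac_saaf"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.grantham is not None and not 0 <= self.grantham <= 215:
            raise ValueError(f"grantham must lie in [0, 215], got {self.grantham}")
        for name in ("homopolymer_len", "cnv_confidence"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


#: Truncating effect classes exempt from substitution-score windows.
TRUNCATING_EFFECTS = {"nonsense", "frameshift_insertion", "frameshift_deletion"}


@dataclass
class VariantRecord:
    """One called variant (one ALT allele) with cohort-wide sample data.

    Parameters
    ----------
    chrom, pos : str, int
        1-based VCF coordinate of the variant.
    ref_allele, alt_allele : str
        Alleles; ``alt_allele`` may be symbolic (``<DEL>``/``<DUP>``) for CNV.
    subject_depths : dict
        Read depth per subject id (may be 0).
    genotypes : dict
        subject id -> True if this ALT allele was called in that subject.
    caller_p : float or None
        Variant-caller p-value in [0, 1].
    variant_type : VariantType
        Must agree with :func:`classify_variant_type` on the alleles.
    gene, cds_change : str
        Gene symbol and HGVS coding change (``c.`` notation), empty if unknown.
    effect : str or None
        Upstream effect class if annotated (e.g. "missense", "nonsense",
        "frameshift_insertion"); filled in by consequence annotation otherwise.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    subject_depths: Mapping[str, int]
    genotypes: Mapping[str, bool]
    caller_p: Optional[float]
    variant_type: VariantType
    gene: str = ""
    cds_change: str = ""
    annotations: VariantAnnotations = field(default_factory=VariantAnnotations)
    effect: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref_allele must be non-empty")
        expected = classify_variant_type(self.ref_allele, self.alt_allele)
        if expected is not self.variant_type:
            raise ValueError(
                f"variant_type {self.variant_type.value} inconsistent with "
                f"alleles {self.ref_allele}>{self.alt_allele} ({expected.value})"
            )
        missing = set(self.genotypes) - set(self.subject_depths)
        if missing:
            raise ValueError(f"subjects lack depth entries: {sorted(missing)}")
        if self.caller_p is not None and not 0.0 <= self.caller_p <= 1.0:
            raise ValueError(f"caller_p must lie in [0, 1], got {self.caller_p}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Allele-exact identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    def called_subjects(self) -> list[str]:
        """Subjects in which this ALT allele was called."""
        return [s for s, called in self.genotypes.items() if called]

    def is_truncating(self) -> bool:
        """True for frameshift/nonsense changes, which are exempt from
        substitution-specific score windows (SIFT/PolyPhen/Grantham)."""
        if self.effect in TRUNCATING_EFFECTS:
            return True
        if self.variant_type is VariantType.INDEL:
            return (len(self.alt_allele) - len(self.ref_allele)) % 3 != 0
        return False


@dataclass
class CohortCallSet:
    """Per-subject variant calls for one case and at least one control."""

    subjects: list[str]
    case_id: str
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        if len(self.subjects) < 2:
            raise ValueError("cohort needs the case plus at least one control")
        if self.case_id not in self.subjects:
            raise ValueError(f"case_id {self.case_id!r} not among subjects")

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.subjects if s != self.case_id]
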