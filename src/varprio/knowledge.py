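"""Knowledge bases: variant catalogs, the Grantham matrix, expression tables.

The membership/frequency stores stand in for the public catalogs used to
discard common or already-reported variation (dbSNP, UCSC common SNPs, DGV,
5000Exomes, ExAC South-Asian allele frequencies, COSMIC).  Site catalogs are
allele-exact; DGV is interval-based because it catalogs structural variation.

The Grantham physicochemical distance matrix is recomputed from Grantham's
(1974) composition/polarity/volume formula rather than shipped as constants:

    D_ij = rho * [alpha (c_i - c_j)^2 + beta (p_i - p_j)^2
                  + gamma (v_i - v_j)^2]^(1/2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho scaling the mean
pairwise distance to 100.  Rounded to integers this spans 5 (Leu-Ile) to 215
(Trp-Cys).  The printed 1974 table deviates from exact recomputation by one
unit on a handful of pairs (no single rho reproduces it entirely); this
implementation standardizes on the exact formula output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from intervaltree import IntervalTree

from .model import VariantRecord

KB_NAMES = ("dbsnp", "ucsc_common", "dgv", "exomes5000", "exac_saaf", "cosmic")
#: Knowledge bases that carry an allele-frequency column.
FREQUENCY_KBS = ("exac_saaf", "exomes5000")

SiteKey = tuple[str, int, str, str]


class KnowledgeBaseFormatError(ValueError):
    """Malformed knowledge-base file; message names the offending line."""


@dataclass
class KnowledgeBase:
    """One membership/frequency store.

    ``sites`` holds allele-exact keys (chrom, pos, ref, alt) with 1-based
    positions; ``intervals`` (DGV only) holds 0-based half-open genomic
    intervals per chromosome; ``frequencies`` (exac_saaf / exomes5000) maps
    site keys to allele frequencies in [0, 1].
    """

    name: str
    sites: set[SiteKey] = field(default_factory=set)
    intervals: dict[str, IntervalTree] = field(default_factory=dict)
    frequencies: dict[SiteKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KB_NAMES:
            raise ValueError(f"unknown knowledge base {self.name!r}")
        if self.intervals and self.name != "dgv":
            raise ValueError("only dgv may carry intervals")
        for key, af in self.frequencies.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency out of [0,1] at {key}: {af}")

    def add_interval(self, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(chrom, IntervalTree()).addi(start, end)


def kb_contains(kb: KnowledgeBase, record: VariantRecord) -> bool:
    """Membership test for a variant record.

    Site catalogs match on the exact (chrom, pos, ref, alt) key; DGV matches
    if the variant's 0-based position falls inside any interval on its
    chromosome; frequency stores match if the key carries any entry.
    """
    if kb.name == "dgv":
        tree = kb.intervals.get(record.chrom)
        return bool(tree is not None and tree.overlaps_point(record.pos - 1))
    key = record.key
    return key in kb.sites or key in kb.frequencies


def kb_frequency(kb: KnowledgeBase, record: VariantRecord) -> Optional[float]:
    """Catalogued allele frequency for the record's key, or None."""
    return kb.frequencies.get(record.key)


def load_membership_kb(path: str | Path, name: str) -> KnowledgeBase:
    """Load a site TSV (chrom, pos, ref, alt[, af]) or DGV BED3 file.

    Site TSVs have a header row and 1-based positions; the ``af`` column is
    required for the frequency stores (exac_saaf, exomes5000) and forbidden
    otherwise.  BED intervals are 0-based half-open.  Duplicate keys collapse
    to one entry (for frequency stores, conflicting frequencies are an error).
    """
    path = Path(path)
    kb = KnowledgeBase(name=name)
    if name == "dgv":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end"], usecols=[0, 1, 2],
            dtype={"chrom": str},
        )
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                start, end = int(row.start), int(row.end)
            except (TypeError, ValueError):
                raise KnowledgeBaseFormatError(
                    f"{path}: line {i}: non-integer BED coordinates") from None
            if end <= start:
                raise KnowledgeBaseFormatError(
                    f"{path}: line {i}: empty interval [{start}, {end})")
            kb.add_interval(str(row.chrom), start, end)
        return kb

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    needs_af = name in FREQUENCY_KBS
    required = ["chrom", "pos", "ref", "alt"] + (["af"] if needs_af else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KnowledgeBaseFormatError(f"{path}: missing columns {missing}")
    if not needs_af and "af" in df.columns:
        raise KnowledgeBaseFormatError(
            f"{path}: af column is only valid for {FREQUENCY_KBS}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if pd.isna(row.pos) or pd.isna(row.chrom) or pd.isna(row.ref) or pd.isna(row.alt):
            raise KnowledgeBaseFormatError(f"{path}: line {i}: incomplete row")
        key = (str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        if needs_af:
            af = float(row.af)
            if not 0.0 <= af <= 1.0:
                raise KnowledgeBaseFormatError(
                    f"{path}: line {i}: allele frequency {af} outside [0, 1]")
            if key in kb.frequencies and kb.frequencies[key] != af:
                raise KnowledgeBaseFormatError(
                    f"{path}: line {i}: conflicting frequencies for {key}")
            kb.frequencies[key] = af
        else:
            kb.sites.add(key)
    return kb


# ---------------------------------------------------------------------------
# Grantham distance matrix
# ---------------------------------------------------------------------------

#: Grantham's (composition, polarity, volume) property triples, in his
#: original row order.
AMINO_ACID_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "S": (1.42, 9.2, 32.0),
    "R": (0.65, 10.5, 124.0),
    "L": (0.0, 4.9, 111.0),
    "P": (0.39, 8.0, 32.5),
    "T": (0.71, 8.6, 61.0),
    "A": (0.0, 8.1, 31.0),
    "V": (0.0, 5.9, 84.0),
    "G": (0.74, 9.0, 3.0),
    "I": (0.0, 5.2, 111.0),
    "F": (0.0, 5.2, 132.0),
    "Y": (0.20, 6.2, 136.0),
    "C": (2.75, 5.5, 55.0),
    "H": (0.58, 10.4, 96.0),
    "Q": (0.89, 10.5, 85.0),
    "N": (1.33, 11.6, 56.0),
    "K": (0.33, 11.3, 119.0),
    "D": (1.38, 13.0, 54.0),
    "E": (0.92, 12.3, 83.0),
    "M": (0.0, 5.7, 105.0),
    "W": (0.13, 5.4, 170.0),
}

GRANTHAM_ALPHA = 1.833
GRANTHAM_BETA = 0.1018
GRANTHAM_GAMMA = 0.000399

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class GranthamMatrix:
    """Symmetric 20x20 integer amino-acid distance matrix, zero diagonal."""

    distances: dict[tuple[str, str], int]

    def distance(self, a: str, b: str) -> int:
        """Distance between two amino acids (1- or 3-letter codes)."""
        a = AA3_TO_1.get(a, a)
        b = AA3_TO_1.get(b, b)
        if a not in AMINO_ACID_PROPERTIES or b not in AMINO_ACID_PROPERTIES:
            raise KeyError(f"not standard amino acids: {a!r}, {b!r}")
        return self.distances[(a, b)]

    @property
    def max_distance(self) -> int:
        return max(self.distances.values())


def _raw_distance(a: str, b: str) -> float:
    ca, pa, va = AMINO_ACID_PROPERTIES[a]
    cb, pb, vb = AMINO_ACID_PROPERTIES[b]
    return math.sqrt(
        GRANTHAM_ALPHA * (ca - cb) ** 2
        + GRANTHAM_BETA * (pa - pb) ** 2
        + GRANTHAM_GAMMA * (va - vb) ** 2
    )


def compute_grantham_matrix() -> GranthamMatrix:
    """Compute the full integer Grantham matrix from the 1974 formula.

    The scale factor rho is chosen so that the mean over the 190 unordered
    amino-acid pairs equals 100 before rounding.
    """
    aas = list(AMINO_ACID_PROPERTIES)
    pairs = list(itertools.combinations(aas, 2))
    raw = {p: _raw_distance(*p) for p in pairs}
    rho = 100.0 / (sum(raw.values()) / len(raw))
    distances: dict[tuple[str, str], int] = {(a, a): 0 for a in aas}
    for (a, b), r in raw.items():
        d = round(rho * r)
        distances[(a, b)] = d
        distances[(b, a)] = d
    return GranthamMatrix(distances=distances)


# ---------------------------------------------------------------------------
# Tissue expression table
# ---------------------------------------------------------------------------

#: Ordinal protein-expression scale emulating GeneCards-style bins.
EXPRESSION_LABELS = {"not detected": 0, "low": 1, "medium": 2, "high": 3}


@dataclass
class ExpressionTable:
    """(gene, tissue) -> ordinal expression level in {0, 1, 2, 3}."""

    entries: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, level in self.entries.items():
            if level not in (0, 1, 2, 3):
                raise ValueError(f"expression level {level} at {key} not in 0..3")

    def level(self, gene: str, tissue: str) -> Optional[int]:
        return self.entries.get((gene, tissue))

    def genes_in_tissue(self, tissue: str) -> list[str]:
        return sorted({g for (g, t) in self.entries if t == tissue})


def load_expression_table(path: str | Path) -> ExpressionTable:
    """Load a TSV with columns gene, tissue, level.

    ``level`` is an integer 0-3 or one of the labels "not detected", "low",
    "medium", "high".  Duplicate (gene, tissue) rows with different levels
    are rejected as ambiguous.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene", "tissue", "level") if c not in df.columns]
    if missing:
        raise KnowledgeBaseFormatError(f"{path}: missing columns {missing}")
    entries: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row.level).strip()
        if raw.lower() in EXPRESSION_LABELS:
            level = EXPRESSION_LABELS[raw.lower()]
        else:
            try:
                level = int(raw)
            except ValueError:
                raise KnowledgeBaseFormatError(
                    f"{path}: line {i}: unknown expression level {raw!r}") from None
        if level not in (0, 1, 2, 3):
            raise KnowledgeBaseFormatError(
                f"{path}: line {i}: expression level {level} outside 0..3")
        key = (str(row.gene), str(row.tissue))
        if key in entries and entries[key] != level:
            raise KnowledgeBaseFormatError(
                f"{path}: line {i}: conflicting levels for {key}")
        entries[key] = level
    return ExpressionTable(entries=entries)
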