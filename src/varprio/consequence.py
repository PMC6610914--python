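"""HGVS coding-change parsing and protein-consequence annotation.

Given a reference coding sequence (CDS) and a structured ``c.`` change, the
annotator applies the change, translates reference and alternate sequences
with the standard genetic code, and classifies the protein-level effect:
missense, nonsense, synonymous, frameshift (by sign), in-frame indel, or
stop loss.  Protein notation uses three-letter amino-acid codes
(``p.Phe139Ser``); frameshifts are reported in the short ``p.Xxx123fs`` form
without downstream-stop scanning.

Only simple coding-DNA notation is supported: substitutions, deletions,
insertions and delins with plain CDS positions.  Intronic offsets
(``c.88+2T>C``), genomic (``g.``) and protein (``p.``) notation are rejected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio.Seq import Seq
from Bio import SeqIO

from .knowledge import AA1_TO_3


class HgvsParseError(ValueError):
    """Text is not a supported HGVS coding-DNA change."""


class ReferenceMismatchError(ValueError):
    """Stated deleted bases disagree with the reference CDS (wrong transcript)."""


class ChangeKind(str, Enum):
    SUBSTITUTION = "substitution"
    DELINS = "delins"
    INSERTION = "insertion"
    DELETION = "deletion"


class Effect(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    INFRAME_INDEL = "inframe_indel"
    STOP_LOSS = "stop_loss"


@dataclass(frozen=True)
class CodingSequence:
    """A gene's coding sequence over {A, C, G, T}, length divisible by 3."""

    gene: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise ValueError(f"{self.gene}: CDS shorter than one codon")
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {len(seq)} not divisible by 3")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.gene}: CDS contains non-ACGT characters")
        if seq[-3:] not in ("TAA", "TAG", "TGA"):
            warnings.warn(f"{self.gene}: CDS lacks a final stop codon", stacklevel=2)


@dataclass(frozen=True)
class CdsChange:
    """Structured coding-DNA change with 1-based CDS coordinates."""

    kind: ChangeKind
    start: int
    end: int
    deleted: str = ""
    inserted: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")
        span = self.end - self.start + 1
        if self.kind is ChangeKind.SUBSTITUTION:
            if len(self.deleted) != span or len(self.inserted) != span:
                raise ValueError("substitution alleles must span start..end")
        elif self.kind is ChangeKind.DELETION and self.inserted:
            raise ValueError("deletion cannot insert bases")
        elif self.kind is ChangeKind.INSERTION and self.deleted:
            raise ValueError("insertion cannot delete bases")
        elif self.kind is ChangeKind.DELINS:
            if self.deleted and len(self.deleted) != span:
                raise ValueError("delins deleted bases must span start..end")

    @property
    def length_preserving(self) -> bool:
        """True when the change does not alter CDS length."""
        if self.kind is ChangeKind.SUBSTITUTION:
            return True
        if self.kind is ChangeKind.DELINS:
            return len(self.inserted) == self.end - self.start + 1
        return False


@dataclass(frozen=True)
class ProteinConsequence:
    """Protein-level effect with its HGVS ``p.`` notation."""

    effect: Effect
    hgvs_p: str
    codon_start: int


def codon_index(cds_pos: int) -> int:
    """Codon number containing a 1-based CDS position: codon i spans
    positions 3i-2 .. 3i, so this is ceil(pos / 3)."""
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return (cds_pos + 2) // 3


_POS = r"(\d+)"
_SUB_RE = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$")
_DELINS_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?del([ACGT]*)ins([ACGT]+)$")
_DEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?del([ACGT]*)$")
_INS_RE = re.compile(rf"^c\.{_POS}_{_POS}ins([ACGT]+)$")
_OFFSET_RE = re.compile(r"c\.[0-9*]*[+\-]")


def parse_hgvs_c(text: str) -> CdsChange:
    """Parse an HGVS coding-DNA change into a :class:`CdsChange`.

    Supported forms: ``c.416T>C``, ``c.1048_1049delGCinsCG``, ``c.76del``,
    ``c.76_78delACT``, ``c.76_77insG``.  Anything else -- protein or genomic
    notation, intronic offsets, malformed text -- raises
    :class:`HgvsParseError`.
    """
    text = text.strip()
    if text.startswith(("p.", "g.", "m.", "n.", "r.")):
        raise HgvsParseError(f"{text!r} is not coding-DNA (c.) notation")
    if not text.startswith("c."):
        raise HgvsParseError(f"{text!r} does not begin with 'c.'")
    if _OFFSET_RE.match(text) or "*" in text:
        raise HgvsParseError(f"intronic/UTR positions unsupported: {text!r}")

    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        return CdsChange(ChangeKind.SUBSTITUTION, pos, pos,
                         deleted=m.group(2), inserted=m.group(3))
    m = _DELINS_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdsChange(ChangeKind.DELINS, start, end,
                         deleted=m.group(3), inserted=m.group(4))
    m = _INS_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsParseError(
                f"insertion must sit between adjacent positions: {text!r}")
        return CdsChange(ChangeKind.INSERTION, start, end, inserted=m.group(3))
    m = _DEL_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        return CdsChange(ChangeKind.DELETION, start, end, deleted=m.group(3))
    raise HgvsParseError(f"unrecognized HGVS coding change: {text!r}")


def _aa3(aa: str) -> str:
    if aa == "*":
        return "Ter"
    return AA1_TO_3.get(aa, aa)


def _translate(seq: str) -> str:
    # Trailing partial codons (possible after a frameshift) are dropped.
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def apply_change(sequence: str, change: CdsChange) -> str:
    """Return the alternate CDS produced by applying ``change``.

    Raises
    ------
    ReferenceMismatchError
        If the change states deleted bases that disagree with the reference.
    ValueError
        If the change coordinates fall outside the sequence.
    """
    n = len(sequence)
    if change.end > n:
        raise ValueError(
            f"change {change.start}..{change.end} outside CDS of length {n}")
    if change.kind is ChangeKind.INSERTION:
        return sequence[:change.start] + change.inserted + sequence[change.start:]
    ref_span = sequence[change.start - 1:change.end]
    if change.deleted and change.deleted != ref_span:
        raise ReferenceMismatchError(
            f"stated reference bases {change.deleted!r} differ from CDS "
            f"{ref_span!r} at c.{change.start}_{change.end}")
    return sequence[:change.start - 1] + change.inserted + sequence[change.end:]


def annotate_consequence(cds: CodingSequence, change: CdsChange) -> ProteinConsequence:
    """Classify the protein-level consequence of a coding change.

    Reference and alternate CDS are translated in full with the standard
    genetic code and compared.  A length-preserving change altering exactly
    one amino acid is missense (``p.Phe139Ser``) or nonsense if the new
    residue is a stop; no change is synonymous; a net length change that is
    not a multiple of 3 is a frameshift (``p.Gly12fs``); a multiple of 3 is
    an in-frame indel.
    """
    alt_seq = apply_change(cds.sequence, change)
    net = len(alt_seq) - len(cds.sequence)

    if net % 3 != 0:
        if change.kind is ChangeKind.INSERTION:
            first_shifted = change.start + 1
        else:
            first_shifted = change.start
        codon = codon_index(first_shifted)
        ref_aa = _translate(cds.sequence)[codon - 1]
        effect = (Effect.FRAMESHIFT_INSERTION if net > 0
                  else Effect.FRAMESHIFT_DELETION)
        return ProteinConsequence(effect, f"p.{_aa3(ref_aa)}{codon}fs", codon)

    ref_prot = _translate(cds.sequence)
    alt_prot = _translate(alt_seq)

    if net != 0:
        codon = codon_index(change.start)
        ref_aa = ref_prot[codon - 1]
        tag = "del" if net < 0 else "ins"
        return ProteinConsequence(
            Effect.INFRAME_INDEL, f"p.{_aa3(ref_aa)}{codon}{tag}", codon)

    diffs = [i for i, (r, a) in enumerate(zip(ref_prot, alt_prot)) if r != a]
    codon = codon_index(change.start)
    if not diffs:
        ref_aa = ref_prot[codon - 1]
        return ProteinConsequence(
            Effect.SYNONYMOUS, f"p.{_aa3(ref_aa)}{codon}=", codon)
    first = diffs[0]
    ref_aa, alt_aa = ref_prot[first], alt_prot[first]
    if len(diffs) == 1:
        if alt_aa == "*":
            effect = Effect.NONSENSE
        elif ref_aa == "*":
            effect = Effect.STOP_LOSS
        else:
            effect = Effect.MISSENSE
        return ProteinConsequence(
            effect, f"p.{_aa3(ref_aa)}{first + 1}{_aa3(alt_aa)}", first + 1)
    # Multi-codon length-preserving delins: reported in range notation.
    last = diffs[-1]
    if "*" in alt_prot[first:last + 1]:
        effect = Effect.NONSENSE
    else:
        effect = Effect.MISSENSE
    alt_aas = "".join(_aa3(a) for a in alt_prot[first:last + 1])
    hgvs_p = (f"p.{_aa3(ref_prot[first])}{first + 1}_"
              f"{_aa3(ref_prot[last])}{last + 1}delins{alt_aas}")
    return ProteinConsequence(effect, hgvs_p, first + 1)


def read_cds_fasta(path: str | Path) -> dict[str, CodingSequence]:
    """Read coding sequences from FASTA; record id is the gene symbol."""
    out: dict[str, CodingSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = CodingSequence(gene=rec.id, sequence=str(rec.seq))
    return out


def write_cds_fasta(cds_by_gene: dict[str, CodingSequence], path: str | Path) -> None:
    """Write coding sequences as FASTA, one record per gene, 60-column wrap."""
    with open(path, "w") as fh:
        for gene in sorted(cds_by_gene):
            seq = cds_by_gene[gene].sequence
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
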