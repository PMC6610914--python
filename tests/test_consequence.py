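"""HGVS parsing, codon arithmetic, and protein-consequence annotation.

The hallmark worked examples are the four coding/protein pairs the method
reports for its candidate genes: c.416T>C (p.Phe139Ser), c.1048_1049delGCinsCG
(p.Ala350Arg), c.1159G>T (p.Gly387Cys), c.430G>C (p.Gly144Arg).  Codon
contexts compatible with the printed reference amino acids are constructed
here and the printed notations must be reproduced exactly.
"""

import numpy as np
import pytest

from varprio import (
    CdsChange,
    CodingSequence,
    Effect,
    annotate_consequence,
    codon_index,
    parse_hgvs_c,
)
from varprio.consequence import (
    ChangeKind,
    HgvsParseError,
    ReferenceMismatchError,
    apply_change,
)

# Independent codon table for the brute-force oracle (hand-entered, not
# derived from the implementation's translation path).
_ORACLE_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _cds_with_codon(codon_number: int, codon: str, fill: str = "GCT",
                    n_codons: int = None, gene: str = "TEST") -> CodingSequence:
    """A CDS whose ``codon_number``-th codon is ``codon`` (alanine filler)."""
    n = n_codons or max(codon_number + 2, 10)
    codons = [fill] * n
    codons[codon_number - 1] = codon
    codons[-1] = "TAA"
    return CodingSequence(gene, "".join(codons))


# ---------------------------------------------------------------------------
# parse_hgvs_c
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("text, kind, start, end, deleted, inserted", [
    ("c.416T>C", ChangeKind.SUBSTITUTION, 416, 416, "T", "C"),
    ("c.1048_1049delGCinsCG", ChangeKind.DELINS, 1048, 1049, "GC", "CG"),
    ("c.1159G>T", ChangeKind.SUBSTITUTION, 1159, 1159, "G", "T"),
    ("c.430G>C", ChangeKind.SUBSTITUTION, 430, 430, "G", "C"),
    ("c.76_78delACT", ChangeKind.DELETION, 76, 78, "ACT", ""),
    ("c.76del", ChangeKind.DELETION, 76, 76, "", ""),
    ("c.76_77insG", ChangeKind.INSERTION, 76, 77, "", "G"),
])
def test_parse_hgvs_c(text, kind, start, end, deleted, inserted):
    change = parse_hgvs_c(text)
    assert change.kind is kind
    assert (change.start, change.end) == (start, end)
    assert (change.deleted, change.inserted) == (deleted, inserted)


def test_equal_length_delins_is_flagged_length_preserving():
    assert parse_hgvs_c("c.1048_1049delGCinsCG").length_preserving
    assert not parse_hgvs_c("c.10_12delACTinsG").length_preserving
    assert parse_hgvs_c("c.416T>C").length_preserving


@pytest.mark.parametrize("text", [
    "p.Gly144Arg",          # protein namespace
    "g.12345A>T",           # genomic namespace
    "c.88+2T>C",            # intronic offset
    "c.-14G>A",             # 5' UTR
    "c.*6A>C",              # 3' UTR
    "416T>C",               # missing prefix
    "c.416T>",              # malformed
    "c.77_76insG",          # non-adjacent insertion coordinates reversed
])
def test_parse_rejects_non_coding_or_malformed(text):
    with pytest.raises(HgvsParseError):
        parse_hgvs_c(text)


# ---------------------------------------------------------------------------
# codon_index
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("pos, codon", [
    (1, 1), (2, 1), (3, 1), (4, 2),       # boundary cases
    (416, 139),                            # the Phe139Ser position
    (1048, 350), (1049, 350),              # the Ala350Arg delins
    (1159, 387),                           # Gly387Cys
    (430, 144),                            # Gly144Arg
])
def test_codon_index(pos, codon):
    assert codon_index(pos) == codon


def test_codon_index_rejects_nonpositive():
    with pytest.raises(ValueError):
        codon_index(0)


# ---------------------------------------------------------------------------
# annotate_consequence: the four hallmark variant/protein pairs
# ---------------------------------------------------------------------------

def test_phe139ser_substitution():
    # codon 139 = TTT (Phe); c.416 is its 2nd base, T>C makes TCT (Ser)
    cds = _cds_with_codon(139, "TTT", n_codons=150, gene="SORD")
    cons = annotate_consequence(cds, parse_hgvs_c("c.416T>C"))
    assert cons.effect is Effect.MISSENSE
    assert cons.hgvs_p == "p.Phe139Ser"
    assert cons.codon_start == 139


def test_ala350arg_delins_reported_missense_style():
    # codon 350 = GCA (Ala) spans c.1048-1050; delins GC>CG makes CGA (Arg)
    cds = _cds_with_codon(350, "GCA", n_codons=360, gene="KRT6A")
    cons = annotate_consequence(cds, parse_hgvs_c("c.1048_1049delGCinsCG"))
    assert cons.effect is Effect.MISSENSE
    assert cons.hgvs_p == "p.Ala350Arg"


def test_gly387cys_substitution():
    # codon 387 = GGT (Gly); c.1159 is its 1st base, G>T makes TGT (Cys)
    cds = _cds_with_codon(387, "GGT", n_codons=400, gene="SVEP1")
    cons = annotate_consequence(cds, parse_hgvs_c("c.1159G>T"))
    assert cons.effect is Effect.MISSENSE
    assert cons.hgvs_p == "p.Gly387Cys"


def test_gly144arg_substitution_and_nonsense_counterpart():
    # codon 144 = GGG (Gly); c.430 is its 1st base, G>C makes CGG (Arg)
    cds = _cds_with_codon(144, "GGG", n_codons=150, gene="MRPL38")
    cons = annotate_consequence(cds, parse_hgvs_c("c.430G>C"))
    assert cons.effect is Effect.MISSENSE
    assert cons.hgvs_p == "p.Gly144Arg"
    # same position on a TGG (Trp) codon, G>A at base 2 makes TGA = stop
    cds2 = _cds_with_codon(144, "TGG", n_codons=150)
    cons2 = annotate_consequence(cds2, parse_hgvs_c("c.431G>A"))
    assert cons2.effect is Effect.NONSENSE
    assert cons2.hgvs_p == "p.Trp144Ter"


# ---------------------------------------------------------------------------
# other effect classes
# ---------------------------------------------------------------------------

def test_synonymous_substitution():
    cds = _cds_with_codon(5, "CTG")  # Leu
    cons = annotate_consequence(cds, parse_hgvs_c("c.15G>A"))  # CTA, still Leu
    assert cons.effect is Effect.SYNONYMOUS


def test_frameshift_by_insertion_and_deletion():
    cds = _cds_with_codon(3, "GGG", n_codons=10)
    ins = annotate_consequence(cds, parse_hgvs_c("c.7_8insA"))
    assert ins.effect is Effect.FRAMESHIFT_INSERTION
    assert ins.hgvs_p == "p.Gly3fs"
    dele = annotate_consequence(cds, parse_hgvs_c("c.7del"))
    assert dele.effect is Effect.FRAMESHIFT_DELETION
    assert dele.hgvs_p == "p.Gly3fs"


def test_inframe_deletion():
    cds = _cds_with_codon(3, "GGG", n_codons=10)
    cons = annotate_consequence(cds, parse_hgvs_c("c.7_9delGGG"))
    assert cons.effect is Effect.INFRAME_INDEL


def test_stop_loss():
    cds = _cds_with_codon(5, "GCT", n_codons=5)  # last codon is TAA
    cons = annotate_consequence(cds, parse_hgvs_c("c.14A>G"))  # TAA->TGA? no: pos14
    # c.13-15 is codon 5 (TAA); c.14 A>G gives TGA (still stop) -> synonymous
    assert cons.effect is Effect.SYNONYMOUS
    cons2 = annotate_consequence(cds, parse_hgvs_c("c.13T>C"))  # CAA = Gln
    assert cons2.effect is Effect.STOP_LOSS


def test_reference_mismatch_signals_wrong_transcript():
    cds = _cds_with_codon(139, "TTT", n_codons=150)
    with pytest.raises(ReferenceMismatchError):
        annotate_consequence(cds, parse_hgvs_c("c.416G>C"))


def test_change_outside_cds_rejected():
    cds = _cds_with_codon(2, "GGG", n_codons=4)
    with pytest.raises(ValueError):
        annotate_consequence(cds, parse_hgvs_c("c.999A>T"))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

def test_substitutions_never_frameshift_random_sample():
    """On 1,000 random single-base substitutions over a random CDS, the
    effect agrees with a brute-force translate-and-diff oracle and is never
    a frameshift."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    sense = [c for c in _ORACLE_CODONS if _ORACLE_CODONS[c] != "*"]
    codons = [sense[i] for i in rng.integers(0, len(sense), size=200)]
    seq = "".join(codons) + "TAA"
    cds = CodingSequence("RANDOM", seq)

    for _ in range(1_000):
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        alt = bases[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        cons = annotate_consequence(
            cds, CdsChange(ChangeKind.SUBSTITUTION, pos, pos, ref, alt))
        assert cons.effect in (Effect.MISSENSE, Effect.NONSENSE,
                               Effect.SYNONYMOUS, Effect.STOP_LOSS)
        # oracle: mutate, translate codon-by-codon with the independent table
        mutated = seq[:pos - 1] + alt + seq[pos:]
        ref_prot = [_ORACLE_CODONS[seq[i:i + 3]] for i in range(0, len(seq), 3)]
        alt_prot = [_ORACLE_CODONS[mutated[i:i + 3]]
                    for i in range(0, len(mutated), 3)]
        diffs = [i for i, (r, a) in enumerate(zip(ref_prot, alt_prot)) if r != a]
        if not diffs:
            assert cons.effect is Effect.SYNONYMOUS
        else:
            (i,) = diffs
            assert cons.codon_start == i + 1
            if alt_prot[i] == "*":
                assert cons.effect is Effect.NONSENSE
            elif ref_prot[i] == "*":
                assert cons.effect is Effect.STOP_LOSS
            else:
                assert cons.effect is Effect.MISSENSE


def test_frameshift_iff_net_length_not_multiple_of_three():
    cds = _cds_with_codon(2, "GGG", n_codons=30)
    for n_ins in range(1, 7):
        change = CdsChange(ChangeKind.INSERTION, 10, 11, inserted="A" * n_ins)
        cons = annotate_consequence(cds, change)
        is_fs = cons.effect in (Effect.FRAMESHIFT_INSERTION,
                                Effect.FRAMESHIFT_DELETION)
        assert is_fs == (n_ins % 3 != 0)


def test_cds_length_must_be_multiple_of_three():
    with pytest.raises(ValueError):
        CodingSequence("BAD", "ACGTA")
    with pytest.warns(UserWarning, match="stop"):
        CodingSequence("NOSTOP", "ATGGCTGCA")


def test_apply_change_roundtrip_lengths():
    cds = _cds_with_codon(2, "GGG", n_codons=10)
    assert len(apply_change(cds.sequence, parse_hgvs_c("c.4_6delGGG"))) == 27
    assert len(apply_change(cds.sequence, parse_hgvs_c("c.4_5insTT"))) == 32
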