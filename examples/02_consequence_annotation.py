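"""Annotate protein-level consequences of HGVS coding changes.

Each example builds a minimal coding sequence whose relevant codon matches
the reference amino acid, applies the coding change, and prints the
resulting effect class and protein notation.  The last example shows a
frameshift, which bypasses substitution-specific score filters downstream.
"""

from varprio import CodingSequence, annotate_consequence, parse_hgvs_c


def cds_with_codon(codon_number: int, codon: str, gene: str) -> CodingSequence:
    codons = ["GCT"] * (codon_number + 10)
    codons[codon_number - 1] = codon
    codons[-1] = "TAA"
    return CodingSequence(gene, "".join(codons))


examples = [
    # (gene, coding change, codon number, reference codon)
    ("SORD", "c.416T>C", 139, "TTT"),               # Phe -> Ser
    ("KRT6A", "c.1048_1049delGCinsCG", 350, "GCA"),  # 2-nt delins, Ala -> Arg
    ("SVEP1", "c.1159G>T", 387, "GGT"),              # Gly -> Cys
    ("MRPL38", "c.430G>C", 144, "GGG"),              # Gly -> Arg
    ("ANY", "c.430_431insA", 144, "GGG"),            # frameshift insertion
]

for gene, hgvs_c, codon, ref_codon in examples:
    cds = cds_with_codon(codon, ref_codon, gene)
    cons = annotate_consequence(cds, parse_hgvs_c(hgvs_c))
    print(f"{gene:8s} {hgvs_c:24s} -> {cons.hgvs_p:14s} [{cons.effect.value}]")

print()
print("A missense call means exactly one amino acid changed; 'fs' marks a")
print("reading-frame shift from an insertion whose length is not a multiple of 3.")
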