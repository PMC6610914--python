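"""Compute the Grantham physicochemical distance matrix from first principles.

The matrix is derived from each amino acid's composition, polarity and
volume; after scaling the mean pairwise distance to 100 and rounding,
values span 5 (Leu-Ile, nearly interchangeable) to 215 (Trp-Cys, maximally
dissimilar).  The deleterious retention window used by the SNV/MNV filter
chains is [101, 215] — substitutions at least as radical as the average.
"""

from varprio import compute_grantham_matrix

gm = compute_grantham_matrix()

print(f"matrix maximum: {gm.max_distance}  (Trp-Cys)")
print(f"minimum off-diagonal: {gm.distance('Leu', 'Ile')}  (Leu-Ile)")
print()
print("substitutions behind the four worked candidate variants:")
for a, b in [("Phe", "Ser"), ("Ala", "Arg"), ("Gly", "Cys"), ("Gly", "Arg")]:
    d = gm.distance(a, b)
    status = "inside" if 101 <= d <= 215 else "outside"
    print(f"  {a} -> {b}: {d:3d}  ({status} the deleterious window [101, 215])")
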