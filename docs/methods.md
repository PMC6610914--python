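# Methods

## Problem setting and model

`varprio` addresses single-case exome prioritization: one affected subject
and a small panel of healthy controls (default 3) are exome-sequenced, and
the goal is to isolate variants that are (a) credible calls, (b) not
explained by population-level variation, (c) predicted to damage protein
function, (d) not already catalogued as somatic cancer variation, (e)
present only in the case, and (f) in genes expressed in the affected
tissue.  With so few controls the cohort cannot power an association test;
the design instead leans on external knowledge bases as a surrogate
control population, which is why the filter chains carry most of the
selection burden.

The pipeline is a deterministic composition of set operations — no fitted
parameters, no stochastic steps.  Given the input pool V and per-stage
predicates f₁…fₙ, the retained set is {v ∈ V : ∧ᵢ fᵢ(v)}; because each fᵢ
is a pure per-record predicate, the retained set is invariant under any
permutation of the stages, a property the test suite verifies on seeded
500-variant pools.  Stage order matters only for attribution (a removed
record is charged to the first stage that drops it), which is what makes
per-stage counts auditable.

## Variant typing and decomposition

Multi-allelic VCF sites are decomposed into one record per ALT allele
before anything else runs, because every downstream decision (annotation
windows, catalog membership, exclusivity) is allele-specific.  The
four-way routing is total on valid allele pairs: SNV (both alleles length
1), MNV (equal lengths > 1), INDEL (unequal lengths — including complex
substitutions, which keeps the partition exhaustive), CNV (symbolic
`<DEL>`/`<DUP>`).  Missing annotations are represented as absent, never 0:
a SIFT score of 0 is a maximally deleterious prediction, not a gap.

## Filter chains

Stage thresholds, with defaults and rationale:

| stage | rule | default | notes |
|---|---|---|---|
| confidence | caller p-value ∈ [0, 0.01] | fixed | first stage of every non-CNV chain |
| exac_saaf | exclude if catalogued AF > t | t = 0 | any observed population frequency disqualifies; configurable |
| sift | retain ∈ [0, 0.05] | fixed | closed interval |
| polyphen | retain ∈ [0.85, 1.0] | fixed | closed interval |
| grantham | retain ∈ [101, 215] | fixed | closed; 215 is the matrix maximum |
| cosmic / common_snp / dgv / exomes5000 | exclude on membership | — | catalog lookup or record flag |
| cnv_confidence | retain if ≥ c | c = 5.0 | no published cutoff; configurable |
| homopolymer | retain if run length ≤ h | h = 6 | typical ion-semiconductor artifact bound; configurable |

All numeric windows are closed at both ends, reading ranges like
"0.0–0.05" literally; the boundary tests pin this down (0.05 retained,
0.051 removed; 101 and 215 retained, 100 removed).

Records missing a score are dropped by the score stages by default — a
variant cannot be confirmed deleterious without a score — but
frameshift/nonsense records bypass the SIFT/PolyPhen/Grantham windows
entirely, since those scores are defined for amino-acid substitutions and
truncating changes are deleterious on independent grounds.  Both behaviors
are configurable per stage (`missing_policy`, `skip_truncating`).

The SNV chain has exactly seven stages; the dbSNP and UCSC-common-SNP
exclusions form a single stage matching against both catalogs.

## Grantham matrix

The matrix is recomputed at build time from the composition/polarity/
volume formula (α = 1.833, β = 0.1018, γ = 0.000399, mean scaled to 100,
rounded to nearest integer) rather than shipped as constants — the
computation is the testable content.  The exact recomputation reproduces
the canonical published integers on the filter-critical entries (maximum
215, minimum 5, and the worked substitutions Phe→Ser 155, Gly→Arg 125) but
differs by one unit on a few pairs (e.g. Met↔Leu 14 vs 15, Val↔Ile 30 vs
29): the historically printed table is internally inconsistent — no single
scaling constant reproduces all of its entries — so this package
standardizes on the exact formula output.  The frozen table under
`tests/data/` is that output, with its anchor entries hand-verified.

## Consequence annotation

HGVS `c.` parsing covers substitutions, deletions, insertions and delins
with plain CDS coordinates; intronic offsets and `g.`/`p.` namespaces are
rejected (the pipeline operates on coding changes only).  Effects are
computed by applying the change to the reference CDS, translating both
sequences with the standard genetic code, and diffing: exactly one changed
residue is missense (nonsense if the new residue is a stop, stop-loss if
the reference residue was the stop), no change is synonymous, a net length
change ≢ 0 (mod 3) is a frameshift (by sign), ≡ 0 an in-frame indel.
Protein notation uses three-letter codes (`p.Phe139Ser`); a delins whose
protein effect is a single substitution is reported missense-style;
frameshifts use the short `p.Xxx123fs` form without downstream-stop
scanning, which the candidate-reporting use case does not need.  A stated
deleted sequence that disagrees with the reference CDS raises a
reference-mismatch error — the standard symptom of annotating against the
wrong transcript.

## Exclusivity

The depth floor (default 100×) is enforced on the case's depth at the
variant; controls need only an explicit no-call.  The floor's placement is
genuinely ambiguous in this design space, so a strict mode additionally
requires every control to reach the floor, making a control no-call
evidence of absence rather than absence of data; neither mode is asserted
as the only correct reading.  Exclusivity is allele-exact: a control
carrying a *different* ALT allele at the same site does not disqualify the
case's allele.  Rejections are recorded per record
(`in_control` / `low_depth` / `control_depth_unassessable`), making the
exclusivity step as auditable as the filter chains.

## Synthetic cohorts

The generator emulates the targeted study conditions: 1 case + 3 controls,
10,000 annotated variant calls, 4 planted true exclusives, over a toy
genome of 10 genes (one contiguous forward-strand CDS of 2,499 sense
codons per chromosome, so VCF and FASTA coordinates agree and consequence
annotation runs end to end).  Per-sample depth is negative-binomial
(mean 180×, dispersion 8 — mid-range exome coverage with realistic
overdispersion); depths that must clear the 100× floor are redrawn until
they do (a truncated draw, so the floor holds with probability 1, not in
expectation).  Annotation values are drawn uniformly inside (or outside)
their windows and quantized to 4 decimals so the VCF round trip through
32-bit INFO floats is lossless.

Each distractor class violates exactly one stage by construction —
including Grantham consistency: every planted substitution is a real
codon change whose amino-acid pair distance comes from the computed
matrix, so annotations never contradict the sequence.  Class counts are
exact integer bookkeeping (fractions of the non-true budget, remainders to
the dbSNP class), not sampling expectations.  Knowledge bases are built
from the labels plus background entries placed away from the genes, and
DGV intervals for planted CNVs are single-base so they can never swallow a
neighboring variant.

What the generator does **not** emulate: linkage structure, realistic
allele-frequency spectra, multi-gene transcripts/splicing, sequencing
error profiles, or variants violating several filters at once.  Passing
the planted-truth recovery test therefore demonstrates that the machinery
composes correctly and attributes removals exactly — not that the filter
thresholds would achieve any particular precision on real exomes, where
annotations are noisy and the classes overlap.

## Numerical and format choices

- VCF coordinates are 1-based throughout; BED intervals 0-based half-open;
  site-catalog TSVs 1-based to match VCF.
- INFO floats survive htslib's 32-bit storage by quantizing reads to six
  significant digits (annotation precision is ≤ 4 decimals).
- All orderings are explicit (coordinate order for records and matrix
  rows, level-descending/symbol-ascending for gene panels), so identical
  inputs give byte-identical outputs.
- Expression is a 4-level ordinal scale (0 = not detected … 3 = high),
  matching how curated protein-expression resources bin their calls; genes
  count as expressed at level ≥ 1.
- The gene × subject score matrices resolve multiple variants per cell by
  keeping the most deleterious score (minimum SIFT, maximum
  PolyPhen/Grantham).

## Problem sizes used in the tests

The acceptance-style tests run the default 10,000-variant cohort once
(≈ 1 s), permutation tests on 500-variant pools (25 permutations), and the
exclusivity oracle on 100 random 500-variant cohorts; the whole suite
completes in a few seconds on one CPU.

## Known limitations

- Only simple HGVS coding notation is parsed; intronic, UTR and complex
  rearrangement notation is out of scope by design.
- CNVs are filtered (confidence, DGV, COSMIC) but receive no protein
  consequence; they carry no coding-change annotation.
- The per-subject-VCF merge keeps the first file's annotations on
  conflict; it assumes per-subject files were annotated consistently.
- Filter-stage attribution depends on stage order (the retained set does
  not); the preset order lists confidence first, population filters before
  functional ones, mirroring how the counts are most interpretable.
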