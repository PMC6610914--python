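# varprio

Knowledge-base filter chains for exome variant prioritization.

`varprio` implements a knowledge-driven workflow for narrowing a
whole-exome variant pool down to a small panel of candidate disease genes
for a single affected subject ("the case") sequenced alongside a small
group of healthy controls.  The workflow has three phases:

1. **Per-type filter chains.**  Annotated variant calls are routed by
   variant type (SNV, MNV, INDEL, CNV) into ordered chains of retain/exclude
   stages: caller confidence (p ≤ 0.01), population allele-frequency
   exclusion (ExAC South-Asian AF), functional-impact windows
   (SIFT ∈ [0, 0.05], PolyPhen ∈ [0.85, 1.0], Grantham ∈ [101, 215]),
   and membership exclusion against catalogs of known variation
   (dbSNP, UCSC common SNPs, DGV, 5000Exomes, COSMIC).  Each stage is a
   pure per-record predicate, so the retained set is invariant under stage
   reordering; the stage order only decides removal attribution.
2. **Case-exclusivity selection.**  A surviving variant is a candidate only
   if it is called in the case at ≥ 100× depth and called in no control —
   allele-exact matching on (chrom, pos, ref, alt).
3. **Consequence annotation and expression screening.**  Candidates get
   protein-level consequences from their HGVS coding changes
   (`c.416T>C` → `p.Phe139Ser`), and their genes are screened against an
   ordinal tissue-expression table; the top-k most-expressed genes form the
   final panel.

The Grantham distance at the core of the functional-impact window is
recomputed from Grantham's composition/polarity/volume formula,

    D(i, j) = ρ · [α (c_i − c_j)² + β (p_i − p_j)² + γ (v_i − v_j)²]^½

with α = 1.833, β = 0.1018, γ = 0.000399 and ρ scaling the mean pairwise
distance to 100; rounded to integers it spans 5 (Leu↔Ile) to 215 (Trp↔Cys).

Because real case cohorts are not redistributable, the package ships a
seeded synthetic-cohort generator (`varprio.simulate`) that plants
case-exclusive deleterious variants among distractor classes, each
engineered to be removed by exactly one named stage, together with matching
knowledge bases, coding sequences, and an expression table.  Every pipeline
stage is therefore testable end to end against known ground truth.

## Worked example

```sh
python examples/04_end_to_end_pipeline.py
```

generates a default cohort (1 case + 3 controls, 10,000 annotated variants,
4 planted true exclusives, seed 42), runs the full pipeline, and prints:

```
variants read:          10000
after filter chains:    2860
case-exclusive (>=100x): 4
liver-expressed genes:  GENE01 (level 3), GENE02 (level 3), GENE03 (level 3), GENE04 (level 3)
top candidate genes:    GENE01, GENE02, GENE03, GENE04

  gene           variant            cds_change   effect       hgvs_p   sift  polyphen  grantham  expression_level
GENE01   chr1:1003416T>A             c.3416T>A missense p.Val1139Asp 0.0109    0.9604       152                 3
...
precision = 1.00, recall = 1.00 against the planted truth
```

Reading the numbers: the filter chains discard the ~71 % of calls that are
low-confidence, population-typical, functionally tolerated, or already
catalogued; exclusivity against the controls removes the rest of the
distractors (shared calls and under-covered sites); the four survivors are
exactly the planted deleterious case-exclusive variants, each a missense
change with a Grantham distance inside the deleterious window and a
liver-high gene.

The other examples are single-capability walkthroughs: the Grantham matrix
(`01`), HGVS consequence annotation (`02`), and a traced filter-chain run
(`03`).  The same workflow is scriptable from a shell:

```sh
varprio simulate --out bundle --seed 42
varprio run --config bundle/config.yaml
varprio write-default-config --out config.yaml
```

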