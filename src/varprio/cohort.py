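"""Case-exclusive variant selection and tissue-expression screening.

A variant is case-exclusive when it is called in the designated case
subject at sufficient read depth (default 100x) and called in no control.
Matching across subjects is allele-exact on (chrom, pos, ref, alt): a
control carrying a *different* ALT allele at the same site does not
disqualify the case's allele.  Strict mode additionally requires every
control to reach the depth floor at the site, so that a no-call is
evidence of absence rather than absence of data.

Surviving genes are then screened against an ordinal tissue-expression
table (0 = not detected .. 3 = high) and the top-k most-expressed genes
form the candidate panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .knowledge import ExpressionTable
from .model import CohortCallSet, VariantRecord

logger = logging.getLogger(__name__)

#: Rejection reasons recorded by :func:`select_exclusive`.
REASON_NOT_IN_CASE = "not_in_case"
REASON_IN_CONTROL = "in_control"
REASON_LOW_DEPTH = "low_depth"
REASON_CONTROL_DEPTH = "control_depth_unassessable"


@dataclass
class ExclusiveVariantSet:
    """Case-exclusive variants with the depth floor they were selected at."""

    case_id: str
    records: list[VariantRecord]
    min_depth: int
    #: variant key -> reason, for every record that was rejected.
    rejections: dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if not rec.genotypes.get(self.case_id, False):
                raise ValueError(f"{rec.key}: not called in case {self.case_id}")
            if rec.subject_depths.get(self.case_id, 0) < self.min_depth:
                raise ValueError(f"{rec.key}: case depth below {self.min_depth}x")
            controls_called = [s for s in rec.called_subjects() if s != self.case_id]
            if controls_called:
                raise ValueError(f"{rec.key}: called in controls {controls_called}")


def select_exclusive(
    cohort: CohortCallSet,
    case_id: str | None = None,
    min_depth: int = 100,
    strict_controls: bool = False,
) -> ExclusiveVariantSet:
    """Select variants called exclusively in the case at >= ``min_depth``.

    Parameters
    ----------
    cohort : CohortCallSet
        Decomposed per-allele records with per-subject genotypes and depths.
    case_id : str, optional
        Defaults to the cohort's designated case; must be one of its subjects.
    min_depth : int
        Depth floor (x coverage) the case must reach at the variant.
    strict_controls : bool
        When set, every control must also reach ``min_depth`` at the site so
        its no-call is informative; otherwise controls need only lack a call.
    """
    case = case_id if case_id is not None else cohort.case_id
    if case not in cohort.subjects:
        raise ValueError(f"case_id {case!r} not among subjects {cohort.subjects}")
    controls = [s for s in cohort.subjects if s != case]
    kept: list[VariantRecord] = []
    rejections: dict[tuple, str] = {}
    for rec in cohort.records:
        if not rec.genotypes.get(case, False):
            rejections[rec.key] = REASON_NOT_IN_CASE
        elif any(rec.genotypes.get(c, False) for c in controls):
            rejections[rec.key] = REASON_IN_CONTROL
        elif rec.subject_depths.get(case, 0) < min_depth:
            rejections[rec.key] = REASON_LOW_DEPTH
        elif strict_controls and any(
                rec.subject_depths.get(c, 0) < min_depth for c in controls):
            rejections[rec.key] = REASON_CONTROL_DEPTH
        else:
            kept.append(rec)
    return ExclusiveVariantSet(case_id=case, records=kept,
                               min_depth=min_depth, rejections=rejections)


def screen_expression(
    genes: Iterable[str],
    table: ExpressionTable,
    tissue: str,
) -> list[tuple[str, int]]:
    """Keep genes expressed (level >= 1) in ``tissue``, with their levels.

    Genes absent from the table are dropped with a warning log; level-0
    (not detected) genes are dropped silently.  Output is sorted by level
    descending, then gene symbol ascending, and is therefore deterministic
    regardless of input order.
    """
    seen = sorted(set(genes))
    out: list[tuple[str, int]] = []
    for gene in seen:
        level = table.level(gene, tissue)
        if level is None:
            logger.warning("gene %s absent from expression table (tissue %s); dropped",
                           gene, tissue)
            continue
        if level >= 1:
            out.append((gene, level))
    out.sort(key=lambda gl: (-gl[1], gl[0]))
    return out


def top_k_expressed(expressed: Sequence[tuple[str, int]], k: int = 4) -> list[str]:
    """The k genes with the highest expression level.

    Ties break by gene symbol ascending; fewer than k genes returns all.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(expressed, key=lambda gl: (-gl[1], gl[0]))
    return [g for g, _ in ranked[:k]]


@dataclass
class PrioritizedGenePanel:
    """Expression-screened genes for one tissue plus the top-k panel."""

    tissue: str
    expressed_genes: list[tuple[str, int]]
    top_genes: list[str]

    def __post_init__(self) -> None:
        expressed = {g for g, _ in self.expressed_genes}
        if not set(self.top_genes) <= expressed:
            raise ValueError("top_genes must be a subset of expressed_genes")


def build_panel(
    genes: Iterable[str],
    table: ExpressionTable,
    tissue: str,
    k: int = 4,
) -> PrioritizedGenePanel:
    """Expression screen + top-k selection in one step."""
    expressed = screen_expression(genes, table, tissue)
    return PrioritizedGenePanel(
        tissue=tissue,
        expressed_genes=expressed,
        top_genes=top_k_expressed(expressed, k=k),
    )
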