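"""End-to-end prioritization pipeline with structured config and reporting.

Stage order: read cohort VCF -> route records by variant type -> per-type
filter chains -> case-exclusivity selection -> protein-consequence
annotation -> tissue-expression screen -> top-k gene panel.  Every count in
the report satisfies the partition invariant (input = retained + removed per
chain; every record lands in exactly one of {candidates, stage attributions,
exclusivity rejections}).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .cohort import PrioritizedGenePanel, build_panel, select_exclusive
from .consequence import (
    HgvsParseError,
    annotate_consequence,
    parse_hgvs_c,
    read_cds_fasta,
)
from .filters import FilterTrace, chain_from_config, preset_chains, run_chain
from .knowledge import (
    ExpressionTable,
    KnowledgeBase,
    load_expression_table,
    load_membership_kb,
)
from .model import CohortCallSet, VariantRecord, VariantType
from .vcf_io import read_cohort_vcf, write_variant_table

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineReport:
    """Everything one pipeline run produced, with per-stage accounting."""

    per_type_traces: dict[VariantType, FilterTrace]
    exclusive_count: int
    exclusivity_rejections: dict[tuple, str]
    expressed_genes: list[tuple[str, int]]
    top_genes: list[str]
    candidate_table: pd.DataFrame
    candidates: list[VariantRecord] = field(default_factory=list)
    panel: Optional[PrioritizedGenePanel] = None

    @property
    def input_count(self) -> int:
        return sum(t.input_count for t in self.per_type_traces.values())

    @property
    def filtered_count(self) -> int:
        return sum(t.retained_count for t in self.per_type_traces.values())

    def stage_counts(self) -> pd.DataFrame:
        rows = []
        for vt, trace in sorted(self.per_type_traces.items(),
                                key=lambda kv: kv[0].value):
            rows.append({"variant_type": vt.value, "stage": "(input)",
                         "count": trace.input_count})
            for stage, n in trace.per_stage_removed.items():
                rows.append({"variant_type": vt.value, "stage": stage,
                             "count": n})
            rows.append({"variant_type": vt.value, "stage": "(retained)",
                         "count": trace.retained_count})
        return pd.DataFrame(rows, columns=["variant_type", "stage", "count"])


DEFAULT_CONFIG: dict = {
    "inputs": {
        "vcf": "cohort.vcf",
        "case_id": "CASE",
        "cds_fasta": "cds.fasta",
        "expression": "expression.tsv",
        "knowledge_bases": {
            "dbsnp": "kb_dbsnp.tsv",
            "ucsc_common": "kb_ucsc_common.tsv",
            "dgv": "kb_dgv.bed",
            "exomes5000": "kb_exomes5000.tsv",
            "exac_saaf": "kb_exac_saaf.tsv",
            "cosmic": "kb_cosmic.tsv",
        },
    },
    "filters": {
        "saaf_threshold": 0.0,
        "cnv_confidence_min": 5.0,
        "homopolymer_max": 6,
    },
    "selection": {"min_depth": 100, "strict_controls": False},
    "expression": {"tissue": "liver", "min_level": 1, "top_k": 4},
    "output": {"dir": "results"},
}

_KNOWN_SECTIONS = {"inputs", "filters", "selection", "expression", "output",
                   "chains"}


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config; relative input paths are resolved
    against the config file's directory."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    base = path.parent
    inputs = config.get("inputs", {})
    for key in ("vcf", "cds_fasta", "expression"):
        if key in inputs and inputs[key]:
            inputs[key] = str((base / inputs[key]))
    if isinstance(inputs.get("vcfs"), list):
        inputs["vcfs"] = [str(base / p) for p in inputs["vcfs"]]
    for name, p in (inputs.get("knowledge_bases") or {}).items():
        inputs["knowledge_bases"][name] = str(base / p)
    out = config.get("output", {})
    if "dir" in out:
        out["dir"] = str(base / out["dir"])
    return config


def _validate_config(config: Mapping) -> None:
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    inputs = config.get("inputs")
    if not inputs:
        raise ConfigError("config must have an 'inputs' section")
    if not inputs.get("case_id"):
        raise ConfigError("inputs.case_id is required")
    if not inputs.get("vcf") and not inputs.get("vcfs"):
        raise ConfigError("inputs.vcf (or inputs.vcfs) is required")


def _load_kbs(paths: Mapping[str, str]) -> dict[str, KnowledgeBase]:
    kbs = {}
    for name, p in paths.items():
        if not Path(p).exists():
            raise ConfigError(f"knowledge base {name!r}: file not found: {p}")
        kbs[name] = load_membership_kb(p, name)
    return kbs


def run_filters(
    records: Iterable[VariantRecord],
    kbs: Mapping[str, KnowledgeBase],
    chains=None,
    **preset_kwargs,
) -> tuple[list[VariantRecord], dict[VariantType, FilterTrace]]:
    """Route records by variant type and run each type's chain."""
    chains = chains or preset_chains(**preset_kwargs)
    by_type: dict[VariantType, list[VariantRecord]] = {vt: [] for vt in VariantType}
    for rec in records:
        by_type[rec.variant_type].append(rec)
    retained: list[VariantRecord] = []
    traces: dict[VariantType, FilterTrace] = {}
    for vt in VariantType:
        kept, trace = run_chain(by_type[vt], chains[vt], kbs)
        retained.extend(kept)
        traces[vt] = trace
    return retained, traces


def annotate_candidates(records: Iterable[VariantRecord],
                        cds_by_gene: Mapping[str, object]) -> None:
    """Fill each record's ``effect`` from its HGVS coding change, in place.

    Records without a gene/CDS match or with unparseable notation keep
    ``effect=None`` (CNVs, for instance, carry no coding change)."""
    for rec in records:
        if not rec.cds_change or rec.gene not in cds_by_gene:
            continue
        try:
            change = parse_hgvs_c(rec.cds_change)
            cons = annotate_consequence(cds_by_gene[rec.gene], change)
        except (HgvsParseError, ValueError) as exc:
            logger.warning("cannot annotate %s %s: %s", rec.gene,
                           rec.cds_change, exc)
            continue
        rec.effect = cons.effect.value
        rec.hgvs_p = cons.hgvs_p  # dynamic attribute; consumed by the report


def run_pipeline(config: Mapping | str | Path,
                 cohort: CohortCallSet | None = None) -> PipelineReport:
    """Execute the full prioritization pipeline from a config mapping or
    YAML path.  An in-memory ``cohort`` may replace ``inputs.vcf``.

    Writes ``candidates.tsv``, ``stage_counts.tsv``, ``variants.tsv`` and
    ``report.json`` into ``output.dir`` when that section is configured.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    _validate_config(config)
    inputs = config["inputs"]
    fcfg = {**DEFAULT_CONFIG["filters"], **(config.get("filters") or {})}
    scfg = {**DEFAULT_CONFIG["selection"], **(config.get("selection") or {})}
    ecfg = {**DEFAULT_CONFIG["expression"], **(config.get("expression") or {})}

    if cohort is None:
        paths = inputs.get("vcfs") or inputs["vcf"]
        cohort = read_cohort_vcf(paths, case_id=inputs["case_id"])
    elif inputs["case_id"] != cohort.case_id:
        raise ConfigError(
            f"config case_id {inputs['case_id']!r} does not match cohort "
            f"case {cohort.case_id!r}")
    if len(cohort.subjects) < 2:
        raise ConfigError("cohort has no controls")

    kbs = _load_kbs(inputs.get("knowledge_bases") or {})
    chains = None
    if config.get("chains"):
        chains = {VariantType(vt): chain_from_config(vt, stages)
                  for vt, stages in config["chains"].items()}
        for vt in VariantType:  # unconfigured types fall back to presets
            chains.setdefault(vt, preset_chains(
                saaf_threshold=fcfg["saaf_threshold"],
                cnv_confidence_min=fcfg["cnv_confidence_min"],
                homopolymer_max=fcfg["homopolymer_max"])[vt])

    retained, traces = run_filters(
        cohort.records, kbs, chains=chains,
        saaf_threshold=fcfg["saaf_threshold"],
        cnv_confidence_min=fcfg["cnv_confidence_min"],
        homopolymer_max=fcfg["homopolymer_max"])
    logger.info("filter chains retained %d of %d records",
                len(retained), len(cohort.records))

    filtered_cohort = CohortCallSet(
        subjects=list(cohort.subjects), case_id=cohort.case_id,
        records=retained)
    exclusive = select_exclusive(
        filtered_cohort, min_depth=int(scfg["min_depth"]),
        strict_controls=bool(scfg["strict_controls"]))
    logger.info("exclusivity retained %d of %d records",
                len(exclusive.records), len(retained))

    cds_by_gene = {}
    if inputs.get("cds_fasta"):
        cds_by_gene = read_cds_fasta(inputs["cds_fasta"])
    annotate_candidates(exclusive.records, cds_by_gene)

    expression: Optional[ExpressionTable] = None
    panel = None
    expressed: list[tuple[str, int]] = []
    top_genes: list[str] = []
    if inputs.get("expression"):
        expression = load_expression_table(inputs["expression"])
        genes = [r.gene for r in exclusive.records if r.gene]
        panel = build_panel(genes, expression, tissue=ecfg["tissue"],
                            k=int(ecfg["top_k"]))
        expressed = [(g, lvl) for g, lvl in panel.expressed_genes
                     if lvl >= int(ecfg["min_level"])]
        top_genes = panel.top_genes

    level_of = dict(expressed)
    rows = []
    for rec in sorted(exclusive.records, key=lambda r: (r.chrom, r.pos)):
        rows.append({
            "gene": rec.gene or ".",
            "variant": f"{rec.chrom}:{rec.pos}{rec.ref_allele}>{rec.alt_allele}",
            "cds_change": rec.cds_change or ".",
            "effect": rec.effect or ".",
            "hgvs_p": getattr(rec, "hgvs_p", None) or ".",
            "sift": rec.annotations.sift,
            "polyphen": rec.annotations.polyphen,
            "grantham": rec.annotations.grantham,
            "expression_level": level_of.get(rec.gene),
        })
    candidate_table = pd.DataFrame(rows, columns=[
        "gene", "variant", "cds_change", "effect", "hgvs_p", "sift",
        "polyphen", "grantham", "expression_level"])

    report = PipelineReport(
        per_type_traces=traces,
        exclusive_count=len(exclusive.records),
        exclusivity_rejections=exclusive.rejections,
        expressed_genes=expressed,
        top_genes=top_genes,
        candidate_table=candidate_table,
        candidates=exclusive.records,
        panel=panel,
    )

    out = config.get("output") or {}
    if out.get("dir"):
        _write_outputs(report, cohort, Path(out["dir"]))
    return report


def _write_outputs(report: PipelineReport, cohort: CohortCallSet,
                   outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.candidate_table.to_csv(outdir / "candidates.tsv", sep="\t",
                                  index=False, na_rep=".")
    report.stage_counts().to_csv(outdir / "stage_counts.tsv", sep="\t",
                                 index=False)
    write_variant_table(report.candidates, outdir / "variants.tsv")
    summary = {
        "input_count": report.input_count,
        "after_filters": report.filtered_count,
        "exclusive_count": report.exclusive_count,
        "expressed_genes": [[g, lvl] for g, lvl in report.expressed_genes],
        "top_genes": report.top_genes,
        "per_type": {
            vt.value: {
                "input": t.input_count,
                "removed": t.per_stage_removed,
                "retained": t.retained_count,
            } for vt, t in report.per_type_traces.items()},
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2) + "\n")


MATRIX_SCORE_FIELDS = ("sift", "polyphen", "grantham")
#: For multiple variants of a gene in one subject, keep the most deleterious
#: score: minimum for SIFT (0 = damaging), maximum for PolyPhen/Grantham.
_WORST = {"sift": min, "polyphen": max, "grantham": max}


def export_subject_gene_matrix(
    records: Iterable[VariantRecord],
    score_field: str,
    destination: str | Path | None = None,
) -> pd.DataFrame:
    """Gene x subject matrix of one score, in coordinate order.

    Rows are genes ordered by their first variant's (chrom, pos); columns
    are subjects; a cell holds the subject's most deleterious score for the
    gene among variants called in that subject, or NaN when absent.  Written
    as TSV with "." for absent cells when ``destination`` is given.
    """
    if score_field not in MATRIX_SCORE_FIELDS:
        raise ValueError(
            f"score_field must be one of {MATRIX_SCORE_FIELDS}, "
            f"got {score_field!r}")
    worst = _WORST[score_field]
    cells: dict[tuple[str, str], float] = {}
    gene_order: dict[str, tuple] = {}
    subjects: list[str] = []
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
        gene = rec.gene or f"{rec.chrom}:{rec.pos}"
        gene_order.setdefault(gene, (rec.chrom, rec.pos))
        value = getattr(rec.annotations, score_field)
        for s in rec.genotypes:
            if s not in subjects:
                subjects.append(s)
        if value is None:
            continue
        for s in rec.called_subjects():
            key = (gene, s)
            cells[key] = worst(cells[key], value) if key in cells else value
    genes = sorted(gene_order, key=gene_order.get)
    df = pd.DataFrame(index=genes, columns=sorted(subjects), dtype=float)
    for (gene, s), v in cells.items():
        df.loc[gene, s] = v
    df.index.name = "gene"
    if destination is not None:
        df.to_csv(destination, sep="\t", na_rep=".")
    return df
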