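"""Composable, traceable filter chains routed by variant type.

Each chain is an ordered list of pure per-record stages, so the retained set
is invariant under stage reordering; the order only affects which stage a
removed record is attributed to.  Four presets mirror the per-type analysis
chains used for knowledge-driven prioritization:

* SNV (7 stages): caller confidence, ExAC-SAAF population frequency, SIFT
  window [0, 0.05], PolyPhen window [0.85, 1.0], Grantham window [101, 215],
  COSMIC exclusion, dbSNP + UCSC common SNPs exclusion.
* MNV: confidence, ExAC-SAAF, SIFT, PolyPhen, Grantham, COSMIC, DGV,
  5000Exomes.
* CNV: CNV-confidence floor, DGV, COSMIC.
* INDEL: confidence, ExAC-SAAF, homopolymer-length cap, COSMIC, DGV.

All numeric windows are closed intervals.  SIFT/PolyPhen/Grantham windows are
substitution-specific, so frameshift and nonsense changes bypass them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .knowledge import KnowledgeBase, kb_contains, kb_frequency
from .model import VariantRecord, VariantType


class FilterMode(str, Enum):
    RETAIN_IN_RANGE = "retain_in_range"
    EXCLUDE_ON_MATCH = "exclude_on_match"
    RETAIN_ON_CONDITION = "retain_on_condition"


class MissingPolicy(str, Enum):
    DROP = "drop"
    KEEP = "keep"


#: Record-level membership flag backing each knowledge base.
_FLAG_FIELDS = {
    "dbsnp": "in_dbsnp",
    "ucsc_common": "in_ucsc_common",
    "dgv": "in_dgv",
    "exomes5000": "in_5000exomes",
    "cosmic": "in_cosmic",
}


class FilterConfigError(ValueError):
    """Invalid filter specification or missing knowledge base."""


@dataclass(frozen=True)
class FilterSpec:
    """One retain/exclude stage.

    ``retain_in_range`` keeps records whose ``field`` lies in the closed
    interval [low, high]; ``retain_on_condition`` is the one-sided variant
    (only one bound set).  ``exclude_on_match`` drops records found in any
    of ``kb_names`` (by catalog lookup, record flag, or — for frequency
    stores — catalogued/annotated frequency above ``freq_threshold``).
    ``missing_policy`` decides the fate of records lacking the field;
    ``skip_truncating`` exempts frameshift/nonsense records from
    substitution-specific score windows.
    """

    name: str
    mode: FilterMode
    field: Optional[str] = None
    low: Optional[float] = None
    high: Optional[float] = None
    kb_names: tuple[str, ...] = ()
    missing_policy: MissingPolicy = MissingPolicy.DROP
    skip_truncating: bool = False
    freq_threshold: float = 0.0

    def __post_init__(self) -> None:
        mode = FilterMode(self.mode)
        object.__setattr__(self, "mode", mode)
        object.__setattr__(self, "missing_policy", MissingPolicy(self.missing_policy))
        object.__setattr__(self, "kb_names", tuple(self.kb_names))
        if mode is FilterMode.RETAIN_IN_RANGE:
            if self.field is None or self.low is None or self.high is None:
                raise FilterConfigError(f"{self.name}: range stage needs field/low/high")
            if self.low > self.high:
                raise FilterConfigError(f"{self.name}: low {self.low} > high {self.high}")
        elif mode is FilterMode.RETAIN_ON_CONDITION:
            if self.field is None or (self.low is None and self.high is None):
                raise FilterConfigError(f"{self.name}: condition stage needs field and a bound")
        elif mode is FilterMode.EXCLUDE_ON_MATCH:
            if not self.kb_names:
                raise FilterConfigError(f"{self.name}: match stage needs kb_names")

    def _value(self, record: VariantRecord):
        if self.field == "caller_p":
            return record.caller_p
        return getattr(record.annotations, self.field)

    def retains(self, record: VariantRecord,
                kbs: Mapping[str, KnowledgeBase]) -> bool:
        """Pure per-record predicate: True if the record survives this stage."""
        if self.mode is FilterMode.EXCLUDE_ON_MATCH:
            return not self._matches(record, kbs)
        if self.skip_truncating and record.is_truncating():
            return True
        value = self._value(record)
        if value is None:
            return self.missing_policy is MissingPolicy.KEEP
        if self.low is not None and value < self.low:
            return False
        if self.high is not None and value > self.high:
            return False
        return True

    def _matches(self, record: VariantRecord,
                 kbs: Mapping[str, KnowledgeBase]) -> bool:
        for name in self.kb_names:
            kb = kbs.get(name)
            if name == "exac_saaf":
                af = record.annotations.exac_saaf
                if af is not None and af > self.freq_threshold:
                    return True
                if kb is not None:
                    caf = kb_frequency(kb, record)
                    if caf is not None and caf > self.freq_threshold:
                        return True
                continue
            flag_field = _FLAG_FIELDS.get(name)
            if flag_field and getattr(record.annotations, flag_field):
                return True
            if kb is not None:
                if name in ("exomes5000",):
                    caf = kb_frequency(kb, record)
                    if caf is not None and caf > self.freq_threshold:
                        return True
                if kb_contains(kb, record):
                    return True
            elif flag_field is None:
                raise FilterConfigError(
                    f"{self.name}: knowledge base {name!r} not loaded")
        return False


@dataclass(frozen=True)
class FilterChain:
    """Ordered, named stages for one variant type."""

    variant_type: VariantType
    stages: tuple[FilterSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "variant_type", VariantType(self.variant_type))
        if not self.stages:
            raise FilterConfigError("chain must have at least one stage")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise FilterConfigError(f"duplicate stage names in chain: {names}")


@dataclass
class FilterTrace:
    """Accounting of one chain run: every input record is either retained or
    attributed to exactly the first stage that removed it."""

    input_count: int
    per_stage_removed: dict[str, int]
    retained_count: int
    removal_attribution: dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_count != self.retained_count + sum(self.per_stage_removed.values()):
            raise ValueError(
                f"partition violated: {self.input_count} != {self.retained_count} "
                f"+ sum({self.per_stage_removed})")


# Default one-sided thresholds; both are configurable because no cutoffs are
# published for them.
DEFAULT_CNV_CONFIDENCE_MIN = 5.0
DEFAULT_HOMOPOLYMER_MAX = 6


def preset_chain(
    variant_type: VariantType | str,
    *,
    saaf_threshold: float = 0.0,
    cnv_confidence_min: float = DEFAULT_CNV_CONFIDENCE_MIN,
    homopolymer_max: int = DEFAULT_HOMOPOLYMER_MAX,
    skip_truncating: bool = True,
    score_missing_policy: MissingPolicy = MissingPolicy.DROP,
) -> FilterChain:
    """Build the preset chain for a variant type.

    The ExAC-SAAF stage excludes any variant with a catalogued South-Asian
    allele frequency above ``saaf_threshold`` (default: any observed
    frequency).  Score windows drop records missing the score by default
    (a variant cannot be confirmed deleterious without one), except
    frameshift/nonsense records when ``skip_truncating`` is set.
    """
    vt = VariantType(variant_type)
    confidence = FilterSpec("confidence", FilterMode.RETAIN_IN_RANGE,
                            field="caller_p", low=0.0, high=0.01)
    saaf = FilterSpec("exac_saaf", FilterMode.EXCLUDE_ON_MATCH,
                      kb_names=("exac_saaf",), freq_threshold=saaf_threshold)
    sift = FilterSpec("sift", FilterMode.RETAIN_IN_RANGE, field="sift",
                      low=0.0, high=0.05, skip_truncating=skip_truncating,
                      missing_policy=score_missing_policy)
    polyphen = FilterSpec("polyphen", FilterMode.RETAIN_IN_RANGE, field="polyphen",
                          low=0.85, high=1.0, skip_truncating=skip_truncating,
                          missing_policy=score_missing_policy)
    grantham = FilterSpec("grantham", FilterMode.RETAIN_IN_RANGE, field="grantham",
                          low=101, high=215, skip_truncating=skip_truncating,
                          missing_policy=score_missing_policy)
    cosmic = FilterSpec("cosmic", FilterMode.EXCLUDE_ON_MATCH, kb_names=("cosmic",))
    dgv = FilterSpec("dgv", FilterMode.EXCLUDE_ON_MATCH, kb_names=("dgv",))

    if vt is VariantType.SNV:
        common_snp = FilterSpec("common_snp", FilterMode.EXCLUDE_ON_MATCH,
                                kb_names=("dbsnp", "ucsc_common"))
        stages = (confidence, saaf, sift, polyphen, grantham, cosmic, common_snp)
    elif vt is VariantType.MNV:
        exomes5000 = FilterSpec("exomes5000", FilterMode.EXCLUDE_ON_MATCH,
                                kb_names=("exomes5000",))
        stages = (confidence, saaf, sift, polyphen, grantham, cosmic, dgv,
                  exomes5000)
    elif vt is VariantType.CNV:
        cnv_conf = FilterSpec("cnv_confidence", FilterMode.RETAIN_ON_CONDITION,
                              field="cnv_confidence", low=cnv_confidence_min)
        stages = (cnv_conf, dgv, cosmic)
    else:  # INDEL
        homopolymer = FilterSpec("homopolymer", FilterMode.RETAIN_ON_CONDITION,
                                 field="homopolymer_len", high=homopolymer_max,
                                 missing_policy=MissingPolicy.KEEP)
        stages = (confidence, saaf, homopolymer, cosmic, dgv)
    return FilterChain(variant_type=vt, stages=stages)


def preset_chains(**kwargs) -> dict[VariantType, FilterChain]:
    """All four preset chains keyed by variant type."""
    return {vt: preset_chain(vt, **kwargs) for vt in VariantType}


def apply_filter(
    records: Iterable[VariantRecord],
    spec: FilterSpec,
    kbs: Mapping[str, KnowledgeBase] | None = None,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split records into (retained, removed) under one stage."""
    kbs = kbs or {}
    retained, removed = [], []
    for rec in records:
        (retained if spec.retains(rec, kbs) else removed).append(rec)
    return retained, removed


def run_chain(
    records: Sequence[VariantRecord],
    chain: FilterChain,
    kbs: Mapping[str, KnowledgeBase] | None = None,
) -> tuple[list[VariantRecord], FilterTrace]:
    """Apply a chain's stages in order with per-stage attribution.

    Every removed record is charged to the first stage that drops it; the
    partition invariant input = retained + sum(removed) is enforced by
    :class:`FilterTrace`.
    """
    kbs = kbs or {}
    current = list(records)
    per_stage: dict[str, int] = {}
    attribution: dict[tuple, str] = {}
    for spec in chain.stages:
        current, dropped = apply_filter(current, spec, kbs)
        per_stage[spec.name] = len(dropped)
        for rec in dropped:
            attribution[rec.key] = spec.name
    trace = FilterTrace(
        input_count=len(records),
        per_stage_removed=per_stage,
        retained_count=len(current),
        removal_attribution=attribution,
    )
    return current, trace


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

def chain_to_config(chain: FilterChain) -> list[dict]:
    """Serialize a chain's stages to plain dicts (for YAML config)."""
    out = []
    for s in chain.stages:
        d: dict = {"name": s.name, "mode": s.mode.value}
        if s.field is not None:
            d["field"] = s.field
        if s.low is not None:
            d["low"] = s.low
        if s.high is not None:
            d["high"] = s.high
        if s.kb_names:
            d["kb"] = list(s.kb_names)
        if s.missing_policy is not MissingPolicy.DROP:
            d["missing_policy"] = s.missing_policy.value
        if s.skip_truncating:
            d["skip_truncating"] = True
        if s.freq_threshold:
            d["freq_threshold"] = s.freq_threshold
        out.append(d)
    return out


def chain_from_config(variant_type: VariantType | str,
                      stages: list[dict]) -> FilterChain:
    """Build a chain from config dicts as emitted by :func:`chain_to_config`."""
    specs = []
    for d in stages:
        d = dict(d)
        kb = d.pop("kb", [])
        if isinstance(kb, str):
            kb = [kb]
        specs.append(FilterSpec(
            name=d.pop("name"),
            mode=FilterMode(d.pop("mode")),
            field=d.pop("field", None),
            low=d.pop("low", None),
            high=d.pop("high", None),
            kb_names=tuple(kb),
            missing_policy=MissingPolicy(d.pop("missing_policy", "drop")),
            skip_truncating=bool(d.pop("skip_truncating", False)),
            freq_threshold=float(d.pop("freq_threshold", 0.0)),
        ))
        if d:
            raise FilterConfigError(f"unknown filter config keys: {sorted(d)}")
    return FilterChain(variant_type=VariantType(variant_type), stages=tuple(specs))
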