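"""Filter chains: presets, boundaries, attribution, and order invariance."""

import itertools

import numpy as np
import pytest

from varprio import (
    FilterSpec,
    KnowledgeBase,
    VariantAnnotations,
    VariantRecord,
    VariantType,
    apply_filter,
    preset_chain,
    run_chain,
)
from varprio.filters import (
    FilterChain,
    FilterConfigError,
    FilterMode,
    MissingPolicy,
    chain_from_config,
    chain_to_config,
)


def _snv(pos=100, caller_p=0.001, sift=0.01, polyphen=0.95, grantham=150,
         **ann_kw):
    return VariantRecord(
        chrom="chr1", pos=pos, ref_allele="A", alt_allele="G",
        subject_depths={"CASE": 150}, genotypes={"CASE": True},
        caller_p=caller_p, variant_type=VariantType.SNV,
        annotations=VariantAnnotations(sift=sift, polyphen=polyphen,
                                       grantham=grantham, **ann_kw))


EMPTY_KBS = {n: KnowledgeBase(name=n)
             for n in ("dbsnp", "ucsc_common", "dgv", "exomes5000",
                       "exac_saaf", "cosmic")}


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def test_snv_preset_has_exactly_seven_stages():
    chain = preset_chain(VariantType.SNV)
    assert len(chain.stages) == 7
    names = [s.name for s in chain.stages]
    assert names == ["confidence", "exac_saaf", "sift", "polyphen",
                     "grantham", "cosmic", "common_snp"]


def test_cnv_preset_stages():
    names = [s.name for s in preset_chain(VariantType.CNV).stages]
    assert names == ["cnv_confidence", "dgv", "cosmic"]


def test_indel_preset_contains_homopolymer_stage():
    names = [s.name for s in preset_chain(VariantType.INDEL).stages]
    assert "homopolymer" in names and "dgv" in names


def test_mnv_preset_contains_dgv_and_exomes5000():
    names = [s.name for s in preset_chain(VariantType.MNV).stages]
    assert "dgv" in names and "exomes5000" in names


def test_unknown_variant_type_rejected():
    with pytest.raises(ValueError):
        preset_chain("SV")


# ---------------------------------------------------------------------------
# boundary behavior: closed intervals as printed
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("field, stage, value, kept", [
    ("sift", "sift", 0.05, True), ("sift", "sift", 0.051, False),
    ("sift", "sift", 0.0, True), ("sift", "sift", 0.2, False),
    ("polyphen", "polyphen", 0.85, True), ("polyphen", "polyphen", 0.849, False),
    ("polyphen", "polyphen", 1.0, True),
    ("grantham", "grantham", 101, True), ("grantham", "grantham", 100, False),
    ("grantham", "grantham", 215, True),
])
def test_score_window_boundaries_inclusive(field, stage, value, kept):
    spec = next(s for s in preset_chain(VariantType.SNV).stages
                if s.name == stage)
    rec = _snv(**{field: value})
    retained, removed = apply_filter([rec], spec, EMPTY_KBS)
    assert (len(retained) == 1) is kept


def test_grantham_216_is_unrepresentable_but_high_bound_is_215():
    # the annotation model itself caps Grantham at the matrix maximum
    with pytest.raises(ValueError):
        VariantAnnotations(grantham=216)


def test_confidence_window():
    spec = preset_chain(VariantType.SNV).stages[0]
    keep, drop = apply_filter([_snv(caller_p=0.01), _snv(caller_p=0.011)],
                              spec, EMPTY_KBS)
    assert len(keep) == 1 and keep[0].caller_p == 0.01


def test_cosmic_flag_exclusion():
    spec = next(s for s in preset_chain(VariantType.SNV).stages
                if s.name == "cosmic")
    rec = _snv(in_cosmic=True)
    retained, removed = apply_filter([rec], spec, EMPTY_KBS)
    assert retained == [] and removed == [rec]


def test_exac_saaf_excludes_any_observed_frequency_by_default():
    spec = next(s for s in preset_chain(VariantType.SNV).stages
                if s.name == "exac_saaf")
    keep, drop = apply_filter(
        [_snv(exac_saaf=0.0001), _snv(pos=101)], spec, EMPTY_KBS)
    assert len(drop) == 1 and drop[0].annotations.exac_saaf == 0.0001


def test_exac_saaf_threshold_configurable():
    chain = preset_chain(VariantType.SNV, saaf_threshold=0.01)
    spec = next(s for s in chain.stages if s.name == "exac_saaf")
    keep, drop = apply_filter([_snv(exac_saaf=0.005)], spec, EMPTY_KBS)
    assert len(keep) == 1


def test_missing_score_dropped_by_default_but_keep_configurable():
    spec = next(s for s in preset_chain(VariantType.SNV).stages
                if s.name == "sift")
    keep, drop = apply_filter([_snv(sift=None)], spec, EMPTY_KBS)
    assert keep == []
    lenient = preset_chain(VariantType.SNV,
                           score_missing_policy=MissingPolicy.KEEP)
    spec2 = next(s for s in lenient.stages if s.name == "sift")
    keep2, _ = apply_filter([_snv(sift=None)], spec2, EMPTY_KBS)
    assert len(keep2) == 1


def test_truncating_records_bypass_score_windows():
    fs = VariantRecord(
        chrom="chr1", pos=5, ref_allele="A", alt_allele="AG",
        subject_depths={"CASE": 150}, genotypes={"CASE": True},
        caller_p=0.001, variant_type=VariantType.INDEL,
        annotations=VariantAnnotations())  # no scores at all
    spec = next(s for s in preset_chain(VariantType.SNV).stages
                if s.name == "sift")
    keep, _ = apply_filter([fs], spec, EMPTY_KBS)
    assert keep == [fs]


def test_match_stage_without_kb_uses_record_flag():
    spec = FilterSpec("dbsnp_only", FilterMode.EXCLUDE_ON_MATCH,
                      kb_names=("dbsnp",))
    keep, drop = apply_filter([_snv(in_dbsnp=True), _snv(pos=101)], spec, {})
    assert len(drop) == 1


def test_spec_validation():
    with pytest.raises(FilterConfigError):
        FilterSpec("bad", FilterMode.RETAIN_IN_RANGE, field="sift",
                   low=0.5, high=0.1)
    with pytest.raises(FilterConfigError):
        FilterSpec("bad", FilterMode.EXCLUDE_ON_MATCH)
    with pytest.raises(FilterConfigError):
        FilterChain(VariantType.SNV, ())


# ---------------------------------------------------------------------------
# run_chain: attribution, partition, idempotence, monotonicity
# ---------------------------------------------------------------------------

def _six_record_fixture():
    """One record passing all stages; one failing each named stage."""
    return {
        "pass": _snv(pos=1),
        "confidence": _snv(pos=2, caller_p=0.5),
        "exac_saaf": _snv(pos=3, exac_saaf=0.1),
        "sift": _snv(pos=4, sift=0.9),
        "cosmic": _snv(pos=5, in_cosmic=True),
        "common_snp": _snv(pos=6, in_dbsnp=True),
    }


def test_run_chain_attribution_matches_design():
    fixture = _six_record_fixture()
    chain = preset_chain(VariantType.SNV)
    retained, trace = run_chain(list(fixture.values()), chain, EMPTY_KBS)
    assert retained == [fixture["pass"]]
    for stage, rec in fixture.items():
        if stage == "pass":
            continue
        assert trace.removal_attribution[rec.key] == stage
    assert trace.input_count == 6
    assert trace.retained_count == 1


def test_empty_input_gives_zero_counts():
    retained, trace = run_chain([], preset_chain(VariantType.SNV), EMPTY_KBS)
    assert retained == []
    assert trace.input_count == trace.retained_count == 0
    assert all(v == 0 for v in trace.per_stage_removed.values())


def test_chain_idempotent():
    records = list(_six_record_fixture().values())
    chain = preset_chain(VariantType.SNV)
    once, _ = run_chain(records, chain, EMPTY_KBS)
    twice, trace2 = run_chain(once, chain, EMPTY_KBS)
    assert twice == once
    assert sum(trace2.per_stage_removed.values()) == 0


def test_partition_invariant_enforced_on_every_run():
    rng = np.random.default_rng(0)
    records = [_snv(pos=int(p), sift=round(float(rng.uniform(0, 0.2)), 3))
               for p in range(1, 101)]
    retained, trace = run_chain(records, preset_chain(VariantType.SNV),
                                EMPTY_KBS)
    assert trace.input_count == trace.retained_count + sum(
        trace.per_stage_removed.values())
    assert len(trace.removal_attribution) == sum(
        trace.per_stage_removed.values())


def test_monotonicity_retained_shrinks_stage_by_stage():
    records = list(_six_record_fixture().values())
    chain = preset_chain(VariantType.SNV)
    current = records
    for spec in chain.stages:
        after, _ = apply_filter(current, spec, EMPTY_KBS)
        assert set(r.key for r in after) <= set(r.key for r in current)
        current = after


def _random_pool(n=500, seed=5):
    """A pool with realistic mixtures of passing/failing annotations."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(_snv(
            pos=i + 1,
            caller_p=round(float(rng.uniform(0, 0.02)), 4),
            sift=round(float(rng.uniform(0, 0.1)), 4),
            polyphen=round(float(rng.uniform(0.7, 1.0)), 4),
            grantham=int(rng.integers(5, 216)),
            exac_saaf=(round(float(rng.uniform(0, 0.2)), 4)
                       if rng.random() < 0.3 else None),
            in_cosmic=bool(rng.random() < 0.2),
            in_dbsnp=bool(rng.random() < 0.2),
        ))
    return out


def test_order_invariance_of_retained_set():
    """Permuting the 7 SNV stages never changes the final retained set —
    each stage is a pure per-record predicate."""
    pool = _random_pool()
    chain = preset_chain(VariantType.SNV)
    baseline, _ = run_chain(pool, chain, EMPTY_KBS)
    baseline_keys = {r.key for r in baseline}
    assert 0 < len(baseline_keys) < len(pool)
    rng = np.random.default_rng(17)
    for _ in range(20):
        perm = list(rng.permutation(len(chain.stages)))
        permuted = FilterChain(VariantType.SNV,
                               tuple(chain.stages[i] for i in perm))
        retained, _ = run_chain(pool, permuted, EMPTY_KBS)
        assert {r.key for r in retained} == baseline_keys


def test_chain_config_roundtrip():
    chain = preset_chain(VariantType.MNV)
    rebuilt = chain_from_config(VariantType.MNV, chain_to_config(chain))
    assert rebuilt == chain
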