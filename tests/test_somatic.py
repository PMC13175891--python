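"""Consensus logic, the eight-rule cascade, contamination screening and
unique-variant collapsing."""

import numpy as np
import pytest

from mipmosaic.somatic import (
    CohortContext,
    DEFAULT_PROFILES,
    SomaticCandidate,
    collapse_unique,
    consensus_double_call,
    detect_contamination,
    filter_somatic,
    standin_callers,
)
from mipmosaic.types import SampleMeta, Variant

from conftest import make_evidence

SNV = Variant("chr1", 100, "A", "T")
INDEL = Variant("chr1", 100, "A", "AT")


def _evmap_for(variant, **kwargs):
    ev = make_evidence(
        contig=variant.contig, pos=variant.pos, ref=variant.ref, alt=variant.alt, **kwargs
    )
    return {(variant.contig, variant.pos): ev}


# --- consensus ---------------------------------------------------------------

SNV_CASES = [
    ({"R"}, False),
    ({"M"}, False),
    ({"P"}, False),
    ({"R", "M"}, True),
    ({"R", "P"}, True),
    ({"M", "P"}, False),  # M-P pairs excluded for SNVs
    ({"R", "M", "P"}, True),
]

INDEL_CASES = [
    ({"R"}, False),
    ({"M"}, False),
    ({"P"}, False),
    ({"R", "M"}, False),
    ({"R", "P"}, False),
    ({"M", "P"}, True),  # the only valid indel double-call
    ({"R", "M", "P"}, True),
]


@pytest.mark.parametrize("callers,expect", SNV_CASES)
def test_consensus_snv(callers, expect):
    sets = {lbl: ({SNV} if lbl in callers else set()) for lbl in "RMP"}
    out = consensus_double_call(sets, _evmap_for(SNV), "s1")
    assert bool(out) is expect
    if out:
        assert out[0].callers == frozenset(callers)


@pytest.mark.parametrize("callers,expect", INDEL_CASES)
def test_consensus_indel(callers, expect):
    sets = {lbl: ({INDEL} if lbl in callers else set()) for lbl in "RMP"}
    out = consensus_double_call(sets, _evmap_for(SNV), "s1")
    assert bool(out) is expect


def test_consensus_never_invents_variants():
    sets = {"R": {SNV}, "M": {SNV}, "P": set()}
    out = consensus_double_call(sets, _evmap_for(SNV), "s1")
    assert {c.variant for c in out} <= {SNV}


def test_consensus_unknown_label_rejected():
    with pytest.raises(ValueError):
        consensus_double_call({"X": {SNV}}, _evmap_for(SNV), "s1")


# --- stand-in callers --------------------------------------------------------


def test_standin_callers_call_clear_variant_in_all_sets():
    """VAF 5% at depth 2000 with 0.1% error is unambiguous for all three
    profiles (binomial LLR far above every threshold)."""
    evmap = _evmap_for(SNV, depth=2000, alt_total=100)
    sets = standin_callers(evmap)
    for lbl in "RMP":
        assert SNV in sets[lbl]


def test_standin_callers_empty_without_alt():
    evmap = _evmap_for(SNV, depth=2000, alt_total=0)
    sets = standin_callers(evmap)
    assert all(not s for s in sets.values())


def test_standin_callers_deterministic_and_validated():
    evmap = _evmap_for(SNV, depth=500, alt_total=10)
    assert standin_callers(evmap, seed=1) == standin_callers(evmap, seed=2)
    with pytest.raises(ValueError):
        standin_callers(evmap, profiles=DEFAULT_PROFILES[:2])


# --- eight-rule filter -------------------------------------------------------


def _candidate(variant=SNV, sample="s1", **ev_kwargs):
    ev = make_evidence(
        contig=variant.contig, pos=variant.pos, ref=variant.ref, alt=variant.alt, **ev_kwargs
    )
    return SomaticCandidate(
        variant=variant, sample=sample, callers=frozenset({"R", "M"}), evidence=ev
    )


def _context(cands, pop_af=None, individuals=None):
    pos = {}
    for c in cands:
        pos.setdefault(c.sample, []).append((c.variant.contig, c.variant.pos))
    return CohortContext(
        sample_positions=pos,
        individuals_by_variant=individuals or {c.variant: {c.sample} for c in cands},
        max_pop_af=pop_af or {},
    )


def test_filter_depth_rule():
    c = _candidate(depth=49, alt_total=20)
    filter_somatic([c], _context([c]))
    assert not c.filter_trace["depth"] and not c.filter_trace["pass"]


def test_filter_boundary_pass():
    """All rules exactly at their passing boundaries."""
    c = _candidate(depth=1000, alt_total=15, alt_offarm=15, mean_qual=31.0, n_probes=2)
    filter_somatic([c], _context([c]))
    assert c.filter_trace["pass"], c.filter_trace


def test_filter_vaf_ceiling():
    c = _candidate(depth=1000, alt_total=450, alt_offarm=450, mean_qual=35.0)
    filter_somatic([c], _context([c]))
    assert not c.filter_trace["vaf_range"]


def test_filter_vaf_override_035():
    c = _candidate(depth=1000, alt_total=380, alt_offarm=380, mean_qual=35.0)
    filter_somatic([c], _context([c]), rules={"max_vaf": 0.35})
    assert not c.filter_trace["vaf_range"]
    filter_somatic([c], _context([c]))
    assert c.filter_trace["vaf_range"]


def test_filter_mean_qual_strictly_above_30():
    c = _candidate(depth=1000, alt_total=20, mean_qual=30.0)
    filter_somatic([c], _context([c]))
    assert not c.filter_trace["basequal"]


def test_filter_offarm_support_not_total():
    c = _candidate(depth=1000, alt_total=20, alt_offarm=14)
    filter_somatic([c], _context([c]))
    assert not c.filter_trace["offarm_support"]


def test_filter_probe_diversity():
    c = _candidate(depth=1000, alt_total=20, n_probes=1)
    filter_somatic([c], _context([c]))
    assert not c.filter_trace["probe_types"]


def test_filter_cluster_removes_all_members():
    cands = [
        _candidate(variant=Variant("chr1", 100 + i, "A", "T")) for i in (0, 5, 10, 15)
    ]
    lone = _candidate(variant=Variant("chr1", 300, "A", "T"))
    filter_somatic(cands + [lone], _context(cands + [lone]))
    assert all(not c.filter_trace["cluster"] for c in cands)
    assert lone.filter_trace["cluster"]


def test_filter_three_in_window_allowed():
    cands = [_candidate(variant=Variant("chr1", 100 + i, "A", "T")) for i in (0, 5, 10)]
    filter_somatic(cands, _context(cands))
    assert all(c.filter_trace["cluster"] for c in cands)


def test_filter_population_af_and_recurrence():
    c = _candidate()
    filter_somatic([c], _context([c], pop_af={SNV: 0.002}))
    assert not c.filter_trace["pop_af"]
    c = _candidate()
    filter_somatic([c], _context([c], individuals={SNV: {"i1", "i2", "i3"}}))
    assert not c.filter_trace["recurrence"]


def test_filter_requires_context():
    with pytest.raises(ValueError):
        filter_somatic([_candidate()], None)


def test_filter_matches_bruteforce_oracle():
    """The cascade agrees rule-for-rule with an independent brute-force
    conjunction on randomized candidates (small version of the full
    equivalence suite)."""
    from oracles import random_candidates, oracle_trace

    cands, context, rules = random_candidates(1000, seed=42)
    filter_somatic(cands, context, rules=rules)
    for c in cands:
        assert c.filter_trace == oracle_trace(c, context, rules)


# --- contamination -----------------------------------------------------------


def _low_vaf_candidate(variant, sample):
    return _candidate(variant=variant, sample=sample, depth=1000, alt_total=20)


def test_contamination_flags_matching_sample():
    donor_vars = {Variant("chr1", 10 * i + 10, "A", "T") for i in range(6)}
    cands = [_low_vaf_candidate(v, "s1.PFC") for v in donor_vars]
    clean, flagged = detect_contamination(
        {"s1.PFC": cands},
        {"donor": donor_vars},
        sample_individual={"s1.PFC": "s1"},
    )
    assert flagged == {"s1.PFC": "donor"}
    assert clean["s1.PFC"] == []


def test_contamination_no_matches_not_flagged():
    cands = [_low_vaf_candidate(Variant("chr1", 10, "A", "T"), "s1.PFC")]
    clean, flagged = detect_contamination(
        {"s1.PFC": cands}, {"donor": {Variant("chr2", 5, "G", "C")}},
        sample_individual={"s1.PFC": "s1"},
    )
    assert not flagged
    assert clean["s1.PFC"] == cands


def test_contamination_threshold_semantics():
    donor_vars = {Variant("chr1", 10 * i + 10, "A", "T") for i in range(6)}
    cands = [_low_vaf_candidate(v, "s1.PFC") for v in donor_vars]
    _, flagged = detect_contamination(
        {"s1.PFC": cands}, {"donor": donor_vars}, min_matches=10**9,
        sample_individual={"s1.PFC": "s1"},
    )
    assert not flagged


def test_contamination_own_germline_ignored():
    own = {Variant("chr1", 10 * i + 10, "A", "T") for i in range(6)}
    cands = [_low_vaf_candidate(v, "s1.PFC") for v in own]
    _, flagged = detect_contamination(
        {"s1.PFC": cands}, {"s1": own}, sample_individual={"s1.PFC": "s1"}
    )
    assert not flagged


# --- unique collapsing -------------------------------------------------------

META = {
    f"i{j}.{r}": SampleMeta(sample_id=f"i{j}.{r}", individual=f"i{j}", diagnosis="ALS", region=r)
    for j in (1, 2)
    for r in ("PFC", "PMC", "SC")
}


def test_collapse_same_variant_three_regions():
    cands = [_candidate(sample=f"i1.{r}") for r in ("PFC", "PMC", "SC")]
    out = collapse_unique(cands, META)
    assert len(out) == 1
    assert out[0].region_count == 3


def test_collapse_two_individuals_two_uniques():
    cands = [_candidate(sample="i1.PFC"), _candidate(sample="i2.PFC")]
    out = collapse_unique(cands, META)
    assert len(out) == 2


def test_collapse_empty():
    assert collapse_unique([], META) == []
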