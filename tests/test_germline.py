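"""Germline genotyping, the five-rule filter and pathogenic selection."""

import pytest

from mipmosaic.germline import (
    GermlineCandidate,
    call_genotype_candidates,
    filter_germline,
    genotype_quality,
    select_pathogenic_germline,
)
from mipmosaic.preprocess import build_evidence_map, dedup_reads
from mipmosaic.synthetic_data import (
    CohortConfig,
    DEFAULT_GENE_PANEL,
    simulate_cohort,
)
from mipmosaic.types import AnnotationRecord, Variant

from conftest import make_evidence

V = Variant("chr1", 50, "A", "T")


def _cand(vaf=0.5, depth=100, qual=None, region="PFC", individual="i1", variant=V):
    k = round(vaf * depth)
    return GermlineCandidate(
        variant=variant,
        individual=individual,
        region=region,
        supporting_reads=k,
        depth=depth,
        qual=qual if qual is not None else genotype_quality(k, depth),
    )


def _depth_fn_const(depth):
    return lambda ind, region, variant: depth


def test_genotype_candidates_vaf_gate():
    evmap = {
        ("chr1", 10): make_evidence(pos=10, depth=100, alt_total=50),
        ("chr1", 20): make_evidence(pos=20, depth=100, alt_total=100),
        ("chr1", 30): make_evidence(pos=30, depth=100, alt_total=1),
    }
    cands = call_genotype_candidates(evmap, "i1", "PFC")
    by_pos = {c.variant.pos: c for c in cands}
    assert by_pos[10].vaf == pytest.approx(0.5)
    assert by_pos[20].vaf == pytest.approx(1.0)
    assert 30 not in by_pos  # 1/100 is far below the genotype range
    assert by_pos[10].qual > 50  # confident het


@pytest.mark.parametrize(
    "kwargs,expect",
    [
        (dict(vaf=0.29, depth=100), False),  # VAF below 0.3
        (dict(vaf=0.5, depth=100, qual=49.0), False),  # quality below 50
        (dict(vaf=0.5, depth=19), False),  # depth below 20
        (dict(vaf=0.5, depth=100), True),  # everything passing
    ],
)
def test_filter_single_region_rules(kwargs, expect):
    calls = filter_germline(
        [_cand(**kwargs)], {"i1": ["PFC"]}, _depth_fn_const(0)
    )
    assert calls[0].retained is expect


def test_filter_rule5_low_coverage_region_exempt():
    """Detected in 3 of 4 regions; the absent region has depth 5 (<10) so
    it failed to cover the site and the variant is retained."""
    cands = [_cand(region=r) for r in ("PFC", "PMC", "SC")]
    calls = filter_germline(
        cands, {"i1": ["PFC", "PMC", "SC", "CB"]}, _depth_fn_const(5)
    )
    assert calls[0].retained
    assert calls[0].region_traces["CB"] == {"covered": False}


def test_filter_rule5_covered_but_undetected_rejects():
    cands = [_cand(region=r) for r in ("PFC", "PMC")]
    calls = filter_germline(cands, {"i1": ["PFC", "PMC", "SC"]}, _depth_fn_const(500))
    assert not calls[0].retained
    assert calls[0].region_traces["SC"]["detected"] is False


def test_filter_unknown_individual_errors():
    with pytest.raises(KeyError):
        filter_germline([_cand()], {"other": ["PFC"]}, _depth_fn_const(0))


def test_filter_trace_is_conjunction():
    """A retained call passes every rule in every covered region; any
    failing call has at least one failing rule recorded."""
    cands = [
        _cand(vaf=0.29, region="PFC"),
        _cand(vaf=0.5, region="PFC", variant=Variant("chr1", 60, "C", "G")),
    ]
    calls = filter_germline(cands, {"i1": ["PFC"]}, _depth_fn_const(0))
    for call in calls:
        rule_values = [
            v
            for t in call.region_traces.values()
            for k, v in t.items()
            if k not in ("covered", "detected")
        ]
        if call.retained:
            assert all(rule_values)
        else:
            assert not all(rule_values) or not call.regions_detected


def _ann(variant, consequence="missense", af=0.0, gene="GRNL", votes=5, clinical="unreported"):
    from mipmosaic.synthetic_data import BENIGN_VERDICT, DAMAGING_VERDICT, PREDICTORS

    verdicts = dict(BENIGN_VERDICT)
    for p in PREDICTORS[:votes]:
        verdicts[p] = DAMAGING_VERDICT[p]
    return AnnotationRecord(
        variant=variant,
        gene=gene,
        consequence=consequence,
        clinical_class=clinical,
        predictor_verdicts=verdicts,
        pop_af_by_ancestry={"EUR": af},
        inheritance="dominant",
    )


def _selection_setup(consequence="frameshift", af=0.0, carriers=("case1",)):
    from mipmosaic.germline import GermlineCall

    calls = [
        GermlineCall(
            variant=V, individual=ind, regions_detected=["PFC"], region_traces={},
            retained=True,
        )
        for ind in carriers
    ]
    annotations = {V: _ann(V, consequence=consequence, af=af)}
    diagnoses = {"case1": "FTD", "case2": "ALS", "ctrl1": "control"}
    return calls, annotations, diagnoses


def test_selection_rejects_common_variant():
    calls, ann, diag = _selection_setup(consequence="missense", af=0.002)
    (s,) = select_pathogenic_germline(calls, ann, DEFAULT_GENE_PANEL, diag)
    assert not s.selected
    assert "common-in-population" in s.reasons


def test_selection_frameshift_dominant_disease_only_is_deleterious():
    calls, ann, diag = _selection_setup(consequence="frameshift", af=0.0)
    (s,) = select_pathogenic_germline(calls, ann, DEFAULT_GENE_PANEL, diag)
    assert s.selected
    assert s.label == "predicted-deleterious"


def test_selection_rejects_synonymous_and_mixed_groups():
    calls, ann, diag = _selection_setup(consequence="synonymous")
    (s,) = select_pathogenic_germline(calls, ann, DEFAULT_GENE_PANEL, diag)
    assert not s.selected and "not-protein-altering" in s.reasons
    calls, ann, diag = _selection_setup(carriers=("case1", "ctrl1"))
    res = select_pathogenic_germline(calls, ann, DEFAULT_GENE_PANEL, diag)
    assert all("observed-in-disease-and-control" in s.reasons for s in res)


def test_selection_missing_annotation_yields_error_record():
    calls, _, diag = _selection_setup()
    (s,) = select_pathogenic_germline(calls, {}, DEFAULT_GENE_PANEL, diag)
    assert not s.selected and s.reasons == ["missing-annotation"]


def test_cohort_germline_recovered_somatic_not_miscalled():
    """With error-free reads, every adequately covered germline implant is
    retained and no somatic implant (VAF <= 0.1) is ever called germline."""
    cfg = CohortConfig(
        n_als=2, n_ftd=1, n_control=1, regions=("PFC", "PMC"),
        contig_length=240, mean_unique_depth=200.0, error_rate=0.0,
        germline_per_individual=2.0, somatic_per_individual=2.0,
    )
    reads, truth, ref, _ = simulate_cohort(cfg, seed=11)
    evidence = {s: build_evidence_map(dedup_reads(r), ref) for s, r in reads.items()}
    regions = {}
    cands = []
    for m in truth.meta:
        regions.setdefault(m.individual, []).append(m.region)
        cands.extend(call_genotype_candidates(evidence[m.sample_id], m.individual, m.region))

    def depth_fn(ind, region, v):
        ev = evidence[f"{ind}.{region}"].get((v.contig, v.pos))
        return ev.total_depth if ev else 0

    calls = filter_germline(cands, regions, depth_fn)
    retained = {(c.individual, c.variant) for c in calls if c.retained}
    implanted = {(g.individual, g.variant) for g in truth.germline}
    assert implanted <= retained
    somatic = {(s.individual, s.variant) for s in truth.somatic}
    assert not (somatic & retained)
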