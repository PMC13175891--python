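"""Generator tests: GC copy rule, spike-in VAF arithmetic, truth
conservation, determinism, repeat-read construction."""

import numpy as np
import pytest

from mipmosaic.synthetic_data import (
    CohortConfig,
    RepeatAllele,
    assign_probe_copies,
    design_spikein,
    make_repeat_locus,
    random_reference,
    simulate_cohort,
    simulate_mip_reads,
    simulate_repeat_reads,
    tile_panel,
)
from mipmosaic.types import Variant


@pytest.mark.parametrize(
    "gc,copies",
    [
        (0.50, 1),
        (0.59, 1),
        (0.60, 2),
        (0.65, 2),
        (0.70, 2),
        (0.75, 5),
        (0.80, 5),
        (0.85, 8),
        (0.90, 8),
        (0.95, 10),
        (1.00, 10),
    ],
)
def test_gc_copy_bins(gc, copies):
    assert assign_probe_copies(gc) == copies


@pytest.mark.parametrize("gc", [-0.1, 1.1])
def test_gc_out_of_range(gc):
    with pytest.raises(ValueError):
        assign_probe_copies(gc)


@pytest.fixture(scope="module")
def one_probe_setup():
    ref = random_reference({"chr1": 120}, seed=3)
    panel = tile_panel(ref, target_len=40, arm_len=20, step=200)
    assert len(panel) == 1
    return ref, panel


def test_het_spike_vaf_converges_to_half_mixing(one_probe_setup):
    """At high depth the empirical VAF of a het spiked site approaches
    mixing_fraction / 2 (within 3 binomial SDs)."""
    ref, panel = one_probe_setup
    pos = panel[0].target.start + 5
    ref_base = ref["chr1"][pos - 1]
    alt = "A" if ref_base != "A" else "C"
    v = Variant("chr1", pos, ref_base, alt)
    depth = 100_000
    mixing = 0.10
    reads = simulate_mip_reads(
        panel, ref, [(v, "het")], mixing, error_rate=0.0,
        mean_unique_depth=depth, seed=9, dup_rate=0.0,
    )
    n_alt = sum(1 for r in reads if r.base_at(pos) == alt)
    p = mixing / 2
    sd = np.sqrt(p * (1 - p) / len(reads))
    assert abs(n_alt / len(reads) - p) < 3 * sd


def test_zero_mixing_zero_error_gives_reference_only(one_probe_setup):
    ref, panel = one_probe_setup
    pos = panel[0].target.start + 5
    ref_base = ref["chr1"][pos - 1]
    v = Variant("chr1", pos, ref_base, "A" if ref_base != "A" else "C")
    reads = simulate_mip_reads(
        panel, ref, [(v, "het")], 0.0, error_rate=0.0, mean_unique_depth=500, seed=2
    )
    span = panel[0].span
    expect = ref["chr1"][span.start - 1 : span.end]
    assert all(r.bases == expect for r in reads)


def test_read_simulation_deterministic(one_probe_setup):
    ref, panel = one_probe_setup
    kw = dict(
        spike_variants=[], mixing_fraction=0.0, error_rate=0.01,
        mean_unique_depth=100, seed=77,
    )
    a = simulate_mip_reads(panel, ref, **kw)
    b = simulate_mip_reads(panel, ref, **kw)
    assert [(r.umi, r.bases, r.quals) for r in a] == [(r.umi, r.bases, r.quals) for r in b]


def test_empty_panel_rejected(one_probe_setup):
    ref, _ = one_probe_setup
    with pytest.raises(ValueError):
        simulate_mip_reads([], ref, [], 0.0, 0.0, 10, seed=1)


def test_spikein_design_tiers_and_truth():
    ref = random_reference({"chr1": 600}, seed=5)
    panel = tile_panel(ref)
    design = design_spikein(panel, ref, n_het=6, seed=8, n_background=3)
    assert len(design.het_truth) == 6
    # expected VAF at a het site equals the tier label
    for tier in design.target_vaf_tiers:
        assert design.mixing_fraction(tier) / 2 == pytest.approx(tier)
    with pytest.raises(ValueError):
        design_spikein(panel, ref, n_het=2, seed=8, tiers=(0.05, 0.05))


def test_cohort_truth_conservation_and_focality():
    cfg = CohortConfig(
        n_als=3, n_ftd=2, n_control=2, regions=("PFC", "PMC", "SC"),
        focal_fraction=1.0, somatic_per_individual=2.0,
    )
    _, truth, _, _ = simulate_cohort(cfg, seed=4, emit_reads=False)
    ann_implants = set(truth.annotations)
    implanted = {g.variant for g in truth.germline} | {s.variant for s in truth.somatic}
    assert implanted == ann_implants
    # focal_fraction=1 -> every somatic implant present in exactly one region
    assert all(s.is_focal for s in truth.somatic)
    for g in truth.germline:
        assert g.zygosity in ("het", "hom")
    assert all(
        max(s.region_vafs.values()) <= cfg.max_somatic_vaf for s in truth.somatic
    )


def test_cohort_requires_every_group():
    with pytest.raises(ValueError):
        CohortConfig(n_als=0)


def test_cohort_reads_deterministic(micro_cohort_config):
    r1, t1, _, _ = simulate_cohort(micro_cohort_config, seed=6)
    r2, t2, _, _ = simulate_cohort(micro_cohort_config, seed=6)
    assert sorted(r1) == sorted(r2)
    s = sorted(r1)[0]
    assert [(r.umi, r.bases) for r in r1[s]] == [(r.umi, r.bases) for r in r2[s]]
    assert [g.variant for g in t1.germline] == [g.variant for g in t2.germline]


# --- repeat reads -----------------------------------------------------------


def test_repeat_reads_exact_motif_runs():
    locus = make_repeat_locus(flank_len=100, seed=1)
    hap = {n: "T" for n in locus.snp_positions}
    reads, truth = simulate_repeat_reads(
        locus, [RepeatAllele(10, hap, 5)], error_rate=0.0, seed=2
    )
    assert len(reads) == 5
    for r in reads:
        core = r.sequence[len(locus.left_flank) : -len(locus.right_flank)]
        assert core == locus.motif * 10


def test_repeat_reads_deterministic_and_snp_validation():
    locus = make_repeat_locus(flank_len=80, seed=1)
    hap = {next(iter(locus.snp_positions)): "G"}
    a, _ = simulate_repeat_reads(locus, [RepeatAllele(4, hap, 3)], 0.01, seed=5)
    b, _ = simulate_repeat_reads(locus, [RepeatAllele(4, hap, 3)], 0.01, seed=5)
    assert [r.sequence for r in a] == [r.sequence for r in b]
    with pytest.raises(ValueError):
        simulate_repeat_reads(locus, [RepeatAllele(4, {"nope": "A"}, 1)], 0.0, seed=1)
    with pytest.raises(ValueError):
        RepeatAllele(-1, {}, 1)
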