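"""Spike-in truth-set construction and pipeline evaluation.

Only heterozygous SNPs of the spiked genome are scored (their expected
allele fraction equals the mixing fraction halved, i.e. the tier label);
sites covered by a single amplicon or at depth below 100 are excluded as
panel-design failures rather than calling failures.  Detected variants
outside the truth set count as false positives, except the background
genome's own germline SNPs and the excluded spike-in sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field


MIN_TRUTH_DEPTH = 100
MIN_COVERING_PROBES = 2


@dataclass
class TruthSet:
    evaluable: list  # Variant
    excluded: dict  # Variant -> exclusion reason
    background: set  # sites (contig, pos) never counted as FP

    def __post_init__(self) -> None:
        overlap = set(self.evaluable) & set(self.excluded)
        if overlap:
            raise ValueError(f"sites both evaluable and excluded: {sorted(overlap)[:3]}")


@dataclass
class BenchmarkMetrics:
    sensitivity: float
    precision: float
    n_evaluable: int
    n_detected: int
    n_false_positive: int
    fp_per_mb: float
    precision_defined: bool = True


def make_truth_set(
    het_snps: list,
    evidence_map: dict,
    background_sites: list = (),
    min_depth: int = MIN_TRUTH_DEPTH,
    min_probes: int = MIN_COVERING_PROBES,
) -> TruthSet:
    """Build the evaluable truth set from spiked heterozygous SNPs.

    A site is excluded when covered by fewer than ``min_probes`` amplicons
    or when its deduplicated depth is below ``min_depth``.
    """
    evaluable = []
    excluded: dict = {}
    for v in het_snps:
        ev = evidence_map.get((v.contig, v.pos))
        depth = ev.total_depth if ev is not None else 0
        n_probes = len(ev.covering_probe_ids) if ev is not None else 0
        if n_probes < min_probes:
            excluded[v] = "single-amplicon"
        elif depth < min_depth:
            excluded[v] = "low-depth"
        else:
            evaluable.append(v)
    background = {(v.contig, v.pos) for v in background_sites}
    return TruthSet(evaluable=evaluable, excluded=excluded, background=background)


def evaluate_calls(calls: list, truth: TruthSet, evaluable_bases: int | None = None) -> BenchmarkMetrics:
    """Score a call list against the truth set.

    sensitivity = detected evaluable / evaluable; precision = detected
    evaluable / (detected evaluable + FP).  Calls at excluded truth sites
    or at background germline sites are ignored entirely.  With zero
    calls, precision is reported as 1.0 with ``precision_defined=False``.
    ``evaluable_bases`` (defaults to the evaluable site count) sets the
    denominator of the FP-per-megabase rate.
    """
    evaluable = set(truth.evaluable)
    excluded = set(truth.excluded)
    called = set(calls)
    detected = evaluable & called
    fp = [
        v
        for v in called - evaluable
        if v not in excluded and (v.contig, v.pos) not in truth.background
    ]
    n_eval = len(evaluable)
    sens = len(detected) / n_eval if n_eval else 0.0
    denom = len(detected) + len(fp)
    precision_defined = denom > 0
    precision = len(detected) / denom if precision_defined else 1.0
    bases = evaluable_bases if evaluable_bases is not None else max(n_eval, 1)
    return BenchmarkMetrics(
        sensitivity=sens,
        precision=precision,
        n_evaluable=n_eval,
        n_detected=len(detected),
        n_false_positive=len(fp),
        fp_per_mb=len(fp) / bases * 1e6,
        precision_defined=precision_defined,
    )


@dataclass
class TierResult:
    tier: float
    metrics: BenchmarkMetrics


def run_tier(
    tier: float,
    seed: int,
    mean_unique_depth: float = 2000.0,
    error_rate: float = 0.001,
    n_het: int = 12,
    n_background: int = 4,
    contig_length: int = 600,
    n_contigs: int = 2,
):
    """Simulate one spike-in mixture and push it through the full somatic
    pipeline (dedup -> evidence -> three callers -> consensus -> eight-rule
    filter).  Returns ``(calls, truth)`` ready for :func:`evaluate_calls`.

    Truth sites are restricted to positions inside the target regions of
    at least two probes so every evaluable site is detectable in
    principle; sites with single-amplicon or shallow coverage are excluded
    by :func:`make_truth_set` exactly as in the published design.
    """
    import numpy as np

    from .preprocess import build_evidence_map, dedup_reads
    from .somatic import (
        CohortContext,
        consensus_double_call,
        filter_somatic,
        standin_callers,
    )
    from .synthetic_data import (
        design_spikein,
        random_reference,
        simulate_mip_reads,
        tile_panel,
    )

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(int(round(tier * 10000)),))
    s_ref, s_design, s_reads = (int(x % (2**31)) for x in ss.generate_state(3))
    reference = random_reference(
        {f"chr{i + 1}": contig_length for i in range(n_contigs)}, seed=s_ref
    )
    panel = tile_panel(reference)
    design = design_spikein(
        panel, reference, n_het=n_het, seed=s_design, n_background=n_background
    )
    reads = simulate_mip_reads(
        panel,
        reference,
        list(design.truth_sites),
        mixing_fraction=design.mixing_fraction(tier),
        error_rate=error_rate,
        mean_unique_depth=mean_unique_depth,
        seed=s_reads,
        background_variants=list(design.background_sites),
    )
    deduped = dedup_reads(reads)
    evidence = build_evidence_map(deduped, reference)
    sets = standin_callers(evidence)
    candidates = consensus_double_call(sets, evidence, sample="spikein")
    context = CohortContext(
        sample_positions={"spikein": [(c.variant.contig, c.variant.pos) for c in candidates]},
        individuals_by_variant={c.variant: {"spikein"} for c in candidates},
    )
    filter_somatic(candidates, context)
    calls = [c.variant for c in candidates if c.filter_trace["pass"]]
    truth = make_truth_set(
        list(design.het_truth),
        evidence,
        background_sites=[v for v, _ in design.background_sites],
    )
    return calls, truth


def run_spikein_benchmark(tiers: tuple, seed: int, **kwargs) -> list:
    """Evaluate the pipeline at each VAF tier; returns TierResult list."""
    out = []
    for tier in tiers:
        calls, truth = run_tier(tier, seed=seed, **kwargs)
        out.append(TierResult(tier=tier, metrics=evaluate_calls(calls, truth)))
    return out
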