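"""Somatic candidate consensus and the eight-rule filter cascade.

Three stand-in callers with distinct sensitivity profiles (labels R, M, P,
mapped in config to the external low-VAF callers whose VCFs are equally
accepted) feed a double-call consensus: SNVs must include caller R in
their support (M-P pairs are dropped for their high false-positive rate),
indels must be called by both M and P (R does not detect indels), and
singletons are always discarded.  Survivors then face eight hard filters
on depth, off-arm support, base quality, probe diversity, VAF range,
candidate clustering, population frequency and cohort recurrence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .types import SiteEvidence, SomaticCandidate, Variant

CALLER_LABELS = frozenset({"R", "M", "P"})

#: Default thresholds of the eight-rule somatic filter.
SOMATIC_RULES = {
    "min_depth": 50,  # rule 1
    "min_offarm_support": 15,  # rule 2
    "min_mean_basequal": 30.0,  # rule 3 (strict >)
    "min_probe_types": 2,  # rule 4
    "min_vaf": 0.001,  # rule 5 lower bound
    "max_vaf": 0.4,  # rule 5 upper bound (0.35 available as override)
    "window_bp": 20,  # rule 6 window width
    "max_in_window": 3,  # rule 6
    "max_pop_af": 0.001,  # rule 7 (strict <)
    "max_individuals": 2,  # rule 8
}

RULE_NAMES = (
    "depth",
    "offarm_support",
    "basequal",
    "probe_types",
    "vaf_range",
    "cluster",
    "pop_af",
    "recurrence",
)


@dataclass(frozen=True)
class CallerProfile:
    """Sensitivity/error profile of one stand-in caller."""

    label: str
    error_rate: float = 0.001
    min_alt: int = 3
    min_vaf: float = 0.001
    llr_threshold: float = 10.0  # log10-LLR x 10 against the error model
    calls_indels: bool = True


#: Profiles mimicking the roles of the three external callers: R is tuned
#: for low-VAF detection but does not call indels; M and P are broader.
DEFAULT_PROFILES = (
    CallerProfile("R", error_rate=0.001, min_alt=3, min_vaf=0.001, llr_threshold=10.0,
                  calls_indels=False),
    CallerProfile("M", error_rate=0.002, min_alt=4, min_vaf=0.002, llr_threshold=12.0),
    CallerProfile("P", error_rate=0.002, min_alt=5, min_vaf=0.002, llr_threshold=15.0),
)


def _call_llr(k: int, n: int, error_rate: float) -> float:
    """Binomial log-likelihood ratio (10 x log10) of a real variant at the
    observed fraction versus sequencing error."""
    if n == 0 or k == 0:
        return 0.0
    p_alt = max(k / n, error_rate)
    return float(
        10.0
        * (binom.logpmf(k, n, p_alt) - binom.logpmf(k, n, error_rate))
        / np.log(10.0)
    )


def standin_callers(
    evidence_map: dict,
    profiles: tuple = DEFAULT_PROFILES,
    seed: int = 0,
) -> dict:
    """Produce one candidate set per caller profile from site evidence.

    Each set holds Variant objects whose support exceeds the profile's
    binomial-LLR threshold.  Deterministic: the seed is accepted for
    interface symmetry with the simulators but the emission rule itself is
    a pure threshold.
    """
    if len(profiles) < 3:
        raise ValueError("need at least three caller profiles")
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("caller profile labels must be distinct")
    sets: dict = {p.label: set() for p in profiles}
    for (contig, pos), ev in evidence_map.items():
        for base, allele in ev.alleles.items():
            if base == ev.ref or allele.count_total == 0:
                continue
            v = Variant(contig, pos, ev.ref, base)
            vaf = ev.vaf(base)
            for p in profiles:
                if v.is_indel and not p.calls_indels:
                    continue
                if allele.count_total < p.min_alt or vaf < p.min_vaf:
                    continue
                if _call_llr(allele.count_total, ev.total_depth, p.error_rate) >= p.llr_threshold:
                    sets[p.label].add(v)
    return sets


def consensus_double_call(sets: dict, evidence_map: dict, sample: str) -> list:
    """Double-call consensus over per-caller candidate sets.

    SNVs are retained when called by R together with at least one other
    caller (M-P-only pairs are excluded); indels require both M and P.
    Variants called by a single caller are discarded.  Evidence and VAF
    are recomputed from ``evidence_map``, never taken from a caller.
    """
    unknown = set(sets) - CALLER_LABELS
    if unknown:
        raise ValueError(f"unknown caller labels: {sorted(unknown)}")
    support: dict = defaultdict(set)
    for label, variants in sets.items():
        for v in variants:
            support[v].add(label)
    out: list[SomaticCandidate] = []
    for v, callers in sorted(support.items(), key=lambda kv: kv[0].key):
        if v.is_indel:
            keep = {"M", "P"} <= callers
        else:
            keep = "R" in callers and len(callers) >= 2
        if not keep:
            continue
        ev = evidence_map.get((v.contig, v.pos))
        if ev is None:
            ev = SiteEvidence(contig=v.contig, pos=v.pos, ref=v.ref)
        out.append(
            SomaticCandidate(variant=v, sample=sample, callers=frozenset(callers), evidence=ev)
        )
    return out


@dataclass
class CohortContext:
    """Cohort-wide context needed by the positional and recurrence rules."""

    sample_positions: dict  # sample -> list[(contig, pos)] of that sample's candidates
    individuals_by_variant: dict  # Variant -> set of individuals carrying it
    max_pop_af: dict = field(default_factory=dict)  # Variant -> max ancestry AF


def _clustered_positions(positions: list, window_bp: int, max_in_window: int) -> set:
    """Positions belonging to any window of ``window_bp`` bases holding
    more than ``max_in_window`` candidates; every member of an offending
    window is flagged."""
    flagged: set = set()
    by_contig: dict = defaultdict(list)
    for contig, pos in positions:
        by_contig[contig].append(pos)
    for contig, ps in by_contig.items():
        ps = sorted(ps)
        n = len(ps)
        j = 0
        for i in range(n):
            # window starting at ps[i], width window_bp
            while j < n and ps[j] <= ps[i] + window_bp - 1:
                j += 1
            if j - i > max_in_window:
                flagged.update((contig, p) for p in ps[i:j])
    return flagged


def filter_somatic(
    candidates: list,
    context: CohortContext,
    rules: dict | None = None,
) -> list:
    """Apply the eight-rule somatic filter; returns candidates with a full
    per-rule trace in ``filter_trace`` (key 'pass' gives the conjunction).
    """
    if context is None:
        raise ValueError("cohort context is required")
    rules = dict(SOMATIC_RULES, **(rules or {}))
    cluster_cache: dict = {}
    for cand in candidates:
        v = cand.variant
        allele = cand.evidence.allele(v.alt)
        vaf = cand.vaf
        if cand.sample not in cluster_cache:
            cluster_cache[cand.sample] = _clustered_positions(
                context.sample_positions.get(cand.sample, []),
                rules["window_bp"],
                rules["max_in_window"],
            )
        flagged = cluster_cache[cand.sample]
        n_individuals = len(context.individuals_by_variant.get(v, set()))
        pop_af = context.max_pop_af.get(v, 0.0)
        trace = {
            "depth": cand.evidence.total_depth >= rules["min_depth"],
            "offarm_support": allele.count_offarm >= rules["min_offarm_support"],
            "basequal": allele.mean_basequal > rules["min_mean_basequal"],
            "probe_types": len(allele.probe_ids) >= rules["min_probe_types"],
            "vaf_range": rules["min_vaf"] <= vaf <= rules["max_vaf"],
            "cluster": (v.contig, v.pos) not in flagged,
            "pop_af": pop_af < rules["max_pop_af"],
            "recurrence": n_individuals <= rules["max_individuals"],
        }
        trace["pass"] = all(trace[r] for r in RULE_NAMES)
        cand.filter_trace = trace
    return candidates


def detect_contamination(
    candidates_by_sample: dict,
    private_germline: dict,
    min_matches: int = 5,
    max_vaf: float = 0.1,
    sample_individual: dict | None = None,
) -> tuple:
    """Flag samples whose low-VAF candidates mirror another individual's
    private germline variants (a stand-in heuristic for cross-sample
    contamination screening).

    ``private_germline`` maps individual -> set[Variant] private to that
    individual.  A sample is flagged when at least ``min_matches`` of its
    candidates with VAF <= ``max_vaf`` match the private germline set of
    one single other individual; the matching candidates are removed.
    Returns ``(clean_candidates_by_sample, flagged)`` with ``flagged``
    mapping sample -> offending source individual.
    """
    flagged: dict = {}
    clean: dict = {}
    for sample, cands in candidates_by_sample.items():
        if sample_individual is not None:
            sample_ind = sample_individual[sample]
        else:
            sample_ind = sample.split(".")[0]
        matches: dict = defaultdict(list)
        for c in cands:
            if c.vaf > max_vaf:
                continue
            for other, variants in private_germline.items():
                if other == sample_ind:
                    continue
                if c.variant in variants:
                    matches[other].append(c)
        source = None
        for other, hits in matches.items():
            if len(hits) >= min_matches:
                source = other
                break
        if source is not None:
            flagged[sample] = source
            removed = {id(c) for c in matches[source]}
            clean[sample] = [c for c in cands if id(c) not in removed]
        else:
            clean[sample] = list(cands)
    return clean, flagged


@dataclass
class UniqueVariant:
    """One unique somatic variant of one individual, with the regions in
    which it was observed."""

    individual: str
    variant: Variant
    regions: list
    vaf_by_region: dict

    @property
    def region_count(self) -> int:
        return len(self.regions)


def collapse_unique(candidates: list, sample_meta: dict) -> list:
    """Collapse passing per-sample candidates to unique variants per
    individual, preserving region lists and per-region VAFs.

    ``sample_meta`` maps sample_id -> SampleMeta.
    """
    grouped: dict = {}
    for c in candidates:
        meta = sample_meta[c.sample]
        key = (meta.individual, c.variant)
        u = grouped.get(key)
        if u is None:
            u = UniqueVariant(
                individual=meta.individual, variant=c.variant, regions=[], vaf_by_region={}
            )
            grouped[key] = u
        if meta.region not in u.regions:
            u.regions.append(meta.region)
        u.vaf_by_region[meta.region] = c.vaf
    return [grouped[k] for k in sorted(grouped, key=lambda k: (k[0], k[1].key))]
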