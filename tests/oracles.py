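"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (plain loops,
grid/golden-section searches) and never call the implementation paths they
check.
"""

from __future__ import annotations

import numpy as np

from mipmosaic.somatic import CohortContext, SOMATIC_RULES, SomaticCandidate
from mipmosaic.types import AlleleEvidence, SiteEvidence, Variant


def oracle_trace(cand: SomaticCandidate, context: CohortContext, rules: dict) -> dict:
    """Plain conjunction of the eight somatic rules, written independently
    of the filter implementation (including an O(n * positions) window
    scan for the clustering rule)."""
    v = cand.variant
    a = cand.evidence.allele(v.alt)
    depth = cand.evidence.total_depth
    vaf = a.count_total / depth if depth else 0.0
    mean_q = a.qual_sum / a.count_total if a.count_total else 0.0

    # rule 6 brute force: every possible 20-bp window position
    same = [p for c, p in context.sample_positions.get(cand.sample, []) if c == v.contig]
    clustered = False
    for w in range(v.pos - rules["window_bp"] + 1, v.pos + 1):
        inside = [p for p in same if w <= p <= w + rules["window_bp"] - 1]
        if v.pos in inside and len(inside) > rules["max_in_window"]:
            clustered = True
            break

    trace = {
        "depth": depth >= rules["min_depth"],
        "offarm_support": a.count_offarm >= rules["min_offarm_support"],
        "basequal": mean_q > rules["min_mean_basequal"],
        "probe_types": len(a.probe_ids) >= rules["min_probe_types"],
        "vaf_range": rules["min_vaf"] <= vaf <= rules["max_vaf"],
        "cluster": not clustered,
        "pop_af": context.max_pop_af.get(v, 0.0) < rules["max_pop_af"],
        "recurrence": len(context.individuals_by_variant.get(v, set())) <= rules["max_individuals"],
    }
    trace["pass"] = all(trace.values())
    return trace


def random_candidates(n: int, seed: int):
    """Randomized candidates that straddle every rule boundary, plus the
    cohort context describing them."""
    rng = np.random.default_rng(seed)
    rules = dict(SOMATIC_RULES)
    cands = []
    n_samples = max(2, n // 50)
    for i in range(n):
        sample = f"s{rng.integers(n_samples)}"
        contig = f"chr{rng.integers(1, 4)}"
        pos = int(rng.integers(1, 2000))
        ref, alt = "A", "T"
        depth = int(rng.choice([20, 49, 50, 51, 200, 1000, 5000]))
        alt_total = int(rng.integers(0, max(2, depth // 2)))
        alt_offarm = int(rng.integers(0, alt_total + 1))
        mean_q = float(rng.uniform(20, 40))
        n_probes = int(rng.integers(0, 4))
        ev = SiteEvidence(contig=contig, pos=pos, ref=ref, total_depth=depth)
        ev.alleles[alt] = AlleleEvidence(
            count_total=alt_total,
            count_offarm=alt_offarm,
            qual_sum=mean_q * alt_total,
            probe_ids={f"p{k}" for k in range(n_probes)},
            probe_ids_all={f"p{k}" for k in range(n_probes)},
        )
        cands.append(
            SomaticCandidate(
                variant=Variant(contig, pos, ref, alt),
                sample=sample,
                callers=frozenset({"R", "M"}),
                evidence=ev,
            )
        )
    positions: dict = {}
    for c in cands:
        positions.setdefault(c.sample, []).append((c.variant.contig, c.variant.pos))
    individuals: dict = {}
    pop_af: dict = {}
    for c in cands:
        individuals[c.variant] = {
            f"i{k}" for k in range(int(rng.integers(1, 5)))
        }
        pop_af[c.variant] = float(rng.choice([0.0, 0.0005, 0.001, 0.01]))
    context = CohortContext(
        sample_positions=positions, individuals_by_variant=individuals, max_pop_af=pop_af
    )
    return cands, context, rules


def or_conditional_mle_bruteforce(a: int, n1: int, b: int, n2: int) -> float:
    """Golden-section maximization of the noncentral hypergeometric
    likelihood on a log-odds grid; independent of the solver used by the
    implementation."""
    m = a + b
    lo = max(0, m - n2)
    hi = min(m, n1)
    xs = np.arange(lo, hi + 1)
    from math import lgamma

    def logw(x):
        return (
            lgamma(n1 + 1) - lgamma(x + 1) - lgamma(n1 - x + 1)
            + lgamma(n2 + 1) - lgamma(m - x + 1) - lgamma(n2 - (m - x) + 1)
        )

    w = np.array([logw(int(x)) for x in xs])

    def loglik(t):  # t = log(psi)
        z = w + xs * t
        zmax = z.max()
        return (w[xs == a][0] + a * t) - (zmax + np.log(np.exp(z - zmax).sum()))

    if a == lo:
        return 0.0
    if a == hi:
        return np.inf
    lo_t, hi_t = -30.0, 30.0
    phi = (np.sqrt(5) - 1) / 2
    c = hi_t - phi * (hi_t - lo_t)
    d = lo_t + phi * (hi_t - lo_t)
    for _ in range(200):
        if loglik(c) > loglik(d):
            hi_t = d
        else:
            lo_t = c
        c = hi_t - phi * (hi_t - lo_t)
        d = lo_t + phi * (hi_t - lo_t)
    return float(np.exp((lo_t + hi_t) / 2))
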