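"""Germline variant calling, filtering and pathogenic selection.

A lightweight binomial genotyper stands in for the external haplotype
caller (externally produced VCFs are equally accepted through io.py); the
filter reproduces the five-rule cascade used for deep MIP panels, and the
selection pathway narrows retained variants to rare, cohort-exclusive,
protein-altering candidates in the disease gene panel before handing them
to the deleteriousness classifier.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .deleteriousness import classify_deleterious
from .types import GermlineCandidate, Variant

#: Default thresholds of the five-rule germline filter.
GERMLINE_RULES = {
    "min_supporting_reads": 10,  # rule 1
    "min_depth": 20,  # rule 2
    "min_vaf": 0.3,  # rule 3
    "min_qual": 50.0,  # rule 4
    "min_covering_reads": 10,  # rule 5: regions below this depth are exempt
}

#: Genotype-candidate emission threshold (below the germline VAF range).
MIN_CANDIDATE_VAF = 0.2

SELECTABLE_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "canonical-splice", "splice-region"}
)


def genotype_quality(k: int, n: int, error_rate: float = 0.001) -> float:
    """Binomial log-likelihood ratio of a genotype vs sequencing error.

    Likelihood under the best diploid genotype (allele fraction 0.5 or 1)
    against errors at ``error_rate``; expressed in log10 units scaled by 10
    so magnitudes resemble familiar Phred-scaled caller qualities.
    """
    if n == 0:
        return 0.0
    best = max(binom.logpmf(k, n, 0.5), binom.logpmf(k, n, 1.0 - error_rate))
    null = binom.logpmf(k, n, error_rate)
    return float(10.0 * (best - null) / np.log(10.0))


def call_genotype_candidates(
    evidence_map: dict,
    individual: str,
    region: str,
    min_vaf: float = MIN_CANDIDATE_VAF,
) -> list:
    """Emit germline candidates from per-site evidence of one sample.

    A site yields a candidate for every non-reference allele at VAF >=
    ``min_vaf``, with a binomial-LLR quality score.
    """
    out: list[GermlineCandidate] = []
    for (contig, pos), ev in evidence_map.items():
        for base, allele in ev.alleles.items():
            if base == ev.ref or allele.count_total == 0:
                continue
            vaf = ev.vaf(base)
            if vaf < min_vaf:
                continue
            out.append(
                GermlineCandidate(
                    variant=Variant(contig, pos, ev.ref, base),
                    individual=individual,
                    region=region,
                    supporting_reads=allele.count_total,
                    depth=ev.total_depth,
                    qual=genotype_quality(allele.count_total, ev.total_depth),
                )
            )
    out.sort(key=lambda c: (c.variant.key, c.region))
    return out


@dataclass
class GermlineCall:
    """A germline variant retained (or rejected) for one individual, with
    a per-region, per-rule filter trace."""

    variant: Variant
    individual: str
    regions_detected: list
    region_traces: dict  # region -> {rule -> bool}
    retained: bool
    mean_vaf: float = 0.0
    per_region_vaf: dict = field(default_factory=dict)


def _region_trace(c: GermlineCandidate, rules: dict) -> dict:
    return {
        "supporting_reads": c.supporting_reads >= rules["min_supporting_reads"],
        "depth": c.depth >= rules["min_depth"],
        "vaf": c.vaf >= rules["min_vaf"],
        "qual": c.qual >= rules["min_qual"],
    }


def filter_germline(
    candidates: list,
    regions_per_individual: dict,
    depth_fn,
    rules: dict | None = None,
) -> list:
    """Apply the five-rule germline filter.

    Rules 1-4 (supporting reads, depth, VAF, quality) must hold in every
    region where the site is adequately covered; rule 5 requires the
    variant to be detected in all such regions — a region whose depth at
    the site is below ``min_covering_reads`` failed to cover the variant
    and is exempt.

    ``regions_per_individual`` maps individual -> iterable of regions;
    ``depth_fn(individual, region, variant)`` returns total deduplicated
    depth at the variant site in that region (used for regions without a
    candidate).  Candidates whose individual is missing from the map raise
    ``KeyError``.
    """
    rules = dict(GERMLINE_RULES, **(rules or {}))
    by_ind_var: dict = defaultdict(dict)
    for c in candidates:
        if c.individual not in regions_per_individual:
            raise KeyError(f"individual {c.individual} absent from metadata")
        by_ind_var[(c.individual, c.variant)][c.region] = c

    calls: list[GermlineCall] = []
    for (individual, variant), by_region in sorted(
        by_ind_var.items(), key=lambda kv: (kv[0][0], kv[0][1].key)
    ):
        traces: dict = {}
        detected: list = []
        retained = True
        vafs: dict = {}
        for region in regions_per_individual[individual]:
            cand = by_region.get(region)
            if cand is None:
                depth = depth_fn(individual, region, variant)
                if depth < rules["min_covering_reads"]:
                    traces[region] = {"covered": False}
                    continue
                # covered but not detected: rule 5 fails
                traces[region] = {"covered": True, "detected": False}
                retained = False
                continue
            t = _region_trace(cand, rules)
            t["covered"] = True
            t["detected"] = True
            traces[region] = t
            detected.append(region)
            vafs[region] = cand.vaf
            if not all(t[k] for k in ("supporting_reads", "depth", "vaf", "qual")):
                retained = False
        if not detected:
            retained = False
        calls.append(
            GermlineCall(
                variant=variant,
                individual=individual,
                regions_detected=detected,
                region_traces=traces,
                retained=retained,
                mean_vaf=float(np.mean(list(vafs.values()))) if vafs else 0.0,
                per_region_vaf=vafs,
            )
        )
    return calls


@dataclass
class PathogenicSelection:
    """Outcome of the pathogenic/deleterious selection pathway for one
    retained germline variant."""

    variant: Variant
    individual: str
    gene: str
    selected: bool
    label: str  # 'known-pathogenic' | 'predicted-deleterious' | 'neither'
    reasons: list


def select_pathogenic_germline(
    calls: list,
    annotations: dict,
    gene_panel: dict,
    diagnoses: dict,
    max_pop_af: float = 0.001,
) -> list:
    """Select pathogenic / predicted-deleterious germline variants.

    A retained variant proceeds to deleteriousness classification iff
    (a) its maximum population AF over all ancestry groups is below
    ``max_pop_af``, (b) it is exclusive to disease cases or to controls
    across the cohort, (c) its consequence is protein-altering (missense,
    nonsense, frameshift or splicing; a splice delta score > 0.5 also
    promotes it), and (d) its gene is in the configured disease panel.
    Labels: 'known-pathogenic' from the clinical-class field,
    'predicted-deleterious' from the ensemble classifier, else 'neither'.

    Variants without an annotation record yield an error entry and are
    skipped.
    """
    retained = [c for c in calls if c.retained]
    carriers_by_variant: dict = defaultdict(set)
    for c in retained:
        carriers_by_variant[c.variant].add(c.individual)

    out: list[PathogenicSelection] = []
    for c in retained:
        rec = annotations.get(c.variant)
        if rec is None:
            out.append(
                PathogenicSelection(
                    variant=c.variant,
                    individual=c.individual,
                    gene="",
                    selected=False,
                    label="neither",
                    reasons=["missing-annotation"],
                )
            )
            continue
        reasons = []
        if rec.max_pop_af >= max_pop_af:
            reasons.append("common-in-population")
        groups = {
            "disease" if diagnoses[i] != "control" else "control"
            for i in carriers_by_variant[c.variant]
        }
        if len(groups) > 1:
            reasons.append("observed-in-disease-and-control")
        splice_promoted = rec.splice_delta > 0.5
        if rec.consequence not in SELECTABLE_CONSEQUENCES and not splice_promoted:
            reasons.append("not-protein-altering")
        if rec.gene not in gene_panel:
            reasons.append("gene-not-in-panel")
        selected = not reasons
        label = "neither"
        if selected:
            if rec.clinical_class == "pathogenic":
                label = "known-pathogenic"
            else:
                verdict, _ = classify_deleterious(rec)
                label = "predicted-deleterious" if verdict == "deleterious" else "neither"
        out.append(
            PathogenicSelection(
                variant=c.variant,
                individual=c.individual,
                gene=rec.gene,
                selected=selected,
                label=label,
                reasons=reasons,
            )
        )
    return out
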