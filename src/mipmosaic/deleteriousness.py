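"""Ensemble deleteriousness classification and inheritance-aware labeling.

A variant is predicted deleterious when it is loss-of-function (nonsense,
frameshift or canonical-splice), or a missense variant that at least three
of ten configured predictors call fully damaging (possibly/likely-damaging
verdicts do not count), or a splice-altering variant by delta score.  A
clinical benign/likely-benign classification overrides everything.

Individuals are labeled germline-positive by a deleterious variant in a
dominant gene; recessive genes require two hits — a lone heterozygous
deleterious variant is recorded but leaves the individual germline-free,
and a germline + somatic deleterious pair in the same recessive gene is
reported as a two-hit record.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .types import AnnotationRecord, LOF_CONSEQUENCES, Variant

#: Verdict counted as fully damaging, per predictor.  MutationAssessor and
#: FATHMM-MKL use their conventional top categories; both are config
#: (pass a modified map to classify_deleterious).
DAMAGING_CATEGORY = {
    "SIFT": frozenset({"deleterious"}),
    "LRT": frozenset({"deleterious"}),
    "FATHMM": frozenset({"deleterious"}),
    "PROVEAN": frozenset({"deleterious"}),
    "MetaSVM": frozenset({"deleterious"}),
    "MetaLR": frozenset({"deleterious"}),
    "PolyPhen2": frozenset({"probably-damaging"}),
    "MutationTaster": frozenset({"disease-causing"}),
    "MutationAssessor": frozenset({"high"}),
    "FATHMM-MKL": frozenset({"damaging"}),
}

MIN_DAMAGING_VOTES = 3
SPLICE_DELTA_CUTOFF = 0.5


def count_damaging_votes(rec: AnnotationRecord, damaging_map: dict | None = None) -> int:
    damaging_map = damaging_map or DAMAGING_CATEGORY
    votes = 0
    for predictor, verdict in rec.predictor_verdicts.items():
        if predictor not in damaging_map:
            raise ValueError(f"unknown predictor {predictor!r}")
        if verdict in damaging_map[predictor]:
            votes += 1
    return votes


def classify_deleterious(
    rec: AnnotationRecord,
    damaging_map: dict | None = None,
    min_votes: int = MIN_DAMAGING_VOTES,
) -> tuple:
    """Classify one annotated variant as deleterious or not.

    Returns ``(verdict, reason)`` with verdict in
    {'deleterious', 'not-deleterious'}.  Precedence: clinical
    benign/likely-benign overrides all; then LoF consequences; then a
    splice delta score above 0.5; then the missense predictor vote.
    """
    if rec.clinical_class == "benign/likely-benign":
        return "not-deleterious", "clinical-benign"
    if rec.consequence in LOF_CONSEQUENCES:
        return "deleterious", "loss-of-function"
    if rec.splice_delta > SPLICE_DELTA_CUTOFF:
        return "deleterious", "splice-altering"
    if rec.consequence == "missense":
        votes = count_damaging_votes(rec, damaging_map)
        if votes >= min_votes:
            return "deleterious", f"damaging-votes={votes}"
        return "not-deleterious", f"damaging-votes={votes}"
    return "not-deleterious", "consequence-not-damaging"


@dataclass(frozen=True)
class TwoHitRecord:
    """Germline + somatic deleterious pair in one recessive gene."""

    individual: str
    gene: str
    germline_variant: Variant
    somatic_variant: Variant


@dataclass
class IndividualLabel:
    individual: str
    status: str  # 'germline-positive' | 'germline-free'
    dominant_hits: list
    recessive_het_records: list  # lone deleterious hets in recessive genes
    two_hits: list


def label_individuals(
    germline_by_individual: dict,
    somatic_by_individual: dict | None = None,
    damaging_map: dict | None = None,
) -> dict:
    """Label individuals germline-positive / germline-free.

    ``germline_by_individual`` and ``somatic_by_individual`` map
    individual -> list of AnnotationRecord for that individual's variants.
    A deleterious germline variant in a dominant gene marks the individual
    germline-positive.  A single deleterious heterozygous variant in a
    recessive gene does not (it is recorded), but a germline + somatic
    deleterious pair in the same recessive gene yields a two-hit record.
    """
    somatic_by_individual = somatic_by_individual or {}
    out: dict = {}
    for individual in sorted(set(germline_by_individual) | set(somatic_by_individual)):
        germ = germline_by_individual.get(individual, [])
        som = somatic_by_individual.get(individual, [])
        dominant_hits = []
        recessive_hets: dict = defaultdict(list)
        for rec in germ:
            verdict, _ = classify_deleterious(rec, damaging_map)
            if verdict != "deleterious":
                continue
            if rec.inheritance == "dominant":
                dominant_hits.append(rec.variant)
            else:
                recessive_hets[rec.gene].append(rec.variant)
        germline_recessive_pairs = [
            g for g, vs in recessive_hets.items() if len(vs) >= 2
        ]
        som_del_by_gene: dict = defaultdict(list)
        for rec in som:
            verdict, _ = classify_deleterious(rec, damaging_map)
            if verdict == "deleterious" and rec.inheritance == "recessive":
                som_del_by_gene[rec.gene].append(rec.variant)
        two_hits = []
        for gene, gvars in recessive_hets.items():
            for sv in som_del_by_gene.get(gene, []):
                two_hits.append(
                    TwoHitRecord(
                        individual=individual,
                        gene=gene,
                        germline_variant=gvars[0],
                        somatic_variant=sv,
                    )
                )
        positive = bool(dominant_hits) or bool(germline_recessive_pairs)
        out[individual] = IndividualLabel(
            individual=individual,
            status="germline-positive" if positive else "germline-free",
            dominant_hits=dominant_hits,
            recessive_het_records=[v for vs in recessive_hets.values() for v in vs],
            two_hits=two_hits,
        )
    return out
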