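"""Long-read tandem-repeat analysis: motif counting between flank anchors,
allele classification and flanking-SNP haplotype phasing.

Designed for the GGGGCC hexanucleotide locus where >30 copies are
generally pathogenic, 20-30 intermediate and <20 normal.  Counts use the
inter-anchor span divided by the motif length rather than exact motif
matching, so sequencing errors inside the repeat do not truncate counts;
anchors are located with mismatch-tolerant infix alignment (<=10%
mismatches by default).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib

from .types import AlleleCall, RepeatRead

MIN_ANCHOR_LEN = 20

NORMAL_MAX = 19  # <20 repeats: normal
INTERMEDIATE_MAX = 30  # 20-30: intermediate; >30: pathogenic

#: Split allele clusters where adjacent sorted counts differ by more than
#: this; small enough that neighboring wild-type alleles (e.g. 5 vs 9
#: copies) resolve as distinct alleles.
CLUSTER_GAP = 3

#: Expanded (pathogenic) reads are merged into one allele call; a spread
#: wider than this within it is flagged as mosaic.
MOSAIC_SPAN = 50


def repeat_class(count: float) -> str:
    if count > INTERMEDIATE_MAX:
        return "pathogenic"
    if count > NORMAL_MAX:
        return "intermediate"
    return "normal"


def _locate(query: str, read: str, max_mismatch: float):
    """Best infix location of ``query`` in ``read``.

    Returns ``(start, end_exclusive, n_locations)`` or None when no
    alignment fits within the mismatch budget.  Multiple disjoint optimal
    locations signal an ambiguous anchor.
    """
    k = int(max_mismatch * len(query))
    res = edlib.align(query, read, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    locs = res["locations"]
    # collapse overlapping optimal locations into distinct hits
    distinct = []
    for s, e in sorted(locs):
        if distinct and s <= distinct[-1][1]:
            continue
        distinct.append((s, e))
    s, e = distinct[0]
    return s, e + 1, len(distinct)


def count_repeats(
    read_id: str,
    sequence: str,
    left_anchor: str,
    right_anchor: str,
    motif: str = "GGGGCC",
    max_mismatch: float = 0.10,
    snp_probes: dict | None = None,
) -> RepeatRead:
    """Count motif copies between the two flank anchors in one read.

    The count is ``floor(inter-anchor span / len(motif))`` after best-fit
    anchor location.  Reads missing either anchor are returned unanchored
    (never counted); an anchor found at two disjoint optimal locations is
    flagged ambiguous.  ``snp_probes`` maps SNP locus name -> (probe
    sequence, offset of the SNP base within the probe); the probes are
    located in the read to report the read's base at each locus.
    """
    if min(len(left_anchor), len(right_anchor)) < MIN_ANCHOR_LEN:
        raise ValueError(f"anchors must be at least {MIN_ANCHOR_LEN} bp")
    rr = RepeatRead(read_id=read_id)
    left = _locate(left_anchor, sequence, max_mismatch)
    right = _locate(right_anchor, sequence, max_mismatch)
    if left is None or right is None:
        return rr
    if left[2] > 1 or right[2] > 1:
        rr.ambiguous = True
        return rr
    span = right[0] - left[1]
    if span < 0:
        return rr
    rr.anchored = True
    rr.repeat_count = span // len(motif)
    if snp_probes:
        for name, (probe, offset) in snp_probes.items():
            hit = _locate(probe, sequence, max_mismatch)
            if hit is not None and hit[2] == 1:
                idx = hit[0] + offset
                if 0 <= idx < len(sequence):
                    rr.flank_snp_alleles[name] = sequence[idx]
    return rr


def locus_anchors(locus, anchor_len: int = 30) -> tuple:
    """Anchor sequences for a simulated :class:`RepeatLocus`: the flank
    ends adjacent to the repeat run."""
    return locus.left_flank[-anchor_len:], locus.right_flank[:anchor_len]


def locus_snp_probes(locus, probe_len: int = 21) -> dict:
    """SNP-locus probes for a simulated locus: the reference flank context
    centered on each SNP position."""
    probes: dict = {}
    half = probe_len // 2
    for name, (side, off) in locus.snp_positions.items():
        flank = locus.left_flank if side == "left" else locus.right_flank
        start = max(0, off - half)
        end = min(len(flank), off + half + 1)
        probes[name] = (flank[start:end], off - start)
    return probes


def classify_alleles(
    reads: list,
    cluster_gap: int = CLUSTER_GAP,
    mosaic_span: int = MOSAIC_SPAN,
    merge_expanded: bool = True,
) -> list:
    """Cluster anchored per-read repeat counts into allele calls.

    Sorted counts are split where adjacent values differ by more than
    ``cluster_gap``; each cluster is classified by its median (normal /
    intermediate / pathogenic).  Clusters lying entirely in the pathogenic
    range are merged into a single expanded allele call, flagged mosaic
    when its spread exceeds ``mosaic_span`` — a spectrum of expanded
    lengths in one sample reflects somatic repeat instability, not a set
    of distinct inherited alleles.
    """
    counts = sorted(r.repeat_count for r in reads if r.anchored and not r.ambiguous)
    if not counts:
        raise ValueError("need at least one anchored read")
    clusters: list[list[int]] = [[counts[0]]]
    for c in counts[1:]:
        if c - clusters[-1][-1] > cluster_gap:
            clusters.append([c])
        else:
            clusters[-1].append(c)
    calls: list[AlleleCall] = []
    expanded: list[int] = []
    for cl in clusters:
        med = (cl[(len(cl) - 1) // 2] + cl[len(cl) // 2]) / 2
        if merge_expanded and repeat_class(med) == "pathogenic" and min(cl) > INTERMEDIATE_MAX:
            expanded.extend(cl)
            continue
        calls.append(AlleleCall(counts=list(cl), allele_class=repeat_class(med)))
    if expanded:
        calls.append(
            AlleleCall(
                counts=expanded,
                allele_class="pathogenic",
                mosaic=(max(expanded) - min(expanded)) > mosaic_span,
            )
        )
    return calls


@dataclass
class PhasingReport:
    """Haplotype sharing between expanded and wild-type alleles."""

    status: str  # 'ok' | 'no-het-loci' | 'uninformative'
    groups: dict = field(default_factory=dict)  # haplotype tuple -> [read ids]
    unassigned: list = field(default_factory=list)
    shares: dict = field(default_factory=dict)  # expanded allele idx -> wild-type median count


def phase_by_snps(reads: list, het_loci: list, alleles: list | None = None) -> PhasingReport:
    """Group reads by their alleles at heterozygous flank SNPs and report,
    per expanded allele cluster, which wild-type allele's haplotype it
    shares.

    ``het_loci`` lists the informative SNP locus names; reads missing any
    of them are unassigned.  With no het loci phasing is impossible and an
    explicit status is returned.
    """
    if not het_loci:
        return PhasingReport(status="no-het-loci")
    groups: dict = defaultdict(list)
    hap_of_read: dict = {}
    unassigned: list = []
    for r in reads:
        if not r.anchored or r.ambiguous:
            continue
        try:
            hap = tuple(r.flank_snp_alleles[l] for l in het_loci)
        except KeyError:
            unassigned.append(r.read_id)
            continue
        groups[hap].append(r.read_id)
        hap_of_read[r.read_id] = hap
    if len(groups) <= 1:
        return PhasingReport(
            status="uninformative", groups=dict(groups), unassigned=unassigned
        )
    # established haplotypes = the two most read-rich groups
    major = sorted(groups, key=lambda h: -len(groups[h]))[:2]
    read_by_id = {r.read_id: r for r in reads}
    shares: dict = {}
    if alleles is None:
        alleles = classify_alleles(reads)
    wild = [a for a in alleles if a.allele_class != "pathogenic"]
    for ai, a in enumerate(alleles):
        if a.allele_class != "pathogenic":
            continue
        member_ids = [
            rid
            for rid, r in read_by_id.items()
            if r.anchored and not r.ambiguous and r.repeat_count in set(a.counts) and rid in hap_of_read
        ]
        haps = Counter(hap_of_read[rid] for rid in member_ids)
        if not haps:
            continue
        top_hap = haps.most_common(1)[0][0]
        match = None
        for w in wild:
            w_ids = [
                rid
                for rid, r in read_by_id.items()
                if r.repeat_count in set(w.counts) and rid in hap_of_read
            ]
            w_haps = Counter(hap_of_read[rid] for rid in w_ids)
            if w_haps and w_haps.most_common(1)[0][0] == top_hap:
                match = w.median_count
                break
        shares[ai] = match
    unmatched = [
        rid for rid in unassigned
    ]
    return PhasingReport(status="ok", groups=dict(groups), unassigned=unmatched, shares=shares)


def waterfall_table(reads: list):
    """Per-read table sorted ascending by repeat count (stable by read id
    on ties); suitable for waterfall plotting.  Unanchored reads are
    omitted."""
    import pandas as pd

    rows = [
        {"read_id": r.read_id, "repeat_count": r.repeat_count, "allele_class": repeat_class(r.repeat_count)}
        for r in sorted(
            (r for r in reads if r.anchored and not r.ambiguous),
            key=lambda r: (r.repeat_count, r.read_id),
        )
    ]
    return pd.DataFrame(rows, columns=["read_id", "repeat_count", "allele_class"])
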