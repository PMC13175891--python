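"""Raw amplicon reads -> deduplicated, arm-aware per-site evidence.

Duplicate reads from the same original molecule are recognized by sharing
mapping coordinates and the dual UMI; one consensus read survives per
molecule.  Per-site evidence tracks, for every allele, how many supporting
reads carry the allele outside their probe-arm spans — alleles under an
arm copy the probe rather than the genome and are excluded from variant
support (though not from depth).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .types import AlleleEvidence, MipRead, SiteEvidence


def _consensus(dupes: list) -> MipRead:
    """Majority-base consensus over duplicates of one molecule.

    Ties go to the base with the higher summed quality, then
    lexicographically; consensus quality is the max over reads carrying
    the chosen base.
    """
    first = dupes[0]
    base_mat = np.array([np.frombuffer(r.bases.encode(), dtype="S1") for r in dupes])
    qual_mat = np.array([r.quals for r in dupes])
    varying = np.nonzero((base_mat != base_mat[0]).any(axis=0))[0]
    bases = base_mat[0].copy()
    quals = qual_mat.max(axis=0)
    for col in varying:
        col_bases = base_mat[:, col]
        col_quals = qual_mat[:, col]
        stats: dict = {}
        for b, q in zip(col_bases, col_quals):
            cnt, qsum, qmax = stats.get(b, (0, 0.0, 0))
            stats[b] = (cnt + 1, qsum + q, max(qmax, q))
        best = min(stats.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
        bases[col] = best[0]
        quals[col] = best[1][2]
    return MipRead(
        contig=first.contig,
        start=first.start,
        end=first.end,
        probe_id=first.probe_id,
        umi=first.umi,
        bases=bases.tobytes().decode(),
        quals=tuple(int(q) for q in quals),
        arm_spans=first.arm_spans,
    )


def dedup_reads(reads: list) -> list:
    """Collapse duplicates sharing (contig, start, end, UMI) into one
    consensus read.  Idempotent; empty input yields empty output."""
    groups: dict = defaultdict(list)
    for r in reads:
        groups[(r.contig, r.start, r.end, r.umi)].append(r)
    out = [dupes[0] if len(dupes) == 1 else _consensus(dupes) for dupes in groups.values()]
    out.sort(key=lambda r: (r.contig, r.start, r.end, r.umi))
    return out


def build_site_evidence(reads: list, site: tuple) -> SiteEvidence:
    """Evidence at one (contig, pos, ref) site from deduplicated reads.

    Zero coverage is not an error: it yields evidence with total_depth 0.
    """
    contig, pos, ref = site
    ev = SiteEvidence(contig=contig, pos=pos, ref=ref)
    for r in reads:
        if r.contig != contig:
            continue
        b = r.base_at(pos)
        if b is None:
            continue
        ev.total_depth += 1
        ev.covering_probe_ids.add(r.probe_id)
        a = ev.alleles.setdefault(b, AlleleEvidence())
        a.count_total += 1
        a.probe_ids_all.add(r.probe_id)
        a.qual_sum += r.qual_at(pos)
        if not r.pos_in_arm(pos):
            a.count_offarm += 1
            a.probe_ids.add(r.probe_id)
    return ev


def build_evidence_map(reads: list, reference: dict) -> dict:
    """Evidence at every covered reference position.

    Returns ``{(contig, pos): SiteEvidence}``.  Depth and probe coverage
    are accumulated per identical read span (amplicon reads share their
    probe's span), mismatch bookkeeping is sparse, so deep data stays
    tractable.
    """
    ref_arrays = {c: np.frombuffer(s.encode(), dtype="S1") for c, s in reference.items()}
    depth_arr = {c: np.zeros(len(s) + 2, dtype=np.int64) for c, s in reference.items()}
    span_probes: dict = defaultdict(set)  # (contig, start, end) -> probe ids
    allele_acc: dict = defaultdict(dict)  # contig -> (pos, base) -> AlleleEvidence

    for r in reads:
        depth_arr[r.contig][r.start] += 1
        depth_arr[r.contig][r.end + 1] -= 1
        span_probes[(r.contig, r.start, r.end)].add(r.probe_id)
        ref_arr = ref_arrays[r.contig]
        read_arr = np.frombuffer(r.bases.encode(), dtype="S1")
        mism = np.nonzero(read_arr != ref_arr[r.start - 1 : r.end])[0]
        acc = allele_acc[r.contig]
        for off in mism:
            pos = r.start + int(off)
            b = r.bases[int(off)]
            a = acc.setdefault((pos, b), AlleleEvidence())
            a.count_total += 1
            a.probe_ids_all.add(r.probe_id)
            a.qual_sum += r.quals[int(off)]
            if not r.pos_in_arm(pos):
                a.count_offarm += 1
                a.probe_ids.add(r.probe_id)

    probe_cov: dict = defaultdict(lambda: defaultdict(set))
    for (contig, start, end), probes in span_probes.items():
        pc = probe_cov[contig]
        for p in range(start, end + 1):
            pc[p].update(probes)

    out: dict = {}
    for contig, darr in depth_arr.items():
        depth = np.cumsum(darr)[:-1]  # depth[pos] for 1-based pos
        covered = np.nonzero(depth)[0]
        seq = reference[contig]
        acc = allele_acc[contig]
        alt_by_pos: dict = defaultdict(dict)
        for (pos, b), a in acc.items():
            alt_by_pos[pos][b] = a
        pc = probe_cov[contig]
        for pos in covered:
            pos = int(pos)
            total = int(depth[pos])
            ref_base = seq[pos - 1]
            alleles = dict(alt_by_pos.get(pos, {}))
            n_alt = sum(a.count_total for a in alleles.values())
            probes_here = set(pc[pos])
            alleles[ref_base] = AlleleEvidence(
                count_total=total - n_alt,
                count_offarm=total - n_alt,  # ref support; arm split not tracked
                probe_ids=probes_here,
                probe_ids_all=probes_here,
            )
            out[(contig, pos)] = SiteEvidence(
                contig=contig,
                pos=pos,
                ref=ref_base,
                total_depth=total,
                alleles=alleles,
                covering_probe_ids=probes_here,
            )
    return out
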