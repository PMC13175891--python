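"""Standard-format I/O for the pipeline.

Reads travel as SAM (probe id, UMI and arm spans in optional tags) or as
an equivalent one-row-per-read TSV dialect; candidate and passing variants
as VCF; truth, evidence, annotation and metadata tables as TSV; intervals
as BED (converted to/from the package's 1-based inclusive coordinates).
"""

from __future__ import annotations

import pandas as pd
import pysam

from .types import AnnotationRecord, Interval, MipRead, SampleMeta, Variant

UMI_TAG = "RX"
PROBE_TAG = "XP"
ARM_TAG = "XA"


def _arm_str(arm_spans) -> str:
    return ";".join(f"{a.start}-{a.end}" for a in arm_spans)


def _parse_arms(contig: str, s: str):
    if not s:
        return ()
    out = []
    for part in s.split(";"):
        a, b = part.split("-")
        out.append(Interval(contig, int(a), int(b)))
    return tuple(out)


def write_sam(reads: list, reference: dict, path: str) -> None:
    """Write reads as a (text) SAM file with UMI/probe/arm tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in sorted(reference.items())],
    }
    tid = {c: i for i, c in enumerate(sorted(reference))}
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"read{i:07d}"
            a.query_sequence = r.bases
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 41) + 33) for q in r.quals)
            )
            a.reference_id = tid[r.contig]
            a.reference_start = r.start - 1
            a.cigartuples = [(0, len(r.bases))]
            a.mapping_quality = 60
            a.set_tag(UMI_TAG, r.umi)
            a.set_tag(PROBE_TAG, r.probe_id)
            a.set_tag(ARM_TAG, _arm_str(r.arm_spans))
            fh.write(a)


def read_sam(path: str) -> list:
    """Read MIP reads back from SAM/BAM written by :func:`write_sam` (or
    any aligner output carrying the same tags)."""
    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            contig = a.reference_name
            start = a.reference_start + 1
            quals = tuple(int(q) for q in (a.query_qualities or []))
            reads.append(
                MipRead(
                    contig=contig,
                    start=start,
                    end=start + len(a.query_sequence) - 1,
                    probe_id=str(a.get_tag(PROBE_TAG)) if a.has_tag(PROBE_TAG) else "",
                    umi=str(a.get_tag(UMI_TAG)) if a.has_tag(UMI_TAG) else "",
                    bases=a.query_sequence,
                    quals=quals,
                    arm_spans=_parse_arms(contig, str(a.get_tag(ARM_TAG)) if a.has_tag(ARM_TAG) else ""),
                )
            )
    return reads


READ_TSV_COLUMNS = ["contig", "start", "end", "probe_id", "umi", "arm_spans", "bases", "quals"]


def write_reads_tsv(reads: list, path: str) -> None:
    rows = [
        {
            "contig": r.contig,
            "start": r.start,
            "end": r.end,
            "probe_id": r.probe_id,
            "umi": r.umi,
            "arm_spans": _arm_str(r.arm_spans),
            "bases": r.bases,
            "quals": ",".join(str(q) for q in r.quals),
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=READ_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    reads = []
    for row in df.itertuples(index=False):
        reads.append(
            MipRead(
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                probe_id=row.probe_id,
                umi=row.umi,
                bases=row.bases,
                quals=tuple(int(q) for q in row.quals.split(",")),
                arm_spans=_parse_arms(row.contig, row.arm_spans),
            )
        )
    return reads


def write_evidence_tsv(evidence_map: dict, path: str) -> None:
    """Per-site, per-allele evidence table (non-reference alleles)."""
    rows = []
    for (contig, pos), ev in sorted(evidence_map.items()):
        for base, a in sorted(ev.alleles.items()):
            if base == ev.ref:
                continue
            rows.append(
                {
                    "contig": contig,
                    "pos": pos,
                    "ref": ev.ref,
                    "alt": base,
                    "total_depth": ev.total_depth,
                    "count_total": a.count_total,
                    "count_offarm": a.count_offarm,
                    "mean_basequal": round(a.mean_basequal, 3),
                    "n_probes_offarm": len(a.probe_ids),
                    "vaf": round(ev.vaf(base), 6),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "total_depth",
            "count_total",
            "count_offarm",
            "mean_basequal",
            "n_probes_offarm",
            "vaf",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(variants: list, reference: dict, path: str, info_fields: dict | None = None) -> None:
    """Write variants as VCF; ``info_fields`` maps Variant -> dict of INFO
    key/values (keys CALLERS, VAF and TRACE are declared)."""
    header = pysam.VariantHeader()
    for c, s in sorted(reference.items()):
        header.contigs.add(c, length=len(s))
    header.info.add("CALLERS", ".", "String", "Supporting caller labels")
    header.info.add("VAF", "1", "Float", "Recomputed variant allele fraction")
    header.info.add("TRACE", ".", "String", "Filter rules failed (PASS if none)")
    with pysam.VariantFile(path, "w", header=header) as fh:
        for v in sorted(variants, key=lambda v: v.key):
            rec = fh.new_record(
                contig=v.contig, start=v.pos - 1, stop=v.pos - 1 + len(v.ref), alleles=(v.ref, v.alt)
            )
            for key, val in (info_fields or {}).get(v, {}).items():
                rec.info[key] = val
            fh.write(rec)


def read_vcf(path: str) -> list:
    """Read variants (first ALT allele per record) from a VCF."""
    out = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            if not rec.alts:
                continue
            out.append(Variant(rec.contig, rec.pos, rec.ref, rec.alts[0]))
    return out


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: list, path: str) -> None:
    """Write intervals as BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path: str) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end = line.split()[:3]
            out.append(Interval(contig, int(start) + 1, int(end)))
    return out


# ---------------------------------------------------------------------------
# annotation + metadata tables


def write_annotations_tsv(annotations: dict, path: str) -> None:
    rows = []
    for v, rec in sorted(annotations.items(), key=lambda kv: kv[0].key):
        row = {
            "contig": v.contig,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": rec.gene,
            "consequence": rec.consequence,
            "clinical_class": rec.clinical_class,
            "splice_delta": rec.splice_delta,
            "inheritance": rec.inheritance,
        }
        for p, verdict in rec.predictor_verdicts.items():
            row[f"pred_{p}"] = verdict
        for g, af in rec.pop_af_by_ancestry.items():
            row[f"af_{g}"] = af
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path: str) -> dict:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict = {}
    pred_cols = [c for c in df.columns if c.startswith("pred_")]
    af_cols = [c for c in df.columns if c.startswith("af_")]
    for row in df.to_dict("records"):
        v = Variant(str(row["contig"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        out[v] = AnnotationRecord(
            variant=v,
            gene=str(row["gene"]),
            consequence=str(row["consequence"]),
            clinical_class=str(row["clinical_class"]),
            predictor_verdicts={c[5:]: str(row[c]) for c in pred_cols},
            splice_delta=float(row["splice_delta"]),
            pop_af_by_ancestry={c[3:]: float(row[c]) for c in af_cols},
            inheritance=str(row["inheritance"]),
        )
    return out


def write_meta_tsv(meta: list, path: str) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SampleMeta(
            sample_id=str(r["sample_id"]),
            individual=str(r["individual"]),
            diagnosis=str(r["diagnosis"]),
            region=str(r["region"]),
            mean_depth=float(r["mean_depth"]),
            sex=str(r["sex"]),
            pmi_hours=float(r["pmi_hours"]),
            batch=str(r["batch"]),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# FASTA (long reads, reference)


def write_fasta(records: list, path: str) -> None:
    """``records``: iterable of objects with .read_id/.sequence or (id, seq)."""
    with open(path, "w") as fh:
        for rec in records:
            rid = getattr(rec, "read_id", None) or rec[0]
            seq = getattr(rec, "sequence", None) or rec[1]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str) -> list:
    out = []
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            out.append((entry.name, entry.sequence))
    return out
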