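"""End-to-end orchestration: simulate -> preprocess -> germline -> somatic
-> deleteriousness -> burden -> focality, with a machine-readable run
manifest (seed, thresholds, per-output checksums).

Stage toggles are validated up front: enabling a stage whose dependency is
toggled off is a configuration error, so a run never reaches a stage whose
inputs were not produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .burden import mixed_model_enrichment, ns_noncoding_ratio, tabulate_burden
from .config import PipelineConfig
from .deleteriousness import label_individuals
from .focality import classify_focality, focal_fraction, regional_vaf_map
from .germline import call_genotype_candidates, filter_germline, select_pathogenic_germline
from .preprocess import build_evidence_map, dedup_reads
from .somatic import (
    CohortContext,
    collapse_unique,
    consensus_double_call,
    detect_contamination,
    filter_somatic,
    standin_callers,
)
from .synthetic_data import simulate_cohort
from .types import SiteEvidence

log = logging.getLogger("mipmosaic")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, config: PipelineConfig, outdir: str | None):
        config.validate()
        self.config = config
        self.out = Path(outdir or config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.enabled = set(config.stages)
        self.manifest: dict = {
            "seed": config.seed,
            "stages": list(config.stages),
            "germline_rules": dict(config.germline_rules),
            "somatic_rules": dict(config.somatic_rules),
            "outputs": {},
            "timings_s": {},
        }
        # stage products
        self.reads_by_sample: dict = {}
        self.evidence_by_sample: dict = {}
        self.retained: list = []
        self.selections: list = []
        self.uniques: list = []
        self.labels: dict = {}

    def register(self, name: str, path: Path) -> None:
        self.manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    def timed(self, stage: str, fn) -> None:
        if stage not in self.enabled:
            log.info("stage %s disabled; skipping", stage)
            return
        t0 = time.monotonic()
        fn()
        self.manifest["timings_s"][stage] = round(time.monotonic() - t0, 3)
        log.info("stage %s done in %.2fs", stage, time.monotonic() - t0)

    # --- stages -------------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        self.reads_by_sample, self.truth, self.reference, self.panel = simulate_cohort(
            cfg.cohort, seed=cfg.child_seed("simulate")
        )
        self.meta_by_sample = {m.sample_id: m for m in self.truth.meta}
        self.regions_per_individual = defaultdict(list)
        for m in self.truth.meta:
            self.regions_per_individual[m.individual].append(m.region)
        p = self.out / "samples.tsv"
        mio.write_meta_tsv(self.truth.meta, p)
        self.register("samples", p)
        p = self.out / "annotations.tsv"
        mio.write_annotations_tsv(self.truth.annotations, p)
        self.register("annotations", p)
        p = self.out / "targets.bed"
        mio.write_bed([pr.target for pr in self.panel], p)
        self.register("targets", p)

    def preprocess(self) -> None:
        n_raw = n_dedup = 0
        for sample_id, reads in sorted(self.reads_by_sample.items()):
            n_raw += len(reads)
            dd = dedup_reads(reads)
            n_dedup += len(dd)
            self.evidence_by_sample[sample_id] = build_evidence_map(dd, self.reference)
        self.manifest["n_reads_raw"] = n_raw
        self.manifest["n_reads_dedup"] = n_dedup

    def _depth_fn(self, individual: str, region: str, variant) -> int:
        ev = self.evidence_by_sample.get(f"{individual}.{region}", {}).get(
            (variant.contig, variant.pos)
        )
        return ev.total_depth if ev is not None else 0

    def germline(self) -> None:
        candidates = []
        for m in self.truth.meta:
            candidates.extend(
                call_genotype_candidates(
                    self.evidence_by_sample[m.sample_id], m.individual, m.region
                )
            )
        calls = filter_germline(
            candidates,
            dict(self.regions_per_individual),
            self._depth_fn,
            rules=self.config.germline_rules,
        )
        self.retained = [c for c in calls if c.retained]
        p = self.out / "germline.vcf"
        mio.write_vcf(
            sorted({c.variant for c in self.retained}, key=lambda v: v.key),
            self.reference,
            p,
        )
        self.register("germline_vcf", p)
        self.selections = select_pathogenic_germline(
            calls,
            self.truth.annotations,
            self.config.cohort.gene_panel,
            self.truth.individuals,
        )
        rows = [
            {
                "individual": s.individual,
                "contig": s.variant.contig,
                "pos": s.variant.pos,
                "ref": s.variant.ref,
                "alt": s.variant.alt,
                "gene": s.gene,
                "selected": s.selected,
                "label": s.label,
                "reasons": ";".join(s.reasons),
            }
            for s in self.selections
        ]
        p = self.out / "germline_selection.tsv"
        pd.DataFrame(
            rows,
            columns=["individual", "contig", "pos", "ref", "alt", "gene", "selected", "label", "reasons"],
        ).to_csv(p, sep="\t", index=False)
        self.register("germline_selection", p)

    def somatic(self) -> None:
        cfg = self.config
        germline_variants = {c.variant for c in self.retained}
        candidates_by_sample: dict = {}
        for sample_id, evmap in sorted(self.evidence_by_sample.items()):
            sets = standin_callers(evmap, seed=cfg.child_seed("somatic"))
            cands = consensus_double_call(sets, evmap, sample_id)
            candidates_by_sample[sample_id] = [
                c for c in cands if c.variant not in germline_variants
            ]
        private_germline: dict = defaultdict(set)
        carriers: dict = defaultdict(set)
        for c in self.retained:
            carriers[c.variant].add(c.individual)
        for v, inds in carriers.items():
            if len(inds) == 1:
                private_germline[next(iter(inds))].add(v)
        candidates_by_sample, contaminated = detect_contamination(
            candidates_by_sample,
            dict(private_germline),
            min_matches=cfg.contamination_min_matches,
            sample_individual={m.sample_id: m.individual for m in self.truth.meta},
        )
        all_cands = [c for cands in candidates_by_sample.values() for c in cands]
        individuals_by_variant: dict = defaultdict(set)
        for c in all_cands:
            individuals_by_variant[c.variant].add(self.meta_by_sample[c.sample].individual)
        context = CohortContext(
            sample_positions={
                s: [(c.variant.contig, c.variant.pos) for c in cands]
                for s, cands in candidates_by_sample.items()
            },
            individuals_by_variant=dict(individuals_by_variant),
            max_pop_af={
                c.variant: self.truth.annotations[c.variant].max_pop_af
                for c in all_cands
                if c.variant in self.truth.annotations
            },
        )
        filter_somatic(all_cands, context, rules=cfg.somatic_rules)
        passing = [c for c in all_cands if c.filter_trace["pass"]]
        p = self.out / "somatic.vcf"
        info = {}
        for c in passing:
            info[c.variant] = {
                "CALLERS": ",".join(sorted(c.callers)),
                "VAF": round(c.vaf, 6),
                "TRACE": "PASS",
            }
        mio.write_vcf(
            sorted({c.variant for c in passing}, key=lambda v: v.key), self.reference, p, info
        )
        self.register("somatic_vcf", p)
        self.uniques = collapse_unique(passing, self.meta_by_sample)
        rows = [
            {
                "individual": u.individual,
                "contig": u.variant.contig,
                "pos": u.variant.pos,
                "ref": u.variant.ref,
                "alt": u.variant.alt,
                "region_count": u.region_count,
                "regions": ";".join(u.regions),
                "vafs": ";".join(f"{u.vaf_by_region[r]:.5f}" for r in u.regions),
            }
            for u in self.uniques
        ]
        p = self.out / "somatic_unique.tsv"
        pd.DataFrame(
            rows,
            columns=["individual", "contig", "pos", "ref", "alt", "region_count", "regions", "vafs"],
        ).to_csv(p, sep="\t", index=False)
        self.register("somatic_unique", p)
        self.manifest["n_somatic_candidates"] = len(all_cands)
        self.manifest["n_somatic_passing"] = len(passing)
        self.manifest["contaminated_samples"] = sorted(contaminated)

    def deleteriousness(self) -> None:
        germ_recs: dict = defaultdict(list)
        for s in self.selections:
            if s.selected and s.variant in self.truth.annotations:
                germ_recs[s.individual].append(self.truth.annotations[s.variant])
        som_recs: dict = defaultdict(list)
        for u in self.uniques:
            if u.variant in self.truth.annotations:
                som_recs[u.individual].append(self.truth.annotations[u.variant])
        labels = label_individuals(dict(germ_recs), dict(som_recs))
        for ind in self.truth.individuals:
            if ind not in labels:
                labels[ind] = label_individuals({ind: []}, {})[ind]
        self.labels = labels
        rows = [
            {
                "individual": ind,
                "diagnosis": self.truth.individuals[ind],
                "status": lab.status,
                "n_dominant_hits": len(lab.dominant_hits),
                "n_recessive_het": len(lab.recessive_het_records),
                "n_two_hit": len(lab.two_hits),
            }
            for ind, lab in sorted(labels.items())
        ]
        p = self.out / "individual_status.tsv"
        pd.DataFrame(
            rows,
            columns=["individual", "diagnosis", "status", "n_dominant_hits", "n_recessive_het", "n_two_hit"],
        ).to_csv(p, sep="\t", index=False)
        self.register("individual_status", p)

    def burden(self) -> None:
        table = tabulate_burden(
            self.uniques,
            self.truth.annotations,
            self.truth.meta,
            self.labels,
            self.config.cohort.gene_panel,
        )
        p = self.out / "burden_table.tsv"
        table.to_csv(p, sep="\t", index=False)
        self.register("burden_table", p)
        results = []
        for diagnosis in ("ALS", "FTD"):
            for category in ("all", "exonic", "protein-altering"):
                try:
                    res = mixed_model_enrichment(table, diagnosis, category, "all-targeted", "all")
                    results.append(
                        {
                            "diagnosis": diagnosis,
                            "category": category,
                            "effect": round(res.effect, 6),
                            "ci_low": round(res.ci_low, 6),
                            "ci_high": round(res.ci_high, 6),
                            "p": res.p_value,
                            "model": res.model,
                        }
                    )
                except Exception as exc:  # tiny cohorts may not support the fit
                    results.append(
                        {"diagnosis": diagnosis, "category": category, "effect": None, "error": str(exc)}
                    )
        p = self.out / "burden_enrichment.tsv"
        pd.DataFrame(results).to_csv(p, sep="\t", index=False)
        self.register("burden_enrichment", p)
        group_ratios, _ = ns_noncoding_ratio(table)
        self.manifest["ns_noncoding_ratio"] = {
            k: (None if v != v else round(v, 4)) for k, v in group_ratios.items()
        }

    def focality(self) -> None:
        rows = []
        calls = []
        for u in self.uniques:
            ev_by_region = {}
            for region in self.regions_per_individual[u.individual]:
                ev = self.evidence_by_sample[f"{u.individual}.{region}"].get(
                    (u.variant.contig, u.variant.pos)
                )
                if ev is None:
                    ev = SiteEvidence(contig=u.variant.contig, pos=u.variant.pos, ref=u.variant.ref)
                ev_by_region[region] = ev
            call = classify_focality(regional_vaf_map(u.variant, ev_by_region))
            calls.append(call)
            rows.append(
                {
                    "individual": u.individual,
                    "contig": u.variant.contig,
                    "pos": u.variant.pos,
                    "ref": u.variant.ref,
                    "alt": u.variant.alt,
                    "classification": call.classification,
                    "region_count": call.region_count,
                    "regions": ";".join(call.regions),
                }
            )
        p = self.out / "focality.tsv"
        pd.DataFrame(
            rows,
            columns=["individual", "contig", "pos", "ref", "alt", "classification", "region_count", "regions"],
        ).to_csv(p, sep="\t", index=False)
        self.register("focality", p)
        ff = focal_fraction(calls)
        self.manifest["focal_fraction"] = None if ff != ff else round(ff, 4)


def run_pipeline(config: PipelineConfig, outdir: str | None = None) -> dict:
    """Run the enabled stages in order; returns the manifest dict (also
    written to ``manifest.json`` in the run directory)."""
    run = _Run(config, outdir)
    run.timed("simulate", run.simulate)
    run.timed("preprocess", run.preprocess)
    run.timed("germline", run.germline)
    run.timed("somatic", run.somatic)
    run.timed("deleteriousness", run.deleteriousness)
    run.timed("burden", run.burden)
    run.timed("focality", run.focality)
    with open(run.out / "manifest.json", "w") as fh:
        json.dump(run.manifest, fh, indent=2, sort_keys=True)
    return run.manifest
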