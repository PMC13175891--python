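"""Synthetic inputs with recorded truth for every pipeline stage.

The generator emulates, at small scale, the data a deep MIP (molecular
inversion probe) panel study produces: amplicon reads with dual UMIs and
probe arms, two-genome spike-in mixtures at known target VAFs, a
case-control cohort with implanted germline and regionally focal or shared
somatic variants, a matching annotation table, and long reads across a
GGGGCC tandem-repeat locus with flanking heterozygous SNPs.

Every public entry point takes an integer seed and is reproducible
bit-for-bit under it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .types import (
    AnnotationRecord,
    Interval,
    MipRead,
    PanelProbe,
    SampleMeta,
    Variant,
)

BASES = "ACGT"

#: CNS regions sampled by the study design this generator emulates.
DEFAULT_REGIONS = (
    "PFC",
    "PMC",
    "premotor",
    "temporal",
    "occipital",
    "anterior_cingulate",
    "hippocampus",
    "cerebellum",
    "cervical_SC",
    "thoracic_SC",
    "lumbar_SC",
)

#: Small default gene panel: gene -> (disease group, inheritance).
DEFAULT_GENE_PANEL = {
    "SOD1L": ("ALS-dominant", "dominant"),
    "TARDBPL": ("ALS-dominant", "dominant"),
    "ALS2L": ("ALS-recessive", "recessive"),
    "GRNL": ("FTD", "dominant"),
    "MAPTL": ("tauopathy", "dominant"),
    "OTHND1": ("other-ND", "dominant"),
}

PREDICTORS = (
    "SIFT",
    "PolyPhen2",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "FATHMM-MKL",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
)

#: The verdict each predictor emits for a fully damaging call.
DAMAGING_VERDICT = {
    "SIFT": "deleterious",
    "LRT": "deleterious",
    "FATHMM": "deleterious",
    "PROVEAN": "deleterious",
    "MetaSVM": "deleterious",
    "MetaLR": "deleterious",
    "PolyPhen2": "probably-damaging",
    "MutationTaster": "disease-causing",
    "MutationAssessor": "high",
    "FATHMM-MKL": "damaging",
}

BENIGN_VERDICT = {p: "tolerated" for p in PREDICTORS}

ANCESTRY_GROUPS = ("AFR", "AMR", "EAS", "EUR", "SAS")


def assign_probe_copies(gc_fraction: float) -> int:
    """Pool copy number for a probe, rebalanced by target GC content.

    GC-rich targets capture poorly, so probes binding them are printed in
    more copies: 60-70% GC -> 2, 70-80% -> 5, 80-90% -> 8, >90% -> 10;
    below 60% GC a single copy.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction {gc_fraction} outside [0, 1]")
    if gc_fraction > 0.9:
        return 10
    if gc_fraction > 0.8:
        return 8
    if gc_fraction > 0.7:
        return 5
    if gc_fraction >= 0.6:
        return 2
    return 1


# ---------------------------------------------------------------------------
# reference + panel


def random_reference(contig_lengths: dict, seed: int) -> dict:
    """Random uniform-composition reference, one sequence per contig."""
    rng = np.random.default_rng(seed)
    ref = {}
    for contig, length in contig_lengths.items():
        ref[contig] = "".join(rng.choice(list(BASES), size=length))
    return ref


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def tile_panel(
    reference: dict,
    target_len: int = 100,
    arm_len: int = 20,
    step: int = 60,
) -> list:
    """Tile overlapping probes across each contig.

    With ``step < target_len`` interior sites are covered by at least two
    distinct probes, which the benchmarking truth-set rules require.
    """
    panel = []
    for contig, seq in reference.items():
        length = len(seq)
        start = arm_len + 1
        i = 0
        while start + target_len - 1 + arm_len <= length:
            t = Interval(contig, start, start + target_len - 1)
            ext = Interval(contig, start - arm_len, start - 1)
            lig = Interval(contig, t.end + 1, t.end + arm_len)
            gc = gc_fraction(seq[t.start - 1 : t.end])
            panel.append(
                PanelProbe(
                    probe_id=f"{contig}_p{i:03d}",
                    target=t,
                    ext_arm=ext,
                    lig_arm=lig,
                    gc_fraction=gc,
                    copies=assign_probe_copies(gc),
                )
            )
            start += step
            i += 1
    return panel


# ---------------------------------------------------------------------------
# read simulation


def _rand_umi(rng: np.random.Generator, umi_len: int) -> str:
    return "".join(rng.choice(list(BASES), size=umi_len))


def _draw_quals(rng: np.random.Generator, n: int) -> np.ndarray:
    """Phred qualities of correctly called bases (about Q37)."""
    return np.clip(np.rint(rng.normal(37.0, 2.0, size=n)), 25, 41).astype(int)


def _apply_errors(
    rng: np.random.Generator,
    bases: np.ndarray,
    quals: np.ndarray,
    error_rate: float,
) -> None:
    """Independent per-base substitutions in place; erroneous bases get
    low qualities so the base-quality filter is genuinely exercised."""
    if error_rate <= 0:
        return
    n = len(bases)
    n_err = rng.binomial(n, error_rate)
    if n_err == 0:
        return
    pos = rng.choice(n, size=n_err, replace=False)
    for p in pos:
        alts = [b for b in BASES if b != bases[p]]
        bases[p] = alts[rng.integers(3)]
        quals[p] = rng.integers(10, 26)


def simulate_mip_reads(
    panel: list,
    reference: dict,
    spike_variants: list,
    mixing_fraction: float,
    error_rate: float,
    mean_unique_depth: float,
    seed: int,
    dup_rate: float = 0.3,
    umi_len: int = 5,
    background_variants: list = (),
) -> list:
    """Simulate dual-UMI MIP amplicon reads from a two-genome mixture.

    ``spike_variants`` is a list of ``(Variant, zygosity)`` with zygosity
    'het' or 'hom' in the spiked genome; a molecule originates from the
    spiked genome with probability ``mixing_fraction``, so the marginal
    alt-allele probability at a heterozygous spiked site is
    ``mixing_fraction / 2``.  ``background_variants`` are carried by the
    background genome at germline fractions (het 0.5, hom 1.0) regardless
    of the mixture.  Each unique molecule is emitted ``1 + Poisson(dup_rate)``
    times with independent sequencing errors, sharing one dual UMI.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate outside [0, 0.05]")
    if not 0.0 <= mixing_fraction <= 1.0:
        raise ValueError("mixing_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    spike_by_site = {
        (v.contig, v.pos): (v.alt, zyg) for v, zyg in spike_variants
    }
    bg_by_site = {(v.contig, v.pos): (v.alt, zyg) for v, zyg in background_variants}
    reads: list[MipRead] = []
    for probe in panel:
        span = probe.span
        ref_seq = reference[span.contig][span.start - 1 : span.end]
        ref_arr = np.array(list(ref_seq))
        spike_here = [
            (pos - span.start, alt, zyg)
            for (contig, pos), (alt, zyg) in spike_by_site.items()
            if contig == span.contig and span.start <= pos <= span.end
        ]
        bg_here = [
            (pos - span.start, alt, zyg)
            for (contig, pos), (alt, zyg) in bg_by_site.items()
            if contig == span.contig and span.start <= pos <= span.end
        ]
        n_mol = rng.poisson(mean_unique_depth)
        arm_spans = (probe.ext_arm, probe.lig_arm)
        for _ in range(n_mol):
            mol = ref_arr.copy()
            from_spike = rng.random() < mixing_fraction
            for off, alt, zyg in bg_here:
                if zyg == "hom" or rng.random() < 0.5:
                    mol[off] = alt
            if from_spike:
                for off, alt, zyg in spike_here:
                    if zyg == "hom" or rng.random() < 0.5:
                        mol[off] = alt
            umi = _rand_umi(rng, 2 * umi_len)
            n_copies = 1 + rng.poisson(dup_rate)
            for _ in range(n_copies):
                bases = mol.copy()
                quals = _draw_quals(rng, len(bases))
                _apply_errors(rng, bases, quals, error_rate)
                reads.append(
                    MipRead(
                        contig=span.contig,
                        start=span.start,
                        end=span.end,
                        probe_id=probe.probe_id,
                        umi=umi,
                        bases="".join(bases),
                        quals=tuple(int(q) for q in quals),
                        arm_spans=arm_spans,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# spike-in design


@dataclass(frozen=True)
class SpikeInDesign:
    """Two-genome mixing design for benchmarking low-VAF detection.

    Heterozygous SNPs private to the spiked genome act as pseudo-somatic
    variants; mixing a fraction ``2 * vaf`` of the spiked genome makes the
    expected allele fraction at those sites equal the tier label ``vaf``.
    """

    target_vaf_tiers: tuple
    truth_sites: tuple  # ((Variant, zygosity), ...)
    background_sites: tuple = ()  # background-genome germline, never FP

    def __post_init__(self) -> None:
        tiers = self.target_vaf_tiers
        if any(b <= a for a, b in zip(tiers, tiers[1:])):
            raise ValueError("VAF tiers must be strictly increasing")

    def mixing_fraction(self, tier: float) -> float:
        return 2.0 * tier

    @property
    def het_truth(self) -> tuple:
        return tuple(v for v, z in self.truth_sites if z == "het")


#: Target VAF tiers of the study's benchmarking design.
DEFAULT_TIERS = (0.005, 0.01, 0.025, 0.05, 0.10)


def design_spikein(
    panel: list,
    reference: dict,
    n_het: int,
    seed: int,
    tiers: tuple = DEFAULT_TIERS,
    n_hom: int = 0,
    n_background: int = 0,
    min_spacing: int = 21,
) -> SpikeInDesign:
    """Pick spiked-genome SNP truth sites inside panel targets.

    Only heterozygous sites are later scored (homozygous ones would sit at
    twice the target fraction); background-genome germline SNPs are
    recorded so they are never counted as false positives.  Sites keep at
    least ``min_spacing`` bases apart, mirroring scattered biological SNPs
    rather than artifact-like clusters.
    """
    rng = np.random.default_rng(seed)
    cover: dict = {}
    for p in panel:
        for pos in range(p.target.start, p.target.end + 1):
            cover[(p.target.contig, pos)] = cover.get((p.target.contig, pos), 0) + 1
    # truth sites sit where at least two probes target the position, so
    # detection failures reflect calling, not panel geometry
    target_sites = sorted(site for site, n in cover.items() if n >= 2)
    n_total = n_het + n_hom + n_background
    if n_total > len(target_sites):
        raise ValueError("panel too small for the requested number of sites")
    order = rng.permutation(len(target_sites))
    chosen: list = []
    for idx in order:
        contig, pos = target_sites[idx]
        if any(c == contig and abs(pos - p) < min_spacing for c, p in chosen):
            continue
        chosen.append((contig, pos))
        if len(chosen) == n_total:
            break
    if len(chosen) < n_total:
        raise ValueError("panel too small for the requested sites at this spacing")
    variants = []
    for contig, pos in chosen:
        ref_base = reference[contig][pos - 1]
        alts = [b for b in BASES if b != ref_base]
        variants.append(Variant(contig, pos, ref_base, alts[rng.integers(3)]))
    truth = tuple(
        (v, "het" if i < n_het else "hom") for i, v in enumerate(variants[: n_het + n_hom])
    )
    background = tuple(
        (v, "het" if rng.random() < 0.7 else "hom")
        for v in variants[n_het + n_hom :]
    )
    return SpikeInDesign(
        target_vaf_tiers=tuple(tiers), truth_sites=truth, background_sites=background
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortConfig:
    """Shape of the simulated case-control cohort."""

    n_als: int = 4
    n_ftd: int = 2
    n_control: int = 2
    regions: tuple = ("PFC", "PMC", "cervical_SC")
    gene_panel: dict = field(default_factory=lambda: dict(DEFAULT_GENE_PANEL))
    contig_length: int = 300
    germline_per_individual: float = 1.0
    somatic_per_individual: float = 1.0
    case_extra_somatic: float = 0.0  # burden effect added to disease cases
    focal_fraction: float = 0.78
    somatic_vaf_tiers: tuple = (0.01, 0.025, 0.05, 0.10)
    max_somatic_vaf: float = 0.10
    germline_hom_fraction: float = 0.1
    deleterious_fraction: float = 0.5
    mean_unique_depth: float = 300.0
    error_rate: float = 0.0
    target_len: int = 80
    arm_len: int = 16
    step: int = 50

    def __post_init__(self) -> None:
        if min(self.n_als, self.n_ftd, self.n_control) < 1:
            raise ValueError("every diagnosis group needs at least one individual")
        if max(self.somatic_vaf_tiers) > self.max_somatic_vaf:
            raise ValueError("somatic VAF tier above configured maximum")


@dataclass(frozen=True)
class GermlineImplant:
    variant: Variant
    individual: str
    zygosity: str  # 'het' | 'hom'
    gene: str


@dataclass(frozen=True)
class SomaticImplant:
    variant: Variant
    individual: str
    region_vafs: dict  # region -> true VAF (0 where absent)
    gene: str

    @property
    def is_focal(self) -> bool:
        return sum(1 for v in self.region_vafs.values() if v > 0) == 1


@dataclass
class CohortTruth:
    """Ground truth recorded by the cohort generator."""

    individuals: dict  # id -> diagnosis
    germline: list  # GermlineImplant
    somatic: list  # SomaticImplant
    annotations: dict  # Variant -> AnnotationRecord
    meta: list  # SampleMeta


def _annotate_implant(
    rng: np.random.Generator,
    variant: Variant,
    gene: str,
    inheritance: str,
    deleterious: bool,
    somatic: bool,
) -> AnnotationRecord:
    if deleterious:
        consequence = str(rng.choice(["missense", "nonsense", "frameshift"], p=[0.6, 0.2, 0.2]))
        n_votes = int(rng.integers(3, 11)) if consequence == "missense" else int(rng.integers(0, 4))
    else:
        consequence = str(rng.choice(["synonymous", "intronic", "noncoding", "missense"]))
        n_votes = int(rng.integers(0, 3)) if consequence == "missense" else 0
    verdicts = dict(BENIGN_VERDICT)
    for p in rng.choice(PREDICTORS, size=n_votes, replace=False):
        verdicts[p] = DAMAGING_VERDICT[p]
    pop_af = {g: 0.0 for g in ANCESTRY_GROUPS}
    if not somatic and rng.random() < 0.15:
        # a common variant that the rare-variant filter must reject
        common_group = str(rng.choice(ANCESTRY_GROUPS))
        pop_af[common_group] = float(rng.uniform(0.002, 0.05))
    return AnnotationRecord(
        variant=variant,
        gene=gene,
        consequence=consequence,
        clinical_class="unreported",
        predictor_verdicts=verdicts,
        splice_delta=0.0,
        pop_af_by_ancestry=pop_af,
        inheritance=inheritance,
    )


def simulate_cohort(config: CohortConfig, seed: int, emit_reads: bool = True):
    """Simulate a case-control cohort with implanted variants.

    Returns ``(reads_by_sample, truth, reference, panel)`` where
    ``reads_by_sample`` maps sample_id -> list[MipRead] (empty dict when
    ``emit_reads`` is False).  Germline implants are present at VAF 0.5
    (het) or 1.0 (hom) in every region; somatic implants are focal (one
    region) with probability ``focal_fraction`` and otherwise shared by
    two or more regions, at a VAF drawn from ``somatic_vaf_tiers``.
    """
    rng = np.random.default_rng(seed)
    genes = list(config.gene_panel)
    reference = random_reference(
        {g: config.contig_length for g in genes}, seed=int(rng.integers(2**31))
    )
    panel = tile_panel(
        reference,
        target_len=config.target_len,
        arm_len=config.arm_len,
        step=config.step,
    )
    target_sites = sorted(
        {(p.target.contig, pos) for p in panel for pos in range(p.target.start, p.target.end + 1)}
    )

    individuals = {}
    meta = []
    for group, n in (
        ("ALS", config.n_als),
        ("FTD", config.n_ftd),
        ("control", config.n_control),
    ):
        for i in range(n):
            ind = f"{group}_{i:03d}"
            individuals[ind] = group
            sex = "F" if rng.random() < 0.5 else "M"
            pmi = float(rng.uniform(6, 48))
            batch = f"b{int(rng.integers(2)) + 1}"
            for region in config.regions:
                meta.append(
                    SampleMeta(
                        sample_id=f"{ind}.{region}",
                        individual=ind,
                        diagnosis=group,
                        region=region,
                        mean_depth=config.mean_unique_depth,
                        sex=sex,
                        pmi_hours=pmi,
                        batch=batch,
                    )
                )

    used_sites: set = set()

    def _new_variant() -> Variant:
        while True:
            contig, pos = target_sites[rng.integers(len(target_sites))]
            if (contig, pos) in used_sites:
                continue
            used_sites.add((contig, pos))
            ref_base = reference[contig][pos - 1]
            alts = [b for b in BASES if b != ref_base]
            return Variant(contig, pos, ref_base, alts[rng.integers(3)])

    germline: list[GermlineImplant] = []
    somatic: list[SomaticImplant] = []
    annotations: dict = {}

    for ind, group in individuals.items():
        n_g = rng.poisson(config.germline_per_individual)
        for _ in range(n_g):
            v = _new_variant()
            zyg = "hom" if rng.random() < config.germline_hom_fraction else "het"
            gene = v.contig
            germline.append(GermlineImplant(v, ind, zyg, gene))
            annotations[v] = _annotate_implant(
                rng,
                v,
                gene,
                config.gene_panel[gene][1],
                deleterious=rng.random() < config.deleterious_fraction,
                somatic=False,
            )
        lam = config.somatic_per_individual + (
            config.case_extra_somatic if group != "control" else 0.0
        )
        n_s = rng.poisson(lam)
        for _ in range(n_s):
            v = _new_variant()
            vaf = float(rng.choice(config.somatic_vaf_tiers))
            if rng.random() < config.focal_fraction or len(config.regions) == 1:
                present = [str(rng.choice(config.regions))]
            else:
                k = int(rng.integers(2, len(config.regions) + 1))
                present = list(rng.choice(config.regions, size=k, replace=False))
            region_vafs = {r: (vaf if r in present else 0.0) for r in config.regions}
            gene = v.contig
            somatic.append(SomaticImplant(v, ind, region_vafs, gene))
            annotations[v] = _annotate_implant(
                rng,
                v,
                gene,
                config.gene_panel[gene][1],
                deleterious=rng.random() < config.deleterious_fraction,
                somatic=True,
            )

    truth = CohortTruth(
        individuals=individuals,
        germline=germline,
        somatic=somatic,
        annotations=annotations,
        meta=meta,
    )

    reads_by_sample: dict = {}
    if emit_reads:
        germ_by_ind: dict = {}
        for g in germline:
            germ_by_ind.setdefault(g.individual, []).append((g.variant, g.zygosity))
        som_by_ind: dict = {}
        for s in somatic:
            som_by_ind.setdefault(s.individual, []).append(s)
        for m in meta:
            site_afs = []
            for v, zyg in germ_by_ind.get(m.individual, []):
                site_afs.append((v, 1.0 if zyg == "hom" else 0.5))
            for s in som_by_ind.get(m.individual, []):
                vaf = s.region_vafs.get(m.region, 0.0)
                if vaf > 0:
                    site_afs.append((s.variant, vaf))
            reads_by_sample[m.sample_id] = _simulate_reads_at_afs(
                panel,
                reference,
                site_afs,
                config.error_rate,
                config.mean_unique_depth,
                seed=int(rng.integers(2**31)),
            )
    return reads_by_sample, truth, reference, panel


def _simulate_reads_at_afs(
    panel: list,
    reference: dict,
    site_afs: list,
    error_rate: float,
    mean_unique_depth: float,
    seed: int,
    dup_rate: float = 0.3,
    umi_len: int = 5,
) -> list:
    """Reads where each molecule carries each variant independently with
    its per-site allele fraction (germline 0.5/1.0, somatic = true VAF)."""
    rng = np.random.default_rng(seed)
    by_site = {(v.contig, v.pos): (v.alt, af) for v, af in site_afs}
    reads: list[MipRead] = []
    for probe in panel:
        span = probe.span
        ref_seq = reference[span.contig][span.start - 1 : span.end]
        ref_arr = np.array(list(ref_seq))
        here = [
            (pos - span.start, alt, af)
            for (contig, pos), (alt, af) in by_site.items()
            if contig == span.contig and span.start <= pos <= span.end
        ]
        n_mol = rng.poisson(mean_unique_depth)
        arm_spans = (probe.ext_arm, probe.lig_arm)
        for _ in range(n_mol):
            mol = ref_arr.copy()
            for off, alt, af in here:
                if rng.random() < af:
                    mol[off] = alt
            umi = _rand_umi(rng, 2 * umi_len)
            for _ in range(1 + rng.poisson(dup_rate)):
                bases = mol.copy()
                quals = _draw_quals(rng, len(bases))
                _apply_errors(rng, bases, quals, error_rate)
                reads.append(
                    MipRead(
                        contig=span.contig,
                        start=span.start,
                        end=span.end,
                        probe_id=probe.probe_id,
                        umi=umi,
                        bases="".join(bases),
                        quals=tuple(int(q) for q in quals),
                        arm_spans=arm_spans,
                    )
                )
    return reads


# ---------------------------------------------------------------------------
# burden-table simulation (individual-level, for model calibration)


def simulate_burden_table(
    n_case: int,
    n_ctrl: int,
    effect: float,
    seed: int,
    base_rate: float = 1.0,
    n_batches: int = 4,
    batch_sd: float = 0.15,
    diagnosis: str = "ALS",
):
    """Per-individual variant-count table with realistic covariates.

    Counts are Poisson with log-free (additive) rate
    ``base_rate + effect * is_case + batch intercept + small covariate
    terms``; used to calibrate the enrichment mixed model against known
    truth without simulating reads.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = n_case + n_ctrl
    is_case = np.array([1] * n_case + [0] * n_ctrl)
    batch = rng.integers(n_batches, size=n)
    batch_eff = rng.normal(0.0, batch_sd, size=n_batches)
    depth = rng.normal(1800.0, 150.0, size=n)
    sex = rng.integers(2, size=n)
    pmi = rng.uniform(6.0, 48.0, size=n)
    n_samples = rng.integers(3, 8, size=n)
    lam = (
        base_rate
        + effect * is_case
        + batch_eff[batch]
        + 0.0001 * (depth - 1800.0)
        + 0.02 * (n_samples - 5)
    )
    counts = rng.poisson(np.clip(lam, 0.05, None))
    return pd.DataFrame(
        {
            "individual": [f"i{j:04d}" for j in range(n)],
            "diagnosis": np.where(is_case == 1, diagnosis, "control"),
            "count": counts,
            "mean_depth": depth,
            "sex": np.where(sex == 1, "M", "F"),
            "pmi_hours": pmi,
            "batch": [f"b{b}" for b in batch],
            "n_samples": n_samples,
        }
    )


# ---------------------------------------------------------------------------
# long reads across a tandem-repeat locus


@dataclass(frozen=True)
class RepeatLocus:
    """A repeat locus: two flanks around a motif run, with named SNP
    positions inside the flanks."""

    motif: str
    left_flank: str
    right_flank: str
    snp_positions: dict  # locus name -> ('left'|'right', 0-based offset)

    def __post_init__(self) -> None:
        for name, (side, off) in self.snp_positions.items():
            flank = self.left_flank if side == "left" else self.right_flank
            if not 0 <= off < len(flank):
                raise ValueError(f"SNP locus {name} outside the {side} flank")


@dataclass(frozen=True)
class RepeatAllele:
    """One allele to simulate: motif copy number, SNP haplotype, read count."""

    repeat_count: int
    snp_alleles: dict  # locus name -> base
    n_reads: int

    def __post_init__(self) -> None:
        if self.repeat_count < 0:
            raise ValueError("repeat_count must be >= 0")


def make_repeat_locus(
    flank_len: int,
    seed: int,
    motif: str = "GGGGCC",
    n_snps: int = 3,
) -> RepeatLocus:
    """Random flanks with ``n_snps`` SNP positions placed away from the
    flank edges (split between the two flanks)."""
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list(BASES), size=flank_len))
    right = "".join(rng.choice(list(BASES), size=flank_len))
    margin = max(5, flank_len // 10)
    if flank_len <= 2 * margin + 1:
        raise ValueError("flank too short to place SNPs")
    positions: dict = {}
    offsets = rng.choice(
        np.arange(margin, flank_len - margin), size=n_snps, replace=False
    )
    for i, off in enumerate(sorted(int(o) for o in offsets)):
        side = "left" if i % 2 == 0 else "right"
        positions[f"rs{i + 1:03d}"] = (side, off)
    return RepeatLocus(motif=motif, left_flank=left, right_flank=right, snp_positions=positions)


@dataclass(frozen=True)
class LongRead:
    read_id: str
    sequence: str


def simulate_repeat_reads(
    locus: RepeatLocus,
    alleles: list,
    error_rate: float,
    seed: int,
):
    """Simulate long reads ``left flank + motif^n + right flank``.

    Returns ``(reads, truth)`` where ``truth`` maps read_id to the
    generating :class:`RepeatAllele`.  SNP alleles are substituted into the
    flanks before errors are applied.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate outside [0, 0.05]")
    rng = np.random.default_rng(seed)
    reads: list[LongRead] = []
    truth: dict = {}
    for ai, allele in enumerate(alleles):
        left = np.array(list(locus.left_flank))
        right = np.array(list(locus.right_flank))
        for name, base in allele.snp_alleles.items():
            if name not in locus.snp_positions:
                raise ValueError(f"unknown SNP locus {name}")
            side, off = locus.snp_positions[name]
            (left if side == "left" else right)[off] = base
        core = list(left) + list(locus.motif * allele.repeat_count) + list(right)
        for ri in range(allele.n_reads):
            bases = np.array(core)
            quals = np.full(len(bases), 30)
            _apply_errors(rng, bases, quals, error_rate)
            read_id = f"a{ai}_r{ri:04d}"
            reads.append(LongRead(read_id=read_id, sequence="".join(bases)))
            truth[read_id] = allele
    return reads, truth
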