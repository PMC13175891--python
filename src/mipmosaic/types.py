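"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package; BED I/O
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True, order=True)
class Variant:
    """A substitution or short indel in VCF-style normalized form."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PanelProbe:
    """One molecular inversion probe: a targeted gap flanked by two
    hybridization arms.  Bases under the arms copy the probe rather than
    the genome, so arm-borne alleles are untrustworthy.
    """

    probe_id: str
    target: Interval
    ext_arm: Interval
    lig_arm: Interval
    gc_fraction: float
    copies: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if self.copies not in (1, 2, 5, 8, 10):
            raise ValueError(f"copies must be one of 1,2,5,8,10; got {self.copies}")
        if self.ext_arm.overlaps(self.lig_arm):
            raise ValueError("probe arms overlap each other")

    @property
    def span(self) -> Interval:
        """Full captured span including both arms."""
        start = min(self.ext_arm.start, self.target.start, self.lig_arm.start)
        end = max(self.ext_arm.end, self.target.end, self.lig_arm.end)
        return Interval(self.target.contig, start, end)


@dataclass
class MipRead:
    """One (possibly deduplicated) amplicon read."""

    contig: str
    start: int  # 1-based inclusive
    end: int
    probe_id: str
    umi: str
    bases: str
    quals: tuple[int, ...]
    arm_spans: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals differ in length")
        if self.end - self.start + 1 != len(self.bases):
            raise ValueError("read span inconsistent with sequence length")

    def base_at(self, pos: int) -> str | None:
        if not self.start <= pos <= self.end:
            return None
        return self.bases[pos - self.start]

    def qual_at(self, pos: int) -> int | None:
        if not self.start <= pos <= self.end:
            return None
        return self.quals[pos - self.start]

    def pos_in_arm(self, pos: int) -> bool:
        return any(a.contains(self.contig, pos) for a in self.arm_spans)


@dataclass
class AlleleEvidence:
    """Per-allele support at one site, after deduplication."""

    count_total: int = 0
    count_offarm: int = 0  # support excluding reads whose allele lies in an arm
    qual_sum: float = 0.0  # summed Phred over supporting reads
    probe_ids: set = field(default_factory=set)  # off-arm supporting probes
    probe_ids_all: set = field(default_factory=set)

    @property
    def mean_basequal(self) -> float:
        return self.qual_sum / self.count_total if self.count_total else 0.0


@dataclass
class SiteEvidence:
    """Deduplicated read support at one genomic site."""

    contig: str
    pos: int
    ref: str
    total_depth: int = 0
    alleles: dict = field(default_factory=dict)  # base -> AlleleEvidence
    covering_probe_ids: set = field(default_factory=set)

    def allele(self, base: str) -> AlleleEvidence:
        return self.alleles.get(base, AlleleEvidence())

    def vaf(self, alt: str) -> float:
        """Allele fraction over ALL deduplicated reads at the site
        (arm-overlapping reads included in both numerator and denominator;
        the arm exclusion applies only to the supporting-read filter)."""
        if self.total_depth == 0:
            return 0.0
        return self.allele(alt).count_total / self.total_depth


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced tissue sample."""

    sample_id: str
    individual: str
    diagnosis: str  # 'ALS' | 'FTD' | 'control'
    region: str
    mean_depth: float = 0.0
    sex: str = "F"
    pmi_hours: float = 24.0
    batch: str = "b1"


@dataclass
class GermlineCandidate:
    """A putative germline variant in one sample (individual x region)."""

    variant: Variant
    individual: str
    region: str
    supporting_reads: int
    depth: int
    qual: float

    @property
    def vaf(self) -> float:
        return self.supporting_reads / self.depth if self.depth else 0.0


@dataclass
class SomaticCandidate:
    """A putative somatic variant in one sample, with recomputed evidence.

    ``vaf`` is always recomputed from ``evidence``; caller-reported VAFs
    are never trusted.
    """

    variant: Variant
    sample: str
    callers: frozenset
    evidence: SiteEvidence
    filter_trace: dict = field(default_factory=dict)

    @property
    def is_indel(self) -> bool:
        return self.variant.is_indel

    @property
    def vaf(self) -> float:
        return self.evidence.vaf(self.variant.alt)


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation of one variant."""

    variant: Variant
    gene: str
    consequence: str
    clinical_class: str = "unreported"
    predictor_verdicts: dict = field(default_factory=dict)
    splice_delta: float = 0.0
    pop_af_by_ancestry: dict = field(default_factory=dict)
    inheritance: str = "dominant"

    @property
    def max_pop_af(self) -> float:
        return max(self.pop_af_by_ancestry.values(), default=0.0)


@dataclass
class RepeatRead:
    """One long read across a tandem-repeat locus."""

    read_id: str
    repeat_count: int = 0
    flank_snp_alleles: dict = field(default_factory=dict)  # locus -> base
    anchored: bool = False
    ambiguous: bool = False


@dataclass
class AlleleCall:
    """A cluster of per-read repeat counts interpreted as one allele."""

    counts: list
    allele_class: str  # 'normal' | 'intermediate' | 'pathogenic'
    haplotype_label: str | None = None
    mosaic: bool = False

    @property
    def median_count(self) -> float:
        s = sorted(self.counts)
        n = len(s)
        return (s[(n - 1) // 2] + s[n // 2]) / 2


CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "canonical-splice",
    "splice-region",
    "synonymous",
    "noncoding",
    "intronic",
)

PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "frameshift", "canonical-splice", "splice-region"}
)

LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical-splice"})
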