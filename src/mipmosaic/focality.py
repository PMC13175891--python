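"""Regional VAF maps, focal/multiregional classification and
discovery-vs-validation VAF concordance.

A somatic variant is focal when it is detected in exactly one assayed CNS
region; detection per region defaults to at least three off-arm
variant-supporting reads (the validation assays' own criterion is
unpublished, so the threshold is configuration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import Variant

DETECTION_MIN_OFFARM_READS = 3


@dataclass
class RegionalVafMap:
    variant: Variant
    vaf: dict  # region -> fraction (0 where undetected)
    depth: dict  # region -> total depth
    detected: dict  # region -> bool


def regional_vaf_map(
    variant: Variant,
    evidence_by_region: dict,
    min_offarm_reads: int = DETECTION_MIN_OFFARM_READS,
) -> RegionalVafMap:
    """VAF of one variant across all assayed regions.

    ``evidence_by_region`` maps region -> SiteEvidence at the variant
    site.  Undetected regions carry VAF 0 together with their depth.
    """
    if not evidence_by_region:
        raise ValueError("need evidence for at least one region")
    vaf: dict = {}
    depth: dict = {}
    detected: dict = {}
    for region, ev in evidence_by_region.items():
        allele = ev.allele(variant.alt)
        is_detected = allele.count_offarm >= min_offarm_reads
        detected[region] = is_detected
        depth[region] = ev.total_depth
        vaf[region] = ev.vaf(variant.alt) if is_detected else 0.0
    return RegionalVafMap(variant=variant, vaf=vaf, depth=depth, detected=detected)


@dataclass
class FocalityCall:
    variant: Variant
    classification: str  # 'focal' | 'multiregional' | 'undetected'
    region_count: int
    regions: list


def classify_focality(vmap: RegionalVafMap) -> FocalityCall:
    """Focal = detected in exactly one region; order of regions is
    irrelevant.  Zero detections are flagged 'undetected'."""
    regions = sorted(r for r, d in vmap.detected.items() if d)
    n = len(regions)
    if n == 0:
        cls = "undetected"
    elif n == 1:
        cls = "focal"
    else:
        cls = "multiregional"
    return FocalityCall(variant=vmap.variant, classification=cls, region_count=n, regions=regions)


def focal_fraction(calls: list) -> float:
    """Fraction of detected variants that are focal."""
    detected = [c for c in calls if c.classification != "undetected"]
    if not detected:
        return float("nan")
    return sum(1 for c in detected if c.classification == "focal") / len(detected)


@dataclass
class ConcordanceResult:
    slope: float
    intercept: float
    r: float
    slope_se: float
    ci_band: list = field(default_factory=list)  # (x, fit, low, high) rows
    identity_p: float = 1.0  # deviation-from-identity test on the slope
    constant_y: bool = False


def vaf_concordance(pairs: list, n_band: int = 25) -> ConcordanceResult:
    """OLS concordance between discovery and validation VAFs.

    ``pairs`` is a list of (discovery_vaf, validation_vaf).  Reports the
    fitted slope/intercept, Pearson r, a 95% CI band over the observed x
    range, and a t-test of the slope against the identity line (slope 1).
    Fewer than three pairs is an error; a constant y is flagged with r=0.
    """
    if len(pairs) < 3:
        raise ValueError("need at least three VAF pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(y) == 0:
        slope = 0.0
        intercept = float(y[0])
        return ConcordanceResult(
            slope=slope, intercept=intercept, r=0.0, slope_se=float("nan"), constant_y=True
        )

    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = (float(v) for v in fit.params)
    slope_se = float(fit.bse[1])
    r = float(np.corrcoef(x, y)[0, 1])
    from scipy.stats import t as t_dist

    if slope_se > 1e-12:
        tstat = (slope - 1.0) / slope_se
        identity_p = float(2 * t_dist.sf(abs(tstat), df=len(x) - 2))
    else:
        # numerically perfect fit: the test degenerates to exact equality
        identity_p = 1.0 if abs(slope - 1.0) < 1e-9 else 0.0
    grid = np.linspace(x.min(), x.max(), n_band)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    band = list(
        zip(grid, pred["mean"].to_numpy(), pred["mean_ci_lower"].to_numpy(), pred["mean_ci_upper"].to_numpy())
    )
    return ConcordanceResult(
        slope=slope,
        intercept=intercept,
        r=r,
        slope_se=slope_se,
        ci_band=band,
        identity_p=identity_p,
    )
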