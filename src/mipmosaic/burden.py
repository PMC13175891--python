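"""Case-control burden tables and enrichment statistics.

Germline 2x2 enrichment uses the exact-test estimator: the conditional
maximum-likelihood odds ratio of the noncentral hypergeometric model with
an exact (test-inversion) confidence interval and Fisher's two-sided p.
Individual-level somatic burden is modeled with a linear mixed model on
per-individual variant counts, adjusting for mean depth, sex, postmortem
interval and samples per donor, with a random intercept per sequencing
batch.  p-values are reported unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact

from .types import PROTEIN_ALTERING

CATEGORIES = ("all", "exonic", "protein-altering", "nonsynonymous", "intronic", "noncoding")
GENE_GROUPS = ("ALS", "FTD", "other-ND", "all-targeted")

_EXONIC = frozenset({"missense", "nonsense", "frameshift", "synonymous"})
_NONSYN = frozenset({"missense", "nonsense", "frameshift"})
_INTRONIC = frozenset({"intronic", "canonical-splice", "splice-region"})

_GROUP_OF_DISEASE = {
    "ALS-dominant": "ALS",
    "ALS-recessive": "ALS",
    "FTD": "FTD",
    "tauopathy": "other-ND",
    "other-ND": "other-ND",
}


def _categories_of(consequence: str) -> set:
    cats = {"all"}
    if consequence in _EXONIC:
        cats.add("exonic")
    if consequence in PROTEIN_ALTERING:
        cats.add("protein-altering")
    if consequence in _NONSYN:
        cats.add("nonsynonymous")
    if consequence in _INTRONIC:
        cats.add("intronic")
    if consequence == "noncoding":
        cats.add("noncoding")
    return cats


def _gene_groups_of(gene: str, gene_panel: dict) -> set:
    groups = {"all-targeted"}
    disease_group = gene_panel.get(gene, (None,))[0]
    mapped = _GROUP_OF_DISEASE.get(disease_group)
    if mapped:
        groups.add(mapped)
    return groups


def tabulate_burden(
    unique_variants: list,
    annotations: dict,
    meta: list,
    individual_status: dict,
    gene_panel: dict,
) -> pd.DataFrame:
    """Per-individual variant-burden table in long format.

    One row per individual x region (plus region 'all') x gene group x
    category, with the individual's covariates repeated.  Disease
    individuals labeled germline-positive are excluded; controls are
    always included.  Variants lacking an annotation raise ``KeyError``.
    """
    meta_by_ind: dict = {}
    regions_by_ind: dict = {}
    for m in meta:
        meta_by_ind[m.individual] = m
        regions_by_ind.setdefault(m.individual, []).append(m.region)

    def _included(ind: str) -> bool:
        m = meta_by_ind[ind]
        if m.diagnosis == "control":
            return True
        status = individual_status.get(ind, "germline-free")
        if hasattr(status, "status"):
            status = status.status
        return status != "germline-positive"

    individuals = [i for i in sorted(meta_by_ind) if _included(i)]
    counts: dict = {}
    for u in unique_variants:
        if u.individual not in meta_by_ind or not _included(u.individual):
            continue
        rec = annotations.get(u.variant)
        if rec is None:
            raise KeyError(f"variant {u.variant} has no annotation record")
        cats = _categories_of(rec.consequence)
        groups = _gene_groups_of(rec.gene, gene_panel)
        for region in list(u.regions) + ["all"]:
            for g in groups:
                for c in cats:
                    key = (u.individual, region, g, c)
                    counts[key] = counts.get(key, 0) + 1

    rows = []
    for ind in individuals:
        m = meta_by_ind[ind]
        n_samples = len(regions_by_ind[ind])
        for region in sorted(set(regions_by_ind[ind])) + ["all"]:
            for g in GENE_GROUPS:
                for c in CATEGORIES:
                    rows.append(
                        {
                            "individual": ind,
                            "diagnosis": m.diagnosis,
                            "region": region,
                            "gene_group": g,
                            "category": c,
                            "count": counts.get((ind, region, g, c), 0),
                            "mean_depth": m.mean_depth,
                            "sex": m.sex,
                            "pmi_hours": m.pmi_hours,
                            "batch": m.batch,
                            "n_samples": n_samples,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact 2x2 enrichment


def _ncg_log_weights(x: np.ndarray, n1: int, n2: int, m: int) -> np.ndarray:
    return (
        gammaln(n1 + 1)
        - gammaln(x + 1)
        - gammaln(n1 - x + 1)
        + gammaln(n2 + 1)
        - gammaln(m - x + 1)
        - gammaln(n2 - (m - x) + 1)
    )


def _ncg_mean(log_psi: float, xs: np.ndarray, logw: np.ndarray) -> float:
    logp = logw + xs * log_psi
    logp -= logsumexp(logp)
    return float(np.sum(xs * np.exp(logp)))


def _ncg_tail(log_psi: float, xs: np.ndarray, logw: np.ndarray, x: int, upper: bool) -> float:
    logp = logw + xs * log_psi
    logp -= logsumexp(logp)
    p = np.exp(logp)
    return float(p[xs >= x].sum() if upper else p[xs <= x].sum())


@dataclass
class EnrichmentResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    defined: bool = True


def fisher_enrichment(
    carriers_case: int,
    n_case: int,
    carriers_ctrl: int,
    n_ctrl: int,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Exact-test enrichment of carrier status in cases versus controls.

    Returns the conditional MLE odds ratio (the estimator reported by
    exact tests, maximizing the noncentral hypergeometric likelihood given
    all margins), the exact test-inversion CI, and Fisher's two-sided p.
    Degenerate margins (no carriers or no non-carriers anywhere) give an
    undefined OR flagged via ``defined=False``.
    """
    if min(carriers_case, carriers_ctrl, n_case - carriers_case, n_ctrl - carriers_ctrl) < 0:
        raise ValueError("carrier counts must be between 0 and group size")
    table = [[carriers_case, n_case - carriers_case], [carriers_ctrl, n_ctrl - carriers_ctrl]]
    _, p = fisher_exact(table, alternative="two-sided")
    m = carriers_case + carriers_ctrl
    lo = max(0, m - n_ctrl)
    hi = min(m, n_case)
    if lo == hi:  # margin degenerate: conditional distribution is a point mass
        return EnrichmentResult(np.nan, np.nan, np.nan, p, defined=False)
    xs = np.arange(lo, hi + 1)
    logw = _ncg_log_weights(xs, n_case, n_ctrl, m)
    x = carriers_case

    span = 50.0  # log-odds search bracket; generous for any realistic table
    if x == lo:
        or_hat = 0.0
    elif x == hi:
        or_hat = np.inf
    else:
        or_hat = float(np.exp(brentq(lambda t: _ncg_mean(t, xs, logw) - x, -span, span)))

    if x == lo:
        ci_low = 0.0
    else:
        ci_low = float(
            np.exp(brentq(lambda t: _ncg_tail(t, xs, logw, x, upper=True) - alpha / 2, -span, span))
        )
    if x == hi:
        ci_high = np.inf
    else:
        ci_high = float(
            np.exp(brentq(lambda t: _ncg_tail(t, xs, logw, x, upper=False) - alpha / 2, -span, span))
        )
    return EnrichmentResult(or_hat, ci_low, ci_high, p)


# ---------------------------------------------------------------------------
# individual-level mixed model


@dataclass
class MixedModelResult:
    effect: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case: int
    n_ctrl: int
    model: str  # 'mixed' | 'ols'


def mixed_model_enrichment(
    table: pd.DataFrame,
    diagnosis: str,
    category: str | None = None,
    gene_group: str | None = None,
    region: str = "all",
) -> MixedModelResult:
    """Disease-vs-control burden effect from a linear mixed model.

    Fits ``count ~ diagnosis + mean_depth + sex + pmi_hours + n_samples``
    with a random intercept per sequencing batch on per-individual counts
    (Gaussian family on counts).  ``table`` is either the long format from
    :func:`tabulate_burden` (then ``category``/``gene_group``/``region``
    select a stratum) or an already-flat per-individual table with a
    ``count`` column.  With a single batch the model degrades to OLS with
    a warning.  Reported p is the unadjusted Wald p for the disease term.
    """
    df = table
    if "category" in df.columns:
        mask = (df["category"] == category) & (df["region"] == region)
        if gene_group is not None:
            mask &= df["gene_group"] == gene_group
        df = df.loc[mask]
    df = df[df["diagnosis"].isin([diagnosis, "control"])].copy()
    groups = set(df["diagnosis"])
    if len(groups) < 2:
        raise ValueError("need both the disease group and controls in the table")
    df["is_case"] = (df["diagnosis"] == diagnosis).astype(float)
    df["sex_male"] = (df["sex"] == "M").astype(float)
    # center/scale continuous covariates for numerical stability
    for col in ("mean_depth", "pmi_hours", "n_samples"):
        s = df[col].astype(float)
        sd = s.std(ddof=0)
        df[col + "_z"] = (s - s.mean()) / (sd if sd > 0 else 1.0)

    import statsmodels.formula.api as smf

    formula = "count ~ is_case + mean_depth_z + sex_male + pmi_hours_z + n_samples_z"
    n_batches = df["batch"].nunique()
    if n_batches < 2:
        warnings.warn("single sequencing batch: degrading to a fixed-effects model")
        fit = smf.ols(formula, data=df).fit()
        model = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(formula, data=df, groups=df["batch"]).fit(reml=True)
        model = "mixed"
    effect = float(fit.params["is_case"])
    se = float(fit.bse["is_case"])
    p = float(fit.pvalues["is_case"])
    z = 1.959963984540054
    return MixedModelResult(
        effect=effect,
        ci_low=effect - z * se,
        ci_high=effect + z * se,
        p_value=p,
        n_case=int(df["is_case"].sum()),
        n_ctrl=int((1 - df["is_case"]).sum()),
        model=model,
    )


def ns_noncoding_ratio(table: pd.DataFrame, gene_group: str = "all-targeted", region: str = "all"):
    """Nonsynonymous-to-noncoding variant ratios.

    Returns ``(group_ratios, per_individual)``: group ratio per diagnosis
    (summed nonsynonymous / summed noncoding, NaN when the denominator is
    zero) and a per-individual frame with an ``undefined`` flag for
    zero-denominator rows.
    """
    df = table[(table["gene_group"] == gene_group) & (table["region"] == region)]
    piv = (
        df[df["category"].isin(["nonsynonymous", "noncoding"])]
        .pivot_table(index=["individual", "diagnosis"], columns="category", values="count")
        .reset_index()
    )
    piv["undefined"] = piv["noncoding"] == 0
    piv["ratio"] = np.where(piv["undefined"], np.nan, piv["nonsynonymous"] / piv["noncoding"].replace(0, np.nan))
    group = {}
    for diag, sub in piv.groupby("diagnosis"):
        denom = sub["noncoding"].sum()
        group[diag] = float(sub["nonsynonymous"].sum() / denom) if denom else float("nan")
    return group, piv
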