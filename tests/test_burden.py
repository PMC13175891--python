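"""Burden tabulation, exact 2x2 enrichment and the mixed model."""

import numpy as np
import pytest

from mipmosaic.burden import (
    fisher_enrichment,
    mixed_model_enrichment,
    ns_noncoding_ratio,
    tabulate_burden,
)
from mipmosaic.somatic import UniqueVariant
from mipmosaic.synthetic_data import (
    BENIGN_VERDICT,
    DEFAULT_GENE_PANEL,
    simulate_burden_table,
)
from mipmosaic.types import AnnotationRecord, SampleMeta, Variant

from oracles import or_conditional_mle_bruteforce


def _meta(ind, diagnosis, regions=("PFC", "PMC")):
    return [
        SampleMeta(sample_id=f"{ind}.{r}", individual=ind, diagnosis=diagnosis, region=r,
                   mean_depth=1800.0, sex="F", pmi_hours=20.0, batch="b1")
        for r in regions
    ]


def _uv(ind, pos, regions=("PFC",)):
    v = Variant("SOD1L", pos, "A", "T")
    return v, UniqueVariant(
        individual=ind, variant=v, regions=list(regions),
        vaf_by_region={r: 0.02 for r in regions},
    )


def _ann(v, consequence):
    return AnnotationRecord(
        variant=v, gene=v.contig, consequence=consequence,
        predictor_verdicts=dict(BENIGN_VERDICT), pop_af_by_ancestry={},
    )


def test_tabulate_category_counts():
    meta = _meta("i1", "ALS") + _meta("c1", "control")
    variants, annotations = [], {}
    for pos, cons in ((10, "missense"), (20, "synonymous"), (30, "intronic")):
        v, u = _uv("i1", pos)
        variants.append(u)
        annotations[v] = _ann(v, cons)
    table = tabulate_burden(variants, annotations, meta, {}, DEFAULT_GENE_PANEL)
    row = table[
        (table.individual == "i1") & (table.region == "all") & (table.gene_group == "all-targeted")
    ].set_index("category")["count"]
    assert row["all"] == 3
    assert row["exonic"] == 2
    assert row["protein-altering"] == 1
    assert row["intronic"] == 1


def test_tabulate_excludes_germline_positive_cases_keeps_controls():
    meta = _meta("i1", "ALS") + _meta("c1", "control")
    status = {"i1": "germline-positive", "c1": "germline-positive"}
    table = tabulate_burden([], {}, meta, status, DEFAULT_GENE_PANEL)
    assert "i1" not in set(table.individual)
    assert "c1" in set(table.individual)


def test_tabulate_empty_cohort():
    table = tabulate_burden([], {}, [], {}, DEFAULT_GENE_PANEL)
    assert table.empty


def test_tabulate_missing_annotation_errors():
    meta = _meta("i1", "ALS")
    _, u = _uv("i1", 10)
    with pytest.raises(KeyError):
        tabulate_burden([u], {}, meta, {}, DEFAULT_GENE_PANEL)


# --- exact 2x2 ---------------------------------------------------------------


def test_fisher_symmetric_table_is_unity():
    r = fisher_enrichment(10, 100, 10, 100)
    assert r.odds_ratio == pytest.approx(1.0, abs=1e-9)


def test_fisher_als_and_ftd_printed_values():
    """Carrier counts recovered from the reported germline-enrichment
    percentages reproduce the published odds ratios."""
    r = fisher_enrichment(41, 291, 7, 144)
    assert r.odds_ratio == pytest.approx(3.20, abs=0.02)
    assert r.ci_low == pytest.approx(1.37, abs=0.02)
    assert r.ci_high == pytest.approx(8.69, abs=0.02)
    assert r.p_value == pytest.approx(3.2e-3, rel=0.05)
    r = fisher_enrichment(22, 117, 7, 144)
    assert r.odds_ratio == pytest.approx(4.51, abs=0.02)


def test_fisher_degenerate_margin_flagged():
    r = fisher_enrichment(0, 50, 0, 60)
    assert not r.defined


def test_fisher_invalid_counts():
    with pytest.raises(ValueError):
        fisher_enrichment(10, 5, 0, 10)


def test_fisher_matches_bruteforce_mle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        n1 = int(rng.integers(5, 120))
        n2 = int(rng.integers(5, 120))
        a = int(rng.integers(0, n1 + 1))
        b = int(rng.integers(0, n2 + 1))
        r = fisher_enrichment(a, n1, b, n2)
        if not r.defined:
            continue
        oracle = or_conditional_mle_bruteforce(a, n1, b, n2)
        if np.isinf(oracle):
            assert np.isinf(r.odds_ratio)
        elif oracle == 0.0:
            assert r.odds_ratio == pytest.approx(0.0, abs=1e-6)
        else:
            assert r.odds_ratio == pytest.approx(oracle, rel=1e-5, abs=1e-6)


# --- mixed model -------------------------------------------------------------


def test_mixed_model_collapses_to_mean_difference():
    """With identical covariates and a single batch the fit reduces to the
    two-sample difference of group means."""
    import pandas as pd

    rng = np.random.default_rng(3)
    n = 60
    df = pd.DataFrame(
        {
            "individual": [f"i{k}" for k in range(n)],
            "diagnosis": ["ALS"] * (n // 2) + ["control"] * (n // 2),
            "count": rng.poisson(1.0, size=n),
            "mean_depth": 1800.0,
            "sex": "F",
            "pmi_hours": 24.0,
            "batch": "b1",
            "n_samples": 5,
        }
    )
    with pytest.warns(UserWarning):
        res = mixed_model_enrichment(df, "ALS")
    expected = df[df.diagnosis == "ALS"]["count"].mean() - df[df.diagnosis == "control"]["count"].mean()
    assert res.effect == pytest.approx(expected, abs=1e-8)
    assert res.model == "ols"


def test_mixed_model_detects_implanted_burden():
    tab = simulate_burden_table(200, 100, effect=0.5, seed=12)
    res = mixed_model_enrichment(tab, "ALS")
    assert res.model == "mixed"
    assert res.effect > 0
    assert res.p_value < 0.05
    assert res.ci_low < res.effect < res.ci_high


def test_mixed_model_requires_two_groups():
    tab = simulate_burden_table(10, 10, effect=0.0, seed=1)
    with pytest.raises(ValueError):
        mixed_model_enrichment(tab[tab.diagnosis == "control"], "ALS")


# --- ratios ------------------------------------------------------------------


def _ratio_table():
    meta = _meta("i1", "ALS") + _meta("i2", "ALS") + _meta("c1", "control")
    variants, annotations = [], {}
    specs = [
        ("i1", 10, "missense"), ("i1", 20, "noncoding"), ("i1", 30, "noncoding"),
        ("i2", 40, "nonsense"), ("i2", 50, "noncoding"),
        ("c1", 60, "noncoding"),
    ]
    for ind, pos, cons in specs:
        v, u = _uv(ind, pos)
        variants.append(u)
        annotations[v] = _ann(v, cons)
    return tabulate_burden(variants, annotations, meta, {}, DEFAULT_GENE_PANEL)


def test_ns_noncoding_group_ratio():
    group, per_ind = ns_noncoding_ratio(_ratio_table())
    assert group["ALS"] == pytest.approx(2 / 3)
    assert group["control"] == pytest.approx(0.0)
    flagged = per_ind[per_ind.undefined]
    assert flagged.empty  # all rows here have noncoding counts


def test_ns_ratio_zero_denominator_flagged():
    meta = _meta("i1", "ALS")
    v, u = _uv("i1", 10)
    table = tabulate_burden([u], {v: _ann(v, "missense")}, meta, {}, DEFAULT_GENE_PANEL)
    group, per_ind = ns_noncoding_ratio(table)
    assert np.isnan(group["ALS"])
    assert per_ind.undefined.all()


def test_ns_ratio_invariant_to_individual_permutation():
    t = _ratio_table()
    g1, _ = ns_noncoding_ratio(t)
    g2, _ = ns_noncoding_ratio(t.sample(frac=1.0, random_state=0))
    assert g1 == g2
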