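"""Binomial enrichment test, BH adjustment, and the gbM labelling rules,
checked against exact-arithmetic and loop-based oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbmscan.classify import (
    GbmEnrichmentModel,
    bh_adjust,
    binomial_enrichment_p,
    classify_genes,
    estimate_background,
)
from gbmscan.metrics import summarize_genes

from conftest import make_genes, make_records


def exact_upper_tail(k, n, p0):
    """P(X ≥ k) by exact rational enumeration."""
    p = Fraction(p0)
    return float(sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)))


def bh_suffix_min(pvals):
    """min-over-suffix step-up computed with explicit loops."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = float("inf")
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        q[i] = min(running, 1.0)
    return q


def test_zero_successes_give_p_one():
    for n in (1, 5, 50):
        assert binomial_enrichment_p(0, n, 0.1) == 1.0


def test_single_trial_tail():
    assert binomial_enrichment_p(1, 1, 0.25) == pytest.approx(0.25, rel=1e-12)


def test_example_tail_against_enumeration():
    assert binomial_enrichment_p(8, 20, 0.1) == pytest.approx(
        exact_upper_tail(8, 20, 0.1), rel=1e-12
    )


def test_zero_reads_is_undefined():
    assert np.isnan(binomial_enrichment_p(0, 0, 0.1))


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        binomial_enrichment_p(5, 3, 0.1)
    with pytest.raises(ValueError):
        binomial_enrichment_p(1, 3, 0.0)


def test_bh_hand_example():
    np.testing.assert_allclose(
        bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )


def test_bh_single_p_is_identity():
    assert bh_adjust([0.2])[0] == 0.2


def test_bh_empty_and_nan_passthrough():
    assert bh_adjust([]).size == 0
    q = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and not np.isnan(q[0])


@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_suffix_min_oracle(pvals):
    np.testing.assert_array_equal(bh_adjust(pvals), bh_suffix_min(pvals))


@given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=60))
def test_bh_q_at_least_p_and_monotone(pvals):
    q = bh_adjust(pvals)
    p = np.asarray(pvals)
    assert (q >= p - 1e-15).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-15).all()


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(4)
    p = rng.uniform(1e-6, 1, 200)
    np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


def test_background_formula_and_clamp():
    records = make_records(
        [
            ("chr1", 5, "+", "CG", 3, 10),
            ("chr1", 30, "+", "CG", 2, 5),
            ("chr1", 6, "+", "CHG", 5, 5),
            ("chr1", 7, "+", "CHH", 1, 9),
        ]
    )
    genes = make_genes([("g1", "chr1", "+", 1, 10), ("g2", "chr1", "+", 20, 40)])
    bg = estimate_background(records, genes)
    assert bg["CG"] == pytest.approx(5 / 15)
    assert bg["CHG"] == pytest.approx(1 - 1e-9)  # fully methylated, clamped


def test_background_requires_coverage_per_context():
    records = make_records([("chr1", 5, "+", "CG", 3, 10)])
    genes = make_genes([("g1", "chr1", "+", 1, 10)])
    with pytest.raises(ValueError, match="background"):
        estimate_background(records, genes)


def _one_gene_summaries(cg=(25, 30, 15), chg=(1, 20, 5), chh=(1, 25, 5)):
    row = {"gene_id": "g1"}
    for ctx, (mc, cov, sites) in zip(("CG", "CHG", "CHH"), (cg, chg, chh)):
        row[f"{ctx}_sites"] = sites
        row[f"{ctx}_meth_sites"] = min(mc, sites)
        row[f"{ctx}_mc"] = mc
        row[f"{ctx}_cov"] = cov
    return pd.DataFrame([row])


def test_single_gene_gbm_example():
    """15 covered CG sites, strong CG enrichment, background non-CG: gbM.

    With one gene per context m=1, so q = p; the expected tails come from
    exact enumeration.
    """
    bg = {"CG": 0.10, "CHG": 0.05, "CHH": 0.05}
    table = classify_genes(_one_gene_summaries(), bg)
    row = table.iloc[0]
    assert row.CG_q == pytest.approx(exact_upper_tail(25, 30, 0.1), rel=1e-9)
    assert row.CG_q < 0.05
    assert row.CHG_q == pytest.approx(exact_upper_tail(1, 20, 0.05), rel=1e-9)
    assert row.CHG_q > 0.05 and row.CHH_q > 0.05
    assert row.label == "gbM"


def test_too_few_cg_sites_is_unclassified():
    table = classify_genes(_one_gene_summaries(cg=(25, 30, 5)), {"CG": 0.1, "CHG": 0.05, "CHH": 0.05})
    assert table.iloc[0].label == "unclassified"


def test_undefined_noncg_defaults_to_not_enriched():
    summaries = _one_gene_summaries(chg=(0, 0, 0), chh=(0, 0, 0))
    bg = {"CG": 0.1, "CHG": 0.05, "CHH": 0.05}
    assert classify_genes(summaries, bg).iloc[0].label == "gbM"
    strict = classify_genes(summaries, bg, strict_noncg=True)
    assert strict.iloc[0].label == "unclassified"


def test_te_like_pattern_is_multi_context():
    summaries = _one_gene_summaries(cg=(25, 30, 15), chg=(18, 20, 5), chh=(20, 25, 5))
    bg = {"CG": 0.10, "CHG": 0.05, "CHH": 0.05}
    assert classify_genes(summaries, bg).iloc[0].label == "multi_context"


def test_labels_partition_fixture(default_mixture):
    _, genes, records, _ = default_mixture
    fit = GbmEnrichmentModel.from_records(records, genes).fit()
    assert fit.label_counts().sum() == len(genes)
    assert (fit.table["CG_q"].dropna() >= fit.table["CG_p"].dropna() - 1e-15).all()


def test_classification_invariant_to_gene_order(small_methylome):
    _, genes, records, _ = small_methylome
    s = summarize_genes(records, genes)
    bg = estimate_background(records, genes)
    a = classify_genes(s, bg).set_index("gene_id")
    shuffled = s.sample(frac=1.0, random_state=5).reset_index(drop=True)
    b = classify_genes(shuffled, bg).set_index("gene_id")
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def test_alpha_monotonicity(small_methylome):
    """Raising alpha never shrinks the gbM set when non-CG tests are far from
    the threshold (as in this fixture, where non-CG q ≈ 1 for gbM genes)."""
    _, genes, records, _ = small_methylome
    s = summarize_genes(records, genes)
    bg = estimate_background(records, genes)
    t1 = classify_genes(s, bg, alpha=0.01)
    t2 = classify_genes(s, bg, alpha=0.05)
    set1 = set(t1.loc[t1["label"] == "gbM", "gene_id"])
    set2 = set(t2.loc[t2["label"] == "gbM", "gene_id"])
    noncg_clear = (
        t2[["CHG_q", "CHH_q"]].fillna(1.0).min(axis=1) > 0.05
    )
    assert set1 - set(t2.loc[noncg_clear, "gene_id"]) <= set2
    assert set1 <= set2


def test_site_mode_runs(small_methylome):
    _, genes, records, _ = small_methylome
    s = summarize_genes(records, genes)
    bg = estimate_background(records, genes)
    table = classify_genes(s, bg, unit="sites")
    assert set(table["label"]).issubset(
        {"gbM", "mCHG_enriched", "mCHH_enriched", "multi_context", "unmethylated", "unclassified"}
    )


def test_fixture_labels_match_rule_chain_oracle(small_methylome):
    """End-to-end: labels equal a loop-based reimplementation of the rule
    chain (binomial tails per gene, per-context BH, threshold logic)."""
    _, genes, records, _ = small_methylome
    s = summarize_genes(records, genes)
    bg = estimate_background(records, genes)
    fit = GbmEnrichmentModel(s, bg).fit()

    from scipy.stats import binom

    qs = {}
    for ctx in ("CG", "CHG", "CHH"):
        ps = []
        for _, row in s.iterrows():
            n, k = row[f"{ctx}_cov"], row[f"{ctx}_mc"]
            ps.append(float(binom.sf(k - 1, n, bg[ctx])) if n > 0 else np.nan)
        qs[ctx] = bh_suffix_min([p for p in ps if not np.isnan(p)])
        it = iter(qs[ctx])
        qs[ctx] = [next(it) if not np.isnan(p) else np.nan for p in ps]
    expected = []
    for i, row in s.iterrows():
        sig = {c: (not np.isnan(qs[c][i])) and qs[c][i] < 0.05 for c in ("CG", "CHG", "CHH")}
        if row["CG_sites"] < 10 or np.isnan(qs["CG"][i]):
            expected.append("unclassified")
        elif sig["CG"] and not sig["CHG"] and not sig["CHH"]:
            expected.append("gbM")
        elif sum(sig.values()) >= 2:
            expected.append("multi_context")
        elif sig["CHG"]:
            expected.append("mCHG_enriched")
        elif sig["CHH"]:
            expected.append("mCHH_enriched")
        else:
            expected.append("unmethylated")
    assert fit.table["label"].tolist() == expected


def test_summary_reports_counts(small_methylome):
    _, genes, records, _ = small_methylome
    fit = GbmEnrichmentModel.from_records(records, genes).fit()
    text = fit.summary()
    assert "gbM" in text and "background p0" in text
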