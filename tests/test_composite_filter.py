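"""Replicate filter selection, composite aggregation, score-set comparison."""

import numpy as np
import pandas as pd
import pytest

import mave_integrate as mi
from conftest import LOW_SKEW_N_WEIGHTS, control_scores, make_score_table
from mave_integrate.composite_filter import (
    FilterConfig,
    FilterSelectionError,
    check_aggregation_compatibility,
)


def test_perfect_separation_passes_all_bootstraps():
    scores = control_scores(seed=0, sd=1e-6, fixed_n=8)
    ev = mi.evaluate_filter_value(scores, 0, FilterConfig(seed=0))
    assert ev.pass_fraction == 1.0
    assert ev.observed_pass


@pytest.mark.parametrize("randomize", [False, True])
def test_identical_control_distributions_rarely_pass(randomize):
    """Test size: same-distribution controls pass at most ~5% of bootstraps."""
    rng = np.random.default_rng(42)
    tokens = [f"A{i}A" for i in range(2, 62)] + [f"A{i}*" for i in range(62, 122)]
    vals = rng.normal(0.5, 0.1, size=(120, 8))
    mask = rng.random((120, 8)) < 0.4
    vals[mask] = np.nan
    df = pd.DataFrame(vals, index=tokens, columns=[f"rep{i}" for i in range(1, 9)])
    scores = mi.ScoreTable(df)
    cfg = FilterConfig(n_boot=1000, seed=1, randomize_association=randomize)
    ev = mi.evaluate_filter_value(scores, 0, cfg)
    mc_sd = np.sqrt(0.05 * 0.95 / cfg.n_boot)
    assert ev.pass_fraction <= 0.05 + 2 * mc_sd


def test_filter_too_high_insufficient_controls():
    scores = control_scores(seed=0, fixed_n=4)
    ev = mi.evaluate_filter_value(scores, 5, FilterConfig(seed=0))
    assert not ev.observed_pass
    assert ev.reason == "insufficient controls"


def test_select_clean_data_returns_zero():
    """With clean scores at every replicate count, the minimal filter wins."""
    scores = control_scores(seed=2, sd=0.02)
    sel = mi.select_replicate_filter(scores, FilterConfig(seed=2))
    assert sel.k_star == 0
    again = mi.select_replicate_filter(scores, FilterConfig(seed=2))
    assert again.k_star == sel.k_star


def test_select_adversarial_low_replicate_noise():
    """Pure-noise scores for variants seen in <= 2 replicates force k* >= 3."""
    scores = control_scores(seed=3, noise_below=2, n_weights=LOW_SKEW_N_WEIGHTS)
    sel = mi.select_replicate_filter(scores, FilterConfig(seed=3))
    assert sel.k_star >= 3
    report = sel.report()
    assert (report.loc[report.k < 3, "pass_fraction"] < 0.95).all()


def test_select_no_k_passes_lists_fractions():
    # controls identically distributed at every replicate count
    scores = control_scores(seed=4, syn_loc=0.5, non_loc=0.5, sd=0.2)
    with pytest.raises(FilterSelectionError, match="k=0"):
        mi.select_replicate_filter(scores, FilterConfig(seed=4))


# ---------------------------------------------------------------------------
# Composite aggregation
# ---------------------------------------------------------------------------


def test_aggregate_composite_arithmetic():
    scores = make_score_table({
        "A2V": [1.0, 1.0, 1.0],
        "A3V": [0.4, 0.6],
        "A4V": [0.2, 0.4, 0.6],
    })
    comp = mi.aggregate_composite(scores, 3)
    assert "A3V" not in comp.index  # below the filter
    assert comp.loc["A2V", "score"] == 1.0
    assert comp.loc["A2V", "sd"] == 0.0
    assert comp.loc["A2V", "cv"] == 0.0
    assert comp.loc["A4V", "score"] == pytest.approx(0.4)
    assert comp.loc["A4V", "sd"] == pytest.approx(0.2)
    assert comp.loc["A4V", "se"] == pytest.approx(0.2 / np.sqrt(3), abs=1e-5)


def test_composite_order_invariance_and_se_shrinkage():
    a = make_score_table({"A2V": [0.2, 0.6, 0.4]})
    b = make_score_table({"A2V": [0.4, 0.2, 0.6]})
    ca = mi.aggregate_composite(a, 0)
    cb = mi.aggregate_composite(b, 0)
    assert ca.loc["A2V", "score"] == pytest.approx(cb.loc["A2V", "score"],
                                                   rel=1e-12)
    # appending a replicate equal to the mean keeps the mean, shrinks se
    c = make_score_table({"A2V": [0.2, 0.6, 0.4, 0.4]})
    cc = mi.aggregate_composite(c, 0)
    assert cc.loc["A2V", "score"] == pytest.approx(ca.loc["A2V", "score"],
                                                   rel=1e-12)
    assert cc.loc["A2V", "se"] < ca.loc["A2V", "se"]


def test_cv_undefined_near_nonsense_anchor():
    comp = mi.aggregate_composite(make_score_table({"A2*": [0.01, -0.01, 0.02]}), 0)
    assert bool(comp.loc["A2*", "cv_undefined"])
    assert np.isnan(comp.loc["A2*", "cv"])


def test_raising_filter_never_increases_variant_count():
    scores = control_scores(seed=6, noise_below=2)
    counts = [len(mi.aggregate_composite(scores, k)) for k in range(0, 9)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_higher_filter_reduces_control_cv():
    """With noisy low-replicate scores, filtering improves mean |cv|."""
    scores = control_scores(seed=7, noise_below=2, syn_loc=1.0, sd=0.05)
    cv_at = {}
    for k in (0, 3):
        comp = mi.aggregate_composite(scores, k)
        syn = comp[(comp.consequence == "synonymous") & (comp.n_reps >= 2)]
        cv_at[k] = syn["cv"].abs().mean()
    assert cv_at[3] <= cv_at[0]


# ---------------------------------------------------------------------------
# Abundance confidence classes
# ---------------------------------------------------------------------------


def make_composite(rows):
    df = pd.DataFrame(rows).set_index("variant")
    df["sd"] = df["se"]
    df["n_reps"] = 4
    return df


def control_rows():
    rows = []
    for i in range(5):
        rows.append({"variant": f"G{i + 50}G", "consequence": "synonymous",
                     "score": 0.8 + 0.05 * i, "se": 0.01})
        rows.append({"variant": f"G{i + 60}*", "consequence": "nonsense",
                     "score": 0.0 + 0.05 * i, "se": 0.01})
    return rows


@pytest.mark.parametrize(
    "score, se, expected",
    [(1.0, 0.01, "wt_like"), (0.0, 0.01, "low"), (0.5, 0.01, "unclassified"),
     (0.5, 5.0, "unclassified")],
)
def test_classify_abundance_confidence(score, se, expected):
    comp = make_composite(
        control_rows()
        + [{"variant": "A2V", "consequence": "missense", "score": score, "se": se}]
    )
    out = mi.classify_abundance_confidence(comp)
    assert out.loc["A2V", "abundance_class"] == expected
    assert out.attrs["q_syn"] > out.attrs["q_non"]


def test_classify_requires_threshold_separation():
    rows = []
    for i in range(5):
        rows.append({"variant": f"G{i + 50}G", "consequence": "synonymous",
                     "score": 0.5, "se": 0.01})
        rows.append({"variant": f"G{i + 60}*", "consequence": "nonsense",
                     "score": 0.5, "se": 0.01})
    with pytest.raises(ValueError, match="separate"):
        mi.classify_abundance_confidence(make_composite(rows))


# ---------------------------------------------------------------------------
# Score-set comparison
# ---------------------------------------------------------------------------


def test_compare_score_sets_identity_and_affine():
    rng = np.random.default_rng(8)
    a = pd.Series(rng.random(50), index=[f"A{i}V" for i in range(2, 52)])
    res = mi.compare_score_sets(a, a)
    assert res["slope"] == pytest.approx(1.0)
    assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
    assert res["pearson_r2"] == pytest.approx(1.0)
    res2 = mi.compare_score_sets(a, 2 * a + 1)
    assert res2["slope"] == pytest.approx(2.0)
    assert res2["intercept"] == pytest.approx(1.0)


def test_compare_score_sets_three_points():
    # y = 0.1 + 0.8 x exactly: closed-form OLS gives slope .8, intercept .1
    a = pd.Series([0.0, 0.5, 1.0], index=["A2V", "A3V", "A4V"])
    b = pd.Series([0.1, 0.5, 0.9], index=["A2V", "A3V", "A4V"])
    res = mi.compare_score_sets(a, b)
    assert res["slope"] == pytest.approx(0.8)
    assert res["intercept"] == pytest.approx(0.1)
    assert res["pearson_r2"] == pytest.approx(1.0)
    assert res["n_overlap"] == 3


def test_compare_score_sets_requires_overlap():
    a = pd.Series([1.0, 2.0], index=["A2V", "A3V"])
    with pytest.raises(ValueError, match=">= 3"):
        mi.compare_score_sets(a, a)


def test_aggregation_gate():
    rng = np.random.default_rng(9)
    a = pd.Series(rng.random(100), index=[f"A{i}V" for i in range(2, 102)])
    ok, fit = check_aggregation_compatibility(a, a + rng.normal(0, 0.01, 100))
    assert ok
    bad, _ = check_aggregation_compatibility(a, 0.5 * a + 0.4)
    assert not bad
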