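"""Generator contracts: determinism, mixtures, sorting physics, closure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mave_integrate as mi
from mave_integrate.synthetic_data import (
    ACTIVITY_LOSS_CUTOFF_LOG10,
    ACTIVITY_WT_CUTOFF_LOG10,
    TrueLibrary,
)


def small_cfg(**kw):
    base = dict(n_variants=120, n_replicates=4, reads_per_bin=5000,
                n_synonymous=20, n_nonsense=20, seed=0)
    base.update(kw)
    return mi.SortSimConfig(**base)


def test_generate_library_deterministic():
    cfg = small_cfg(seed=7)
    a = mi.generate_library(cfg)
    b = mi.generate_library(cfg)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.presence, b.presence)


def test_degenerate_mixture_all_wt_like():
    cfg = small_cfg(class_mixture={"wt_like": 1.0, "loss_abundance_only": 0.0,
                                   "loss_activity_only": 0.0, "loss_both": 0.0})
    lib = mi.generate_library(cfg)
    missense = lib.truth[lib.truth.consequence == "missense"]
    assert (missense.true_class == "wt_like").all()
    assert (missense.true_abundance >= 0.8).all()


def test_class_counts_within_binomial_bounds():
    cfg = mi.SortSimConfig(n_variants=1000, seed=7,
                           class_mixture={"wt_like": 0.5, "loss_abundance_only": 0.2,
                                          "loss_activity_only": 0.1, "loss_both": 0.2})
    lib = mi.generate_library(cfg)
    missense = lib.truth[lib.truth.consequence == "missense"]
    n = len(missense)
    for cls, p in cfg.class_mixture.items():
        k = int((missense.true_class == cls).sum())
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        assert lo <= k <= hi, (cls, k, lo, hi)


def test_library_control_invariants():
    lib = mi.generate_library(small_cfg())
    syn = lib.truth[lib.truth.consequence == "synonymous"]
    non = lib.truth[lib.truth.consequence == "nonsense"]
    assert len(syn) == 20 and len(non) == 20
    assert (syn.true_abundance > 0.9).all()
    assert (non.true_abundance < 0.1).all()
    act = np.log10(lib.truth.true_activity_raw)
    wt_act = lib.truth.true_class.isin(["wt_like", "loss_abundance_only"])
    assert (act[wt_act] > ACTIVITY_WT_CUTOFF_LOG10).all()
    assert (act[~wt_act] < ACTIVITY_LOSS_CUTOFF_LOG10).all()


def test_too_few_variants_for_controls():
    with pytest.raises(ValueError, match="too small"):
        mi.generate_library(small_cfg(n_variants=30))


def test_saturation_library_covers_positions(bundled_cds):
    lib = mi.generate_library(small_cfg(), cds=bundled_cds)
    missense = lib.truth[lib.truth.consequence == "missense"]
    per_pos = missense.variant.map(lambda t: mi.parse_variant(t).position)
    # consecutive saturation: early positions carry all 19 substitutions
    assert per_pos.value_counts().max() == 19
    prot = bundled_cds.translate()
    for tok in missense.variant.head(30):
        v = mi.parse_variant(tok)
        assert prot[v.position - 1] == v.wt_aa


# ---------------------------------------------------------------------------
# Sorting simulation
# ---------------------------------------------------------------------------


def test_read_conservation_and_determinism():
    cfg = small_cfg(seed=3)
    lib = mi.generate_library(cfg)
    a = mi.simulate_sort_replicate(lib, cfg, 0)
    b = mi.simulate_sort_replicate(lib, cfg, 0)
    pd.testing.assert_frame_equal(a.counts, b.counts)
    # every bin sequenced to depth reads_per_bin, total 4x
    assert (a.depths == cfg.reads_per_bin).all()
    assert a.counts.to_numpy().sum() == 4 * cfg.reads_per_bin


def test_replicates_differ():
    cfg = small_cfg(seed=3, dropout_rate=0.0)
    lib = mi.generate_library(cfg)
    a = mi.simulate_sort_replicate(lib, cfg, 0)
    b = mi.simulate_sort_replicate(lib, cfg, 1)
    assert not a.counts.equals(b.counts)


def test_zero_noise_top_variant_in_top_bin():
    # one variant at abundance 1.0 over a population spanning [0, 1]
    tokens = [f"A{i}V" for i in range(2, 102)]
    truth = pd.DataFrame({
        "variant": tokens,
        "consequence": "missense",
        "true_abundance": np.linspace(0.0, 1.0, 100),
        "true_activity_raw": 0.5,
        "true_class": "wt_like",
    })
    presence = pd.DataFrame(True, index=tokens, columns=["rep1"])
    lib = TrueLibrary(truth=truth, presence=presence)
    cfg = small_cfg(n_variants=120, fluorescence_noise_sd=1e-12, n_replicates=1)
    bct = mi.simulate_sort_replicate(lib, cfg, 0)
    top = bct.counts.loc["A101V"]
    assert top["bin4"] / top.sum() > 0.99


def test_dropout_removes_variants():
    cfg = small_cfg(seed=5, dropout_rate=0.5)
    lib = mi.generate_library(cfg)
    bct = mi.simulate_sort_replicate(lib, cfg, 0)
    assert set(bct.counts.index) == set(lib.presence.index[lib.presence.iloc[:, 0]])
    assert len(bct.counts) < cfg.n_variants


def test_zero_reads_rejected():
    cfg = small_cfg()
    lib = mi.generate_library(cfg)
    with pytest.raises(ValueError, match="reads_per_bin"):
        mi.simulate_sort_replicate(lib, small_cfg(reads_per_bin=0), 0)


def test_mean_bin_index_monotone_in_abundance(bundled_cds):
    """Higher true abundance gives stochastically higher mean bin index."""
    cfg = mi.SortSimConfig(n_variants=1000, fluorescence_noise_sd=0.15,
                           dropout_rate=0.0, seed=3)
    lib = mi.generate_library(cfg, cds=bundled_cds)
    bct = mi.simulate_sort_replicate(lib, cfg, 0)
    c = bct.counts.to_numpy()
    mean_bin = (c * np.arange(1, 5)).sum(axis=1) / c.sum(axis=1)
    truth = lib.truth.set_index("variant").loc[bct.counts.index, "true_abundance"]
    rho = stats.spearmanr(truth, mean_bin).statistic
    assert rho > 0.95


# ---------------------------------------------------------------------------
# Activity scores
# ---------------------------------------------------------------------------


def test_activity_zero_noise_respects_cutoffs():
    lib = mi.generate_library(small_cfg())
    act = mi.generate_activity_scores(lib, seed=0, noise_sd_log10=0.0)
    raw = act.df["activity_raw"]
    truth = lib.truth.set_index("variant")
    active = truth.true_class.isin(["wt_like", "loss_abundance_only"])
    assert (raw[active.index[active]] > 10 ** ACTIVITY_WT_CUTOFF_LOG10).all()
    assert (raw[active.index[~active]] < 10 ** ACTIVITY_LOSS_CUTOFF_LOG10).all()


def test_activity_misclassification_rate_under_noise():
    cfg = mi.SortSimConfig(n_variants=500, seed=11)
    lib = mi.generate_library(cfg)
    act = mi.generate_activity_scores(lib, seed=11, noise_sd_log10=0.1)
    calls = mi.classify_activity(act.df["activity_raw"])
    truth = lib.truth.set_index("variant")
    expected = truth.true_class.isin(["wt_like", "loss_abundance_only"]).map(
        {True: "wt_like", False: "loss"}
    )
    assert (calls != expected).mean() < 0.05


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------


def test_catalog_null_case_matches_spectrum(bundled_cds):
    spectrum = mi.null_spectrum(bundled_cds)
    cmap = mi.assign_null_classes(spectrum, seed=4)
    folds = {c: 1.0 for c in mi.CLASSES}
    cat = mi.generate_cancer_catalog(spectrum, cmap, folds, 20_000, seed=4)
    obs, n = mi.observed_class_fractions(cat, cmap)
    expected = mi.null_spectrum(bundled_cds, class_map=cmap).expected_class_fractions()
    assert n == 20_000
    # multinomial error at n=20k: a few sd of ~0.004
    assert (obs - expected).abs().max() < 0.02


def test_catalog_empty_and_zero_weights(bundled_cds):
    spectrum = mi.null_spectrum(bundled_cds)
    cmap = mi.assign_null_classes(spectrum, seed=4)
    empty = mi.generate_cancer_catalog(spectrum, cmap,
                                       {c: 1.0 for c in mi.CLASSES}, 0, seed=4)
    assert len(empty.df) == 0
    with pytest.raises(ValueError, match="zero"):
        mi.generate_cancer_catalog(spectrum, cmap,
                                   {c: 0.0 for c in mi.CLASSES}, 10, seed=4)


# ---------------------------------------------------------------------------
# Toy CDS
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_codons", [2, 3, 10, 50])
def test_generate_toy_cds(n_codons):
    cds = mi.generate_toy_cds(n_codons, seed=9)
    assert cds.n_codons == n_codons
    assert cds.nucleotides.startswith("ATG")
    assert cds.has_terminal_stop
    assert "*" not in cds.translate()[:-1]
    assert cds.nucleotides == mi.generate_toy_cds(n_codons, seed=9).nucleotides


def test_toy_cds_requires_two_codons():
    with pytest.raises(ValueError):
        mi.generate_toy_cds(1)
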