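"""Replicate-count filtering and composite abundance scores.

Variants sequenced in only a handful of sorting replicates carry noisy
scores.  The replicate filter demands that a variant be observed in at
least k* replicates, where k* is chosen as the smallest value at which the
synonymous and nonsense control distributions separate reliably: the upper
bound of the 95% confidence interval of the mean nonsense composite score
must fall below the 5th percentile of synonymous composite scores.
Reliability is measured by bootstrap: control (score, replicate-count)
pairs are resampled within each class and the separation test repeated;
k* is the smallest k whose bootstrap pass fraction reaches the configured
threshold (default 0.95).

``randomize_association=True`` additionally shuffles the replicate-count
labels across the pooled controls in each bootstrap — a null calibration
that destroys the count/quality association the filter exploits, useful to
verify that a chosen k* is not an artifact.

Composite scores are the plain mean of a variant's replicate scores after
the filter, reported with sample sd, standard error, and coefficient of
variation, plus a confidence class (wt_like / low / unclassified) from the
control percentile thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_variants import NONSENSE, SYNONYMOUS, ScoreTable, parse_variant


@dataclass
class FilterConfig:
    k_range: Sequence[int] = tuple(range(0, 16))
    n_boot: int = 100
    ci_level: float = 0.95
    syn_tail: float = 0.05
    pass_fraction: float = 0.95
    seed: int = 0
    #: "normal" (mean +/- z*se over nonsense variants) or
    #: "bootstrap_percentile" (percentile CI of the mean over resamples)
    ci_method: str = "normal"
    randomize_association: bool = False
    min_controls: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.syn_tail < 0.5):
            raise ValueError("syn_tail must be in [0, 0.5)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.ci_method not in ("normal", "bootstrap_percentile"):
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


@dataclass
class FilterEvaluation:
    k: int
    pass_fraction: float
    observed_pass: bool
    reason: str = ""


class FilterSelectionError(RuntimeError):
    pass


def _composites_and_counts(scores: ScoreTable) -> pd.DataFrame:
    """Per-variant composite (mean over available replicates) and n_reps."""
    df = scores.df
    out = pd.DataFrame(
        {
            "score": df.mean(axis=1, skipna=True),
            "n_reps": df.notna().sum(axis=1),
        }
    )
    out["consequence"] = [parse_variant(t).consequence for t in out.index]
    return out.dropna(subset=["score"])


def _separation_test(
    syn: np.ndarray, non: np.ndarray, cfg: FilterConfig, rng=None
) -> bool:
    """Upper CI bound of the mean nonsense score < lower synonymous tail."""
    q_syn = float(np.percentile(syn, 100.0 * cfg.syn_tail))
    if cfg.ci_method == "normal":
        z = stats.norm.ppf(0.5 + cfg.ci_level / 2.0)
        se = non.std(ddof=1) / np.sqrt(len(non)) if len(non) > 1 else 0.0
        upper = non.mean() + z * se
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        means = rng.choice(non, size=(200, len(non)), replace=True).mean(axis=1)
        upper = float(np.percentile(means, 100.0 * (0.5 + cfg.ci_level / 2.0)))
    return bool(upper < q_syn)


def evaluate_filter_value(
    scores: ScoreTable,
    k: int,
    cfg: FilterConfig | None = None,
    boot_seed: int | None = None,
) -> FilterEvaluation:
    """Bootstrap pass fraction of the control-separation test at filter k.

    Controls are the synonymous and nonsense variants of ``scores``; each
    bootstrap resamples (composite score, n_reps) pairs within class,
    filters at ``n_reps >= k`` and applies the separation test.
    """
    if cfg is None:
        cfg = FilterConfig()
    if boot_seed is None:
        boot_seed = cfg.seed
    comp = _composites_and_counts(scores)
    syn = comp[comp["consequence"] == SYNONYMOUS]
    non = comp[comp["consequence"] == NONSENSE]

    def filtered_pass(s_scores, s_n, n_scores, n_n, rng=None) -> bool | None:
        s_keep = s_scores[s_n >= k]
        n_keep = n_scores[n_n >= k]
        if len(s_keep) < cfg.min_controls or len(n_keep) < cfg.min_controls:
            return None  # insufficient controls
        return _separation_test(s_keep, n_keep, cfg, rng)

    obs = filtered_pass(
        syn["score"].to_numpy(), syn["n_reps"].to_numpy(),
        non["score"].to_numpy(), non["n_reps"].to_numpy(),
    )
    if obs is None:
        return FilterEvaluation(k, 0.0, False, "insufficient controls")

    rng = np.random.default_rng([int(boot_seed), 707, int(k)])
    s_sc, s_n = syn["score"].to_numpy(), syn["n_reps"].to_numpy()
    n_sc, n_n = non["score"].to_numpy(), non["n_reps"].to_numpy()
    n_pass = 0
    n_valid = 0
    for _ in range(cfg.n_boot):
        si = rng.integers(0, len(s_sc), len(s_sc))
        ni = rng.integers(0, len(n_sc), len(n_sc))
        bs_sc, bs_n = s_sc[si], s_n[si]
        bn_sc, bn_n = n_sc[ni], n_n[ni]
        if cfg.randomize_association:
            pooled = np.concatenate([bs_n, bn_n])
            rng.shuffle(pooled)
            bs_n, bn_n = pooled[: len(bs_n)], pooled[len(bs_n):]
        res = filtered_pass(bs_sc, bs_n, bn_sc, bn_n, rng)
        n_valid += 1
        if res:
            n_pass += 1
    frac = n_pass / n_valid if n_valid else 0.0
    return FilterEvaluation(k, frac, bool(obs))


@dataclass
class FilterSelection:
    k_star: int
    evaluations: list[FilterEvaluation]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [e.k for e in self.evaluations],
                "pass_fraction": [e.pass_fraction for e in self.evaluations],
                "observed_pass": [e.observed_pass for e in self.evaluations],
                "reason": [e.reason for e in self.evaluations],
            }
        )


def select_replicate_filter(
    scores: ScoreTable, cfg: FilterConfig | None = None
) -> FilterSelection:
    """Smallest k in ``cfg.k_range`` with bootstrap pass fraction >=
    ``cfg.pass_fraction``; deterministic given ``cfg.seed``."""
    if cfg is None:
        cfg = FilterConfig()
    evals: list[FilterEvaluation] = []
    k_star: int | None = None
    for k in cfg.k_range:
        ev = evaluate_filter_value(scores, int(k), cfg)
        evals.append(ev)
        if k_star is None and ev.pass_fraction >= cfg.pass_fraction:
            k_star = int(k)
    if k_star is None:
        lines = ", ".join(f"k={e.k}: {e.pass_fraction:.2f}" for e in evals)
        raise FilterSelectionError(
            f"no replicate filter value reaches pass fraction "
            f"{cfg.pass_fraction}: {lines}"
        )
    return FilterSelection(k_star=k_star, evaluations=evals)


# ---------------------------------------------------------------------------
# Composite scores
# ---------------------------------------------------------------------------

#: composite scores below this are too close to the nonsense anchor for a
#: meaningful coefficient of variation
CV_MIN_SCORE = 0.05


def aggregate_composite(scores: ScoreTable, k_star: int) -> pd.DataFrame:
    """Composite abundance scores for variants in >= k_star replicates.

    Columns: consequence, n_reps, score (mean), sd (sample), se, cv,
    cv_undefined.  cv is reported only when score > 0.05 (otherwise the
    ratio blows up near the nonsense anchor and cv_undefined is set).
    """
    df = scores.df
    n = df.notna().sum(axis=1)
    keep = n >= max(k_star, 1)
    sub = df[keep]
    mean = sub.mean(axis=1, skipna=True)
    sd = sub.std(axis=1, ddof=1, skipna=True)
    se = sd / np.sqrt(n[keep])
    out = pd.DataFrame(
        {
            "consequence": [parse_variant(t).consequence for t in sub.index],
            "n_reps": n[keep],
            "score": mean,
            "sd": sd,
            "se": se,
        }
    )
    cv_ok = out["score"] > CV_MIN_SCORE
    out["cv"] = (out["sd"] / out["score"]).where(cv_ok)
    out["cv_undefined"] = ~cv_ok
    out.index.name = "variant"
    return out


def classify_abundance_confidence(
    composite: pd.DataFrame,
    syn_tail: float = 0.05,
    non_tail: float = 0.95,
    z: float = 2.0,
) -> pd.DataFrame:
    """Assign wt_like / low / unclassified abundance classes.

    Thresholds are empirical percentiles of the control composites
    (q_syn: lower ``syn_tail`` of synonymous; q_non: upper ``non_tail`` of
    nonsense).  A variant is wt_like when its score minus z*se clears
    q_non and its score plus z*se reaches q_syn; low when the mirrored
    condition holds; otherwise unclassified.
    """
    syn = composite.loc[composite["consequence"] == SYNONYMOUS, "score"]
    non = composite.loc[composite["consequence"] == NONSENSE, "score"]
    if syn.empty or non.empty:
        raise ValueError("composite table must contain both control types")
    q_syn = float(np.percentile(syn, 100.0 * syn_tail))
    q_non = float(np.percentile(non, 100.0 * non_tail))
    if q_syn <= q_non:
        raise ValueError(
            f"control thresholds failed to separate: q_syn {q_syn:.4f} <= "
            f"q_non {q_non:.4f}"
        )
    out = composite.copy()
    score, se = out["score"], out["se"].fillna(np.inf)
    lo, hi = score - z * se, score + z * se
    wt = (lo > q_non) & (hi >= q_syn)
    low = (hi < q_syn) & (lo <= q_non)
    out["abundance_class"] = np.select([wt, low], ["wt_like", "low"], "unclassified")
    out.attrs["q_syn"] = q_syn
    out.attrs["q_non"] = q_non
    return out


def compare_score_sets(a: pd.Series, b: pd.Series) -> dict[str, float]:
    """Agreement of two composite score sets over their shared variants.

    OLS of b on a plus Pearson r^2 and Spearman rho^2; used to decide
    whether two libraries can be aggregated without extra normalization
    (slope near 1, intercept near 0).
    """
    shared = a.dropna().index.intersection(b.dropna().index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 overlapping variants, got {len(shared)}")
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    fit = stats.linregress(x, y)
    rho = stats.spearmanr(x, y).statistic
    return {
        "n_overlap": int(len(shared)),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r2": float(fit.rvalue**2),
        "spearman_rho2": float(rho**2),
    }


def check_aggregation_compatibility(
    a: pd.Series,
    b: pd.Series,
    max_slope_dev: float = 0.15,
    max_intercept: float = 0.15,
) -> tuple[bool, dict[str, float]]:
    """Gate for pooling two score sets: |slope-1| and |intercept| within
    tolerance."""
    fit = compare_score_sets(a, b)
    ok = (
        abs(fit["slope"] - 1.0) <= max_slope_dev
        and abs(fit["intercept"]) <= max_intercept
    )
    return ok, fit
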