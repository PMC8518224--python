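"""Joint abundance x activity classification and class enrichment.

Activity scores come on a raw (log-spread) scale with fixed cutoffs:
WT-like above 10^-1.11 (the lower 95th percentile of synonymous variants
in the source assay) and loss below 10^-2.13 (the upper 95th percentile of
nonsense variants).  Cutoffs are applied on the raw scale; rescaling to a
0-1 reporting scale (mean nonsense -> 0, WT -> 1) is cosmetic.

Crossing the activity call with the abundance confidence class yields four
functional classes — wt_like, loss_abundance_only, loss_activity_only,
loss_both — plus unclassified for variants indeterminate or missing on
either axis.  Category-level fold enrichment divides a category's class
fractions by baseline (All-SNV) fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_variants import CancerCatalog, ScoreTable, SYNONYMOUS, parse_variant
from .mutational_null import CLASSES

ACTIVITY_WT_CUTOFF = 10.0 ** -1.11
ACTIVITY_LOSS_CUTOFF = 10.0 ** -2.13

#: known dominant-negative variants (stable but catalytically dead,
#: suppressing co-expressed WT protein)
KNOWN_DOMINANT_NEGATIVES = ("C124S", "G129E", "R130G", "R130Q")


@dataclass
class ClassificationConfig:
    activity_wt_cutoff: float = ACTIVITY_WT_CUTOFF
    activity_loss_cutoff: float = ACTIVITY_LOSS_CUTOFF
    #: how to pick the WT anchor for rescaling: "synonymous_mean" or a number
    wt_anchor_policy: str = "synonymous_mean"

    def __post_init__(self) -> None:
        if self.activity_loss_cutoff >= self.activity_wt_cutoff:
            raise ValueError("loss cutoff must lie below the WT cutoff")


def rescale_activity(
    raw: pd.Series, nonsense_raw: pd.Series, wt_score: float
) -> pd.Series:
    """Rescale raw activity so mean nonsense -> 0 and WT -> 1."""
    mean_non = float(nonsense_raw.dropna().mean())
    if not wt_score > mean_non:
        raise ValueError(
            f"WT anchor {wt_score} must exceed mean nonsense activity {mean_non}"
        )
    return ((raw - mean_non) / (wt_score - mean_non)).rename("scaled_activity")


def classify_activity(
    raw: float | pd.Series, cfg: ClassificationConfig | None = None
):
    """wt_like / loss / indeterminate from raw-scale cutoffs."""
    if cfg is None:
        cfg = ClassificationConfig()
    if np.isscalar(raw):
        if raw <= 0:
            raise ValueError(f"raw activity must be positive, got {raw}")
        if raw > cfg.activity_wt_cutoff:
            return "wt_like"
        if raw < cfg.activity_loss_cutoff:
            return "loss"
        return "indeterminate"
    series = pd.Series(raw)
    if (series.dropna() <= 0).any():
        raise ValueError("raw activity scores must be positive")
    out = pd.Series("indeterminate", index=series.index, name="activity_class")
    out[series > cfg.activity_wt_cutoff] = "wt_like"
    out[series < cfg.activity_loss_cutoff] = "loss"
    out[series.isna()] = "missing"
    return out


_JOINT = {
    ("wt_like", "wt_like"): "wt_like",
    ("low", "wt_like"): "loss_abundance_only",
    ("wt_like", "loss"): "loss_activity_only",
    ("low", "loss"): "loss_both",
}


def four_way_classify(abundance_class: str, activity_class: str) -> str:
    """Joint functional class; any indeterminate/unclassified/missing axis
    makes the variant unclassified."""
    return _JOINT.get((abundance_class, activity_class), "unclassified")


def classify_variants(
    composite: pd.DataFrame,
    activity: ScoreTable,
    cfg: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Full classification table over the union of both assays.

    ``composite`` must carry ``abundance_class`` (see
    ``composite_filter.classify_abundance_confidence``); ``activity`` is a
    raw activity ScoreTable with one column.  The output distinguishes
    variants unclassified because an assay call was indeterminate from
    those missing from one assay (``unclassified_reason``).
    """
    if cfg is None:
        cfg = ClassificationConfig()
    act_raw = activity.df.iloc[:, 0]
    act_class = classify_activity(act_raw, cfg)

    idx = composite.index.union(act_raw.index)
    ab_class = composite["abundance_class"].reindex(idx).fillna("missing")
    ac = act_class.reindex(idx).fillna("missing")
    joint = [four_way_classify(a, b) for a, b in zip(ab_class, ac)]

    reason = np.select(
        [
            (ab_class == "missing") | (ac == "missing"),
            (ab_class == "unclassified") | (ac == "indeterminate"),
        ],
        ["missing_assay", "indeterminate"],
        "",
    )
    out = pd.DataFrame(
        {
            "abundance_class": ab_class,
            "activity_class": ac,
            "joint_class": joint,
            "unclassified_reason": reason,
        },
        index=idx,
    )
    out.loc[out["joint_class"] != "unclassified", "unclassified_reason"] = ""

    # cosmetic 0-1 activity scale for reporting
    cons = pd.Series([parse_variant(t).consequence for t in act_raw.index],
                     index=act_raw.index)
    non_raw = act_raw[cons == "nonsense"]
    if cfg.wt_anchor_policy == "synonymous_mean":
        syn_raw = act_raw[cons == SYNONYMOUS]
        wt_anchor = float(syn_raw.mean()) if len(syn_raw) else float(act_raw.max())
    else:
        wt_anchor = float(cfg.wt_anchor_policy)
    if len(non_raw) and wt_anchor > float(non_raw.mean()):
        out["scaled_activity"] = rescale_activity(
            act_raw, non_raw, wt_anchor
        ).reindex(idx)
    else:
        out["scaled_activity"] = np.nan
    out.index.name = "variant"
    return out


# ---------------------------------------------------------------------------
# Category enrichment
# ---------------------------------------------------------------------------


def _class_fractions(
    catalog_df: pd.DataFrame, class_of: Mapping[str, str], mode: str
) -> tuple[pd.Series, int]:
    classes = catalog_df["variant"].map(lambda t: class_of.get(t))
    keep = classes.isin(CLASSES)
    if not keep.any():
        raise ValueError("category has no classified variants")
    if mode == "unique_variant":
        sub = catalog_df[keep].drop_duplicates("variant")
        w = pd.Series(1.0, index=sub.index)
        cls = classes[sub.index]
    elif mode == "per_observation":
        sub = catalog_df[keep]
        w = sub["n_observations"].astype(float)
        cls = classes[keep]
    else:
        raise ValueError(f"unknown counting mode {mode!r}")
    counts = w.groupby(cls.to_numpy()).sum()
    frac = counts.reindex(CLASSES, fill_value=0.0)
    n = int(w.sum())
    return frac / frac.sum(), n


def category_enrichment(
    catalog: CancerCatalog,
    class_map: Mapping[str, str],
    baseline: pd.Series,
    mode: str = "per_observation",
) -> pd.DataFrame:
    """Fold enrichment/depletion per class per category vs a baseline.

    ``baseline`` holds All-SNV class fractions (summing to 1 over the four
    classes).  Fractions within each category are computed over classified
    variants only; ``mode`` selects per-observation or unique-variant
    counting.  A baseline fraction of 0 with nonzero observed is reported
    as +inf with a warning.
    """
    baseline = baseline.reindex(CLASSES).astype(float)
    if abs(float(baseline.sum()) - 1.0) > 1e-9:
        raise ValueError("baseline fractions must sum to 1")
    rows = []
    for cat, sub in catalog.df.groupby("category"):
        frac, n = _class_fractions(sub, class_map, mode)
        for cls in CLASSES:
            b = float(baseline[cls])
            o = float(frac[cls])
            if b == 0.0:
                if o > 0.0:
                    warnings.warn(
                        f"class {cls!r} has baseline fraction 0", stacklevel=2
                    )
                    fold = float("inf")
                else:
                    fold = float("nan")
            else:
                fold = o / b
            rows.append(
                {
                    "category": cat,
                    "functional_class": cls,
                    "observed_fraction": o,
                    "baseline_fraction": b,
                    "fold_enrichment": fold,
                    "n_classified": n,
                }
            )
    return pd.DataFrame(rows)


def split_dominant_negative_candidates(
    classes: pd.DataFrame,
    catalog: CancerCatalog | None = None,
    known: Iterable[str] = KNOWN_DOMINANT_NEGATIVES,
) -> dict:
    """Partition loss_activity_only variants into known dominant negatives
    and novel candidates.

    With a catalog, also reports the known set's share of
    loss_activity_only observations per category (the fraction of the
    class's burden carried by already-characterized dominant negatives).
    """
    known = {str(parse_variant(t)) for t in known}
    loa = set(classes.index[classes["joint_class"] == "loss_activity_only"])
    result = {
        "known": sorted(loa & known),
        "novel_candidates": sorted(loa - known),
    }
    if catalog is not None:
        shares = {}
        df = catalog.df
        for cat, sub in df.groupby("category"):
            in_loa = sub[sub["variant"].isin(loa)]
            total = int(in_loa["n_observations"].sum())
            if total == 0:
                continue
            known_obs = int(
                in_loa.loc[in_loa["variant"].isin(known), "n_observations"].sum()
            )
            shares[cat] = known_obs / total
        result["known_contribution_share"] = shares
    return result
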