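"""Per-replicate abundance scores from four-bin sort-seq counts.

A variant's reads are depth-normalized per bin, renormalized to a
distribution over the four bins, and summarized by a bin-weighted average
with weights (0, 1/3, 2/3, 1) — the canonical sort-seq abundance
estimator.  Raw scores are then anchored to the control medians so that
nonsense variants sit near 0 and synonymous variants near 1:

    s' = (s - median_nonsense) / (median_synonymous - median_nonsense)

Values outside [0, 1] are legitimate (a variant can be more abundant than
the synonymous median).  Variants below the per-replicate read filter are
missing, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_variants import NONSENSE, SYNONYMOUS, ScoreTable, parse_variant
from .synthetic_data import BinCountTable

BIN_WEIGHTS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)

#: separator for codon-level tags on variant tokens, e.g. "R130Q/cga"
CODON_TAG_SEP = "/"


class ReplicateSeparationError(RuntimeError):
    """Synonymous and nonsense controls failed to separate in a replicate."""


@dataclass
class ScoringConfig:
    bin_weights: tuple[float, float, float, float] = BIN_WEIGHTS
    min_reads_per_variant: int = 5
    #: anchor statistic for control normalization ("median" or "mean")
    control_stat: str = "median"
    #: minimum scored controls of each type required to normalize
    min_controls: int = 5

    def __post_init__(self) -> None:
        if not all(
            b > a for a, b in zip(self.bin_weights, self.bin_weights[1:])
        ):
            raise ValueError("bin weights must be strictly increasing")
        if self.control_stat not in ("median", "mean"):
            raise ValueError("control_stat must be 'median' or 'mean'")


def bin_frequencies(
    counts: pd.DataFrame, depths: pd.Series, min_reads: int = 5
) -> pd.DataFrame:
    """Depth-normalized within-variant bin frequencies.

    f_b = (c_b / N_b) / sum_b' (c_b' / N_b').  Rows with fewer than
    ``min_reads`` total reads come back all-NaN (flagged unscored, not an
    exception).
    """
    depths = depths.astype(float)
    if (depths <= 0).any():
        raise ValueError("all per-bin depths must be positive")
    rel = counts.astype(float).div(depths, axis=1)
    norm = rel.sum(axis=1)
    freqs = rel.div(norm.where(norm > 0), axis=0)
    low = counts.sum(axis=1) < min_reads
    freqs[low] = np.nan
    return freqs


def weighted_average_score(
    freqs: pd.DataFrame, cfg: ScoringConfig | None = None
) -> pd.Series:
    """Raw abundance score: sum_b w_b f_b, in [0, 1]."""
    if cfg is None:
        cfg = ScoringConfig()
    w = np.asarray(cfg.bin_weights)
    return pd.Series(freqs.to_numpy() @ w, index=freqs.index, name="raw_score")


def normalize_scores(
    raw: pd.Series,
    synonymous: pd.Series,
    nonsense: pd.Series,
    cfg: ScoringConfig | None = None,
) -> pd.Series:
    """Anchor raw scores to control statistics (median by default)."""
    if cfg is None:
        cfg = ScoringConfig()
    syn = synonymous.dropna()
    non = nonsense.dropna()
    if len(syn) < cfg.min_controls or len(non) < cfg.min_controls:
        raise ReplicateSeparationError(
            f"need >= {cfg.min_controls} scored controls of each type, "
            f"got {len(syn)} synonymous / {len(non)} nonsense"
        )
    stat = np.median if cfg.control_stat == "median" else np.mean
    m_syn = float(stat(syn))
    m_non = float(stat(non))
    if m_syn <= m_non:
        raise ReplicateSeparationError(
            f"replicate failed separation: synonymous {cfg.control_stat} "
            f"{m_syn:.4f} <= nonsense {cfg.control_stat} {m_non:.4f}"
        )
    return ((raw - m_non) / (m_syn - m_non)).rename("score")


def _strip_codon_tags(scores: pd.Series) -> pd.Series:
    """Average codon-level entries ("R130Q/1", "R130Q/2") into one
    amino-acid-level score per variant (unweighted mean)."""
    if not any(CODON_TAG_SEP in str(t) for t in scores.index):
        return scores
    aa_tokens = [str(t).split(CODON_TAG_SEP)[0] for t in scores.index]
    return scores.groupby(pd.Index(aa_tokens, name=scores.index.name or "variant")).mean()


def score_replicate(
    table: BinCountTable, cfg: ScoringConfig | None = None
) -> pd.Series:
    """One replicate's normalized abundance scores (NaN where unscored).

    Codon-level rows tagged ``aa_token/<tag>`` are averaged into their
    amino-acid variant before normalization.  Controls are recognized from
    the variant tokens themselves (synonymous: wt == mut; nonsense:
    mut == ``*``).
    """
    if cfg is None:
        cfg = ScoringConfig()
    freqs = bin_frequencies(
        table.counts, table.depths, min_reads=cfg.min_reads_per_variant
    )
    raw = weighted_average_score(freqs, cfg)
    raw = _strip_codon_tags(raw)
    cons = pd.Series(
        [parse_variant(t).consequence for t in raw.index], index=raw.index
    )
    normalized = normalize_scores(
        raw, raw[cons == SYNONYMOUS], raw[cons == NONSENSE], cfg
    )
    return normalized.rename(table.replicate)


def score_replicates(
    tables: list[BinCountTable], cfg: ScoringConfig | None = None
) -> ScoreTable:
    """Score every replicate and assemble the variant x replicate table."""
    cols = [score_replicate(t, cfg) for t in tables]
    df = pd.concat(cols, axis=1)
    df.index.name = "variant"
    return ScoreTable(df)
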