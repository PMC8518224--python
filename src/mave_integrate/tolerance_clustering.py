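"""Positional substitution-tolerance profiles and their clustering.

A position's tolerance profile is the vector of composite abundance scores
of its missense substitutions (up to 19 non-WT amino acids; stop
substitutions are excluded by default).  High-coverage positions (>= 17
scored missense variants by default) are clustered hierarchically on a
pairwise-complete Euclidean distance — computed over amino acids scored at
both positions and rescaled by sqrt(19 / n_shared) so sparser overlaps are
not systematically closer — and summarized into tolerant / partially
tolerant / intolerant groups by the positional median score.

Linkage, metric, coverage threshold and group boundaries are all
configurable; the defaults are package choices, not measured constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_variants import AA1, MISSENSE, parse_variant

#: group boundaries on the positional median composite score
TOLERANT_MIN_MEDIAN = 0.75
INTOLERANT_MAX_MEDIAN = 0.35


def tolerance_profiles(
    composite: pd.DataFrame, include_stop: bool = False
) -> pd.DataFrame:
    """Position x amino-acid matrix of composite scores (missense only by
    default; NaN where unscored)."""
    rows = []
    for tok, rec in composite.iterrows():
        v = parse_variant(tok)
        if v.consequence == MISSENSE or (include_stop and v.consequence == "nonsense"):
            rows.append((v.position, v.mut_aa, rec["score"]))
    if not rows:
        return pd.DataFrame(columns=list(AA1))
    df = pd.DataFrame(rows, columns=["position", "mut_aa", "score"])
    mat = df.pivot_table(index="position", columns="mut_aa", values="score")
    cols = list(AA1) + (["*"] if include_stop else [])
    return mat.reindex(columns=[c for c in cols if c in mat.columns])


def select_high_coverage_positions(
    profiles: pd.DataFrame, min_missense: int = 17
) -> list[int]:
    """Positions with at least ``min_missense`` scored missense variants."""
    n_scored = profiles.notna().sum(axis=1)
    return sorted(int(p) for p in profiles.index[n_scored >= min_missense])


def _pairwise_complete_distance(mat: np.ndarray, min_shared: int = 5):
    """Euclidean distance over jointly scored amino acids, scaled by
    sqrt(19 / n_shared); NaN where fewer than ``min_shared`` are shared."""
    n = mat.shape[0]
    dist = np.full((n, n), np.nan)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            ns = int(shared.sum())
            if ns < min_shared:
                continue
            d = np.sqrt(np.sum((mat[i, shared] - mat[j, shared]) ** 2))
            dist[i, j] = dist[j, i] = d * np.sqrt(19.0 / ns)
    return dist


@dataclass
class ClusterResult:
    positions: list[int]  # clustered positions, input (ascending) order
    order: list[int]  # positions in dendrogram leaf order
    linkage: np.ndarray
    flat_groups: pd.Series  # position -> cluster id (1..k)
    newick: str
    excluded: list[int]  # positions dropped for insufficient overlap


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(length, 0.0):.6g}"

    return walk(tree, tree.dist) + ";"


def cluster_positions(
    profiles: pd.DataFrame,
    linkage_method: str = "average",
    n_groups: int = 3,
    min_shared: int = 5,
) -> ClusterResult:
    """Agglomerative clustering of positional tolerance profiles.

    Positions sharing fewer than ``min_shared`` scored amino acids with
    every other position are excluded (reported in ``excluded``).  Input
    rows are sorted by position before clustering so the output is
    invariant to row order, with ties broken by position index.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    profiles = profiles.sort_index()
    mat = profiles.to_numpy(dtype=float)
    dist = _pairwise_complete_distance(mat, min_shared=min_shared)

    n = len(profiles)
    connected = [
        i for i in range(n) if np.isfinite(np.delete(dist[i], i)).any()
    ]
    excluded = [int(profiles.index[i]) for i in range(n) if i not in connected]
    if len(connected) < 2:
        raise ValueError("fewer than 2 positions share enough scored amino acids")
    sub = dist[np.ix_(connected, connected)]
    # remaining unordered pairs below the overlap floor get the max distance
    if np.isnan(sub).any():
        sub = np.where(np.isnan(sub), np.nanmax(sub) * 1.5, sub)
        np.fill_diagonal(sub, 0.0)
    Z = hierarchy.linkage(squareform(sub, checks=False), method=linkage_method)
    positions = [int(profiles.index[i]) for i in connected]
    leaf_order = [positions[i] for i in hierarchy.leaves_list(Z)]
    flat = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    newick = _linkage_to_newick(Z, [f"pos{p}" for p in positions])
    return ClusterResult(
        positions=positions,
        order=leaf_order,
        linkage=Z,
        flat_groups=pd.Series(flat, index=pd.Index(positions, name="position"),
                              name="cluster"),
        newick=newick,
        excluded=excluded,
    )


def tolerance_group(
    profile: pd.Series,
    min_scored: int = 17,
    tolerant_min: float = TOLERANT_MIN_MEDIAN,
    intolerant_max: float = INTOLERANT_MAX_MEDIAN,
) -> str | None:
    """tolerant / partial / intolerant by positional median score; None
    below the coverage threshold."""
    scored = profile.dropna()
    if len(scored) < min_scored:
        return None
    med = float(scored.median())
    if med >= tolerant_min:
        return "tolerant"
    if med <= intolerant_max:
        return "intolerant"
    return "partial"


def tolerance_groups(
    profiles: pd.DataFrame, min_scored: int = 17
) -> pd.DataFrame:
    """Per-position median, coverage and tolerance group (high-coverage
    positions only)."""
    rows = []
    for pos, prof in profiles.iterrows():
        grp = tolerance_group(prof, min_scored=min_scored)
        if grp is None:
            continue
        scored = prof.dropna()
        rows.append(
            {
                "position": int(pos),
                "n_scored": int(len(scored)),
                "positional_median": float(scored.median()),
                "group": grp,
            }
        )
    return pd.DataFrame(rows)


def plot_tolerance_heatmap(profiles: pd.DataFrame, order: list[int], path) -> None:
    """Optional heatmap of clustered profiles (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = profiles.loc[order]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.18 * len(mat))))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.2)
    ax.set_yticks(range(len(mat)), [str(p) for p in mat.index], fontsize=5)
    ax.set_xticks(range(mat.shape[1]), list(mat.columns), fontsize=6)
    ax.set_xlabel("substituted amino acid")
    ax.set_ylabel("position (cluster order)")
    fig.colorbar(im, ax=ax, label="composite abundance score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
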