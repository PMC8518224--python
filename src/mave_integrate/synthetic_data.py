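"""Synthetic sort-seq experiments with known ground truth.

Everything downstream of raw sequencing is testable against data generated
here: a library of protein variants with true abundances and true
lipid-phosphatase activities, FACS sorting of fluorescent cells into four
equally populated bins with Gaussian cell-to-cell noise, multinomial read
sampling per bin, per-variant-per-replicate dropout (emulating loss of
variants during library generation), activity tables with lognormal
measurement noise, somatic-variant catalogs sampled from an SNV null
spectrum with chosen per-class fold enrichments, and toy coding sequences.

The fluorescence model is a unit-interval location model: each cell's
log-fluorescence ratio is the variant's true abundance plus
``Normal(0, fluorescence_noise_sd)``.  This is the simplest model that
preserves the monotone abundance-to-bin relationship the sort-seq readout
assumes (fluorescence proportional to steady-state abundance); it makes no
claim to emulate a particular cytometer.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_variants import (
    AA1,
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    CancerCatalog,
    CdsSequence,
    ScoreTable,
    parse_variant,
)
from .mutational_null import CLASSES, NullSpectrum

# Raw activity-scale cutoffs (log10): WT-like above -1.11, loss below -2.13.
ACTIVITY_WT_CUTOFF_LOG10 = -1.11
ACTIVITY_LOSS_CUTOFF_LOG10 = -2.13

#: classes whose true activity is WT-like (drawn above the WT cutoff)
_ACTIVE_CLASSES = ("wt_like", "loss_abundance_only")


@dataclass
class SortSimConfig:
    """Knobs of the synthetic sort-seq experiment.

    Defaults are desk scale: 500 variants x 8 replicates at 50,000 reads
    per bin, a variant:read ratio comparable to real sorting runs without
    their size.  ``fluorescence_noise_sd`` is on the unit abundance scale;
    ``dropout_rate`` is the per-variant-per-replicate probability of being
    absent from a replicate before sorting.
    """

    n_variants: int = 500
    n_replicates: int = 8
    reads_per_bin: int = 50_000
    fluorescence_noise_sd: float = 0.10
    dropout_rate: float = 0.20
    cells_per_variant: int = 100
    n_synonymous: int = 25
    n_nonsense: int = 25
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "wt_like": 0.5,
            "loss_abundance_only": 0.2,
            "loss_activity_only": 0.1,
            "loss_both": 0.2,
        }
    )
    activity_noise_sd_log10: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        total = sum(self.class_mixture.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class mixture proportions must sum to 1")


@dataclass
class TrueLibrary:
    """Ground truth for a simulated variant library.

    ``truth`` has columns ``variant``, ``consequence``, ``true_abundance``,
    ``true_activity_raw``, ``true_class``; ``presence`` is a boolean
    (variant x replicate) matrix of per-replicate dropout flags.
    """

    truth: pd.DataFrame
    presence: pd.DataFrame

    @property
    def variants(self) -> list[str]:
        return list(self.truth["variant"])


# abundance draw per true class (uniform intervals on the unit scale);
# controls sit tight against the scale anchors
_ABUNDANCE_RANGES = {
    "wt_like": (0.8, 1.0),
    "loss_activity_only": (0.8, 1.0),
    "loss_abundance_only": (0.0, 0.2),
    "loss_both": (0.0, 0.2),
    SYNONYMOUS: (0.92, 1.0),
    NONSENSE: (0.0, 0.08),
}

# log10 raw activity draw: active classes clear the WT cutoff (-1.11),
# loss classes sit below the loss cutoff (-2.13), both with margin so that
# lognormal noise of sd 0.1 rarely crosses a cutoff
_ACTIVITY_LOG10_RANGES = {True: (-0.9, -0.1), False: (-2.5, -2.3)}


def _invent_missense_tokens(rng: np.random.Generator, n: int, n_positions: int = 400):
    """Unique invented missense tokens over positions 2..n_positions."""
    tokens: list[str] = []
    seen: set[str] = set()
    aas = np.array(list(AA1))
    while len(tokens) < n:
        pos = int(rng.integers(2, n_positions + 1))
        wt, mut = rng.choice(aas, size=2, replace=False)
        tok = f"{wt}{pos}{mut}"
        if tok not in seen:
            seen.add(tok)
            tokens.append(tok)
    return tokens


def generate_library(
    config: SortSimConfig,
    seed: int | None = None,
    cds: CdsSequence | None = None,
) -> TrueLibrary:
    """Draw a variant library with true abundances, activities and classes.

    Includes designated synonymous and nonsense control sets
    (``config.n_synonymous`` / ``config.n_nonsense``, >= 20 each by
    default).  When ``cds`` is given the library emulates site saturation:
    positions are filled consecutively from residue 2 with all 19 non-WT
    substitutions each (dense positional coverage, as an NNK library
    gives), and control variants use the real WT residues; otherwise
    variant names are invented over scattered positions.
    """
    if seed is None:
        seed = config.seed
    n_controls = config.n_synonymous + config.n_nonsense
    if config.n_variants < n_controls + 4:
        raise ValueError(
            f"n_variants={config.n_variants} too small for "
            f"{n_controls} controls plus a missense set"
        )
    rng = np.random.default_rng([int(seed), 101])
    n_missense = config.n_variants - n_controls

    if cds is not None:
        prot = cds.translate().rstrip("*")
        mis_tokens = []
        pos = 2
        while len(mis_tokens) < n_missense:
            wt = prot[pos - 1]
            for mut in AA1:
                if mut != wt and len(mis_tokens) < n_missense:
                    mis_tokens.append(f"{wt}{pos}{mut}")
            pos += 1
            if pos > len(prot):
                raise ValueError("CDS too short for requested library size")
        non_pos = rng.choice(np.arange(2, len(prot) + 1),
                             size=config.n_nonsense, replace=False)
        non_tokens = [f"{prot[p - 1]}{p}*" for p in non_pos]
        syn_pos = rng.choice(np.arange(2, len(prot) + 1),
                             size=config.n_synonymous, replace=False)
        syn_tokens = [f"{prot[p - 1]}{p}{prot[p - 1]}" for p in syn_pos]
    else:
        mis_tokens = _invent_missense_tokens(rng, n_missense)
        aas = np.array(list(AA1))
        syn_tokens, non_tokens = [], []
        seen = set(mis_tokens)
        pos = 2
        while len(syn_tokens) < config.n_synonymous:
            aa = rng.choice(aas)
            tok = f"{aa}{pos}{aa}"
            if tok not in seen:
                seen.add(tok)
                syn_tokens.append(tok)
            pos += 1
        pos = 2
        while len(non_tokens) < config.n_nonsense:
            aa = rng.choice(aas)
            tok = f"{aa}{pos}*"
            if tok not in seen:
                seen.add(tok)
                non_tokens.append(tok)
            pos += 1

    classes = list(
        rng.choice(
            CLASSES,
            size=n_missense,
            p=[config.class_mixture.get(c, 0.0) for c in CLASSES],
        )
    )
    tokens = mis_tokens + syn_tokens + non_tokens
    consequences = (
        [MISSENSE] * n_missense
        + [SYNONYMOUS] * config.n_synonymous
        + [NONSENSE] * config.n_nonsense
    )
    # synonymous controls are wt-like; nonsense controls lose both properties
    true_classes = classes + ["wt_like"] * config.n_synonymous + [
        "loss_both"
    ] * config.n_nonsense

    abundance = np.empty(len(tokens))
    activity_log10 = np.empty(len(tokens))
    for i, (cons, cls) in enumerate(zip(consequences, true_classes)):
        key = cons if cons in (SYNONYMOUS, NONSENSE) else cls
        lo, hi = _ABUNDANCE_RANGES[key]
        abundance[i] = rng.uniform(lo, hi)
        lo, hi = _ACTIVITY_LOG10_RANGES[cls in _ACTIVE_CLASSES]
        activity_log10[i] = rng.uniform(lo, hi)

    truth = pd.DataFrame(
        {
            "variant": tokens,
            "consequence": consequences,
            "true_abundance": abundance,
            "true_activity_raw": 10.0 ** activity_log10,
            "true_class": true_classes,
        }
    )
    presence = pd.DataFrame(
        rng.random((len(tokens), config.n_replicates)) >= config.dropout_rate,
        index=pd.Index(tokens, name="variant"),
        columns=[f"rep{r + 1}" for r in range(config.n_replicates)],
    )
    return TrueLibrary(truth=truth, presence=presence)


@dataclass
class BinCountTable:
    """Reads per variant per fluorescence bin for one sorting replicate."""

    counts: pd.DataFrame  # index variant, columns bin1..bin4
    replicate: str = "rep1"

    def __post_init__(self) -> None:
        if list(self.counts.columns) != ["bin1", "bin2", "bin3", "bin4"]:
            raise ValueError("count columns must be bin1..bin4")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def depths(self) -> pd.Series:
        """Per-bin total sequencing depth N_b."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "variant"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, replicate: str = "rep1") -> "BinCountTable":
        df = pd.read_csv(path, sep="\t", index_col="variant")
        return cls(counts=df[["bin1", "bin2", "bin3", "bin4"]].astype(int),
                   replicate=replicate)


def simulate_sort_replicate(
    library: TrueLibrary,
    config: SortSimConfig,
    replicate_index: int,
    seed: int | None = None,
) -> BinCountTable:
    """Simulate one FACS sort replicate and its sequencing reads.

    Cells of variants present in this replicate get fluorescence
    ``true_abundance + Normal(0, noise_sd)``; quartile gates are drawn at
    the 25/50/75th percentiles of the pooled cell population (equally
    populated bins by construction); reads are drawn multinomially per bin
    to ``reads_per_bin`` with probabilities proportional to each variant's
    cell count in that bin.
    """
    if config.reads_per_bin <= 0:
        raise ValueError("reads_per_bin must be positive")
    if library.truth.empty:
        raise ValueError("library is empty")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 202, int(replicate_index)])

    rep_col = library.presence.columns[replicate_index]
    present = library.presence[rep_col].to_numpy()
    tokens = np.asarray(library.variants)[present]
    abund = library.truth["true_abundance"].to_numpy()[present]
    if len(tokens) < 4:
        raise ValueError("fewer than 4 variants present in replicate")

    n_cells = config.cells_per_variant
    fluor = abund[:, None] + rng.normal(
        0.0, config.fluorescence_noise_sd, size=(len(tokens), n_cells)
    )
    gates = np.percentile(fluor, [25, 50, 75])
    # bin index 0..3 per cell; occupancy[v, b] = cells of variant v in bin b
    bins = np.searchsorted(gates, fluor, side="right")
    occupancy = np.stack(
        [(bins == b).sum(axis=1) for b in range(4)], axis=1
    ).astype(float)

    counts = np.zeros((len(tokens), 4), dtype=int)
    for b in range(4):
        tot = occupancy[:, b].sum()
        if tot == 0:
            continue
        counts[:, b] = rng.multinomial(config.reads_per_bin, occupancy[:, b] / tot)
    df = pd.DataFrame(
        counts,
        index=pd.Index(tokens, name="variant"),
        columns=["bin1", "bin2", "bin3", "bin4"],
    )
    return BinCountTable(counts=df, replicate=rep_col)


def generate_activity_scores(
    library: TrueLibrary,
    seed: int | None = None,
    noise_sd_log10: float | None = None,
) -> ScoreTable:
    """Raw phosphatase-style activity scores with lognormal noise.

    Raw activity is ``true_activity_raw`` times a lognormal factor
    (``noise_sd_log10`` on the log10 scale).  Before noise, active classes
    lie above the WT cutoff 10^-1.11 and loss classes below the loss
    cutoff 10^-2.13 by construction of the library.
    """
    if seed is None:
        seed = 0
    if noise_sd_log10 is None:
        noise_sd_log10 = 0.10
    rng = np.random.default_rng([int(seed), 303])
    raw = library.truth["true_activity_raw"].to_numpy()
    noisy = raw * 10.0 ** rng.normal(0.0, noise_sd_log10, size=len(raw))
    df = pd.DataFrame(
        {"activity_raw": noisy},
        index=pd.Index(library.variants, name="variant"),
    )
    return ScoreTable(df)


def assign_null_classes(
    spectrum: NullSpectrum,
    mixture: Mapping[str, float] | None = None,
    seed: int = 0,
    nonsense_class: str | None = "loss_both",
) -> dict[str, str]:
    """Assign every SNV-reachable variant a functional class at random.

    Missense variants draw from ``mixture`` (default: the library mixture);
    nonsense variants get ``nonsense_class`` (``loss_both`` by default, or
    the mixture draw when None).  Used to close the loop between catalog
    generation and enrichment recovery.
    """
    if mixture is None:
        mixture = {
            "wt_like": 0.5,
            "loss_abundance_only": 0.2,
            "loss_activity_only": 0.1,
            "loss_both": 0.2,
        }
    rng = np.random.default_rng([int(seed), 404])
    p = np.array([mixture.get(c, 0.0) for c in CLASSES], dtype=float)
    p = p / p.sum()
    out: dict[str, str] = {}
    for tok, cons in zip(spectrum.df["variant"], spectrum.df["consequence"]):
        if cons == NONSENSE and nonsense_class is not None:
            out[tok] = nonsense_class
        else:
            out[tok] = str(rng.choice(CLASSES, p=p))
    return out


def generate_cancer_catalog(
    spectrum: NullSpectrum,
    class_map: Mapping[str, str],
    fold_enrichments: Mapping[str, float],
    n_observations: int,
    seed: int = 0,
    category: str = "simulated",
) -> CancerCatalog:
    """Sample a somatic-style catalog from the null spectrum with chosen
    per-class fold enrichments.

    Sampling weight of a variant = degeneracy frequency x fold enrichment
    of its class, renormalized; ``n_observations`` draws with replacement.

    Because observed class fractions must sum to 1, a requested fold
    vector f is realized up to the renormalization constant
    s = sum_c baseline_c * f_c: the recovered fold of class c is f_c / s
    in expectation.  s is 1 (folds realized exactly) iff the requested
    vector is feasible; an enrichment of a rare class leaves s near 1.
    """
    rng = np.random.default_rng([int(seed), 505])
    df = spectrum.df
    tokens = df["variant"].to_numpy()
    classes = np.array([class_map.get(t) for t in tokens], dtype=object)
    folds = np.array(
        [fold_enrichments.get(c, 0.0) if c is not None else 0.0 for c in classes]
    )
    weights = df["frequency"].to_numpy() * folds
    if n_observations == 0:
        empty = pd.DataFrame(columns=["variant", "category", "n_observations"])
        return CancerCatalog(empty.astype({"n_observations": int}, errors="ignore"))
    if weights.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    p = weights / weights.sum()
    draws = rng.multinomial(n_observations, p)
    keep = draws > 0
    out = pd.DataFrame(
        {
            "variant": tokens[keep],
            "category": category,
            "n_observations": draws[keep].astype(int),
        }
    ).reset_index(drop=True)
    return CancerCatalog(out)


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ["TAA", "TAG", "TGA"]


def generate_toy_cds(n_codons: int, seed: int = 0, name: str = "toy") -> CdsSequence:
    """A random CDS of ``n_codons`` codons: ATG start, random sense codons,
    a random stop codon last."""
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    rng = np.random.default_rng([int(seed), 606])
    middle = rng.choice(_SENSE_CODONS, size=n_codons - 2).tolist()
    stop = str(rng.choice(_STOP_CODONS))
    return CdsSequence(name=name, nucleotides="".join(["ATG", *middle, stop]))
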