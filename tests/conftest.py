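"""Shared fixtures and independent oracles."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

import mave_integrate as mi
from mave_integrate.io_variants import ScoreTable


# ---------------------------------------------------------------------------
# Independent brute-force SNV enumerator (oracle for the null model).
# Mutates the full nucleotide string one position at a time and translates
# the whole CDS, sharing no code with the package's codon-wise enumeration.
# ---------------------------------------------------------------------------


def brute_force_spectrum(nt: str, include_start=False, include_stop=False):
    """Counter[(wt, pos, mut)] over non-synonymous SNVs, plus event totals."""
    protein = str(Seq(nt).translate())
    n_codons = len(nt) // 3
    lo = 0 if include_start else 1
    hi = n_codons
    if protein.endswith("*") and not include_stop:
        hi -= 1
    freqs: Counter = Counter()
    totals = Counter()
    for i in range(len(nt)):
        codon_idx = i // 3
        if not (lo <= codon_idx < hi):
            continue
        for alt in "ACGT":
            if alt == nt[i]:
                continue
            mutant = nt[:i] + alt + nt[i + 1 :]
            mut_protein = str(Seq(mutant).translate())
            wt_aa, mut_aa = protein[codon_idx], mut_protein[codon_idx]
            if wt_aa == mut_aa:
                totals["synonymous"] += 1
            else:
                totals["nonsense" if mut_aa == "*" else "missense"] += 1
                freqs[(wt_aa, codon_idx + 1, mut_aa)] += 1
    return freqs, totals


def make_score_table(rows: dict[str, list[float | None]], n_reps=8) -> ScoreTable:
    """Build a replicate score table from {token: [values...]} with NaN pads."""
    data = {}
    for tok, vals in rows.items():
        row = [np.nan] * n_reps
        row[: len(vals)] = [np.nan if v is None else v for v in vals]
        data[tok] = row
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=[f"rep{i+1}" for i in range(n_reps)])
    df.index.name = "variant"
    return ScoreTable(df)


def control_scores(
    seed: int,
    n_syn=60,
    n_non=60,
    n_reps=8,
    syn_loc=1.0,
    non_loc=0.0,
    sd=0.05,
    noise_below=0,
    noise_loc=0.5,
    noise_sd=0.8,
    fixed_n=None,
    n_weights=None,
) -> ScoreTable:
    """Synonymous/nonsense control table with per-variant replicate counts.

    Variants drawn with ``n_reps_observed <= noise_below`` get pure-noise
    scores (same distribution for both classes), emulating unreliable
    low-replicate measurements.  ``n_weights`` sets the replicate-count
    distribution over 1..n_reps (uniform by default; real libraries skew
    low, which is what makes the replicate filter matter).
    """
    rng = np.random.default_rng(seed)
    tokens, rows = [], []
    ns = np.arange(1, n_reps + 1)
    p = None
    if n_weights is not None:
        p = np.asarray(n_weights, dtype=float)
        p = p / p.sum()
    for i in range(n_syn + n_non):
        is_syn = i < n_syn
        tokens.append(f"A{i + 2}A" if is_syn else f"A{i + 2}*")
        n = fixed_n if fixed_n is not None else int(rng.choice(ns, p=p))
        if n <= noise_below:
            vals = rng.normal(noise_loc, noise_sd, n)
        else:
            vals = rng.normal(syn_loc if is_syn else non_loc, sd, n)
        row = np.full(n_reps, np.nan)
        row[rng.choice(n_reps, size=n, replace=False)] = vals
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(tokens, name="variant"),
                      columns=[f"rep{j+1}" for j in range(n_reps)])
    return ScoreTable(df)


#: low-skewed replicate-count distribution over 1..8 (half the variants in
#: <= 2 replicates), the sparseness regime the replicate filter exists for
LOW_SKEW_N_WEIGHTS = [0.25, 0.25] + [0.5 / 6] * 6


# ---------------------------------------------------------------------------
# Session-scoped default simulation (the study conditions: 500 variants,
# 8 replicates, 50k reads/bin, fluorescence noise 0.10, 20% dropout)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def bundled_cds():
    return mi.read_cds_fasta(mi.BUNDLED_CDS)


@pytest.fixture(scope="session")
def default_run(bundled_cds):
    cfg = mi.SortSimConfig(seed=1)
    library = mi.generate_library(cfg, cds=bundled_cds)
    tables = [
        mi.simulate_sort_replicate(library, cfg, r)
        for r in range(cfg.n_replicates)
    ]
    scores = mi.score_replicates(tables)
    return {"cfg": cfg, "library": library, "tables": tables, "scores": scores}


@pytest.fixture(scope="session")
def zero_noise_run(bundled_cds):
    cfg = mi.SortSimConfig(seed=2, fluorescence_noise_sd=1e-12, dropout_rate=0.0)
    library = mi.generate_library(cfg, cds=bundled_cds)
    tables = [
        mi.simulate_sort_replicate(library, cfg, r)
        for r in range(cfg.n_replicates)
    ]
    scores = mi.score_replicates(tables)
    return {"cfg": cfg, "library": library, "scores": scores}
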