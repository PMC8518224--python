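"""Single-nucleotide-variant null spectrum of a coding sequence.

In the absence of selection, the protein variants observed in tumors would
mirror what single-nucleotide mutation can produce: every position of the
CDS substituted to each of the three alternative nucleotides, translated,
with synonymous changes discarded and the remaining protein variants
weighted by how many distinct nucleotide changes produce them (codon-table
degeneracy).  Comparing observed class fractions in a variant catalog
against these expected fractions gives per-class fold enrichments.

The initiator codon and the terminal stop codon are excluded by default, so
a CDS of 403 sense codons + stop contributes 402 x 9 = 3618 events.
Mutation-rate weighting (transition/transversion or signature-specific) is
deliberately uniform by default; ``rate_weight`` hooks in a custom weight
per substitution if ever needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import pandas as pd
from Bio.Seq import Seq

from .io_variants import (
    MISSENSE,
    NONSENSE,
    SYNONYMOUS,
    CdsSequence,
    VariantId,
)

NUCLEOTIDES = "ACGT"

#: the four functional classes used throughout the package
CLASSES = ("wt_like", "loss_abundance_only", "loss_activity_only", "loss_both")


@dataclass(frozen=True)
class SnvEvent:
    """One single-nucleotide substitution in the CDS and its protein effect."""

    nt_position: int  # 1-based position in the CDS
    ref_nt: str
    alt_nt: str
    codon_index: int  # 1-based codon number
    ref_codon: str
    alt_codon: str
    protein_variant: VariantId
    consequence: str


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def enumerate_snvs(
    cds: CdsSequence,
    include_start: bool = False,
    include_stop: bool = False,
) -> list[SnvEvent]:
    """Enumerate all single-nucleotide substitutions of the CDS.

    Every included codon contributes exactly 9 events (3 positions x 3
    alternative nucleotides).  Codon 1 (initiator) is excluded unless
    ``include_start``; a terminal stop codon is excluded unless
    ``include_stop``.
    """
    codons = cds.codons
    start = 0 if include_start else 1
    end = len(codons)
    if cds.has_terminal_stop and not include_stop:
        end -= 1
    events: list[SnvEvent] = []
    for ci in range(start, end):
        ref_codon = codons[ci]
        wt_aa = _translate_codon(ref_codon)
        for offset in range(3):
            ref_nt = ref_codon[offset]
            for alt_nt in NUCLEOTIDES:
                if alt_nt == ref_nt:
                    continue
                alt_codon = ref_codon[:offset] + alt_nt + ref_codon[offset + 1 :]
                mut_aa = _translate_codon(alt_codon)
                variant = VariantId(wt_aa, ci + 1, mut_aa)
                events.append(
                    SnvEvent(
                        nt_position=ci * 3 + offset + 1,
                        ref_nt=ref_nt,
                        alt_nt=alt_nt,
                        codon_index=ci + 1,
                        ref_codon=ref_codon,
                        alt_codon=alt_codon,
                        protein_variant=variant,
                        consequence=variant.consequence,
                    )
                )
    return events


@dataclass
class NullSpectrum:
    """Degeneracy-weighted spectrum of SNV-reachable protein variants.

    ``df`` has one row per unique non-synonymous protein variant with
    columns ``variant`` (canonical token), ``consequence``, ``frequency``
    (number of distinct SNV events producing it, optionally rate-weighted)
    and, when a class map was supplied, ``functional_class``.
    """

    df: pd.DataFrame
    n_events_total: int
    n_events_by_consequence: dict[str, int]

    @property
    def total_frequency(self) -> float:
        return float(self.df["frequency"].sum())

    def expected_class_fractions(self) -> pd.Series:
        """Expected class fractions over classified spectrum variants,
        degeneracy-frequency weighted and renormalized."""
        if "functional_class" not in self.df.columns:
            raise ValueError("spectrum was built without a class map")
        sub = self.df.dropna(subset=["functional_class"])
        weights = sub.groupby("functional_class")["frequency"].sum()
        out = weights.reindex(CLASSES, fill_value=0.0).astype(float)
        return out / out.sum()

    def class_coverage(self) -> float:
        """Fraction of spectrum variants assigned a class by the class map."""
        if "functional_class" not in self.df.columns:
            return 0.0
        return float(self.df["functional_class"].notna().mean())


def null_spectrum(
    cds: CdsSequence,
    class_map: Mapping[str, str] | None = None,
    include_start: bool = False,
    include_stop: bool = False,
    rate_weight: Callable[[str, str], float] | None = None,
    min_class_coverage: float = 0.25,
) -> NullSpectrum:
    """Collapse the SNV event list to unique missense/nonsense protein
    variants with degeneracy frequencies.

    ``class_map`` maps canonical variant tokens to one of the four
    functional classes; variants it does not cover are kept with a missing
    class and excluded from expected-fraction denominators.  A warning
    reports class coverage when it falls below ``min_class_coverage``.
    ``rate_weight(ref_nt, alt_nt)`` weights each event (default 1.0,
    i.e. a uniform mutation-rate model).
    """
    events = enumerate_snvs(cds, include_start=include_start, include_stop=include_stop)
    rows: dict[str, dict] = {}
    for ev in events:
        if ev.consequence == SYNONYMOUS:
            continue
        token = str(ev.protein_variant)
        w = 1.0 if rate_weight is None else float(rate_weight(ev.ref_nt, ev.alt_nt))
        if token not in rows:
            rows[token] = {
                "variant": token,
                "consequence": ev.consequence,
                "frequency": 0.0,
            }
        rows[token]["frequency"] += w
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df = df.sort_values("variant", kind="mergesort").reset_index(drop=True)
    by_cons = {
        c: sum(1 for ev in events if ev.consequence == c)
        for c in (SYNONYMOUS, MISSENSE, NONSENSE)
    }
    if class_map is not None and not df.empty:
        df["functional_class"] = [class_map.get(t) for t in df["variant"]]
        coverage = df["functional_class"].notna().mean()
        if coverage < min_class_coverage:
            warnings.warn(
                f"class map covers only {coverage:.1%} of spectrum variants",
                stacklevel=2,
            )
    return NullSpectrum(
        df=df, n_events_total=len(events), n_events_by_consequence=by_cons
    )


def observed_class_fractions(
    catalog,
    class_map: Mapping[str, str],
    mode: str = "per_observation",
) -> tuple[pd.Series, int]:
    """Class fractions among catalog variants that the class map covers.

    ``mode`` is ``per_observation`` (weight each observation) or
    ``unique_variant`` (weight each distinct variant once).  Returns the
    fractions over the four classes (summing to 1) and the number of
    classified observations (or variants) counted.
    """
    if mode not in ("per_observation", "unique_variant"):
        raise ValueError(f"unknown mode {mode!r}")
    df = catalog.df if hasattr(catalog, "df") else catalog
    if mode == "unique_variant":
        df = df.drop_duplicates("variant")
        weights = pd.Series(1, index=df.index)
    else:
        weights = df["n_observations"]
    classes = df["variant"].map(lambda t: class_map.get(t))
    keep = classes.notna()
    if not keep.any():
        raise ValueError("no catalog observation maps to a functional class")
    counts = (
        pd.DataFrame({"functional_class": classes[keep], "w": weights[keep]})
        .groupby("functional_class")["w"]
        .sum()
    )
    out = counts.reindex(CLASSES, fill_value=0).astype(float)
    n_classified = int(weights[keep].sum())
    return out / out.sum(), n_classified


def fold_enrichment(observed: pd.Series, expected: pd.Series) -> pd.Series:
    """Per-class fold enrichment: observed fraction / expected fraction.

    An expected fraction of 0 with nonzero observed yields +inf with a
    warning rather than an error.
    """
    expected = expected.reindex(observed.index)
    if abs(float(expected.sum()) - 1.0) > 1e-9:
        raise ValueError("expected fractions must sum to 1")
    folds = observed.astype(float).copy()
    for cls in observed.index:
        e, o = float(expected[cls]), float(observed[cls])
        if e == 0.0:
            if o > 0.0:
                warnings.warn(f"class {cls!r} has expected fraction 0", stacklevel=2)
                folds[cls] = float("inf")
            else:
                folds[cls] = float("nan")
        else:
            folds[cls] = o / e
    return folds.rename("fold_enrichment")
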