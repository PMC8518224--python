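"""Variant nomenclature and table/sequence I/O.

Amino-acid-level protein variants are the unit of record throughout the
package.  A variant is written wild-type residue, 1-based protein position,
mutant residue; one-letter ("R130Q", "R130*") and three-letter
("Arg130Gln", "Arg130Ter") notations are accepted on input and the
one-letter form is canonical internally.  Consequence (missense, nonsense,
synonymous) is fully determined by the two residues.

The readers/writers here carry every external table the pipeline touches:
replicate and composite score tables (TSV), activity-score tables (TSV),
variant catalogs in the style of ClinVar/cBioPortal extracts (TSV), and a
coding sequence as FASTA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_TOKEN_RE = re.compile(r"^([A-Za-z]{3}|[A-Za-z*])(\d+)([A-Za-z]{3}|[A-Za-z*])$")


class VariantParseError(ValueError):
    """Raised when a variant token cannot be interpreted."""


@dataclass(frozen=True, order=True)
class VariantId:
    """A single-residue protein change, e.g. R130Q.

    ``wt_aa`` and ``mut_aa`` are one-letter codes with ``*`` for stop.
    ``position`` is the 1-based protein coordinate (Met1 is position 1).
    """

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantParseError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa != "*" and aa not in AA1:
                raise VariantParseError(f"unknown amino-acid code {aa!r}")

    @property
    def consequence(self) -> str:
        if self.wt_aa == self.mut_aa:
            return SYNONYMOUS
        if self.mut_aa == "*":
            return NONSENSE
        return MISSENSE

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def _resolve_aa(code: str, token: str) -> str:
    if code == "*":
        return "*"
    if len(code) == 1:
        up = code.upper()
        if up in AA1:
            return up
        raise VariantParseError(f"unknown amino-acid code {code!r} in {token!r}")
    cap = code.capitalize()
    if cap in AA3_TO_1:
        return AA3_TO_1[cap]
    raise VariantParseError(f"unknown amino-acid code {code!r} in {token!r}")


def parse_variant(token: str) -> VariantId:
    """Parse one-letter, three-letter, or Ter/``*`` stop notation.

    >>> parse_variant("Arg130Pro")
    VariantId(wt_aa='R', position=130, mut_aa='P')
    """
    if not token or not token.strip():
        raise VariantParseError("empty variant token")
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise VariantParseError(f"malformed variant token {token!r}")
    wt, pos, mut = m.groups()
    return VariantId(_resolve_aa(wt, token), int(pos), _resolve_aa(mut, token))


def format_variant(v: VariantId, style: str = "one") -> str:
    """Format a variant; ``style`` is ``"one"`` (R130*) or ``"three"`` (Arg130Ter)."""
    if style == "one":
        return str(v)
    if style == "three":
        return f"{AA1_TO_3[v.wt_aa]}{v.position}{AA1_TO_3[v.mut_aa]}"
    raise ValueError(f"unknown style {style!r}")


# ---------------------------------------------------------------------------
# Coding sequences
# ---------------------------------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}


class CdsError(ValueError):
    pass


@dataclass(frozen=True)
class CdsSequence:
    """A protein-coding nucleotide sequence under the standard genetic code."""

    name: str
    nucleotides: str

    def __post_init__(self) -> None:
        nt = self.nucleotides
        if len(nt) % 3 != 0:
            raise CdsError(f"CDS length {len(nt)} is not divisible by 3")
        if set(nt) - set("ACGT"):
            bad = sorted(set(nt) - set("ACGT"))
            raise CdsError(f"CDS contains non-ACGT symbols: {bad}")
        prot = str(Seq(nt).translate())
        if "*" in prot[:-1]:
            idx = prot.index("*") + 1
            raise CdsError(f"internal stop codon at codon index {idx}")

    @property
    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def translate(self) -> str:
        return str(Seq(self.nucleotides).translate())

    @property
    def has_terminal_stop(self) -> bool:
        return self.nucleotides[-3:] in STOP_CODONS


def read_cds_fasta(path: str | Path) -> CdsSequence:
    """Read the first record of a FASTA file as a CDS.

    Sequence is uppercased and U is normalized to T before validation.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise CdsError(f"no FASTA records in {path}")
    rec = records[0]
    nt = str(rec.seq).upper().replace("U", "T")
    return CdsSequence(name=rec.id, nucleotides=nt)


def write_cds_fasta(cds: CdsSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{cds.name}\n")
        for i in range(0, len(cds.nucleotides), 60):
            fh.write(cds.nucleotides[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

#: decimal text with >= 10 significant digits so write/read round-trips
FLOAT_FORMAT = "%.12g"


@dataclass
class ScoreTable:
    """Per-variant scores across one or more labelled columns.

    ``df`` is indexed by canonical variant tokens; columns are replicate
    labels (or a single score column).  Missing scores are NaN, never zero.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dups = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate variant rows: {dups}")
        if self.df.columns.has_duplicates:
            raise ValueError("replicate labels must be unique")

    @property
    def variants(self) -> list[VariantId]:
        return [parse_variant(t) for t in self.df.index]

    def consequences(self) -> pd.Series:
        return pd.Series(
            [parse_variant(t).consequence for t in self.df.index],
            index=self.df.index,
            name="consequence",
        )

    def n_reps(self) -> pd.Series:
        """Number of non-missing replicate scores per variant."""
        return self.df.notna().sum(axis=1).rename("n_reps")


def read_score_table(
    path: str | Path,
    variant_col: str = "variant",
    score_cols: Iterable[str] | None = None,
) -> ScoreTable:
    """Read a TSV score table.

    ``score_cols`` selects replicate/score columns; by default every column
    other than the variant column is used.  The column mapping is
    configurable because deposited supplementary tables differ in layout.
    """
    df = pd.read_csv(path, sep="\t", dtype={variant_col: str})
    if variant_col not in df.columns:
        raise ValueError(f"missing variant column {variant_col!r} in {path}")
    tokens = []
    for i, tok in enumerate(df[variant_col]):
        try:
            tokens.append(str(parse_variant(tok)))
        except VariantParseError as e:
            # +2: one for the header line, one for 1-based numbering
            raise VariantParseError(f"{path} line {i + 2}: {e}") from e
    cols = list(score_cols) if score_cols is not None else [
        c for c in df.columns if c != variant_col
    ]
    out = df[cols].copy()
    out.index = pd.Index(tokens, name="variant")
    return ScoreTable(out.astype(float))


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    df = table.df.copy()
    df.index.name = "variant"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Variant catalogs (clinical / somatic extracts)
# ---------------------------------------------------------------------------


@dataclass
class CancerCatalog:
    """Observations of variants per category (cancer type or clinical group).

    ``df`` has columns ``variant``, ``category``, ``n_observations`` with one
    row per (variant, category) pair after aggregation.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"variant", "category", "n_observations"}
        if not required <= set(self.df.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        if (self.df["n_observations"] < 1).any():
            raise ValueError("n_observations must be >= 1")
        if self.df.duplicated(["variant", "category"]).any():
            raise ValueError("(variant, category) pairs must be unique")

    @property
    def categories(self) -> list[str]:
        return sorted(self.df["category"].unique())


def read_cancer_catalog(
    path: str | Path,
    variant_col: str = "variant",
    category_col: str = "category",
    count_col: str = "count",
) -> CancerCatalog:
    """Read a variant catalog TSV; rows with identical (variant, category)
    are summed.  The count column is optional and defaults to 1 per row."""
    df = pd.read_csv(path, sep="\t", dtype={variant_col: str, category_col: str})
    for col in (variant_col, category_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    tokens = []
    for i, tok in enumerate(df[variant_col]):
        try:
            tokens.append(str(parse_variant(tok)))
        except VariantParseError as e:
            raise VariantParseError(f"{path} line {i + 2}: {e}") from e
    counts = (
        df[count_col].astype(int)
        if count_col in df.columns
        else pd.Series(1, index=df.index)
    )
    agg = (
        pd.DataFrame(
            {"variant": tokens, "category": df[category_col], "n_observations": counts}
        )
        .groupby(["variant", "category"], as_index=False)["n_observations"]
        .sum()
    )
    return CancerCatalog(agg)


def write_cancer_catalog(catalog: CancerCatalog, path: str | Path) -> None:
    out = catalog.df.rename(columns={"n_observations": "count"})
    out.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Generic TSV writer used for all derived outputs (>=10 sig. digits)."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
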