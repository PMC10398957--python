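"""Gene-set overlap and enrichment statistics.

All cross-signature comparisons in the pipeline (mouse-model signatures,
GWAS gene lists, transcription-factor enrichment, generic gene-set
over-representation) reduce to 2x2 contingency tables tested with
Fisher's exact test or a Pearson chi-squared test. Odds ratios are the
sample cross-product ratio ad/bc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .clustering import bh_adjust

__all__ = [
    "ContingencyTable",
    "SignatureSet",
    "HomologyMap",
    "FisherResult",
    "ChiSquaredResult",
    "fisher_exact_2x2",
    "chi_squared_2x2",
    "overlap_fisher",
    "map_homologs",
    "tf_enrichment",
    "ora_gene_sets",
    "read_gmt",
    "read_signature_tsv",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of non-negative counts::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table must have positive total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def odds_ratio(self) -> float:
        """Sample cross-product ratio ad/bc (inf when bc = 0 and ad > 0)."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return float("nan") if num == 0 else float("inf")
        return num / den


@dataclass
class SignatureSet:
    """A named gene list with optional per-gene direction (up/down)."""

    name: str
    genes: list[str]
    directions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate genes in signature {self.name!r}: {dupes[:5]}")
        stray = set(self.directions) - set(self.genes)
        if stray:
            raise ValueError(f"directions given for non-member genes: {sorted(stray)[:5]}")
        bad = {d for d in self.directions.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"directions must be 'up' or 'down', got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def subset(self, direction: str) -> list[str]:
        return [g for g in self.genes if self.directions.get(g) == direction]


@dataclass
class HomologyMap:
    """Mouse symbol -> human symbol pairs (two-column table)."""

    pairs: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("homology table needs two columns: mouse, human")
        return cls(dict(zip(df[0], df[1])))


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    table: ContingencyTable


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    p_value: float
    df: int
    table: ContingencyTable


def fisher_exact_2x2(table: ContingencyTable, alternative: str = "two-sided") -> FisherResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p is the sum of probabilities of all margin-fixed tables no
    more probable than the observed one. The reported odds ratio is the
    sample cross-product ratio, not the conditional MLE.
    """
    res = scipy.stats.fisher_exact(table.as_array(), alternative=alternative)
    return FisherResult(float(res.pvalue), table.odds_ratio, table)


def chi_squared_2x2(table: ContingencyTable, yates: bool = False) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on a 2x2 table (df = 1)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined for a table with a zero margin")
    stat, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=yates)
    return ChiSquaredResult(float(stat), float(p), int(dof), table)


def overlap_fisher(
    set_a: set[str] | list[str],
    set_b: set[str] | list[str],
    universe: set[str] | list[str],
) -> FisherResult:
    """Fisher test of the overlap of two gene sets within a universe.

    Builds a = |A∩B|, b = |A\\B|, c = |B\\A|, d = |universe \\ (A∪B)|.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    for label, s in (("A", set_a), ("B", set_b)):
        extra = s - universe
        if extra:
            raise ValueError(
                f"set {label} contains genes outside the universe: {sorted(extra)[:10]}"
            )
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return fisher_exact_2x2(ContingencyTable(a, b, c, d))


def map_homologs(
    signature: SignatureSet, homology: HomologyMap, universe: set[str] | list[str]
) -> tuple[SignatureSet, int]:
    """Map a (mouse) signature into the human analysis universe.

    Keeps genes that both map and land inside the universe; returns the
    mapped signature (directions carried over) and the number dropped.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    mapped: list[str] = []
    directions: dict[str, str] = {}
    unmapped = 0
    for gene in signature.genes:
        human = homology.pairs.get(gene)
        if human is None or human not in universe:
            unmapped += 1
            continue
        if human in directions or human in mapped:
            continue  # two mouse genes collapsing onto one human symbol
        mapped.append(human)
        if gene in signature.directions:
            directions[human] = signature.directions[gene]
    return SignatureSet(f"{signature.name}_human", mapped, directions), unmapped


def tf_enrichment(
    signature: SignatureSet,
    tf_list: set[str] | list[str],
    universe: set[str] | list[str],
) -> dict[str, ChiSquaredResult]:
    """Transcription-factor enrichment within a signature, chi-squared.

    For the whole signature and each direction present, builds the 2x2 of
    (TF, non-TF) inside the gene list against the rest of the universe.
    """
    if not signature.genes:
        raise ValueError("empty signature")
    universe = set(universe)
    tfs = set(tf_list) & universe
    if not tfs:
        raise ValueError("no transcription factors present in the universe")
    results: dict[str, ChiSquaredResult] = {}
    subsets: dict[str, list[str]] = {"all": signature.genes}
    for direction in ("up", "down"):
        sub = signature.subset(direction)
        if sub:
            subsets[direction] = sub
    for label, genes in subsets.items():
        gene_set = set(genes)
        a = len(gene_set & tfs)
        b = len(gene_set - tfs)
        c = len(tfs - gene_set)
        d = len(universe) - a - b - c
        results[label] = chi_squared_2x2(ContingencyTable(a, b, c, d))
    return results


def ora_gene_sets(
    signature: SignatureSet,
    collection: dict[str, list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """Over-representation of a signature against a gene-set collection.

    One-sided (enrichment) Fisher test per set, restricted to the
    universe, with BH adjustment across sets. Stand-in for interactive GO
    enrichment services; no term-redundancy clustering is attempted.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    sig = set(signature.genes) & universe
    rows = []
    for name, genes in collection.items():
        gene_set = set(genes) & universe
        a = len(sig & gene_set)
        b = len(sig - gene_set)
        c = len(gene_set - sig)
        d = len(universe) - a - b - c
        table = ContingencyTable(a, b, c, d)
        res = fisher_exact_2x2(table, alternative="greater")
        rows.append(
            {
                "set": name,
                "overlap": a,
                "set_size": len(gene_set),
                "signature_size": len(sig),
                "odds_ratio": table.odds_ratio,
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection (set name, description, genes...)."""
    collection: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 fields): {line[:80]!r}")
        collection[fields[0]] = [g for g in fields[2:] if g]
    return collection


def read_signature_tsv(path: str | Path, name: str | None = None) -> SignatureSet:
    """Read a signature TSV with columns ``gene`` and optional ``direction``."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("signature TSV needs a 'gene' column")
    genes = df["gene"].astype(str).tolist()
    directions = {}
    if "direction" in df.columns:
        directions = {
            g: d for g, d in zip(genes, df["direction"]) if isinstance(d, str) and d in ("up", "down")
        }
    return SignatureSet(name or Path(path).stem, genes, directions)
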