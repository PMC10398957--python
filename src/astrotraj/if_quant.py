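"""Immunofluorescence nucleus-count statistics.

Marker-positive nucleus counts are pooled over donors and images within
each group (AD vs control) and the pooled proportions compared with a
two-sided Fisher's exact test — the aggregated-count design used for
validation imaging, not a per-donor stratified model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import ContingencyTable, FisherResult, fisher_exact_2x2

__all__ = ["MARKER_TABLE_COLUMNS", "pool_counts", "compare_proportions", "ProportionComparison"]

#: schema of an IF marker-count table
MARKER_TABLE_COLUMNS = ["donor", "group", "image", "marker", "denominator", "positive", "total"]


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in MARKER_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"marker count table missing columns: {missing}")
    bad = table[(table["positive"] < 0) | (table["total"] < 0)]
    if len(bad):
        raise ValueError(f"negative counts in rows: {bad.index.tolist()[:5]}")
    over = table[table["positive"] > table["total"]]
    if len(over):
        first = over.iloc[0]
        raise ValueError(
            "positive exceeds denominator in row "
            f"(donor={first['donor']!r}, image={first['image']!r}, "
            f"marker={first['marker']!r}): {first['positive']} > {first['total']}"
        )


def pool_counts(
    table: pd.DataFrame, marker: str, denominator: str
) -> tuple[ContingencyTable, list[str]]:
    """Pool marker-positive counts per group into a 2x2 table.

    Rows with the requested marker and denominator label are summed per
    group; cells are (positive, negative = total - positive) per group.
    Returns the table plus the group order of its rows.
    """
    _validate_table(table)
    sub = table[(table["marker"] == marker) & (table["denominator"] == denominator)]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError(
            f"need both groups to compare; found {groups!r} for marker "
            f"{marker!r} over denominator {denominator!r}"
        )
    if len(groups) > 2:
        raise ValueError(f"expected exactly two groups, found {groups!r}")
    pooled = sub.groupby("group")[["positive", "total"]].sum()
    g1, g2 = groups
    return (
        ContingencyTable(
            a=int(pooled.loc[g1, "positive"]),
            b=int(pooled.loc[g1, "total"] - pooled.loc[g1, "positive"]),
            c=int(pooled.loc[g2, "positive"]),
            d=int(pooled.loc[g2, "total"] - pooled.loc[g2, "positive"]),
        ),
        groups,
    )


@dataclass(frozen=True)
class ProportionComparison:
    groups: tuple[str, str]
    proportions: tuple[float, float]
    odds_ratio: float
    p_value: float
    fisher: FisherResult


def compare_proportions(pooled: ContingencyTable, groups: tuple[str, str] = ("g1", "g2")) -> ProportionComparison:
    """Compare pooled marker-positive proportions between two groups."""
    n1 = pooled.a + pooled.b
    n2 = pooled.c + pooled.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need a nonzero denominator")
    res = fisher_exact_2x2(pooled)
    return ProportionComparison(
        groups=tuple(groups),
        proportions=(round(pooled.a / n1, 3), round(pooled.c / n2, 3)),
        odds_ratio=res.odds_ratio,
        p_value=res.p_value,
        fisher=res,
    )
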