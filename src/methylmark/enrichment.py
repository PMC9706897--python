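"""Gene-family overrepresentation of DMGs by 2x2 chi-square.

The background is an HGNC-style family table: a many-to-many mapping of
gene symbols to named families, together with the universe of all symbols
it covers. For each family a 2x2 table is built —

    rows:    DMG, non-DMG universe gene
    columns: in family, not in family

and tested with the chi-square test. Both the Yates-corrected and the
uncorrected statistic are reported; the corrected p drives the enrichment
flag (p < threshold AND the DMG in-family proportion exceeding the
background proportion, i.e. overrepresentation only). No correction across
families is applied to the flag; a Benjamini-Hochberg FDR column is emitted
for information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class FamilyTable:
    """Family name -> member symbols, plus the background universe.

    ``universe`` defaults to the union of all family members; pass it
    explicitly to include family-less genes in the background.
    """

    families: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, members in self.families.items():
            if not members:
                raise ValueError(f"family {name!r} is empty")
        members_union = set().union(*self.families.values()) if self.families else set()
        if not self.universe:
            self.universe = set(members_union)
        elif not members_union <= self.universe:
            raise ValueError("family members outside the declared universe")


def read_family_table(path, universe: set[str] | None = None) -> FamilyTable:
    """Read a two-column TSV (family_name, gene_symbol)."""
    df = pd.read_csv(path, sep="\t")
    families = {
        name: set(sub["gene_symbol"])
        for name, sub in df.groupby("family_name")
    }
    return FamilyTable(families=families, universe=universe or set())


def write_family_table(table: FamilyTable, path) -> None:
    rows = [
        {"family_name": name, "gene_symbol": sym}
        for name in sorted(table.families)
        for sym in sorted(table.families[name])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """(corrected chi2, corrected p, uncorrected chi2) for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0, 0.0
    chi2_c, p_c, _, _ = stats.chi2_contingency(table, correction=True)
    chi2_u, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2_c), float(p_c), float(chi2_u)


def family_enrichment(
    dmgs: list[str] | set[str],
    table: FamilyTable,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every family for DMG overrepresentation.

    Returns a DataFrame sorted by p with columns ``family, a, b, c, d,
    chi2, chi2_uncorrected, p_value, q_value, dmg_fraction_of_family,
    enriched``. Counts: a = DMGs in family, b = DMGs outside, c = non-DMG
    universe genes in family, d = non-DMG universe genes outside.

    DMGs outside the universe are dropped first; if none remain, raises.
    """
    dmg_set = set(dmgs) & table.universe
    if not dmg_set:
        raise ValueError("no DMGs intersect the family-table universe")
    n_universe = len(table.universe)
    rows = []
    for name, members in table.families.items():
        a = len(dmg_set & members)
        c = len(members - dmg_set)
        b = len(dmg_set) - a
        d = n_universe - len(dmg_set) - c
        chi2_c, p_c, chi2_u = _chi2_2x2(a, b, c, d)
        over = (a / (a + b)) > (c / (c + d)) if (c + d) else a > 0
        rows.append({
            "family": name,
            "a": a, "b": b, "c": c, "d": d,
            "chi2": chi2_c,
            "chi2_uncorrected": chi2_u,
            "p_value": p_c,
            "dmg_fraction_of_family": a / (a + c),
            "enriched": bool(p_c < p_threshold and over),
        })
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out[["family", "a", "b", "c", "d", "chi2", "chi2_uncorrected",
                "p_value", "q_value", "dmg_fraction_of_family", "enriched"]]
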