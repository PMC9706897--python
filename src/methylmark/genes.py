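"""Mapping DMRs to genes and classifying DMR genomic location.

A gene is a candidate differentially methylated gene (DMG) for a direction
when at least one DMR of that direction overlaps its gene body by >= 1 bp
(half-open interval arithmetic; promoters/flanks are not added). Genes hit
by both NC- and ESCC-DMRs are excluded from both lists — mixed-direction
genes are ambiguous as markers.

Genes are plain DataFrames with BED6-style columns
``symbol, chrom, start, end, strand`` (0-based half-open). Strand is
carried but ignored for overlap: methylation intervals are strandless here.
"""

from __future__ import annotations

import pandas as pd

GENE_COLUMNS = ["symbol", "chrom", "start", "end", "strand"]


def _overlapping_symbols(dmrs: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Symbols of genes overlapping >= 1 bp with any DMR (half-open)."""
    hits: set[str] = set()
    for chrom, gsub in genes.groupby("chrom", sort=False):
        dsub = dmrs[dmrs["chrom"] == chrom]
        if dsub.empty:
            continue
        ds = dsub["bed_start"].to_numpy()
        de = dsub["bed_end"].to_numpy()
        for sym, gs, ge in zip(gsub["symbol"], gsub["start"], gsub["end"]):
            if ((ds < ge) & (gs < de)).any():
                hits.add(sym)
    return hits


def map_dmrs_to_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame
) -> tuple[list[str], list[str], list[str]]:
    """Map DMRs onto gene bodies with the both-direction exclusion rule.

    Returns (nc_dmgs, escc_dmgs, excluded_symbols), each sorted. A symbol in
    ``excluded_symbols`` overlapped DMRs of both directions and appears in
    neither DMG list.
    """
    if not genes["symbol"].is_unique:
        raise ValueError("gene symbols must be unique")
    nc = _overlapping_symbols(dmrs[dmrs["direction"] == "NC"], genes)
    escc = _overlapping_symbols(dmrs[dmrs["direction"] == "ESCC"], genes)
    both = nc & escc
    return sorted(nc - both), sorted(escc - both), sorted(both)


def classify_dmr_location(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-direction fractions of inner-genic vs intergenic DMRs.

    A DMR is inner-genic iff its interval midpoint lies within any gene body.
    Fractions per direction sum to 1 (directions without DMRs report NaN).
    """
    rows = []
    for direction in ("NC", "ESCC"):
        sub = dmrs[dmrs["direction"] == direction]
        if sub.empty:
            rows.append({"direction": direction, "n": 0,
                         "inner_genic": float("nan"),
                         "intergenic": float("nan")})
            continue
        inner = 0
        for chrom, grp in sub.groupby("chrom", sort=False):
            gsub = genes[genes["chrom"] == chrom]
            gs = gsub["start"].to_numpy()
            ge = gsub["end"].to_numpy()
            mids = (grp["bed_start"].to_numpy() + grp["bed_end"].to_numpy()) // 2
            for mid in mids:
                if ((gs <= mid) & (mid < ge)).any():
                    inner += 1
        frac = inner / len(sub)
        rows.append({"direction": direction, "n": len(sub),
                     "inner_genic": frac, "intergenic": 1.0 - frac})
    return pd.DataFrame(rows)


def read_genes_bed(path) -> pd.DataFrame:
    """Read a BED6 gene annotation (chrom, start, end, name, score, strand)."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "symbol", "score", "strand"])
    genes = bed[["symbol", "chrom", "start", "end", "strand"]].copy()
    if (genes["end"] <= genes["start"]).any():
        raise ValueError("gene intervals must satisfy end > start")
    return genes


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": genes["start"],
        "end": genes["end"],
        "name": genes["symbol"],
        "score": 0,
        "strand": genes.get("strand", "+"),
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def count_supporting_dmrs(symbol: str, direction: str, dmrs: pd.DataFrame,
                          genes: pd.DataFrame) -> int:
    """Number of DMRs of one direction overlapping the gene body."""
    gene = genes.loc[genes["symbol"] == symbol].iloc[0]
    sub = dmrs[(dmrs["direction"] == direction) & (dmrs["chrom"] == gene["chrom"])]
    ds = sub["bed_start"].to_numpy()
    de = sub["bed_end"].to_numpy()
    return int(((ds < gene["end"]) & (gene["start"] < de)).sum())


def write_dmgs(nc_dmgs, escc_dmgs, excluded, dmrs: pd.DataFrame,
               genes: pd.DataFrame, path) -> None:
    """DMG TSV: symbol, direction, n_supporting_dmrs; excluded symbols flagged."""
    rows = [
        {"symbol": s, "direction": d,
         "n_supporting_dmrs": count_supporting_dmrs(s, d, dmrs, genes)}
        for d, symbols in (("NC", nc_dmgs), ("ESCC", escc_dmgs))
        for s in symbols
    ]
    rows += [{"symbol": s, "direction": "excluded", "n_supporting_dmrs": 0}
             for s in excluded]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
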