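"""Differentially methylated region (DMR) calling by greedy chaining.

DMCs of one direction on one chromosome are chained left to right: the next
DMC extends the current chain iff its gap to the previous member is below
``max_gap`` AND the resulting span (last - first member position) stays
within ``max_len``. Otherwise the chain is closed — emitted if it holds at
least ``min_dmcs`` members — and a new chain starts at the current DMC.
Opposite-direction DMCs are invisible to a chain and never break it.

The defaults (max_len=100 bp, min_dmcs=3, max_gap=50 bp) target regions
short enough to design methylation-specific PCR amplicons over. The short
max_len deliberately splits dense DMC runs: a 114-bp run of six DMCs yields
two regions at max_len=100 but a single region at max_len=300.

Emitted coordinates: ``start``/``end`` are the first/last member CpG
positions; ``bed_start``/``bed_end`` give the half-open interval
[start, end+2) covering the final CpG dinucleotide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DMR_COLUMNS = ["chrom", "start", "end", "bed_start", "bed_end", "span",
               "direction", "dmc_count", "dmr_id", "members"]


def _chain_positions(pos: np.ndarray, max_len: int, min_dmcs: int,
                     max_gap: int) -> list[list[int]]:
    """Greedy chains over sorted positions of a single chromosome/direction."""
    chains: list[list[int]] = []
    current: list[int] = []
    for p in pos:
        if current and (p - current[-1] < max_gap) and (p - current[0] <= max_len):
            current.append(p)
        else:
            if len(current) >= min_dmcs:
                chains.append(current)
            current = [p]
    if len(current) >= min_dmcs:
        chains.append(current)
    return chains


def call_dmrs(
    dmcs: pd.DataFrame,
    max_len: int = 100,
    min_dmcs: int = 3,
    max_gap: int = 50,
) -> pd.DataFrame:
    """Group sorted DMCs into DMRs, per chromosome and direction.

    Raises if the input is not sorted by (chrom, pos).
    """
    if len(dmcs):
        key = list(zip(dmcs["chrom"], dmcs["pos"]))
        if key != sorted(key):
            raise ValueError("DMC table must be sorted by (chrom, pos)")
    rows = []
    for direction in ("NC", "ESCC"):
        sub = dmcs[dmcs["direction"] == direction]
        for chrom, grp in sub.groupby("chrom", sort=True):
            pos = grp["pos"].to_numpy(dtype=int)
            for i, chain in enumerate(
                _chain_positions(pos, max_len, min_dmcs, max_gap)
            ):
                rows.append({
                    "chrom": chrom,
                    "start": chain[0],
                    "end": chain[-1],
                    "bed_start": chain[0],
                    "bed_end": chain[-1] + 2,
                    "span": chain[-1] - chain[0],
                    "direction": direction,
                    "dmc_count": len(chain),
                    "members": list(chain),
                })
    out = pd.DataFrame(rows, columns=[c for c in DMR_COLUMNS if c != "dmr_id"])
    out = out.sort_values(["chrom", "start", "direction"],
                          kind="stable").reset_index(drop=True)
    out["dmr_id"] = [
        f"{d}-DMR{i + 1}"
        for d, i in zip(out["direction"],
                        out.groupby("direction").cumcount())
    ]
    return out[DMR_COLUMNS]


def dmr_summary(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-direction counts, mean member counts and adjacent-DMR distances.

    The distance between two consecutive DMRs of one direction on one
    chromosome is next start minus previous end.
    """
    rows = []
    for direction in ("NC", "ESCC"):
        sub = dmrs[dmrs["direction"] == direction] if len(dmrs) else dmrs
        dists: list[int] = []
        for _, grp in (sub.groupby("chrom", sort=True) if len(sub) else ()):
            grp = grp.sort_values("start")
            gaps = grp["start"].to_numpy()[1:] - grp["end"].to_numpy()[:-1]
            dists.extend(gaps.astype(int).tolist())
        rows.append({
            "direction": direction,
            "n_dmrs": len(sub),
            "mean_dmc_count": float(sub["dmc_count"].mean()) if len(sub) else 0.0,
            "mean_adjacent_distance": float(np.mean(dists)) if dists else float("nan"),
            "median_adjacent_distance": float(np.median(dists)) if dists else float("nan"),
        })
    return pd.DataFrame(rows)


def write_dmrs(dmrs: pd.DataFrame, bed_path, members_path=None) -> None:
    """Write a BED-like TSV (half-open coords) plus optional member sidecar."""
    bed = pd.DataFrame({
        "chrom": dmrs["chrom"],
        "start": dmrs["bed_start"],
        "end": dmrs["bed_end"],
        "name": dmrs["dmr_id"],
        "dmc_count": dmrs["dmc_count"],
        "span": dmrs["span"],
    })
    bed.to_csv(bed_path, sep="\t", index=False)
    if members_path is not None:
        rows = [
            {"dmr_id": rid, "chrom": chrom, "pos": p}
            for rid, chrom, members in zip(dmrs["dmr_id"], dmrs["chrom"],
                                           dmrs["members"])
            for p in members
        ]
        pd.DataFrame(rows).to_csv(members_path, sep="\t", index=False)
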