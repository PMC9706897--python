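"""In-silico bisulfite conversion and MSP/Sanger call analysis.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T
after PCR) while methylated cytosines stay C. Reading a Sanger trace of the
converted amplicon therefore gives a per-CpG methylation call: C at a CpG
offset means methylated, T unmethylated, anything else a failed call.

Only the forward ("top") bisulfite strand is modelled and non-CpG cytosines
are treated as always unmethylated (fully converted), matching the standard
MSP interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
MISSING = "missing"


@dataclass
class TargetRegion:
    """An MSP amplicon: reference sequence plus its CpG cytosine offsets."""

    name: str
    chrom: str
    start: int
    end: int
    sequence: str
    cpg_positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"end - start = {self.end - self.start}"
            )
        if not self.cpg_positions:
            self.cpg_positions = [
                i for i in range(len(self.sequence) - 1)
                if self.sequence[i:i + 2] == "CG"
            ]
        for i in self.cpg_positions:
            if self.sequence[i:i + 2] != "CG":
                raise ValueError(f"{self.name}: offset {i} is not a CpG cytosine")


@dataclass
class MspCallMatrix:
    """Per-sample, per-CpG methylation calls with group labels.

    ``calls``: rows = samples, columns = CpG positions, cells in
    {methylated, unmethylated, missing}. ``groups``: group label per sample
    (e.g. Normal, ESCC-tissue, ESCC-cfDNA).
    """

    calls: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.groups.index):
            raise ValueError("calls and groups must share the sample index")
        allowed = {METHYLATED, UNMETHYLATED, MISSING}
        bad = set(self.calls.to_numpy().ravel()) - allowed
        if bad:
            raise ValueError(f"unknown call values: {sorted(map(str, bad))}")


def bisulfite_convert(seq: str, methylated_offsets: set[int] | list[int]) -> str:
    """Convert a sequence as bisulfite would, given the methylated C offsets.

    Cytosines at ``methylated_offsets`` survive as C; all other cytosines
    read out as T; A/G/T are untouched. Offsets must point at cytosines.
    """
    seq = seq.upper()
    offsets = set(methylated_offsets)
    for i in offsets:
        if not 0 <= i < len(seq) or seq[i] != "C":
            raise ValueError(f"methylated offset {i} is not a cytosine")
    return "".join(
        ("C" if i in offsets else "T") if base == "C" else base
        for i, base in enumerate(seq)
    )


def call_cpg_status(region: TargetRegion, bs_seq: str) -> list[str]:
    """Per-CpG call vector from a bisulfite-converted read of the region."""
    bs_seq = bs_seq.upper()
    if len(bs_seq) != len(region.sequence):
        raise ValueError("converted sequence length differs from reference")
    calls = []
    for i in region.cpg_positions:
        base = bs_seq[i]
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(MISSING)
    return calls


def methylation_frequency(calls: MspCallMatrix, group: str) -> tuple[int, int, float]:
    """Pooled methylated/unmethylated counts and percent for one group.

    Pools every non-missing CpG-site x sample call of the group's rows.
    Percent is methylated/(methylated+unmethylated), rounded half-up to two
    decimals.
    """
    if group not in set(calls.groups):
        raise ValueError(f"group {group!r} not present")
    sub = calls.calls.loc[calls.groups == group].to_numpy()
    n_meth = int((sub == METHYLATED).sum())
    n_unmeth = int((sub == UNMETHYLATED).sum())
    if n_meth + n_unmeth == 0:
        raise ValueError("no informative calls")
    pct = 100.0 * n_meth / (n_meth + n_unmeth)
    # round half-up to 2 decimals (Python's round() is half-even)
    pct = float(np.floor(pct * 100 + 0.5) / 100)
    return n_meth, n_unmeth, pct


def group_contingency_test(
    calls: MspCallMatrix, groups: tuple[str, str]
) -> dict:
    """Chi-square (Yates-corrected) on the 2x2 methylated/unmethylated table.

    Returns the statistic, p-value and the table itself, keyed by group.
    """
    table = []
    for g in groups:
        n_meth, n_unmeth, _ = methylation_frequency(calls, g)
        table.append([n_meth, n_unmeth])
    arr = np.array(table, dtype=float)
    if arr.sum(axis=0).min() == 0:
        chi2, p, chi2_u = 0.0, 1.0, 0.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=True)
        chi2_u, _, _, _ = stats.chi2_contingency(arr, correction=False)
    return {
        "groups": list(groups),
        "table": {g: {"methylated": int(r[0]), "unmethylated": int(r[1])}
                  for g, r in zip(groups, table)},
        "chi2": float(chi2),
        "chi2_uncorrected": float(chi2_u),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_regions_tsv(path) -> list[TargetRegion]:
    """Region TSV: name, chrom, start, end, sequence."""
    df = pd.read_csv(path, sep="\t")
    return [
        TargetRegion(name=r["name"], chrom=r["chrom"], start=int(r["start"]),
                     end=int(r["end"]), sequence=r["sequence"])
        for _, r in df.iterrows()
    ]


def read_call_matrix(path) -> MspCallMatrix:
    """Call-matrix TSV: sample_id, group, then one column per CpG position."""
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    groups = df.pop("group")
    return MspCallMatrix(calls=df.fillna(MISSING), groups=groups)


def write_call_matrix(calls: MspCallMatrix, path) -> None:
    out = calls.calls.copy()
    out.insert(0, "group", calls.groups)
    out.to_csv(path, sep="\t", index=True, index_label="sample_id")
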