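"""Differentially methylated CpG (DMC) calling and adjacency statistics.

A CpG is differentially methylated between tumor and paired normal samples
when a two-sided paired t-test gives p < 0.05 and the fold change between
group means is >= 2. Sites hypermethylated in normal tissue are labelled
``NC`` (they are the hypomethylation events in tumor); sites hypermethylated
in tumor are labelled ``ESCC``.

Fold change is the ratio of the larger group mean over the smaller, with a
small pseudocount added to both means (1 percentage point on the percent
scale, 0.01 on the beta scale) so fully unmethylated sites do not divide by
zero.

The emitted table is a DataFrame with columns ``chrom, pos, mean_normal,
mean_tumor, fold_change, p_value, q_value, direction`` sorted by coordinate.
``q_value`` is a Benjamini-Hochberg FDR over all tested sites, reported for
information only — filtering uses the raw p-value.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MethylationMatrix, validate_metadata

logger = logging.getLogger(__name__)

DMC_COLUMNS = ["chrom", "pos", "mean_normal", "mean_tumor",
               "fold_change", "p_value", "q_value", "direction"]


def _paired_columns(meta: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Return (normal, tumor) sample columns aligned by pair_id."""
    if "pair_id" not in meta.columns:
        raise ValueError("paired test requires a pair_id column")
    paired = meta.dropna(subset=["pair_id"])
    normals, tumors = [], []
    for _, sub in paired.groupby("pair_id", sort=True):
        by_group = sub.set_index("group")["sample_id"]
        normals.append(by_group["normal"])
        tumors.append(by_group["tumor"])
    if len(normals) < 2:
        raise ValueError("paired test requires at least 2 complete pairs")
    return normals, tumors


def call_dmcs(
    m: MethylationMatrix,
    meta: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    test: str = "paired_t",
) -> pd.DataFrame:
    """Call DMCs between tumor and normal samples.

    Parameters
    ----------
    m
        Methylation matrix (no missing values; impute first).
    meta
        Sample metadata with ``sample_id``, ``group`` and, for the paired
        test, ``pair_id``.
    test
        ``"paired_t"`` (paired two-sided Student t) or ``"wilcoxon"``
        (two-sided Wilcoxon rank-sum / Mann-Whitney for unpaired groups).

    Sites with zero-variance paired differences have an undefined t
    statistic; they are skipped and their count logged.
    """
    validate_metadata(meta)
    pseudo = 1.0 if m.platform == "wgbs" else 0.01

    if test == "paired_t":
        normal_cols, tumor_cols = _paired_columns(meta)
    elif test == "wilcoxon":
        normal_cols = meta.loc[meta["group"] == "normal", "sample_id"].tolist()
        tumor_cols = meta.loc[meta["group"] == "tumor", "sample_id"].tolist()
        if min(len(normal_cols), len(tumor_cols)) < 2:
            raise ValueError("wilcoxon requires >= 2 samples per group")
    else:
        raise ValueError(f"unknown test {test!r}")

    normal = m.values[normal_cols].to_numpy(dtype=float)
    tumor = m.values[tumor_cols].to_numpy(dtype=float)
    mean_n = normal.mean(axis=1)
    mean_t = tumor.mean(axis=1)

    if test == "paired_t":
        diff = tumor - normal
        degenerate = diff.std(axis=1) == 0
        n_degenerate = int(degenerate.sum())
        if n_degenerate:
            logger.info("call_dmcs: skipping %d zero-variance sites", n_degenerate)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_rel(tumor, normal, axis=1)
        p = np.where(degenerate, np.nan, res.pvalue)
    else:
        res = stats.mannwhitneyu(tumor, normal, axis=1,
                                 alternative="two-sided")
        p = res.pvalue

    hi = np.maximum(mean_n, mean_t) + pseudo
    lo = np.minimum(mean_n, mean_t) + pseudo
    fold_change = hi / lo

    tested = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    emit = tested & (p < p_threshold) & (fold_change >= fc_threshold)
    direction = np.where(mean_t > mean_n, "ESCC", "NC")
    out = pd.DataFrame({
        "chrom": m.manifest["chrom"].to_numpy()[emit],
        "pos": m.manifest["pos"].to_numpy()[emit],
        "mean_normal": mean_n[emit],
        "mean_tumor": mean_t[emit],
        "fold_change": fold_change[emit],
        "p_value": p[emit],
        "q_value": q[emit],
        "direction": direction[emit],
    })
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def adjacent_distances(dmcs: pd.DataFrame, direction: str) -> list[int]:
    """Distances (bp) between consecutive same-direction DMCs per chromosome."""
    sub = dmcs[dmcs["direction"] == direction]
    dists: list[int] = []
    for _, grp in sub.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size >= 2:
            dists.extend(np.diff(pos).astype(int).tolist())
    return dists


def adjacent_correlation(
    dmcs: pd.DataFrame, m: MethylationMatrix, direction: str
) -> tuple[float, list[float]]:
    """Pearson correlation across samples of consecutive same-direction DMCs.

    Pairs where either site has zero variance across samples are skipped.
    Returns (mean r, per-pair r). With no usable pairs, mean is NaN.
    """
    if m.values.shape[1] < 3:
        raise ValueError("adjacent_correlation requires >= 3 samples")
    idx = m.site_index()
    arr = m.values.to_numpy(dtype=float)
    sub = dmcs[dmcs["direction"] == direction]
    rs: list[float] = []
    for _, grp in sub.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        chrom = grp["chrom"].iloc[0]
        for a, b in zip(pos[:-1], pos[1:]):
            x = arr[idx[(chrom, int(a))]]
            y = arr[idx[(chrom, int(b))]]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            rs.append(float(stats.pearsonr(x, y)[0]))
    mean_r = float(np.mean(rs)) if rs else float("nan")
    return mean_r, rs


def write_dmcs(dmcs: pd.DataFrame, path) -> None:
    dmcs.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dmcs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
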