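"""Methylation matrix containers, TSV I/O, site filtering and KNN imputation.

The central container is :class:`MethylationMatrix`: a per-CpG methylation
matrix (sites x samples) carrying a coordinate manifest and a platform tag.
Two platforms are supported:

* ``wgbs`` — whole-genome bisulfite sequencing; values are percent
  methylation in [0, 100]. Uncovered sites appear as exact zeros.
* ``array450k`` — 450k-style beta values in [0, 1]; uncovered probes appear
  as missing (NaN) cells.

Coordinates are 0-based and intervals half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORM_RANGE = {"wgbs": (0.0, 100.0), "array450k": (0.0, 1.0)}


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout or range."""


@dataclass
class MethylationMatrix:
    """Per-CpG methylation values with a coordinate manifest.

    Parameters
    ----------
    manifest
        DataFrame with columns ``chrom`` and ``pos`` (0-based coordinate of
        the CpG cytosine), one row per matrix row, sorted by (chrom, pos).
    values
        Sites x samples DataFrame of methylation values; NaN marks missing.
    platform
        ``"wgbs"`` (percent scale) or ``"array450k"`` (beta scale).
    """

    manifest: pd.DataFrame
    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORM_RANGE:
            raise ValueError(f"unknown platform {self.platform!r}")
        if len(self.manifest) != len(self.values):
            raise FormatError(
                f"manifest has {len(self.manifest)} rows but matrix has "
                f"{len(self.values)}"
            )
        if not self.values.columns.is_unique:
            raise FormatError("duplicate sample columns")
        order = np.lexsort((self.manifest["pos"].to_numpy(),
                            self.manifest["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(order))):
            self.manifest = self.manifest.iloc[order].reset_index(drop=True)
            self.values = self.values.iloc[order].reset_index(drop=True)
        else:
            self.manifest = self.manifest.reset_index(drop=True)
            self.values = self.values.reset_index(drop=True)
        lo, hi = PLATFORM_RANGE[self.platform]
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < lo) | (arr > hi)
        if np.any(bad & ~np.isnan(arr)):
            raise FormatError(
                f"values outside the {self.platform} range [{lo}, {hi}]"
            )

    @property
    def n_sites(self) -> int:
        return len(self.manifest)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def site_index(self) -> dict[tuple[str, int], int]:
        """Map (chrom, pos) -> row number."""
        return {
            (c, int(p)): i
            for i, (c, p) in enumerate(
                zip(self.manifest["chrom"], self.manifest["pos"])
            )
        }


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table.

    Requires unique ``sample_id`` and ``group`` in {normal, tumor}; when a
    ``pair_id`` column is present, every non-null pair must map exactly one
    normal to one tumor sample.
    """
    if not meta["sample_id"].is_unique:
        raise FormatError("sample_id values are not unique")
    bad = set(meta["group"]) - {"normal", "tumor"}
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")
    if "pair_id" in meta.columns:
        paired = meta.dropna(subset=["pair_id"])
        for pid, sub in paired.groupby("pair_id"):
            groups = sorted(sub["group"])
            if groups != ["normal", "tumor"]:
                raise FormatError(
                    f"pair {pid!r} does not map one normal to one tumor"
                )
    return meta


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_methylation(m: MethylationMatrix, matrix_path, manifest_path) -> None:
    """Write the matrix (rows keyed 'chrom:pos') and its manifest as TSV."""
    key = m.manifest["chrom"].astype(str) + ":" + m.manifest["pos"].astype(str)
    out = m.values.copy()
    out.insert(0, "site", key)
    out.to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
    m.manifest.to_csv(manifest_path, sep="\t", index=False)


def read_methylation(matrix_path, manifest_path, platform: str) -> MethylationMatrix:
    """Read a methylation matrix TSV plus manifest TSV.

    Rows are re-sorted by (chrom, pos); values are validated against the
    platform range and any out-of-range value raises :class:`FormatError`.
    """
    mat = pd.read_csv(matrix_path, sep="\t")
    manifest = pd.read_csv(manifest_path, sep="\t")
    if "site" not in mat.columns:
        raise FormatError("matrix TSV must carry a leading 'site' column")
    if len(mat) != len(manifest):
        raise FormatError(
            f"manifest rows ({len(manifest)}) != matrix rows ({len(mat)})"
        )
    values = mat.drop(columns="site")
    return MethylationMatrix(manifest=manifest, values=values, platform=platform)


def read_bedgraphs(paths: dict[str, str | Path], platform: str = "wgbs") -> MethylationMatrix:
    """Merge per-sample bedGraph-like files into one matrix.

    Each file has four columns (chrom, start, end, value) with the CpG
    cytosine at ``start``; samples are keyed by the dict. Sites absent from a
    sample become missing cells.
    """
    frames = []
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "end", sample],
                         usecols=[0, 1, 3])
        frames.append(df.set_index(["chrom", "pos"])[sample])
    merged = pd.concat(frames, axis=1).sort_index()
    manifest = merged.index.to_frame(index=False)
    return MethylationMatrix(manifest=manifest,
                             values=merged.reset_index(drop=True),
                             platform=platform)


def read_metadata(path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_sites(m: MethylationMatrix, max_missing_fraction: float = 0.9) -> MethylationMatrix:
    """Drop uninformative CpG rows, platform-dependently.

    WGBS: rows whose values are 0 in every sample are removed (these are
    uncovered sites). Array: rows missing in strictly more than
    ``max_missing_fraction`` of samples are removed. Row order is preserved;
    an empty result warns rather than errors.
    """
    arr = m.values.to_numpy(dtype=float)
    if m.platform == "wgbs":
        keep = ~np.all(arr == 0.0, axis=1)
    else:
        missing_frac = np.isnan(arr).mean(axis=1)
        keep = missing_frac <= max_missing_fraction
    if not keep.any():
        logger.warning("filter_sites removed every row")
    return MethylationMatrix(
        manifest=m.manifest.loc[keep].reset_index(drop=True),
        values=m.values.loc[keep].reset_index(drop=True),
        platform=m.platform,
    )


def knn_impute(m: MethylationMatrix, k: int = 10) -> MethylationMatrix:
    """Fill missing cells with the mean over the k nearest site rows.

    Distance between two rows is the plain Euclidean distance over their
    mutually observed columns; donor rows must have an observed value at the
    target column. Ties in distance are broken by row (coordinate) order.
    Observed values are never altered. A row with no observed value at all
    raises, naming the row.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = m.values.to_numpy(dtype=float).copy()
    nan_mask = np.isnan(arr)
    if not nan_mask.any():
        return m
    all_missing = np.where(nan_mask.all(axis=1))[0]
    if all_missing.size:
        c, p = m.manifest.iloc[all_missing[0]][["chrom", "pos"]]
        raise ValueError(f"row {c}:{p} has no observed values; cannot impute")

    filled = arr.copy()
    rows_with_missing = np.where(nan_mask.any(axis=1))[0]
    obs = ~nan_mask
    shrunk = 0
    for i in rows_with_missing:
        # squared Euclidean over columns observed in both rows
        both = obs[i] & obs
        diff = np.where(both, arr - arr[i], 0.0)
        n_shared = both.sum(axis=1)
        d2 = np.einsum("ij,ij->i", diff, diff)
        d2[n_shared == 0] = np.inf
        d2[i] = np.inf
        order = np.argsort(d2, kind="stable")  # stable => row-order ties
        for j in np.where(nan_mask[i])[0]:
            donors = order[obs[order, j] & np.isfinite(d2[order])][:k]
            if donors.size == 0:
                raise ValueError(
                    "no donor row has an observed value at column "
                    f"{m.values.columns[j]!r} for row {i}"
                )
            if donors.size < k:
                shrunk += 1
            filled[i, j] = arr[donors, j].mean()
    if shrunk:
        logger.info("knn_impute: %d cells used fewer than k=%d donors", shrunk, k)
    values = pd.DataFrame(filled, columns=m.values.columns)
    return replace(m, values=values)
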