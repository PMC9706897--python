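"""Synthetic paired tumor/normal methylomes with planted, known truth.

Every downstream stage (site filtering, DMC/DMR calling, gene mapping,
enrichment, risk scoring, MSP analysis) can be exercised against data whose
ground truth is known exactly. The generator emulates the salient structure
of real paired methylomes:

* bounded methylation values via a Beta marginal at each site;
* paired tumor/normal samples sharing a per-pair random effect;
* correlation between adjacent CpGs via an AR(1) latent Gaussian mapped
  through the Beta quantile (a Gaussian copula along the chromosome);
* a genome-wide tumor-ward hypomethylation background (a configurable
  fraction of background sites lose methylation in tumor);
* planted hypermethylated regions — the DMR truth — where the tumor-normal
  mean difference equals a chosen delta;
* platform-style missingness: NaN cells for the 450k-like mode, exact
  all-zero rows ("uncovered") for the WGBS-like mode.

The generative model is a stand-in: no published generative model exists
for these data, so all distributional choices here are explicit defaults,
not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .enrichment import FamilyTable
from .io import MethylationMatrix
from .msp import METHYLATED, UNMETHYLATED, MISSING, MspCallMatrix

Region = tuple[str, int, int, str, float]  # chrom, start, end, direction, delta


@dataclass
class SimulationTruth:
    """Ground-truth parameters of one simulated cohort.

    Parameters
    ----------
    planted_regions
        (chrom, start, end, direction, delta) tuples; half-open intervals.
        delta is the tumor-normal mean methylation difference magnitude in
        percentage points. Direction ESCC plants tumor hypermethylation,
        NC plants normal hypermethylation.
    baseline_normal_mean
        Background normal-tissue mean methylation, percent.
    tumor_hypo_fraction
        Fraction of background sites given a tumor-ward hypomethylation
        shift of ``hypo_delta`` points (the genome-wide hypomethylation of
        tumors).
    ar1_rho
        Latent adjacent-site correlation of the Gaussian copula.
    concentration
        Beta precision (a+b); larger means less per-sample noise.
    pair_effect_sd
        SD (points) of the shared per-pair shift.
    missing_rate
        Fraction of background sites made missing (NaN cells in array mode,
        all-zero rows in WGBS mode).
    """

    planted_regions: list[Region] = field(default_factory=list)
    baseline_normal_mean: float = 15.0
    tumor_hypo_fraction: float = 0.0
    hypo_delta: float = 10.0
    ar1_rho: float = 0.7
    concentration: float = 60.0
    pair_effect_sd: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, start, end, direction, delta in self.planted_regions:
            if not 0.0 <= delta <= 100.0:
                raise ValueError("delta must be in [0, 100]")
            if direction not in ("NC", "ESCC"):
                raise ValueError(f"unknown direction {direction!r}")
            if end <= start:
                raise ValueError("planted region must have end > start")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not abs(self.ar1_rho) < 1.0:
            raise ValueError("|ar1_rho| must be < 1")


def generate_scaffold(n_chroms: int, sites_per_chrom: int,
                      mean_gap: int = 50, seed: int = 0) -> pd.DataFrame:
    """CpG coordinate scaffold: DataFrame (chrom, pos), sorted, gaps >= 2.

    Gaps are 1 + geometric with mean ``mean_gap - 1``, so adjacent CpGs can
    never overlap (a CpG occupies 2 bp) and the mean adjacent gap is
    ``mean_gap``.
    """
    if n_chroms < 1 or sites_per_chrom < 1:
        raise ValueError("counts must be >= 1")
    if mean_gap < 2:
        raise ValueError("mean_gap must be >= 2")
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chroms + 1):
        gaps = 1 + rng.geometric(1.0 / (mean_gap - 1), size=sites_per_chrom)
        pos = np.cumsum(gaps)
        frames.append(pd.DataFrame({"chrom": f"chr{c}", "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def plant_dense_regions(
    scaffold: pd.DataFrame,
    n_regions: int,
    sites_per_region: int = 4,
    direction: str = "ESCC",
    delta: float = 40.0,
    max_gap: int = 49,
    max_span: int = 100,
    seed: int = 0,
) -> list[Region]:
    """Pick non-overlapping runs of consecutive scaffold CpGs as truth regions.

    Only runs whose internal gaps are < ``max_gap`` and whose span fits
    ``max_span`` are eligible, so a correctly planted region is in principle
    recoverable by the default DMR rules. Raises if too few eligible runs
    exist.
    """
    rng = np.random.default_rng(seed)
    eligible: list[tuple[str, np.ndarray, int]] = []
    for chrom, grp in scaffold.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        for i in range(len(pos) - sites_per_region + 1):
            run = pos[i:i + sites_per_region]
            if (np.diff(run) < max_gap).all() and run[-1] - run[0] <= max_span:
                eligible.append((chrom, run, i))
    rng.shuffle(eligible)
    chosen: list[Region] = []
    used: list[tuple[str, int, int]] = []
    for chrom, run, _ in eligible:
        start, end = int(run[0]), int(run[-1]) + 2
        # keep regions well separated so truths stay distinct
        if any(c == chrom and start < e + 200 and s - 200 < end
               for c, s, e in used):
            continue
        chosen.append((chrom, start, end, direction, float(delta)))
        used.append((chrom, start, end))
        if len(chosen) == n_regions:
            break
    if len(chosen) < n_regions:
        raise ValueError(
            f"only {len(chosen)} of {n_regions} requested dense runs available"
        )
    return sorted(chosen)


def _ar1_latents(n_sites_per_chrom: list[int], n_cols: int, rho: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) latent Gaussians, restarted at chromosome breaks."""
    blocks = []
    innov_sd = np.sqrt(1.0 - rho ** 2)
    for n in n_sites_per_chrom:
        z = np.empty((n, n_cols))
        z[0] = rng.standard_normal(n_cols)
        eps = rng.standard_normal((n - 1, n_cols)) * innov_sd
        for t in range(1, n):
            z[t] = rho * z[t - 1] + eps[t - 1]
        blocks.append(z)
    return np.vstack(blocks)


def generate_paired_methylomes(
    scaffold: pd.DataFrame,
    n_pairs: int,
    truth: SimulationTruth,
    platform: str = "wgbs",
) -> tuple[MethylationMatrix, pd.DataFrame, SimulationTruth]:
    """Simulate a paired tumor/normal cohort over the scaffold.

    Returns (matrix, sample_metadata, truth); the truth object is returned
    unchanged so downstream recall/precision can be scored against it.
    Values are percent in WGBS mode, beta in 450k mode.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(truth.seed)
    chroms = scaffold["chrom"].to_numpy()
    pos = scaffold["pos"].to_numpy()
    n_sites = len(scaffold)

    extent = {c: (g["pos"].min(), g["pos"].max())
              for c, g in scaffold.groupby("chrom")}
    in_region = np.zeros(n_sites, dtype=bool)
    mean_n = np.full(n_sites, truth.baseline_normal_mean)
    mean_t = np.full(n_sites, truth.baseline_normal_mean)
    for chrom, start, end, direction, delta in truth.planted_regions:
        if chrom not in extent:
            raise ValueError(f"planted region on unknown chromosome {chrom}")
        lo, hi = extent[chrom]
        if start < lo or end > hi + 2:
            raise ValueError(
                f"planted region {chrom}:{start}-{end} outside scaffold extent"
            )
        mask = (chroms == chrom) & (pos >= start) & (pos < end)
        in_region |= mask
        if direction == "ESCC":
            # tumor gains methylation over the background
            mean_t[mask] = truth.baseline_normal_mean + delta
        else:
            # normal carries the high methylation; tumor stays at baseline,
            # so tumor - normal = -delta without clipping at 0
            mean_n[mask] = truth.baseline_normal_mean + delta

    background = ~in_region
    if truth.tumor_hypo_fraction > 0:
        hypo = background & (rng.random(n_sites) < truth.tumor_hypo_fraction)
        mean_t[hypo] = np.maximum(mean_t[hypo] - truth.hypo_delta, 1.0)

    sample_ids, groups, pair_ids = [], [], []
    for p in range(1, n_pairs + 1):
        sample_ids += [f"P{p:02d}_N", f"P{p:02d}_T"]
        groups += ["normal", "tumor"]
        pair_ids += [f"P{p:02d}", f"P{p:02d}"]
    n_cols = 2 * n_pairs

    pair_shift = rng.normal(0.0, truth.pair_effect_sd, size=n_pairs)
    col_shift = np.repeat(pair_shift, 2)
    mu = np.where(
        np.array([g == "tumor" for g in groups])[None, :],
        mean_t[:, None], mean_n[:, None],
    ) + col_shift[None, :]

    m = np.clip(mu / 100.0, 0.005, 0.995)
    a = m * truth.concentration
    b = (1.0 - m) * truth.concentration
    sites_per_chrom = [int((chroms == c).sum()) for c in
                       pd.unique(chroms)]
    z = _ar1_latents(sites_per_chrom, n_cols, truth.ar1_rho, rng)
    u = norm.cdf(z)
    values = 100.0 * beta_dist.ppf(u, a, b)

    if truth.missing_rate > 0:
        if platform == "wgbs":
            uncovered = background & (rng.random(n_sites) < truth.missing_rate)
            values[uncovered, :] = 0.0
        else:
            holes = (rng.random(values.shape) < truth.missing_rate)
            holes[in_region, :] = False
            values[holes] = np.nan

    if platform == "array450k":
        values = values / 100.0

    ages = rng.integers(40, 76, size=n_pairs)
    sexes = rng.choice(["M", "F"], size=n_pairs)
    stages = rng.choice(["I", "II", "III", "IV"], size=n_pairs)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "group": groups,
        "pair_id": pair_ids,
        "age": np.repeat(ages, 2),
        "sex": np.repeat(sexes, 2),
        "stage": [stages[i // 2] if g == "tumor" else ""
                  for i, g in enumerate(groups)],
    })
    matrix = MethylationMatrix(
        manifest=scaffold[["chrom", "pos"]].copy(),
        values=pd.DataFrame(values, columns=sample_ids),
        platform=platform,
    )
    return matrix, meta, truth


def generate_gene_annotation(scaffold: pd.DataFrame, n_genes: int,
                             seed: int = 0) -> pd.DataFrame:
    """Random non-degenerate gene-body intervals on scaffold chromosomes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_names = list(pd.unique(scaffold["chrom"]))
    extent = {c: int(scaffold.loc[scaffold["chrom"] == c, "pos"].max())
              for c in chrom_names}
    rows = []
    for i in range(n_genes):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = int(rng.integers(200, 2001))
        start = int(rng.integers(0, max(extent[chrom], 1)))
        rows.append({
            "symbol": f"GENE{i + 1:04d}",
            "chrom": chrom,
            "start": start,
            "end": start + length,
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    return pd.DataFrame(rows)


def generate_family_table(
    genes: list[str],
    n_families: int,
    enriched: tuple[str, float] | None = None,
    designated_genes: list[str] | None = None,
    seed: int = 0,
) -> FamilyTable:
    """Random HGNC-style family memberships over a gene universe.

    Every base family is nonempty; memberships are many-to-many (a second
    membership is drawn with probability 0.1). When ``enriched`` is given as
    (family_name, target_fraction), that family is added with members drawn
    from ``designated_genes`` so that round(target_fraction * n_designated)
    of them belong to it — enabling enrichment-recovery tests.
    """
    genes = list(genes)
    if n_families > len(genes):
        raise ValueError("n_families cannot exceed the number of genes")
    rng = np.random.default_rng(seed)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    families: dict[str, set[str]] = {
        f"FAM{i + 1:03d}": {shuffled[i]} for i in range(n_families)
    }
    names = list(families)
    for g in shuffled[n_families:]:
        families[names[int(rng.integers(n_families))]].add(g)
    for g in shuffled:
        if rng.random() < 0.1:
            families[names[int(rng.integers(n_families))]].add(g)

    if enriched is not None:
        fam_name, frac = enriched
        if not 0.0 <= frac <= 1.0:
            raise ValueError("target_fraction must be in [0, 1]")
        designated = list(designated_genes or [])
        n_in = int(round(frac * len(designated)))
        members = set(rng.choice(designated, size=n_in, replace=False)) \
            if n_in else set()
        if not members:  # families must be nonempty
            others = [g for g in genes if g not in designated]
            members = {others[0] if others else genes[0]}
        families[fam_name] = members
    return FamilyTable(families=families, universe=set(genes))


def generate_msp_calls(
    n_per_group: dict[str, int],
    n_cpgs: int,
    p_meth: dict[str, float],
    missing_rate: float = 0.0,
    seed: int = 0,
) -> MspCallMatrix:
    """Bernoulli per-CpG methylation calls for labelled sample groups."""
    for g, p in p_meth.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_meth[{g!r}] must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], []
    for group, n in n_per_group.items():
        p = p_meth[group]
        for i in range(n):
            meth = rng.random(n_cpgs) < p
            miss = rng.random(n_cpgs) < missing_rate
            row = np.where(miss, MISSING,
                           np.where(meth, METHYLATED, UNMETHYLATED))
            rows.append(row)
            ids.append(f"{group}_{i + 1:02d}")
            labels.append(group)
    calls = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                         columns=[f"CpG{j + 1}" for j in range(n_cpgs)])
    return MspCallMatrix(calls=calls, groups=pd.Series(labels, index=calls.index,
                                                       name="group"))


def write_truth(truth: SimulationTruth, path) -> None:
    pd.DataFrame(
        truth.planted_regions,
        columns=["chrom", "start", "end", "direction", "delta"],
    ).to_csv(path, sep="\t", index=False)


def read_truth(path, **params) -> SimulationTruth:
    df = pd.read_csv(path, sep="\t")
    regions = [tuple(r) for r in
               df[["chrom", "start", "end", "direction", "delta"]].itertuples(index=False)]
    return SimulationTruth(planted_regions=regions, **params)


def score_recovery(dmrs: pd.DataFrame, truth: SimulationTruth) -> dict:
    """Fraction of planted truth regions overlapped (>= 1 bp) by a called DMR.

    Overlap is half-open interval intersection on the same chromosome with
    matching direction. Also reports precision: the fraction of called DMRs
    touching any truth region.
    """
    n_truth = len(truth.planted_regions)
    recovered = 0
    for chrom, start, end, direction, _ in truth.planted_regions:
        sub = dmrs[(dmrs["chrom"] == chrom) & (dmrs["direction"] == direction)]
        if ((sub["bed_start"] < end) & (start < sub["bed_end"])).any():
            recovered += 1
    true_calls = 0
    for _, r in dmrs.iterrows():
        hit = any(
            c == r["chrom"] and d == r["direction"]
            and r["bed_start"] < e and s < r["bed_end"]
            for c, s, e, d, _ in truth.planted_regions
        )
        true_calls += bool(hit)
    return {
        "n_truth": n_truth,
        "n_recovered": recovered,
        "recall": recovered / n_truth if n_truth else float("nan"),
        "n_called": len(dmrs),
        "precision": true_calls / len(dmrs) if len(dmrs) else float("nan"),
    }
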