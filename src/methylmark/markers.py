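"""Gene-level methylation markers: risk score, ROC/Youden and group tests.

The marker model is a logistic regression of sample type (normal=0,
tumor=1) on gene-level mean methylation of a small feature panel. The
fitted probability is the per-sample risk score; ROC analysis picks the
operating threshold where the Youden index (sensitivity + specificity - 1)
is maximal, and samples scoring strictly above it are called positive.

AUC is computed by the trapezoid rule over the empirical ROC curve, which
equals the normalized Mann-Whitney concordance (ties counted 1/2); its 95%
confidence interval uses DeLong's asymptotic variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .io import MethylationMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene-level summarization and grouping
# ---------------------------------------------------------------------------

def summarize_gene_methylation(
    m: MethylationMatrix, genes: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Mean methylation per gene body: genes x samples.

    Each gene's value is the unweighted arithmetic mean over the CpG
    sites/probes falling in [start, end) on its chromosome; missing cells
    are ignored. Genes covering no site are omitted and returned in the
    second element.
    """
    chroms = m.manifest["chrom"].to_numpy()
    pos = m.manifest["pos"].to_numpy()
    arr = m.values.to_numpy(dtype=float)
    rows, covered, dropped = [], [], []
    for _, g in genes.iterrows():
        mask = (chroms == g["chrom"]) & (pos >= g["start"]) & (pos < g["end"])
        if not mask.any():
            dropped.append(g["symbol"])
            continue
        with np.errstate(invalid="ignore"):
            rows.append(np.nanmean(arr[mask], axis=0))
        covered.append(g["symbol"])
    if not covered:
        raise ValueError("no gene covers any CpG site")
    gm = pd.DataFrame(rows, index=pd.Index(covered, name="symbol"),
                      columns=m.values.columns)
    if dropped:
        logger.info("summarize_gene_methylation: %d genes uncovered", len(dropped))
    return gm, dropped


def kmeans_groups(gm: pd.DataFrame, k: int = 3, seed: int = 0,
                  n_restarts: int = 10) -> pd.Series:
    """Euclidean k-means on gene rows, labels keyed by symbol.

    Best of ``n_restarts`` initializations by within-cluster sum of squares.
    Labels are renumbered so group 0 has the highest mean methylation,
    making the labelling deterministic up to genuine WSS ties.
    """
    if k > len(gm):
        raise ValueError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(gm.to_numpy(dtype=float))
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    return pd.Series([relabel[int(r)] for r in raw], index=gm.index,
                     name="group")


# ---------------------------------------------------------------------------
# logistic risk model
# ---------------------------------------------------------------------------

@dataclass
class RiskModel:
    """Fitted logistic classifier over gene-level methylation."""

    feature_genes: list[str]
    intercept: float
    coefficients: np.ndarray
    n: int
    converged: bool
    ridge_penalty: float | None = None  # set only under separation fallback
    stderr: np.ndarray | None = None


def fit_risk_model(gm: pd.DataFrame, labels: pd.Series) -> RiskModel:
    """Maximum-likelihood logistic fit of tumor status on feature genes.

    ``gm`` is features (genes) x samples; ``labels`` maps sample to
    {0 normal, 1 tumor}. Under perfect separation (unbounded MLE) the fit
    falls back to a ridge-stabilized logistic regression and records the
    penalty used.
    """
    y = labels.loc[gm.columns].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("labels must contain both classes, coded 0/1")
    X = gm.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = fit.params
        separated = (not fit.mle_retvals["converged"]) or np.any(
            np.abs(params) > 1e3
        )
        if not separated:
            return RiskModel(
                feature_genes=list(gm.index),
                intercept=float(params[0]),
                coefficients=np.asarray(params[1:], dtype=float),
                n=len(y),
                converged=True,
                stderr=np.asarray(fit.bse, dtype=float),
            )
    except Exception:  # PerfectSeparationError and numerical failures
        pass
    penalty = 1.0  # L2 strength (1/C); enough to bound the optimum
    logger.warning("fit_risk_model: separation detected; ridge fallback "
                   "with L2 penalty %.3g", penalty)
    clf = LogisticRegression(C=1.0 / penalty, max_iter=1000)
    clf.fit(X, y)
    return RiskModel(
        feature_genes=list(gm.index),
        intercept=float(clf.intercept_[0]),
        coefficients=np.asarray(clf.coef_[0], dtype=float),
        n=len(y),
        converged=True,
        ridge_penalty=penalty,
    )


def score(model: RiskModel, gm: pd.DataFrame) -> pd.Series:
    """Risk score per sample: inverse-logit of the linear predictor."""
    missing = [g for g in model.feature_genes if g not in gm.index]
    if missing:
        raise ValueError(f"feature genes absent from matrix: {missing}")
    X = gm.loc[model.feature_genes].to_numpy(dtype=float).T
    eta = model.intercept + X @ model.coefficients
    return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=gm.columns,
                     name="risk_score")


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]
    youden_threshold: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def youden_sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def youden_specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimator (single curve)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)

    def midrank(x: np.ndarray) -> np.ndarray:
        return stats.rankdata(x, method="average")

    all_ranks = midrank(np.concatenate([pos, neg]))
    pos_ranks = midrank(pos)
    neg_ranks = midrank(neg)
    # placement values: fraction of the other class below each observation
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(scores, labels) -> RocResult:
    """Full ROC evaluation with Youden-optimal operating point.

    Thresholds are the midpoints between consecutive distinct scores plus
    -inf and +inf; "positive" means score strictly greater than the
    threshold. Youden ties are broken toward the higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    distinct = np.unique(s)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])

    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tp = np.array([(s[y == 1] > t).sum() for t in thresholds])
    fp = np.array([(s[y == 0] > t).sum() for t in thresholds])
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg

    # trapezoid AUC over the curve traced in threshold order
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    var = _delong_variance(s, y)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    j = best[np.argmax(spec[best])]
    thr = float(thresholds[j])
    tp_j, fp_j = int(tp[j]), int(fp[j])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci_95=ci,
        youden_threshold=thr,
        tp=tp_j,
        tn=n_neg - fp_j,
        fp=fp_j,
        fn=n_pos - tp_j,
    )


def mann_whitney_auc(scores, labels) -> float:
    """Normalized Mann-Whitney concordance (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    conc = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(conc / (pos.size * neg.size))


# ---------------------------------------------------------------------------
# stratified rates and simple statistics
# ---------------------------------------------------------------------------

def stratified_detection_rates(
    scores, labels, covariates: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Positive-call rates per covariate stratum with a chi-square p.

    For each covariate column the samples are split by its values; the rate
    is positives/total within the stratum and the p-value comes from the
    chi-square test of the strata x {positive, negative} table. A covariate
    with a single stratum reports p = NaN (not applicable).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    positive = s > threshold
    rows = []
    for cov in covariates.columns:
        values = covariates[cov]
        strata = [v for v in pd.unique(values) if pd.notna(v)]
        counts = []
        for v in strata:
            in_stratum = (values == v).to_numpy()
            n_pos = int(positive[in_stratum].sum())
            n_tot = int(in_stratum.sum())
            counts.append((n_pos, n_tot - n_pos))
        if len(strata) >= 2 and all(sum(c) for c in counts):
            table = np.array(counts)
            if table.sum(axis=0).min() == 0:
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table)[1])
        else:
            p = float("nan")
        for v, (n_pos, n_neg) in zip(strata, counts):
            rows.append({
                "covariate": cov, "stratum": v,
                "n": n_pos + n_neg,
                "positive": n_pos,
                "rate": n_pos / (n_pos + n_neg) if (n_pos + n_neg) else float("nan"),
                "p_value": p,
            })
    return pd.DataFrame(rows)


def correlate_with_covariate(gene_values, covariate) -> tuple[float, float]:
    """Pearson r of a gene's methylation against a numeric covariate."""
    x = np.asarray(gene_values, dtype=float)
    y = np.asarray(covariate, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("need >= 3 complete observations")
    r, p = stats.pearsonr(x[keep], y[keep])
    return float(r), float(p)


def group_compare(values, groups) -> tuple[float, float]:
    """Two-sided rank test across groups.

    Two groups: Wilcoxon rank-sum (Mann-Whitney). The exact null
    distribution is used when both groups are small (<= 25) and tie-free;
    otherwise the normal approximation with tie correction and without
    continuity correction, so identical group distributions give p = 1.
    More than two groups: Kruskal-Wallis.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    uniq = pd.unique(g)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    samples = [v[g == u] for u in uniq]
    if any(len(x) == 0 for x in samples):
        raise ValueError("every group needs >= 1 value")
    if len(uniq) == 2:
        x, y = samples
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        if not has_ties and max(len(x), len(y)) <= 25:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def write_roc(result: RocResult, tsv_path) -> None:
    pd.DataFrame({
        "threshold": result.thresholds,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
    }).to_csv(tsv_path, sep="\t", index=False)


def model_to_dict(model: RiskModel) -> dict:
    return {
        "feature_genes": model.feature_genes,
        "intercept": model.intercept,
        "coefficients": list(map(float, model.coefficients)),
        "n": model.n,
        "ridge_penalty": model.ridge_penalty,
    }
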