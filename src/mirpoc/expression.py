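"""Count-based differential expression and the supporting statistics.

The differential-expression (DE) core is a deliberately simplified
negative-binomial Wald fit for two-group contrasts:

* median-of-ratios size factors (geometric-mean reference over features
  with no zero count),
* per-feature method-of-moments dispersion with shrinkage toward a
  binned-trend, floored at 1e-8,
* a two-group NB GLM with log link. For a saturated two-group design with
  known dispersion the maximum-likelihood group mean is the sample mean of
  normalized counts and the Fisher information gives
  ``Var(log mu_hat) = (1 + alpha * mu) / (n * mu)``; the Wald statistic is
  the log fold change over its standard error against a standard normal.

No outlier refitting or independent filtering is attempted; the target use
is pairwise contrasts of small-n groups with a raw-p screen, with BH
adjusted p-values emitted alongside.

Also here: the qPCR delta-delta-Ct quantifier and the two-sample /
multi-group testing cascade (Shapiro-Wilk -> Levene -> t / Welch /
Mann-Whitney / Wilcoxon; one-way ANOVA with Student-Newman-Keuls post hoc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def median_of_ratios_norm(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors via the median-of-ratios method.

    The reference is the per-feature geometric mean across samples,
    restricted to features with no zero count; each sample's factor is the
    median of its count/reference ratios. Raises if no feature is nonzero
    in every sample.
    """
    mat = _count_matrix(counts)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; "
            "median-of-ratios needs at least one, or use a pseudo-reference"
        )
    logs = np.log(mat[nonzero])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    group_labels: pd.Series | None = None,
    shrinkage: float = 0.3,
    n_bins: int = 10,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-feature NB dispersion: method of moments, shrunk to a trend.

    The raw estimate on normalized counts is ``max(0, (s^2 - mu) / mu^2)``;
    when ``group_labels`` is given, moments are pooled within groups
    (weighted by degrees of freedom) so planted group differences do not
    inflate the estimate. Each raw value is then pulled toward the mean
    dispersion of its log-mean bin with weight ``shrinkage`` and floored.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage weight must be in [0, 1]")
    mat = _count_matrix(counts)
    norm = mat / size_factors.to_numpy()[None, :]

    if group_labels is None:
        groups = [np.arange(norm.shape[1])]
    else:
        lab = np.asarray(group_labels)
        groups = [np.flatnonzero(lab == g) for g in pd.unique(lab)]
    for idx in groups:
        if len(idx) < 2:
            raise ValueError("dispersion estimation needs >= 2 samples per group")

    num = np.zeros(norm.shape[0])
    den = 0.0
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        a = np.where(np.isfinite(a), a, 0.0)
        num += np.maximum(a, 0.0) * (len(idx) - 1)
        den += len(idx) - 1
    raw = num / den

    mean_norm = norm.mean(axis=1)
    trend = _binned_trend(mean_norm, raw, n_bins)
    final = (1.0 - shrinkage) * raw + shrinkage * trend
    return pd.Series(np.maximum(final, floor), index=counts.index, name="dispersion")


def _binned_trend(mean_norm: np.ndarray, raw: np.ndarray, n_bins: int) -> np.ndarray:
    logm = np.log10(mean_norm + 1.0)
    edges = np.quantile(logm, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        return np.full_like(raw, raw.mean())
    which = np.clip(np.searchsorted(edges, logm, side="right") - 1, 0, len(edges) - 2)
    trend = np.empty_like(raw)
    for b in range(len(edges) - 1):
        mask = which == b
        trend[mask] = raw[mask].mean() if mask.any() else raw.mean()
    return trend


# ---------------------------------------------------------------------------
# NB Wald contrast
# ---------------------------------------------------------------------------

def nb_wald_contrast(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    group_labels: pd.Series,
    contrast: tuple[str, str],
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test; log2fc is treated over reference.

    The fold change is the ratio of normalized group means; a pseudo-count
    is added to *both* means only when either is zero (flagged in the
    ``pseudo`` column), keeping the estimate finite and the contrast
    antisymmetric under swapping treated and reference.
    """
    treated, reference = contrast
    lab = np.asarray(group_labels)
    t_idx = np.flatnonzero(lab == treated)
    r_idx = np.flatnonzero(lab == reference)
    if len(t_idx) < 2 or len(r_idx) < 2:
        raise ValueError(f"contrast groups {contrast} need >= 2 samples each")

    mat = _count_matrix(counts)
    norm = mat / size_factors.to_numpy()[None, :]
    mu_t = norm[:, t_idx].mean(axis=1)
    mu_r = norm[:, r_idx].mean(axis=1)
    alpha = dispersions.reindex(counts.index).to_numpy()

    zero = (mu_t == 0.0) | (mu_r == 0.0)
    mt = mu_t + pseudo_count * zero
    mr = mu_r + pseudo_count * zero
    log2fc = np.log2(mt / mr)
    var_ln = (1.0 + alpha * mt) / (len(t_idx) * mt) + (1.0 + alpha * mr) / (len(r_idx) * mr)
    se = np.sqrt(var_ln) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isfinite(p), p, 1.0)

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "stat": z,
            "p": p,
            "padj": bh_adjust(p),
            "mean_expression": norm.mean(axis=1),
            "pseudo": zero,
        },
        index=counts.index,
    )
    out.index.name = "feature_id"
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass
class DEResults:
    """Fitted contrasts of a :class:`DifferentialExpression` model."""

    size_factors: pd.Series
    dispersions: pd.Series
    contrasts: dict = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return self.contrasts[name]

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["NB Wald differential expression", f"  features : {len(self.dispersions)}"]
        lines.append(f"  median dispersion : {float(np.median(self.dispersions)):.4g}")
        for name, tab in self.contrasts.items():
            sig = tab["p"] <= alpha
            up = int((sig & (tab["log2fc"] > 0)).sum())
            down = int((sig & (tab["log2fc"] < 0)).sum())
            lines.append(f"  {name}: {int(sig.sum())} with p<={alpha} ({up} up, {down} down)")
        return "\n".join(lines)


class DifferentialExpression:
    """NB Wald DE model over a count matrix and group labels.

    ``fit(contrasts)`` normalizes, estimates dispersion (pooled within
    groups) and computes one Wald table per ``(treated, reference)`` pair,
    returning a :class:`DEResults`.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        group_labels: pd.Series,
        shrinkage: float = 0.3,
        pseudo_count: float = 0.5,
    ):
        if (np.asarray(_count_matrix(counts)) < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.index.duplicated().any() or counts.columns.duplicated().any():
            raise ValueError("feature and sample ids must be unique")
        self.counts = counts
        self.group_labels = pd.Series(np.asarray(group_labels), index=counts.columns)
        self.shrinkage = shrinkage
        self.pseudo_count = pseudo_count

    def fit(self, contrasts: dict[str, tuple[str, str]]) -> DEResults:
        sf = median_of_ratios_norm(self.counts)
        disp = estimate_dispersion(
            self.counts, sf, group_labels=self.group_labels, shrinkage=self.shrinkage
        )
        tables = {
            name: nb_wald_contrast(
                self.counts, sf, disp, self.group_labels, pair, pseudo_count=self.pseudo_count
            )
            for name, pair in contrasts.items()
        }
        return DEResults(size_factors=sf, dispersions=disp, contrasts=tables)


# ---------------------------------------------------------------------------
# two-sample cascade and multi-group ANOVA / SNK
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    normality_p: float


@dataclass
class CascadeResult:
    groups: tuple[GroupStats, GroupStats]
    chosen_test: str
    p: float
    levene_p: float | None
    trace: list[str]


def stats_cascade(sample_a, sample_b, paired: bool = False, alpha: float = 0.05) -> CascadeResult:
    """Normality-gated two-sample test selection.

    Both samples Shapiro-Wilk-normal at ``alpha`` -> Levene; equal
    variances -> Student t (paired/unpaired), unequal -> Welch. Any
    non-normal sample -> Mann-Whitney (unpaired) or Wilcoxon signed-rank
    (paired). The decision path is recorded in ``trace``.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per sample for normality testing")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")

    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    trace = [f"shapiro_a p={sw_a:.4g}", f"shapiro_b p={sw_b:.4g}"]
    normal = sw_a > alpha and sw_b > alpha

    levene_p = None
    if normal:
        levene_p = stats.levene(a, b).pvalue
        trace.append(f"levene p={levene_p:.4g}")
        if levene_p > alpha:
            if paired:
                chosen, p = "t", stats.ttest_rel(a, b).pvalue
            else:
                chosen, p = "t", stats.ttest_ind(a, b, equal_var=True).pvalue
        else:
            chosen, p = "welch", stats.ttest_ind(a, b, equal_var=False).pvalue
    else:
        if paired:
            chosen, p = "wilcoxon", stats.wilcoxon(a, b).pvalue
        else:
            chosen, p = "mann_whitney", stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    trace.append(f"chosen={chosen}")

    gs = tuple(
        GroupStats(label=l, n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), normality_p=float(sw))
        for l, x, sw in (("a", a, sw_a), ("b", b, sw_b))
    )
    return CascadeResult(groups=gs, chosen_test=chosen, p=float(p), levene_p=levene_p, trace=trace)


def anova_snk(groups: list, alpha: float = 0.05) -> dict:
    """One-way ANOVA with a Student-Newman-Keuls stepwise post hoc.

    Group means are ordered and ranges tested from widest to narrowest
    with studentized-range critical values (range span as the number of
    means, error df from the pooled within-group variance); a
    non-significant range protects all sub-ranges. Unequal group sizes use
    the harmonic mean of the pair. Returns the ANOVA p and a boolean
    pairwise significance matrix (empty of hits when ANOVA does not
    reject).
    """
    if len(groups) < 3:
        raise ValueError("anova_snk needs >= 3 groups; use stats_cascade for two")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    k = len(arrays)
    labels = list(range(k))
    anova_p = float(stats.f_oneway(*arrays).pvalue)

    sig = pd.DataFrame(False, index=labels, columns=labels)
    if anova_p > alpha:
        return {"anova_p": anova_p, "significant": sig, "alpha": alpha}

    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_err = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err

    order = np.argsort(means)  # ascending
    sorted_means = means[order]
    nonsig_spans: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        qcrit = stats.studentized_range.ppf(1.0 - alpha, span, df_err)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(lo <= i and j <= hi for lo, hi in nonsig_spans):
                continue  # protected by a wider accepted range
            gi, gj = order[i], order[j]
            n_h = 2.0 / (1.0 / ns[gi] + 1.0 / ns[gj])
            q_obs = (sorted_means[j] - sorted_means[i]) / np.sqrt(mse / n_h)
            if q_obs > qcrit:
                sig.loc[gi, gj] = sig.loc[gj, gi] = True
            else:
                nonsig_spans.append((i, j))
    return {"anova_p": anova_p, "significant": sig, "alpha": alpha}


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct: pd.DataFrame,
    housekeeping_id: str,
    group_labels: pd.Series,
    reference_group: str,
) -> pd.DataFrame:
    """Delta-delta-Ct group fold changes relative to a reference group.

    Per sample, dCt = Ct_target - Ct_housekeeping; per group, ddCt is the
    group-mean dCt minus the reference-group mean; fold = 2^(-ddCt).
    Returns a genes x groups table (reference column all ones).
    """
    if housekeeping_id not in ct.index:
        raise ValueError(f"housekeeping feature {housekeeping_id!r} missing from Ct table")
    hk = ct.loc[housekeeping_id]
    if hk.isna().any():
        raise ValueError("housekeeping Ct has missing values")
    lab = pd.Series(np.asarray(group_labels), index=ct.columns)
    if reference_group not in set(lab):
        raise ValueError(f"reference group {reference_group!r} absent")

    dct = ct.drop(index=housekeeping_id).sub(hk, axis=1)
    group_mean = dct.T.groupby(lab.to_numpy()).mean().T
    ddct = group_mean.sub(group_mean[reference_group], axis=0)
    return np.power(2.0, -ddct)


def _count_matrix(counts: pd.DataFrame) -> np.ndarray:
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    return mat
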