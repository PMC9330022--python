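"""Differential-expression core for small-replicate count data.

The test of record is the classic conditional negative-binomial exact
test with a single common dispersion, applied to library-size-equalized
pseudo-counts: with equal per-sample NB means and sizes, the group-A sum
conditional on the feature total follows a negative hypergeometric
distribution that is free of the mean, so exact two-sided p-values can
be enumerated. This is the simplest member of the NB-testing family and
the one with a tractable brute-force oracle; tagwise/trended dispersion
shrinkage and GLM designs are deliberately out of scope.

Normalization is trimmed-mean-of-M-values (TMM) with CPM / log2-CPM on
effective library sizes. Differentially expressed miRNAs (DEMs) are
called at |log2FC| >= 1.5, log2CPM > 2, FDR <= 0.05 by default;
differentially expressed genes (DEGs) use a Welch t-test on
log-expression with Bonferroni control and a 2-fold change threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix

LOGFC_PRIOR = 0.125  # prior count stabilizing log2FC at zero counts
LOGCPM_PRIOR = 2.0  # prior count for log2CPM


@dataclass
class DEThresholds:
    """DEM call thresholds: |log2FC| >= min_abs_log2fc, log2CPM strictly
    > min_log2cpm, FDR <= max_fdr."""

    min_abs_log2fc: float = 1.5
    min_log2cpm: float = 2.0
    max_fdr: float = 0.05

    def validate(self) -> None:
        if self.min_abs_log2fc <= 0 or self.min_log2cpm <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.max_fdr <= 1:
            raise ValueError("max_fdr must be in (0, 1]")


@dataclass
class DegThresholds:
    """DEG call thresholds: linear fold change >= min_fc (or <= 1/min_fc)
    plus Bonferroni-adjusted Welch-t p <= alpha."""

    min_fc: float = 2.0
    alpha: float = 0.05

    def validate(self) -> None:
        if self.min_fc <= 1:
            raise ValueError("min_fc must be > 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass
class ComparisonResult:
    """Per-feature DE statistics for one group-vs-group comparison.

    ``log2fc`` is group A over group B. ``direction`` is UP_IN_A /
    UP_IN_B for DE features, NONE otherwise.
    """

    label: str
    group_a: str
    group_b: str
    table: pd.DataFrame  # index feature; log2fc, log2cpm, pvalue, fdr, de, direction

    def de_set(self) -> dict[str, int]:
        """DE features as feature -> +1 (up in A) / -1 (up in B)."""
        de = self.table[self.table["de"]]
        return {f: (1 if row["log2fc"] > 0 else -1) for f, row in de.iterrows()}


# ---------------------------------------------------------------------------
# normalization


def _lib_sizes(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return lib


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference column.

    Trims 30% of M-values and 5% of A-values from each tail, then takes
    the weighted mean of the surviving M-values with inverse asymptotic
    (delta-method binomial) variance weights.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    fo, fr = obs / lib_obs, ref / lib_ref
    m = np.log2(fo / fr)
    a = 0.5 * np.log2(fo * fr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    w = 1.0 / ((lib_obs - obs[keep2]) / (lib_obs * obs[keep2]) + (lib_ref - ref[keep2]) / (lib_ref * ref[keep2]))
    f = np.sum(w * m[keep2]) / np.sum(w)
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: CountMatrix | pd.DataFrame, ref_sample: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The default reference is the sample whose 75th-percentile scaled
    count is closest to the mean across samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = _lib_sizes(mat)
    x = mat.values.astype(float)
    if ref_sample is None:
        q75 = np.quantile(x, 0.75, axis=0) / lib.values
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref_sample not in mat.columns:
            raise ValueError(f"unknown reference sample {ref_sample!r}")
        ref_idx = int(mat.columns.get_loc(ref_sample))
    ref = x[:, ref_idx]
    lib_ref = float(lib.iloc[ref_idx])
    factors = np.array(
        [_tmm_pair(x[:, j], ref, float(lib.iloc[j]), lib_ref) for j in range(x.shape[1])]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.Series:
    lib = _lib_sizes(counts)
    if factors is None:
        return lib
    if not lib.index.equals(factors.index):
        raise ValueError("factors were computed on a different sample set")
    return lib * factors


def cpm(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    log: bool = False,
    prior_count: float = LOGCPM_PRIOR,
) -> pd.DataFrame:
    """Counts per million on effective library sizes.

    The log variant uses log2((count + prior_s) / (efflib_s + 2 prior_s)
    * 1e6) with the prior scaled by each sample's relative library size,
    so a zero count maps to a finite floor that is comparable across
    samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    eff = effective_lib_sizes(mat, factors)
    if not log:
        return mat / eff.values * 1e6
    prior = prior_count * eff.values / eff.values.mean()
    return np.log2((mat + prior) / (eff.values + 2 * prior) * 1e6)


# ---------------------------------------------------------------------------
# dispersion

def _pseudo_counts(mat: pd.DataFrame, eff: pd.Series) -> tuple[pd.DataFrame, float]:
    """Scale counts to the geometric-mean effective library size."""
    common = float(np.exp(np.mean(np.log(eff.values))))
    return mat * (common / eff.values), common


def _cond_loglik(pseudo: np.ndarray, group_sizes: list[np.ndarray], phi: float) -> float:
    """Conditional NB log-likelihood of within-group splits given totals.

    For a group of n samples with equal means and dispersion phi, the
    split of the group total is negative-hypergeometric with size
    parameters 1/phi per sample; terms free of phi are dropped.
    """
    r = 1.0 / phi
    ll = 0.0
    for idx in group_sizes:
        y = pseudo[:, idx]
        n = len(idx)
        z = y.sum(axis=1)
        ll += float(
            np.sum(special.gammaln(y + r))
            - y.shape[0] * n * special.gammaln(r)
            + y.shape[0] * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
        )
    return ll


def estimate_common_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: pd.Series | dict | list,
    factors: pd.Series | None = None,
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are first scaled to a common effective library size
    (pseudo-counts); the conditional likelihood of the within-group
    splits is maximized over phi on a log grid and refined by bounded
    scalar optimization. Returns 0.0 (with a warning) when no group has
    replication.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if isinstance(groups, (dict,)):
        groups = pd.Series(groups)
    elif isinstance(groups, list):
        groups = pd.Series(groups, index=mat.columns)
    eff = effective_lib_sizes(mat, factors)
    pseudo, _ = _pseudo_counts(mat, eff)
    x = pseudo.values
    group_idx = []
    for _, members in groups.groupby(groups):
        idx = np.array([mat.columns.get_loc(s) for s in members.index])
        if len(idx) >= 2:
            group_idx.append(idx)
    if not group_idx:
        warnings.warn("no group has >= 2 replicates; returning dispersion 0")
        return 0.0

    grid = np.concatenate([[1e-6], 10 ** np.linspace(-4, 1, 26)])
    ll = np.array([_cond_loglik(x, group_idx, phi) for phi in grid])
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda phi: -_cond_loglik(x, group_idx, phi),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi_hat = float(res.x)
    return max(phi_hat, 0.0) if phi_hat > 2e-6 else 0.0


# ---------------------------------------------------------------------------
# exact test


def _split_logpmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """log pmf of the group-A sum k = 0..t conditional on the total t.

    phi > 0: negative-hypergeometric with sizes n_a/phi and n_b/phi.
    phi = 0: Binomial(t, n_a / (n_a + n_b)) (Poisson limit).
    """
    k = np.arange(t + 1, dtype=float)
    if phi == 0:
        p = n_a / (n_a + n_b)
        logp = (
            special.gammaln(t + 1)
            - special.gammaln(k + 1)
            - special.gammaln(t - k + 1)
            + k * np.log(p)
            + (t - k) * np.log1p(-p)
        )
    else:
        ra, rb = n_a / phi, n_b / phi
        logp = (
            special.gammaln(k + ra)
            - special.gammaln(k + 1)
            + special.gammaln(t - k + rb)
            - special.gammaln(t - k + 1)
        )
    return logp - special.logsumexp(logp)


def exact_test_pvalue(ka: int, kb: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for an observed (group-A sum, group-B sum) split.

    Doubled-tail convention: twice the smaller of the lower/upper tail
    probabilities at the observed split, capped at 1.
    """
    t = ka + kb
    if t == 0:
        return 1.0
    pm = np.exp(_split_logpmf(t, n_a, n_b, phi))
    lower = float(pm[: ka + 1].sum())
    upper = float(pm[ka:].sum())
    return min(1.0, 2.0 * min(lower, upper))


def nb_exact_test(
    counts: CountMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    phi: float,
    factors: pd.Series | None = None,
    label: str | None = None,
) -> ComparisonResult:
    """Conditional NB exact test of group A vs group B per feature.

    Counts are scaled to a common effective library size; the rounded
    group sums are tested against the conditional split distribution.
    log2FC is the ratio of normalized group means with a prior count of
    0.125; log2CPM is the average normalized abundance with a prior of 2.
    DE flags/directions are left unset (NONE) -- apply :func:`bh_adjust`
    and :func:`call_dems`.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    mat = counts.counts
    if isinstance(group_a, str):
        name_a, samples_a = group_a, counts.samples_of_group(group_a)
    else:
        name_a, samples_a = "A", list(group_a)
    if isinstance(group_b, str):
        name_b, samples_b = group_b, counts.samples_of_group(group_b)
    else:
        name_b, samples_b = "B", list(group_b)
    if not samples_a or not samples_b:
        raise ValueError("both groups must be nonempty")
    if set(samples_a) & set(samples_b):
        raise ValueError("groups must be disjoint")

    sub = mat[samples_a + samples_b]
    eff_all = effective_lib_sizes(mat, factors)
    eff = eff_all[samples_a + samples_b]
    pseudo, common = _pseudo_counts(sub, eff)
    n_a, n_b = len(samples_a), len(samples_b)
    ya = pseudo[samples_a].sum(axis=1).values
    yb = pseudo[samples_b].sum(axis=1).values

    ka = np.round(ya).astype(int)
    kb = np.round(yb).astype(int)
    pvals = np.array(
        [exact_test_pvalue(int(a), int(b), n_a, n_b, phi) for a, b in zip(ka, kb)]
    )

    mean_a = ya / n_a
    mean_b = yb / n_b
    log2fc = np.log2((mean_a + LOGFC_PRIOR) / (mean_b + LOGFC_PRIOR))
    avg = (ya + yb) / (n_a + n_b)
    log2cpm = np.log2((avg + LOGCPM_PRIOR) / (common + 2 * LOGCPM_PRIOR) * 1e6)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "log2cpm": log2cpm,
            "pvalue": pvals,
            "fdr": np.nan,
            "de": False,
            "direction": "NONE",
        },
        index=mat.index,
    )
    return ComparisonResult(
        label=label or f"{name_a}-{name_b}", group_a=name_a, group_b=name_b, table=table
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dems(result: ComparisonResult, thresholds: DEThresholds | None = None) -> ComparisonResult:
    """Apply BH correction and DEM thresholds; fill de/direction columns.

    A feature is DE iff |log2FC| >= min_abs_log2fc AND log2CPM strictly
    > min_log2cpm AND FDR <= max_fdr.
    """
    thresholds = thresholds or DEThresholds()
    thresholds.validate()
    t = result.table
    t = t.assign(fdr=bh_adjust(t["pvalue"].values))
    de = (
        (t["log2fc"].abs() >= thresholds.min_abs_log2fc)
        & (t["log2cpm"] > thresholds.min_log2cpm)
        & (t["fdr"] <= thresholds.max_fdr)
    )
    direction = np.where(~de, "NONE", np.where(t["log2fc"] > 0, "UP_IN_A", "UP_IN_B"))
    t = t.assign(de=de, direction=direction)
    return ComparisonResult(result.label, result.group_a, result.group_b, t)


# ---------------------------------------------------------------------------
# DEG t-test and QC


def deg_ttest(
    expr: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    thresholds: DegThresholds | None = None,
) -> pd.DataFrame:
    """Welch t-test on log2 expression with Bonferroni control.

    Fold change is the ratio of group geometric means (2^(mean log2
    difference)); DE iff FC >= min_fc or <= 1/min_fc AND adjusted p <=
    alpha. Returns a per-gene table with fc, pvalue, p_bonf, de.
    """
    thresholds = thresholds or DegThresholds()
    thresholds.validate()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 replicates")
    xa = expr[group_a].values
    xb = expr[group_b].values
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pvals = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    # zero within-group variance with separated means: p -> 0
    sep = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    pvals = np.where(sep & (xa.mean(axis=1) != xb.mean(axis=1)), 0.0, pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    p_bonf = np.minimum(pvals * expr.shape[0], 1.0)
    fc = 2.0 ** (xa.mean(axis=1) - xb.mean(axis=1))
    de = ((fc >= thresholds.min_fc) | (fc <= 1.0 / thresholds.min_fc)) & (
        p_bonf <= thresholds.alpha
    )
    return pd.DataFrame(
        {"fc": fc, "pvalue": pvals, "p_bonf": p_bonf, "de": de}, index=expr.index
    )


def qc_correlation(expr: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation; constant samples give NaN."""
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 features for correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = pd.DataFrame(
            np.corrcoef(expr.values.T), index=expr.columns, columns=expr.columns
        )
    return corr


def qc_pca(expr: pd.DataFrame, n_components: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample-space PCA by SVD of the feature-centered matrix.

    Returns (scores: samples x components, variance fractions).
    """
    n_samples = expr.shape[1]
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if n_components > n_samples - 1:
        raise ValueError(f"n_components must be <= n_samples - 1 = {n_samples - 1}")
    x = expr.values.T  # samples x features
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        (u * s)[:, :n_components],
        index=expr.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return scores, frac[:n_components]
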