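"""Statistical evaluation layer: group comparisons, correlation, ROC,
bootstrap.

The layer mirrors a standard biomarker workup: Mann-Whitney U tests for
demographics and behavioral scores, a two-way ANOVA (group x condition) with
Bonferroni-corrected per-condition contrasts for the EEG biomarkers,
channelwise unpaired t-tests for cordance maps, Spearman rank correlation
between the entropy score and symptom severity, empirical ROC curves with
the Mann-Whitney AUC and Hanley-McNeil standard error, a weighted
combination sweep of the entropy score with the omission rate, and a
bootstrap-of-means simulation (B resamples per group x condition cell,
kernel densities, one-way ANOVA with all pairwise Bonferroni confidence
intervals, and ROC on the bootstrapped means).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    pvalue: float
    estimates: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    alpha: float = 0.05
    note: str | None = None

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.alpha)


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC, SE, CI and Youden cut-off."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    cutoff_sens_ci95: tuple[float, float]
    cutoff_spec_ci95: tuple[float, float]
    score_def: str = "score"


@dataclass
class BootstrapResult:
    """Bootstrap-of-means simulation over group x condition cells."""

    means: dict[tuple[str, str], np.ndarray]
    kde: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    anova: StatResult
    pairwise: pd.DataFrame
    roc: dict[str, ROCResult]
    B: int
    seed: int


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b, alpha: float = 0.05) -> StatResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples without ties (scipy's 'auto'
    policy), normal approximation with tie correction otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = ("exact" if (a.size <= 20 and b.size <= 20 and no_ties)
              else "asymptotic")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return StatResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      estimates={"median_a": float(np.median(a)),
                                 "median_b": float(np.median(b)),
                                 "n_a": a.size, "n_b": b.size},
                      alpha=alpha)


def two_way_anova_bonferroni(values, group, condition,
                             alpha: float = 0.05) -> StatResult:
    """Two-way ANOVA (group x condition) with Bonferroni post-hoc contrasts.

    Main effects and the interaction come from an ordinary least-squares fit
    (both factors between-observation; when the same subjects contribute to
    every condition the within-subject structure is noted on the result).
    The post-hoc table compares the two groups within each condition with
    pooled-MSE t statistics, Bonferroni-adjusted p values and simultaneous
    95% confidence intervals.
    """
    df = pd.DataFrame({"value": np.asarray(values, float),
                       "group": np.asarray(group, dtype=object),
                       "condition": np.asarray(condition, dtype=object)})
    cells = df.groupby(["group", "condition"], observed=True).size()
    glev = sorted(df["group"].unique())
    clev = sorted(df["condition"].unique())
    if len(glev) < 2 or len(clev) < 2:
        raise ValueError("need at least two levels per factor")
    for g in glev:
        for c in clev:
            if cells.get((g, c), 0) < 2:
                raise ValueError(f"cell (group={g!r}, condition={c!r}) has "
                                 "fewer than 2 observations")
    model = smf.ols("value ~ C(group) * C(condition)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    tol = 1e-12 * max(1.0, float(np.mean(df["value"] ** 2)))
    if mse < tol:
        # degenerate zero-residual data: F = 0 for null effects
        mse = 0.0
        zero_ss = table["sum_sq"].abs() < tol
        table.loc[zero_ss, "F"] = 0.0
        table.loc[zero_ss, "PR(>F)"] = 1.0
    df_resid = float(model.df_resid)
    k = len(clev)
    rows = []
    tcrit = sps.t.ppf(1 - alpha / (2 * k), df_resid)
    for c in clev:
        sub = df[df["condition"] == c]
        x0 = sub.loc[sub["group"] == glev[0], "value"].to_numpy()
        x1 = sub.loc[sub["group"] == glev[1], "value"].to_numpy()
        diff = float(x1.mean() - x0.mean())
        se = np.sqrt(mse * (1 / x0.size + 1 / x1.size))
        t = diff / se if se > 0 else np.nan
        p_raw = 2 * sps.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
        rows.append({"condition": c,
                     "comparison": f"{glev[1]} - {glev[0]}",
                     "mean_diff": diff, "t": float(t),
                     "p_raw": float(p_raw),
                     "p_adj": float(min(1.0, k * p_raw)),
                     "ci_low": diff - tcrit * se,
                     "ci_high": diff + tcrit * se})
    posthoc = pd.DataFrame(rows)
    effects = {name: {"F": float(table.loc[name, "F"]),
                      "p": float(table.loc[name, "PR(>F)"])}
               for name in ("C(group)", "C(condition)",
                            "C(group):C(condition)")}
    inter = effects["C(group):C(condition)"]
    return StatResult(
        "two-way-anova", inter["F"], inter["p"],
        estimates={"group": effects["C(group)"],
                   "condition": effects["C(condition)"],
                   "interaction": inter},
        posthoc=posthoc, alpha=alpha,
        note=("condition treated as a between-observation factor; repeated "
              "measurements per subject are not modeled"))


def channelwise_ttests(values: pd.DataFrame, band: str = "theta",
                       channels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Unpaired two-sided t tests per channel x condition.

    `values` is tidy with columns subject_id, group, condition, channel,
    band, value (the cordance z-scores).  Returns one row per channel x
    condition with t, p and a significance flag; degenerate channels
    (zero variance in both groups) are flagged with NaN statistics.
    """
    df = values[values["band"] == band]
    glev = sorted(df["group"].unique())
    if len(glev) != 2:
        raise ValueError("exactly two groups required")
    if channels is None:
        channels = list(pd.unique(df["channel"]))
    rows = []
    for cond in sorted(df["condition"].unique()):
        for ch in channels:
            sub = df[(df["condition"] == cond) & (df["channel"] == ch)]
            x0 = sub.loc[sub["group"] == glev[0], "value"].to_numpy(float)
            x1 = sub.loc[sub["group"] == glev[1], "value"].to_numpy(float)
            if x0.size == 0 or x1.size == 0:
                raise ValueError(f"channel {ch!r} missing in a group")
            if x0.std() == 0 and x1.std() == 0:
                t = p = np.nan
            else:
                t, p = sps.ttest_ind(x1, x0, equal_var=True)
            rows.append({"condition": cond, "channel": ch,
                         "mean_diff": float(x1.mean() - x0.mean()),
                         "t": float(t), "p": float(p),
                         "significant": bool(np.isfinite(p) and p < alpha)})
    return pd.DataFrame(rows)


def spearman(x, y, alpha: float = 0.05) -> StatResult:
    """Spearman rank correlation with a two-tailed p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", np.nan, np.nan, alpha=alpha,
                          note="constant input; correlation undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(r), float(p),
                      estimates={"r": float(r), "n": int(x.size)},
                      alpha=alpha)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _binom_ci(successes: int, n: int, alpha: float = 0.05,
              ) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval."""
    lo = sps.beta.ppf(alpha / 2, successes, n - successes + 1) \
        if successes > 0 else 0.0
    hi = sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes) \
        if successes < n else 1.0
    return float(lo), float(hi)


def roc(scores, labels, score_def: str = "score") -> ROCResult:
    """Empirical ROC for positive class = 1, higher score = more positive.

    AUC is the Mann-Whitney statistic / (n_pos * n_neg); its standard error
    uses the Hanley-McNeil formula and the 95% CI is the normal interval
    clipped to [0, 1].  The cut-off maximizes Youden's J (reported as the
    midpoint between the adjacent distinct scores), with exact binomial 95%
    CIs on its sensitivity and specificity.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided",
                         method="asymptotic").statistic
    auc = float(u) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2)
           + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(pos >= th).mean() for th in thresholds])
    spec = np.array([(neg < th).mean() for th in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    tp = int((pos >= thresholds[best]).sum())
    tn = int((neg < thresholds[best]).sum())
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=auc, auc_se=se, auc_ci95=ci,
        cutoff=float(thresholds[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
        cutoff_sens_ci95=_binom_ci(tp, n1),
        cutoff_spec_ci95=_binom_ci(tn, n0),
        score_def=score_def)


def combine_scores(apen_values, omission_rates, weight: float) -> np.ndarray:
    """Weighted combination: apen + weight * omission (raw scales)."""
    a = np.asarray(apen_values, float)
    o = np.asarray(omission_rates, float)
    if a.size != o.size:
        raise ValueError("apen and omission vectors must align")
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    return a + weight * o


def sweep_combination_weights(apen_values, omission_rates, labels,
                              weights=None, standardize: bool = False,
                              ) -> pd.DataFrame:
    """Evaluate roc() for each combination weight; column `best` marks the
    weight with the highest AUC.

    standardize=True z-scores both inputs first (the raw-scale combination
    is unit-dependent: the entropy score is ~0-1 while omission is in %).
    """
    if weights is None:
        weights = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    a = np.asarray(apen_values, float)
    o = np.asarray(omission_rates, float)
    if standardize:
        a = (a - a.mean()) / a.std() if a.std() > 0 else a - a.mean()
        o = (o - o.mean()) / o.std() if o.std() > 0 else o - o.mean()
    rows = []
    for w in weights:
        r = roc(combine_scores(a, o, float(w)), labels,
                score_def=f"apen + {w:.1f} * omission")
        rows.append({"weight": float(w), "auc": r.auc})
    out = pd.DataFrame(rows)
    out["best"] = out["auc"] == out["auc"].max()
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_mean_ci(values, B: int = 1000, seed: int = 0,
                      alpha: float = 0.05,
                      ) -> tuple[np.ndarray, tuple[float, float]]:
    """Percentile bootstrap CI of the mean; returns (resampled means, CI)."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(B, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return means, (float(lo), float(hi))


def bootstrap_means(cells: dict[tuple[str, str], np.ndarray],
                    B: int = 1000, seed: int = 0,
                    alpha: float = 0.05) -> BootstrapResult:
    """Bootstrap-of-means simulation over group x condition cells.

    For each cell, B resamples with replacement of the cell's own size yield
    a distribution of means (a Gaussian kernel density with Silverman's
    bandwidth is evaluated for plotting).  A one-way ANOVA compares all cells
    on the bootstrapped means, with every pairwise mean difference reported
    alongside Bonferroni-adjusted simultaneous 95% CIs (pooled-MSE).  Per
    condition, an ROC on the bootstrapped means of the two groups summarizes
    separability (AUC, SE, CI).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(seed)
    keys = list(cells)
    means: dict[tuple[str, str], np.ndarray] = {}
    kde: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key in keys:
        x = np.asarray(cells[key], float)
        if x.size < 2:
            raise ValueError(f"cell {key} needs at least 2 values")
        idx = rng.integers(0, x.size, size=(B, x.size))
        m = x[idx].mean(axis=1)
        means[key] = m
        grid = np.linspace(m.min() - 3 * m.std() - 1e-12,
                           m.max() + 3 * m.std() + 1e-12, 256)
        if m.std() > 0:
            dens = sps.gaussian_kde(m, bw_method="silverman")(grid)
        else:
            dens = np.zeros_like(grid)
        kde[key] = (grid, dens)

    f, p = sps.f_oneway(*[means[k] for k in keys])
    anova = StatResult("bootstrap-one-way-anova", float(f), float(p),
                       alpha=alpha)

    n_cells = len(keys)
    n_pairs = n_cells * (n_cells - 1) // 2
    pooled = np.concatenate([means[k] for k in keys])
    grand_df = pooled.size - n_cells
    mse = float(np.sum([(means[k] - means[k].mean()) ** 2
                        for k in keys])) / grand_df if grand_df > 0 else np.nan
    tcrit = sps.t.ppf(1 - alpha / (2 * n_pairs), grand_df)
    rows = []
    for i in range(n_cells):
        for jx in range(i + 1, n_cells):
            a, b = keys[i], keys[jx]
            diff = float(means[a].mean() - means[b].mean())
            se = np.sqrt(mse * (1 / means[a].size + 1 / means[b].size))
            rows.append({
                "comparison": f"{a[0]}_{a[1]} vs {b[0]}_{b[1]}",
                "mean_diff": diff,
                "ci_low": diff - tcrit * se,
                "ci_high": diff + tcrit * se,
            })
    pairwise = pd.DataFrame(rows)

    groups = sorted({g for g, _ in keys})
    conditions = sorted({c for _, c in keys})
    rocs: dict[str, ROCResult] = {}
    if len(groups) == 2:
        for cond in conditions:
            key0, key1 = (groups[0], cond), (groups[1], cond)
            if key0 in means and key1 in means:
                scores = np.concatenate([means[key0], means[key1]])
                labels = np.concatenate([np.zeros(B, int), np.ones(B, int)])
                rocs[cond] = roc(scores, labels,
                                 score_def=f"bootstrapped mean ({cond})")
    return BootstrapResult(means, kde, anova, pairwise, rocs, B=B, seed=seed)
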