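"""Internal-validation and subgroup statistics.

Bland-Altman agreement (percent or absolute-years differences), Spearman
correlation with a Bonett-Wright Fisher-z confidence interval, WHO BMI
classification, heart-age-gap tables by comorbidity / BMI class / decade,
nonparametric group comparison (Mann-Whitney for two groups, Kruskal-Wallis
with Dunn/Holm post-hoc for more), and forward stepwise OLS for composite
comorbidity burden.

Conventions: the Bland-Altman percent difference divides by the pair mean;
limits of agreement are bias +/- 1.96*SD of the differences and are reported
alongside the (much narrower) t-based CI of the bias, since summaries in the
clinical literature frequently conflate the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .derivation import DECADE_GROUPS

__all__ = [
    "BlandAltmanResult",
    "CorrelationResult",
    "GroupComparisonResult",
    "bland_altman",
    "spearman_ci",
    "classify_bmi",
    "age_gap_by_group",
    "compare_groups",
    "stepwise_ols",
]

BMI_CLASSES = ("normal", "overweight", "obesity I", "obesity II", "obesity III")
_BMI_EDGES = (25.0, 30.0, 35.0, 40.0)


@dataclass(frozen=True)
class BlandAltmanResult:
    mode: str  # 'percent' | 'absolute'
    bias: float
    lower_loa: float
    upper_loa: float
    bias_ci: tuple[float, float]
    p_value: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci: tuple[float, float]
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparisonResult:
    groups: tuple
    medians: dict  # group -> (median, q1, q3)
    summary: dict  # group -> "median (q1-q3)" string
    test: str
    statistic: float
    p_value: float
    posthoc: dict | None  # (g1, g2) -> Holm-adjusted p, only if omnibus < .05


def bland_altman(predicted, chronological, mode: str = "absolute") -> BlandAltmanResult:
    """Agreement between predicted and chronological age.

    mode='percent' uses d_i = 100*(pred-chrono)/mean(pred, chrono);
    mode='absolute' uses plain year differences.  Limits of agreement are
    bias +/- 1.96*SD(d); the bias CI and p come from a one-sample t-test of
    d against zero (p=1 for exact agreement).
    """
    pred = np.asarray(predicted, dtype=float)
    chrono = np.asarray(chronological, dtype=float)
    if pred.shape != chrono.shape or pred.ndim != 1:
        raise ValueError("predicted and chronological must be equal-length 1-d")
    n = len(pred)
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    if mode == "percent":
        denom = (pred + chrono) / 2.0
        if np.any(denom <= 0):
            raise ValueError("percent mode requires pred + chrono > 0 per pair")
        d = 100.0 * (pred - chrono) / denom
    elif mode == "absolute":
        d = pred - chrono
    else:
        raise ValueError("mode must be 'percent' or 'absolute'")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = 1.96 * sd
    if sd == 0.0:
        p = 1.0 if bias == 0.0 else 0.0
        ci = (bias, bias)
    else:
        se = sd / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        ci = (bias - tcrit * se, bias + tcrit * se)
        p = float(sps.ttest_1samp(d, 0.0).pvalue)
    return BlandAltmanResult(
        mode=mode,
        bias=bias,
        lower_loa=bias - loa,
        upper_loa=bias + loa,
        bias_ci=ci,
        p_value=p,
        n=n,
    )


def spearman_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Spearman rho with a Bonett-Wright Fisher-z confidence interval.

    SE(z) = sqrt((1 + rho^2/2)/(n-3)); ties get average ranks.  Degenerate
    perfect correlations return a point CI at +/-1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    n = len(x)
    if abs(rho) >= 1.0 - 1e-12:  # numerically perfect monotone association
        rho = 1.0 if rho > 0 else -1.0
        return CorrelationResult(rho=rho, ci=(rho, rho), p_value=float(p), n=n)
    z = np.arctanh(rho)
    se = np.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
    zcrit = sps.norm.ppf(1 - alpha / 2)
    ci = (float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se)))
    return CorrelationResult(rho=rho, ci=ci, p_value=float(p), n=n)


def classify_bmi(bmi: float) -> str:
    """WHO BMI class; boundaries are half-open at 25/30/35/40 kg/m^2."""
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be finite and > 0 kg/m^2, got {bmi!r}")
    for label, edge in zip(BMI_CLASSES, _BMI_EDGES):
        if bmi < edge:
            return label
    return BMI_CLASSES[-1]


def _decade_label(age: float) -> str:
    for lo, hi in DECADE_GROUPS:
        if lo <= age < (hi + 1 if hi < 85 else 85.0001):
            return f"{lo}-{hi}"
    return "other"


def age_gap_by_group(
    cohort: pd.DataFrame,
    functional_age: np.ndarray,
    grouping: str,
    age_col: str = "age_yr",
) -> pd.DataFrame:
    """Mean heart-age gap (functional - chronological) per subgroup.

    ``grouping`` is ``'bmi_class'``, ``'decade'`` or the name of a boolean
    comorbidity column.  Each row carries a one-sample t-test of the group's
    gaps against zero; for a boolean grouping an independent-samples t-test
    between the flagged and unflagged gaps is added (``p_between``).  Groups
    with n < 2 report their gap with p marked unavailable (NaN).
    """
    gap = np.asarray(functional_age, dtype=float) - cohort[age_col].to_numpy(
        dtype=float
    )
    if grouping == "bmi_class":
        labels = cohort["bmi"].map(classify_bmi)
        order = list(BMI_CLASSES)
    elif grouping == "decade":
        labels = cohort[age_col].map(_decade_label)
        order = [f"{lo}-{hi}" for lo, hi in DECADE_GROUPS]
    else:
        if grouping not in cohort.columns:
            raise KeyError(f"no column {grouping!r} in cohort")
        labels = cohort[grouping].astype(bool).map({True: grouping, False: "without"})
        order = [grouping, "without"]
    rows = []
    by_label = {}
    for grp in order:
        g = gap[(labels == grp).to_numpy()]
        by_label[grp] = g
        if len(g) == 0:
            continue
        if len(g) >= 2 and np.std(g, ddof=1) > 0:
            p = float(sps.ttest_1samp(g, 0.0).pvalue)
        elif len(g) >= 2:
            p = 1.0 if np.all(g == 0) else 0.0
        else:
            p = np.nan
        rows.append(
            {"group": grp, "n": len(g), "mean_gap_yr": float(np.mean(g)), "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["group", "n", "mean_gap_yr", "p_value"])
    if grouping not in ("bmi_class", "decade"):
        a, b = by_label.get(order[0], []), by_label.get(order[1], [])
        if len(a) >= 2 and len(b) >= 2:
            p_between = float(sps.ttest_ind(a, b).pvalue)
        else:
            p_between = np.nan
        out["p_between"] = p_between
    return out


def _dunn_posthoc(groups: dict, alpha_adjust: str = "holm") -> dict:
    """Dunn's rank-sum z-tests with tie correction, Holm-adjusted."""
    labels = list(groups)
    all_vals = np.concatenate([groups[g] for g in labels])
    n_tot = len(all_vals)
    ranks = sps.rankdata(all_vals)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        k = len(groups[g])
        mean_rank[g] = float(np.mean(ranks[start : start + k]))
        sizes[g] = k
        start += k
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs, pvals = [], []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
            pairs.append((g1, g2))
            pvals.append(2.0 * sps.norm.sf(abs(z)))
    adj = multipletests(pvals, method=alpha_adjust)[1]
    return dict(zip(pairs, (float(p) for p in adj)))


def compare_groups(values_by_group: dict) -> GroupComparisonResult:
    """Nonparametric comparison of a metric across groups.

    Two groups: Mann-Whitney U (asymptotic, tie-corrected).  More: Kruskal-
    Wallis, with Dunn post-hoc (Holm adjustment) only when the omnibus test
    is significant at 0.05.  Per-group medians are reported in the
    "median (q1-q3)" format used in clinical summary tables.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    medians, summary = {}, {}
    for g, v in groups.items():
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        medians[g] = (float(med), float(q1), float(q3))
        summary[g] = f"{med:g} ({q1:g}-{q3:g})"
    vals = list(groups.values())
    if len(groups) == 2:
        test = "mann-whitney"
        if all(np.array_equal(vals[0], v) for v in vals[1:]):
            stat, p = float(len(vals[0]) * len(vals[1]) / 2.0), 1.0
        else:
            res = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided",
                                   method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
        posthoc = None
    else:
        test = "kruskal-wallis"
        if all(np.array_equal(vals[0], v) for v in vals[1:]):
            stat, p = 0.0, 1.0
        else:
            res = sps.kruskal(*vals)
            stat, p = float(res.statistic), float(res.pvalue)
        posthoc = _dunn_posthoc(groups) if p < 0.05 else None
    return GroupComparisonResult(
        groups=tuple(groups),
        medians=medians,
        summary=summary,
        test=test,
        statistic=stat,
        p_value=p,
        posthoc=posthoc,
    )


def stepwise_ols(
    cohort: pd.DataFrame,
    response: str,
    candidates: list[str],
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> dict:
    """Forward stepwise OLS with univariate pre-screening.

    Candidates failing the univariate screen (slope p >= entry_p) never
    enter.  At each step the candidate with the smallest partial p below
    ``entry_p`` is added, then included terms with p above ``removal_p`` are
    dropped.  Deterministic given the data.  Returns the selected variables,
    their coefficients, and the univariate screen table.
    """
    y = cohort[response].to_numpy(dtype=float)
    screen = {}
    eligible = []
    for c in candidates:
        x = sm.add_constant(cohort[c].to_numpy(dtype=float))
        fit = sm.OLS(y, x).fit()
        p = float(fit.pvalues[1])
        screen[c] = p
        if p < entry_p:
            eligible.append(c)
    selected: list[str] = []
    while True:
        best, best_p = None, entry_p
        for c in eligible:
            if c in selected:
                continue
            X = sm.add_constant(cohort[selected + [c]].to_numpy(dtype=float))
            fit = sm.OLS(y, X).fit()
            p = float(fit.pvalues[-1])
            if p < best_p:
                best, best_p = c, p
        if best is None:
            break
        selected.append(best)
        # backward check
        while len(selected) > 1:
            X = sm.add_constant(cohort[selected].to_numpy(dtype=float))
            fit = sm.OLS(y, X).fit()
            pvals = fit.pvalues[1:]
            worst = int(np.argmax(pvals))
            if pvals[worst] > removal_p:
                selected.pop(worst)
            else:
                break
    if selected:
        X = sm.add_constant(cohort[selected].to_numpy(dtype=float))
        fit = sm.OLS(y, X).fit()
        coefs = dict(zip(["const"] + selected, (float(b) for b in fit.params)))
        r2 = float(fit.rsquared)
    else:
        coefs, r2 = {}, 0.0
    return {
        "selected": selected,
        "coefficients": coefs,
        "r_squared": r2,
        "univariate_p": screen,
    }
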