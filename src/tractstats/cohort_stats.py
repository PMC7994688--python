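"""Group-level cohort statistics and the demographics table.

One-way ANOVA on per-tract mean FA across the three groups, Wilcoxon
rank-sum tests for neurocognitive scores, two-sample t / chi-squared tests
with Bonferroni correction for the demographics table, and lesion
distribution summaries.
"""

from __future__ import annotations

import logging
from itertools import combinations as _combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

log = logging.getLogger(__name__)

_EXACT_LIMIT = 200_000  # max label splits enumerated for the exact rank test


def percent_int(count: int, total: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero)."""
    if total <= 0:
        raise ConfigError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def percent_trunc1(count: int, total: int) -> float:
    """Percentage truncated to one decimal.

    Truncation (not rounding) reproduces the convention of the printed
    lesion-share table this formatter mirrors.
    """
    if total <= 0:
        raise ConfigError("total must be positive")
    x = 100.0 * count / total
    return float(np.floor(x * 10.0 + 1e-9) / 10.0)


def format_count_pct(count: int, total: int) -> str:
    return f"{count} ({percent_int(count, total)}%)"


def format_mean_sd(values) -> str:
    values = np.asarray(values, dtype=float)
    return f"{values.mean():.1f} ± {values.std(ddof=1):.1f}"


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m) over a family of m comparisons."""
    return min(1.0, p * m)


def group_anova(groups) -> tuple[float, float]:
    """One-way between-groups ANOVA.

    Parameters
    ----------
    groups : sequence of 1-D arrays
        One array of values per group; at least two groups of two.

    Returns
    -------
    (F, p)
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ConfigError("every group needs at least 2 subjects")
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def anova_by_tract(tract_means: pd.DataFrame, groups,
                   kind: str = "between") -> pd.DataFrame:
    """Per-tract three-group ANOVA on subject mean FA.

    ``kind="between"`` runs an independent one-way ANOVA per tract (the
    groups are unpaired, so a within-subject group factor is impossible).
    ``kind="mixed"`` tests the between-subjects group effect of a mixed
    group x tract design, i.e. one ANOVA on each subject's mean over
    tracts, reported once under tract "ALL".
    """
    groups = np.asarray(groups)
    if kind == "mixed":
        subj_mean = tract_means.mean(axis=1)
        f, p = group_anova([subj_mean[groups == g] for g in pd.unique(groups)])
        return pd.DataFrame({"tract": ["ALL"], "F": [f], "p": [p]})
    if kind != "between":
        raise ConfigError(f"kind must be 'between' or 'mixed', got {kind!r}")
    rows = []
    for tract in tract_means.columns:
        col = tract_means[tract].to_numpy()
        f, p = group_anova([col[groups == g] for g in pd.unique(groups)])
        rows.append({"tract": tract, "F": f, "p": p})
    return pd.DataFrame(rows)


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w: float, alternative: str):
    """Exact rank-sum p by enumerating all C(n, n_a) label splits."""
    sums = np.fromiter(
        (sum(c) for c in _combinations(ranks, n_a)),
        dtype=float, count=comb(len(ranks), n_a),
    )
    eps = 1e-9
    p_less = np.count_nonzero(sums <= w + eps) / len(sums)
    p_greater = np.count_nonzero(sums >= w - eps) / len(sums)
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def wilcoxon_rank(a, b, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties.

    The statistic is the rank sum of the first sample.  Exact enumeration
    of label splits is used for small samples (both n <= 10); larger
    samples use the normal approximation with tie-corrected variance and
    continuity correction.  All-tied inputs give p = 1 (flagged).

    ``alternative="less"`` tests whether sample ``a`` tends to be lower.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each sample needs at least 2 values")
    if alternative not in ("two-sided", "less", "greater"):
        raise ConfigError(f"unknown alternative {alternative!r}")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n_a].sum())

    if np.ptp(pooled) == 0:
        log.warning("all values tied across both samples; p = 1")
        return w, 1.0

    if max(n_a, n_b) <= 10 and comb(n, n_a) <= _EXACT_LIMIT:
        return w, _exact_ranksum_p(ranks, n_a, w, alternative)

    mean = n_a * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    # Continuity correction shrinks |w - mean| by 0.5.
    def z_of(delta):
        return delta / np.sqrt(var)
    if alternative == "less":
        p = stats.norm.cdf(z_of(w - mean + 0.5))
    elif alternative == "greater":
        p = stats.norm.sf(z_of(w - mean - 0.5))
    else:
        p = 2.0 * stats.norm.sf(z_of(abs(w - mean) - 0.5))
    return w, float(min(1.0, p))


def _chi2_counts(x_a, x_b):
    """2 x k contingency table over the union of observed levels."""
    levels = sorted(set(x_a) | set(x_b))
    table = np.array([
        [sum(1 for v in x_a if v == lv) for lv in levels],
        [sum(1 for v in x_b if v == lv) for lv in levels],
    ])
    return levels, table


def demographics_table(records, group_a: str, group_b: str,
                       continuous=("age",),
                       categorical=("sex", "wmh_present"),
                       include_scores: bool = True,
                       yates: bool = False) -> pd.DataFrame:
    """Pairwise group comparison table with Bonferroni correction.

    Continuous variables get two-sample t tests, categorical variables
    Pearson chi-squared (Yates correction optional for 2x2), and
    neurocognitive scores Wilcoxon rank-sum tests.  The Bonferroni family
    is the full set of variables in the table.  Counts are reported as
    "13 (62%)" with integer percentages, continuous variables as
    "mean ± SD".
    """
    rec_a = [r for r in records if r.group == group_a]
    rec_b = [r for r in records if r.group == group_b]
    if len(rec_a) < 2 or len(rec_b) < 2:
        raise ConfigError("each group needs at least 2 records")

    rows = []

    def cont_values(recs, name):
        return np.array([float(getattr(r, name)) for r in recs])

    for name in continuous:
        va, vb = cont_values(rec_a, name), cont_values(rec_b, name)
        if np.ptp(np.concatenate([va, vb])) == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = stats.ttest_ind(va, vb)
        rows.append({
            "variable": name, "kind": "t",
            "statistic": float(t_stat), "p_raw": float(p),
            "summary_a": format_mean_sd(va), "summary_b": format_mean_sd(vb),
        })

    for name in categorical:
        xa = [getattr(r, name) for r in rec_a]
        xb = [getattr(r, name) for r in rec_b]
        levels, table = _chi2_counts(xa, xb)
        if len(levels) < 2:
            log.warning("variable %r has a single level; chi2 undefined", name)
            stat, p = 0.0, 1.0
        else:
            if np.any(table == 0):
                log.warning("empty cell in chi2 table for %r "
                            "(Yates correction %s)", name, yates)
            stat, p, _, _ = stats.chi2_contingency(table, correction=yates)
        # Summaries report the first level's share (e.g. females, lesions).
        lead = levels[0] if len(levels) else None
        ca = sum(1 for v in xa if v == lead)
        cb = sum(1 for v in xb if v == lead)
        rows.append({
            "variable": name, "kind": "chi2",
            "statistic": float(stat), "p_raw": float(p),
            "summary_a": format_count_pct(ca, len(rec_a)),
            "summary_b": format_count_pct(cb, len(rec_b)),
        })

    if include_scores and rec_a[0].scores and rec_b[0].scores:
        for m in sorted(rec_a[0].scores):
            va = np.array([r.scores[m] for r in rec_a])
            vb = np.array([r.scores[m] for r in rec_b])
            w, p = wilcoxon_rank(va, vb)
            rows.append({
                "variable": m, "kind": "rank-sum",
                "statistic": float(w), "p_raw": float(p),
                "summary_a": format_mean_sd(va), "summary_b": format_mean_sd(vb),
            })

    df = pd.DataFrame(rows)
    df["p_bonf"] = [bonferroni(p, len(df)) for p in df["p_raw"]]
    return df


def wmh_distribution(lesions) -> pd.DataFrame:
    """Counts and percentage shares of lesions per (region, hemisphere).

    The percentage denominator is the total lesion count; shares are
    truncated to one decimal.  Zero lesions yield an empty frame.
    """
    lesions = list(lesions)
    if not lesions:
        return pd.DataFrame(columns=["region", "hemisphere", "count", "percent"])
    counts = {}
    for les in lesions:
        key = (les.region, les.hemisphere)
        counts[key] = counts.get(key, 0) + 1
    total = len(lesions)
    rows = [
        {"region": region, "hemisphere": hemi, "count": c,
         "percent": percent_trunc1(c, total)}
        for (region, hemi), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
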