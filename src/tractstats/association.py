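"""FA-neurocognition association with false-discovery-rate control.

Pearson correlations between per-tract mean FA and the nine neurocognitive
measures within a chosen group, with Benjamini-Hochberg step-up adjustment
over the full tract x measure family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ConstantInputError

log = logging.getLogger(__name__)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigError("inputs must have equal length")
    if len(x) < 3:
        raise ConfigError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation input is constant")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values in the input order, rejection mask at
    level ``q``).  The adjusted value of the i-th smallest p is
    ``min over j >= i of min(1, m * p_(j) / j)``, and the rejection set
    equals the classical step-up rule's.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ConfigError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ConfigError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def correlate_tracts_measures(tract_means: pd.DataFrame, records,
                              group: str = "SCD",
                              q: float = 0.05) -> pd.DataFrame:
    """All tract x measure correlations within one group, BH-adjusted.

    Parameters
    ----------
    tract_means : DataFrame
        Subjects (index = subject_id) x tracts matrix of mean FA.
    records : list of SubjectRecord
        Must carry the nine scores for the chosen group's subjects;
        missing scores are excluded pairwise (logged).

    Returns
    -------
    DataFrame with columns tract, measure, n, r, p_raw, p_bh, significant,
    sorted by adjusted then raw p.  The BH family is the full set of
    tract x measure pairs.
    """
    recs = [r for r in records if r.group == group]
    if len(recs) < 3:
        raise ConfigError(f"group {group!r} needs at least 3 subjects")
    ids = [r.subject_id for r in recs]
    missing = [s for s in ids if s not in tract_means.index]
    if missing:
        raise ConfigError(f"no tract means for subjects {missing}")
    measures = sorted(recs[0].scores)
    if not measures:
        raise ConfigError("records carry no scores")

    scores = pd.DataFrame(
        {m: [r.scores.get(m, np.nan) for r in recs] for m in measures},
        index=ids,
    )
    fa = tract_means.loc[ids]

    rows = []
    for tract in fa.columns:
        for m in measures:
            pair = pd.DataFrame({"fa": fa[tract], "score": scores[m]}).dropna()
            if len(pair) < len(recs):
                log.info("excluded %d subjects with missing %s for %s",
                         len(recs) - len(pair), m, tract)
            r, p = pearson_r(pair["fa"], pair["score"])
            rows.append({"tract": tract, "measure": m, "n": len(pair),
                         "r": r, "p_raw": p})
    df = pd.DataFrame(rows)
    adj, reject = bh_adjust(df["p_raw"].to_numpy(), q)
    df["p_bh"] = adj
    df["significant"] = reject
    return df.sort_values(["p_bh", "p_raw"], kind="stable").reset_index(drop=True)
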