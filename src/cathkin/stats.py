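"""Exact small-sample group comparisons and the median summary table.

With six subjects per group, normal approximations to rank tests are poor
and cannot produce the attainable p-value floor (2/2^6 = 0.03125 for a
six-pair signed-rank test). Both tests here therefore enumerate the full
permutation distribution on the observed (possibly tied) values, using
mid-ranks for ties, and report the doubled smaller tail capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "wilcoxon_signed_rank_exact",
    "summarize_cohort",
    "SUMMARY_FEATURES",
]

_TOL = 1e-8


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("exact p-value must lie in (0, 1]")


def mann_whitney_exact(a, b) -> TestResult:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    U is the rank-sum statistic of the first sample (mid-ranks for ties).
    The null distribution enumerates all C(n1+n2, n1) assignments of the
    pooled observed values to the two groups; p doubles the smaller tail
    probability, capped at 1. Intended for n <= ~10 per group.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    us = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    lo = np.mean(us <= u_obs + _TOL)
    hi = np.mean(us >= u_obs - _TOL)
    p = min(1.0, 2.0 * min(lo, hi))
    return TestResult("mann-whitney-exact", float(u_obs), float(p), (n1, n2))


def wilcoxon_signed_rank_exact(x, y) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test by sign-pattern enumeration.

    Zero differences are dropped (Wilcoxon convention); |d| is ranked with
    mid-ranks for ties; W+ is the positive-rank sum. The null enumerates
    all 2^n sign patterns; p doubles the smaller tail, capped at 1.
    Intended for n <= ~15 pairs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; the test carries no information")
    n = d.size
    if n > 20:
        raise ValueError(f"{n} non-zero pairs: enumeration of 2^n patterns is impractical")
    r = rankdata(np.abs(d))
    w_obs = r[d > 0].sum()
    signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1  # rows: sign patterns
    ws = signs @ r
    lo = np.mean(ws <= w_obs + _TOL)
    hi = np.mean(ws >= w_obs - _TOL)
    p = min(1.0, 2.0 * min(lo, hi))
    return TestResult("wilcoxon-signed-rank-exact", float(w_obs), float(p), (n,))


#: Feature columns summarized in the median table, in display order.
SUMMARY_FEATURES = ["T_p", "v_d", "a_d", "j_d", "d_tip", "d_shape"]


def summarize_cohort(features: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Median table with exact p-values, one row per feature x stage.

    For each feature and stage: group medians per equipment condition, the
    Mann-Whitney p across experience groups per equipment, and the Wilcoxon
    signed-rank p across equipment within each group (paired by subject).
    Significance columns mark p < ``alpha``. Missing design cells raise.
    """
    required = {"subject_id", "group", "equipment", "stage"}
    if not required <= set(features.columns):
        raise ValueError(f"features table missing columns {sorted(required - set(features.columns))}")
    feats = [f for f in SUMMARY_FEATURES if f in features.columns]
    if not feats:
        raise ValueError("no known feature columns to summarize")

    missing = []
    for g in ("novice", "expert"):
        for e in ("conventional", "robotic"):
            for s in (1, 2):
                if features.query("group == @g and equipment == @e and stage == @s").empty:
                    missing.append((g, e, s))
    if missing:
        raise ValueError(f"missing design cells (group, equipment, stage): {missing}")

    def cell(g: str, e: str, s: int, f: str) -> pd.Series:
        sub = features.query("group == @g and equipment == @e and stage == @s")
        return sub.sort_values("subject_id").set_index("subject_id")[f]

    rows = []
    for f in feats:
        for s in (1, 2):
            vals = {(g, e): cell(g, e, s, f) for g in ("novice", "expert") for e in ("conventional", "robotic")}
            if any(v.isna().any() for v in vals.values()):
                continue  # feature absent for this design (e.g. no shapes)
            row = {"feature": f, "stage": s}
            for e in ("conventional", "robotic"):
                row[f"median_novice_{e}"] = float(vals[("novice", e)].median())
                row[f"median_expert_{e}"] = float(vals[("expert", e)].median())
                row[f"p_mw_{e}"] = mann_whitney_exact(
                    vals[("novice", e)], vals[("expert", e)]
                ).p_value
            for g in ("novice", "expert"):
                conv, robo = vals[(g, "conventional")], vals[(g, "robotic")]
                robo = robo.reindex(conv.index)
                row[f"p_wi_{g}"] = wilcoxon_signed_rank_exact(conv.values, robo.values).p_value
            for col in ("p_mw_conventional", "p_mw_robotic", "p_wi_novice", "p_wi_expert"):
                row[f"sig_{col[2:]}"] = row[col] < alpha
            rows.append(row)
    return pd.DataFrame(rows)
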