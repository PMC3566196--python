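"""Group comparison statistics for matched-pair cohort tables.

The battery mirrors small-sample practice for matched designs:

* continuous variables — a rank-transform two-step procedure: pool both
  groups, convert to midranks, then fit a random-intercept-per-pair
  linear model on the ranks and test the group fixed effect (two-sided).
  For balanced complete-pair data this REML fit with an unconstrained
  pair variance component is algebraically the paired t-test on
  within-pair rank differences, which is how the complete-pair path is
  computed; incomplete pairs fall back to a numerical mixed-model fit.
* ordinal visual scores — Mann-Whitney U with midrank ties, exact
  enumeration for small tie-free samples and a tie- and
  continuity-corrected normal approximation otherwise.
* association with a continuous covariate — Spearman rank correlation.

Missing values (n.a. entries) are excluded and the n actually used is
reported in every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError, UndefinedStatisticError

#: Pooled-sample-size boundary between exact and approximate
#: Mann-Whitney p-values.
MWU_EXACT_MAX_N = 12


@dataclass
class ComparisonResult:
    """Outcome of one group comparison or correlation."""

    variable: str
    test: str
    statistic: float
    p_value: float
    n: Dict[str, int]
    group_means: Dict[str, float] = field(default_factory=dict)
    group_sds: Dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Midranks 1..n over non-missing entries; NaN entries stay NaN."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        raise EmptyInputError("rank transform needs >= 2 non-missing values")
    out = np.full(v.shape, np.nan)
    out[finite] = sps.rankdata(v[finite], method="average")
    return out


def _group_arrays(records: pd.DataFrame, variable: str):
    groups = sorted(records["group"].dropna().unique())
    if len(groups) != 2:
        raise EmptyInputError(f"expected exactly 2 groups, got {groups}")
    return groups


def paired_rank_lmm_test(records: pd.DataFrame, variable: str) -> ComparisonResult:
    """Rank-transform then random-intercept model for a matched design.

    ``records`` needs columns ``group``, ``pair_id`` and ``variable``.
    Step 1 pools both groups and converts to midranks; step 2 fits
    ranks ~ group + (1 | pair) by REML and reports the two-sided Wald
    test of the group effect against a t reference with
    (complete pairs - 1) degrees of freedom. With complete pairs this
    is evaluated in closed form (identical to the paired t-test on
    within-pair rank differences); otherwise statsmodels' MixedLM is
    used, with a paired-t fallback on the complete pairs if the
    numerical fit fails to converge.
    """
    df = records[["group", "pair_id", variable]].copy()
    df = df[np.isfinite(pd.to_numeric(df[variable], errors="coerce"))]
    df[variable] = df[variable].astype(float)
    groups = _group_arrays(df, variable)
    if df.groupby(["pair_id", "group"]).size().max() > 1:
        raise ValueError("at most one record per (pair_id, group) allowed")

    df["rank"] = rank_transform(df[variable].to_numpy())
    wide = df.pivot(index="pair_id", columns="group", values="rank")
    complete = wide.dropna()
    if len(complete) < 3:
        raise EmptyInputError(
            f"need >= 3 complete pairs, have {len(complete)}")

    raw = {g: df.loc[df["group"] == g, variable] for g in groups}
    meta = dict(
        variable=variable,
        n={g: int(raw[g].size) for g in groups},
        group_means={g: float(raw[g].mean()) for g in groups},
        group_sds={g: float(raw[g].std(ddof=1)) for g in groups},
    )

    balanced = len(complete) == len(wide)
    if balanced:
        d = (complete[groups[0]] - complete[groups[1]]).to_numpy()
        n = d.size
        se = d.std(ddof=1) / np.sqrt(n)
        if se == 0:
            # exact null: no within-pair rank difference anywhere
            return ComparisonResult(test="rank-LMM (paired REML, closed form)",
                                    statistic=0.0, p_value=1.0, **meta)
        tstat = d.mean() / se
        p = 2.0 * sps.t.sf(abs(tstat), df=n - 1)
        return ComparisonResult(test="rank-LMM (paired REML, closed form)",
                                statistic=float(tstat), p_value=float(p), **meta)

    # incomplete pairs: numerical REML fit
    import statsmodels.formula.api as smf

    df["g"] = (df["group"] == groups[0]).astype(float)
    try:
        model = smf.mixedlm("rank ~ g", df, groups=df["pair_id"])
        fit = model.fit(reml=True)
        if not fit.converged:
            raise RuntimeError("MixedLM did not converge")
        tstat = float(fit.params["g"] / fit.bse["g"])
        p = 2.0 * sps.t.sf(abs(tstat), df=len(complete) - 1)
        return ComparisonResult(test="rank-LMM (MixedLM REML)",
                                statistic=tstat, p_value=float(p), **meta)
    except Exception as exc:  # pragma: no cover - exercised via fallback test
        d = (complete[groups[0]] - complete[groups[1]]).to_numpy()
        tstat, p = sps.ttest_rel(complete[groups[0]], complete[groups[1]])
        res = ComparisonResult(test="paired t on rank differences (fallback)",
                               statistic=float(tstat), p_value=float(p), **meta)
        res.notes = f"mixed-model fit failed ({exc}); paired-t fallback"
        return res


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple:
    """Exact two-sided Mann-Whitney p over all group assignments.

    Counts, by dynamic programming over the pooled midranks (doubled to
    integers so ties cost nothing), how many of the C(n, n_a) label
    assignments give a rank sum at least as far from its null mean as
    the observed one. Valid with and without ties; the permutation null
    of the rank sum is symmetric because reflecting ranks r -> n+1-r
    preserves the tie structure.
    """
    na, n = a.size, a.size + b.size
    doubled = np.rint(2 * sps.rankdata(np.concatenate([a, b]))).astype(int)
    r2_obs = int(doubled[:na].sum())
    u_obs = r2_obs / 2.0 - na * (na + 1) / 2.0
    mean2 = na * (n + 1)  # doubled-scale null mean of the rank sum
    total2 = int(doubled.sum())
    # ways[k][s]: subsets of size k with doubled rank sum s
    ways = np.zeros((na + 1, total2 + 1), dtype=np.uint64)
    ways[0, 0] = 1
    for r2 in doubled:
        for k in range(na, 0, -1):  # backwards: each element used once
            ways[k, r2:] += ways[k - 1, : total2 + 1 - r2]
    counts = ways[na]
    dev = abs(r2_obs - mean2)
    s = np.arange(total2 + 1)
    extreme = np.abs(s - mean2) >= dev
    p = float(counts[extreme].sum() / counts.sum())
    return u_obs, min(p, 1.0)


def mann_whitney_u(group_a: Sequence[float],
                   group_b: Sequence[float],
                   variable: str = "") -> ComparisonResult:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact enumeration (tie-aware) when the pooled sample has <= 12
    values; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("both groups need >= 1 non-missing value")
    pooled = np.concatenate([a, b])
    exact = pooled.size <= MWU_EXACT_MAX_N
    if exact:
        statistic, p_value = _exact_mwu_p(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        statistic, p_value = float(res.statistic), float(min(res.pvalue, 1.0))
    return ComparisonResult(
        variable=variable,
        test="Mann-Whitney U (exact)" if exact
        else "Mann-Whitney U (normal approximation, tie-corrected)",
        statistic=statistic, p_value=p_value,
        n={"a": int(a.size), "b": int(b.size)},
        group_means={"a": float(a.mean()), "b": float(b.mean())},
        group_sds={"a": float(a.std(ddof=1)) if a.size > 1 else np.nan,
                   "b": float(b.std(ddof=1)) if b.size > 1 else np.nan})


def spearman_correlation(x: Sequence[float], y: Sequence[float],
                         variable: str = "") -> ComparisonResult:
    """Spearman rho (Pearson on midranks) with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise EmptyInputError("Spearman correlation needs >= 3 paired values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedStatisticError("zero variance in a rank vector")
    rho, p = sps.spearmanr(x, y)
    return ComparisonResult(variable=variable, test="Spearman rank correlation",
                            statistic=float(rho), p_value=float(p),
                            n={"pairs": int(x.size)})


def group_summary(records: pd.DataFrame, variable: str,
                  statistic: str = "mean") -> Dict[str, Dict[str, float]]:
    """Per-group mean/median (missing excluded) with the n used.

    Returns ``{group: {"value": ..., "n": ...}}``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    out = {}
    for g, sub in records.groupby("group"):
        v = pd.to_numeric(sub[variable], errors="coerce").dropna()
        if v.empty:
            raise EmptyInputError(f"group {g!r} has no non-missing {variable}")
        out[str(g)] = {"value": float(getattr(v, statistic)()), "n": int(v.size)}
    return out
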