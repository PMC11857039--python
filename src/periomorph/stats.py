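"""Nonparametric statistical battery for per-disc aggregates.

The analysis pipeline mirrors repeated-measures practice for within-animal
designs: a Shapiro–Wilk normality gate routes to the nonparametric branch,
surface conditions are compared with Friedman tests over complete animal
blocks followed by Dunn-type rank post hoc comparisons with Bonferroni
correction, healing intervals are compared with Mann–Whitney tests, and
metric pairs with Spearman rank correlations.  Family-wise α arithmetic
(e.g. 5 % / 14 comparisons = 0.36 %) is exposed explicitly and never
silently applied: in-study tests report at the configured α (default 5 %).

Blocks (animals) with any missing condition are dropped listwise for
Friedman — the test needs complete blocks, and imputation would invent
data.  Missing values must arrive as NaN, never as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


def bonferroni_alpha(fwer: float, n_comparisons: int) -> float:
    """Per-comparison significance level maintaining a family-wise error rate.

    ``bonferroni_alpha(0.05, 14)`` ≈ 0.0036, i.e. 0.36 % when printed as a
    two-decimal percentage.
    """
    if not 0 < fwer < 1:
        raise ValueError(f"fwer must lie in (0, 1), got {fwer}")
    if n_comparisons < 1:
        raise ValueError(f"n_comparisons must be >= 1, got {n_comparisons}")
    return fwer / n_comparisons


def descriptives(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean ± SD and n per group (ddof=1 SD; NaN-aware)."""
    rows = []
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        rows.append({"group": name, "n": x.size,
                     "mean": x.mean() if x.size else math.nan,
                     "sd": x.std(ddof=1) if x.size > 1 else math.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

@dataclass
class NormalityReport:
    """Per-group Shapiro–Wilk results and the resulting branch decision."""

    per_group: pd.DataFrame
    alpha: float
    nonparametric: bool


def shapiro_gate(groups: dict[str, np.ndarray], alpha: float = 0.05) -> NormalityReport:
    """Shapiro–Wilk W and p per group; route nonparametric if any p ≤ alpha.

    Groups with n < 3 are skipped with a warning (the statistic is
    undefined); a constant sample is degenerate and flagged non-normal.
    """
    rows = []
    any_nonnormal = False
    for name, x in groups.items():
        x = np.asarray(x, dtype=float)
        x = x[~np.isnan(x)]
        if x.size < 3:
            logger.warning("group %r has n=%d < 3; skipped by normality gate",
                           name, x.size)
            rows.append({"group": name, "n": x.size, "W": math.nan,
                         "p": math.nan, "note": "skipped (n < 3)"})
            continue
        if np.ptp(x) == 0:
            rows.append({"group": name, "n": x.size, "W": math.nan, "p": 0.0,
                         "note": "degenerate (constant); flagged non-normal"})
            any_nonnormal = True
            continue
        W, p = sps.shapiro(x)
        rows.append({"group": name, "n": x.size, "W": W, "p": p, "note": ""})
        if p <= alpha:
            any_nonnormal = True
    return NormalityReport(per_group=pd.DataFrame(rows), alpha=alpha,
                           nonparametric=any_nonnormal)


# ---------------------------------------------------------------------------
# Friedman + post hoc
# ---------------------------------------------------------------------------

@dataclass
class FriedmanReport:
    """Friedman omnibus result with pairwise post hoc table.

    ``posthoc`` has columns cond_a, cond_b, statistic, p_raw, p_adjusted,
    significant; adjusted p = min(1, raw × number of pairs).
    """

    statistic: float
    p_value: float
    n_blocks: int
    n_conditions: int
    dropped_blocks: list
    alpha: float
    posthoc: pd.DataFrame | None
    descriptives: pd.DataFrame | None = None
    missing: bool = False

    @property
    def significant(self) -> bool:
        return (not self.missing) and self.p_value <= self.alpha


def _dunn_posthoc(ranks: np.ndarray, conditions, pairs, alpha: float) -> pd.DataFrame:
    """Dunn-type z tests on Friedman within-block mean ranks."""
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"cond_a": conditions[i], "cond_b": conditions[j],
                     "statistic": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * len(pairs))
    df["significant"] = df["p_adjusted"] <= alpha
    return df


def _wilcoxon_posthoc(data: np.ndarray, conditions, pairs, alpha: float) -> pd.DataFrame:
    rows = []
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(data[:, i], data[:, j], zero_method="wilcox")
        rows.append({"cond_a": conditions[i], "cond_b": conditions[j],
                     "statistic": stat, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * len(pairs))
    df["significant"] = df["p_adjusted"] <= alpha
    return df


def friedman_bonferroni(matrix, conditions=None, *, alpha: float = 0.05,
                        posthoc: str = "dunn", pairs: str = "all",
                        control: str | None = None) -> FriedmanReport:
    """Friedman test over blocks × conditions with Bonferroni post hoc.

    ``matrix`` is a blocks × conditions array or DataFrame (columns =
    conditions, rows = animal blocks).  Blocks containing any missing value
    are dropped listwise (and logged).  Post hoc pairs are either all
    pairwise comparisons or each condition against ``control``; the pairwise
    statistic is a Dunn-type rank z test (matching the usual
    "Friedman with Bonferroni" software behaviour) or, alternatively,
    Wilcoxon signed-rank (``posthoc='wilcoxon'``).
    """
    if isinstance(matrix, pd.DataFrame):
        conditions = list(matrix.columns) if conditions is None else list(conditions)
        data = matrix.to_numpy(dtype=float)
        block_ids = list(matrix.index)
    else:
        data = np.asarray(matrix, dtype=float)
        conditions = (list(conditions) if conditions is not None
                      else [f"C{j + 1}" for j in range(data.shape[1])])
        block_ids = list(range(data.shape[0]))

    complete = ~np.isnan(data).any(axis=1)
    dropped = [b for b, ok in zip(block_ids, complete) if not ok]
    if dropped:
        logger.info("dropping %d incomplete block(s): %s", len(dropped), dropped)
    data = data[complete]
    n, k = data.shape

    if k < 2 or n < 2:
        logger.warning("Friedman not run: %d complete blocks × %d conditions", n, k)
        return FriedmanReport(statistic=math.nan, p_value=math.nan, n_blocks=n,
                              n_conditions=k, dropped_blocks=dropped, alpha=alpha,
                              posthoc=None, missing=True)

    ranks = np.apply_along_axis(sps.rankdata, 1, data)  # midranks for ties
    if np.allclose(data, data[:, [0]]):
        stat, p = 0.0, 1.0  # all conditions identical within every block
    else:
        stat, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])

    if pairs == "control":
        if control is None or control not in conditions:
            raise ValueError("pairs='control' requires a control condition name")
        ci = conditions.index(control)
        pair_idx = [(j, ci) for j in range(k) if j != ci]
    else:
        pair_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]

    if posthoc == "dunn":
        ph = _dunn_posthoc(ranks, conditions, pair_idx, alpha)
    elif posthoc == "wilcoxon":
        ph = _wilcoxon_posthoc(data, conditions, pair_idx, alpha)
    elif posthoc == "none":
        ph = None
    else:
        raise ValueError(f"unknown posthoc method {posthoc!r}")

    desc = descriptives({c: data[:, j] for j, c in enumerate(conditions)})
    return FriedmanReport(statistic=float(stat), p_value=float(p), n_blocks=n,
                          n_conditions=k, dropped_blocks=dropped, alpha=alpha,
                          posthoc=ph, descriptives=desc)


# ---------------------------------------------------------------------------
# Timepoint comparison and correlations
# ---------------------------------------------------------------------------

@dataclass
class TestReport:
    """Generic two-sample / correlation result."""

    name: str
    statistic: float
    p_value: float
    n: tuple
    method: str = ""
    missing: bool = False


def mannwhitney_timepoints(values_a, values_b, *, alpha: float = 0.05) -> TestReport:
    """Two-sided Mann–Whitney U between two healing intervals.

    The exact null distribution is used when both samples have n ≤ 8 and the
    pooled data are tie-free; otherwise the normal approximation with tie
    correction (and continuity correction) is used.  Empty samples yield a
    missing result.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return TestReport(name="mann-whitney", statistic=math.nan,
                          p_value=math.nan, n=(a.size, b.size), missing=True)
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical samples: U at its null mean, two-sided p = 1 with no ties broken
        return TestReport(name="mann-whitney", statistic=a.size * b.size / 2.0,
                          p_value=1.0, n=(a.size, b.size), method=method)
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestReport(name="mann-whitney", statistic=float(u), p_value=float(p),
                      n=(a.size, b.size), method=method)


def spearman(x, y) -> TestReport:
    """Spearman rank correlation (midranks), two-sided p.

    Zero variance in either variable leaves rho undefined (missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return TestReport(name="spearman", statistic=math.nan, p_value=math.nan,
                          n=(x.size,), missing=True)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestReport(name="spearman", statistic=math.nan, p_value=math.nan,
                          n=(x.size,), missing=True, method="zero variance")
    rho, p = sps.spearmanr(x, y)
    return TestReport(name="spearman", statistic=float(rho), p_value=float(p),
                      n=(x.size,))


def spearman_grid(per_disc: pd.DataFrame, metric_pairs, *,
                  condition_col: str = "condition",
                  timepoint_col: str = "timepoint_weeks") -> pd.DataFrame:
    """Correlation grid: rows = condition, columns = metric pair × timepoint.

    ``per_disc`` is a wide per-disc table with one column per metric.  Each
    cell holds the Spearman p-value (the study reports the grid as
    p-values); the companion ``rho`` columns carry the coefficients.
    """
    rows = []
    for cond, sub in per_disc.groupby(condition_col, sort=False):
        row = {condition_col: cond}
        for tp, tsub in sub.groupby(timepoint_col, sort=False):
            for m1, m2 in metric_pairs:
                rep = spearman(tsub[m1], tsub[m2])
                key = f"{m1}~{m2}@{tp}wk"
                row[f"p[{key}]"] = rep.p_value
                row[f"rho[{key}]"] = rep.statistic
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline: gate → Friedman → post hoc
# ---------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    """Full condition-comparison battery for one metric/region/timepoint."""

    normality: NormalityReport
    friedman: FriedmanReport
    branch: str = "nonparametric"


def compare_conditions(matrix, conditions=None, *, alpha: float = 0.05,
                       posthoc: str = "dunn", pairs: str = "all",
                       control: str | None = None) -> ConditionComparison:
    """Normality gate followed by the Friedman/Bonferroni comparison.

    The Friedman branch is reported regardless of the gate outcome (the
    battery is nonparametric by design); the gate records whether a
    parametric analysis would even have been admissible.
    """
    if isinstance(matrix, pd.DataFrame):
        cond_names = list(matrix.columns)
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        cond_names = (list(conditions) if conditions is not None
                      else [f"C{j + 1}" for j in range(data.shape[1])])
    gate = shapiro_gate({c: data[:, j] for j, c in enumerate(cond_names)},
                        alpha=alpha)
    fr = friedman_bonferroni(data, cond_names, alpha=alpha, posthoc=posthoc,
                             pairs=pairs, control=control)
    branch = "nonparametric" if gate.nonparametric else "nonparametric (by design)"
    return ConditionComparison(normality=gate, friedman=fr, branch=branch)


def pivot_metric(per_disc: pd.DataFrame, *, value_col: str = "value",
                 block_col: str = "animal",
                 condition_col: str = "condition") -> pd.DataFrame:
    """Blocks × conditions matrix for one already-filtered metric slice."""
    return per_disc.pivot_table(index=block_col, columns=condition_col,
                                values=value_col, aggfunc="mean")
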