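"""Longitudinal cohort statistics.

Aggregates per-scan readouts over a cohort (long-format table: animal_id,
group, day, readout, value), tracks body-weight change against the humane
endpoint, compares groups by one- or two-way ANOVA with Tukey or Dunnett
post-hoc tests, and correlates CT readouts with histology by Spearman rank
correlation (mid-rank ties, two-sided p from the t approximation on n−2
degrees of freedom, with an exact permutation option for small n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import LungQuantError, UndefinedCorrelationError

#: Body-weight loss (percent of baseline) defining the humane endpoint.
HUMANE_ENDPOINT_LOSS_PCT: float = -20.0


@dataclass(frozen=True)
class WeightChange:
    percent: float
    humane_endpoint: bool


def percent_weight_change(baseline_g: float, current_g: float) -> WeightChange:
    """Body weight as percent variation from baseline (day 0).

    Flags the humane endpoint when the loss reaches 20% of baseline.
    """
    if baseline_g <= 0:
        raise ValueError(f"baseline weight must be > 0 g, got {baseline_g}")
    pct = 100.0 * (current_g - baseline_g) / baseline_g
    return WeightChange(pct, pct <= HUMANE_ENDPOINT_LOSS_PCT)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    readout_pair: tuple[str, str] | None = None


def spearman(
    x, y, method: str = "t", readout_pair: tuple[str, str] | None = None
) -> CorrelationResult:
    """Spearman rank correlation with mid-rank tie handling.

    Pairs with a missing value in either vector are dropped pairwise.
    ``method='t'`` uses the t approximation on n−2 df (the common software
    default); ``method='exact'`` enumerates all permutations (n ≤ 9 only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got "
                         f"{x.shape} and {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"Spearman correlation needs n >= 3 pairs, got {n}")
    rx = stats.rankdata(x)  # average (mid-rank) ties
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: a vector is constant after ranking")
    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        rho = float(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return CorrelationResult(rho, count / total, n, readout_pair)
    res = stats.spearmanr(x, y)  # t approximation, two-sided
    return CorrelationResult(float(res.statistic), float(res.pvalue), n,
                             readout_pair)


class Design(str, Enum):
    ONE_WAY = "ONE_WAY"
    TWO_WAY_DAYxGROUP = "TWO_WAY_DAYxGROUP"


class PostHoc(str, Enum):
    TUKEY = "TUKEY"
    DUNNETT = "DUNNETT"


@dataclass
class ComparisonReport:
    """ANOVA table plus adjusted pairwise contrasts.

    ``pairwise`` columns: group_a, group_b, day, estimate (mean difference
    a−b), p_adj, method.  ``missing_cells`` lists (group, day) design cells
    with no data — reported, never silently dropped.
    """

    anova: pd.DataFrame
    pairwise: pd.DataFrame
    design: Design
    posthoc: PostHoc
    missing_cells: list[tuple[str, int]] = field(default_factory=list)

    @property
    def anova_p(self) -> float:
        """p-value of the group main effect."""
        return float(self.anova.loc["C(group)", "PR(>F)"])


def group_compare(
    table: pd.DataFrame,
    readout: str,
    design: Design | str = Design.ONE_WAY,
    posthoc: PostHoc | str = PostHoc.TUKEY,
    reference: str = "saline",
) -> ComparisonReport:
    """ANOVA with multiplicity-adjusted post-hoc contrasts.

    ``table`` is long-format with columns animal_id, group, day, readout,
    value.  ONE_WAY pools days; TWO_WAY_DAYxGROUP fits the day×group
    factorial and runs the post-hoc within each day.  DUNNETT compares
    every group to ``reference``; TUKEY all pairs.
    """
    design = Design(design)
    posthoc = PostHoc(posthoc)
    df = table[table["readout"] == readout].copy() if "readout" in table else table.copy()
    if df.empty:
        raise LungQuantError(f"no records for readout {readout!r}")
    df["group"] = df["group"].astype(str)
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise LungQuantError("group comparison needs at least 2 groups")
    sizes = df.groupby("group")["value"].count()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise LungQuantError(f"groups with fewer than 2 animals: {small}")
    if posthoc is PostHoc.DUNNETT and reference not in groups:
        raise LungQuantError(
            f"Dunnett reference group {reference!r} not in table "
            f"(groups: {groups})")

    missing_cells: list[tuple[str, int]] = []
    if design is Design.ONE_WAY:
        model = ols("value ~ C(group)", data=df).fit()
        anova = anova_lm(model, typ=2)
        day_slices: list[tuple[object, pd.DataFrame]] = [(None, df)]
    else:
        if "day" not in df.columns:
            raise LungQuantError("two-way design requires a 'day' column")
        days = sorted(df["day"].unique())
        for g in groups:
            for d in days:
                if df[(df["group"] == g) & (df["day"] == d)].empty:
                    missing_cells.append((g, int(d)))
        model = ols("value ~ C(group) + C(day) + C(group):C(day)", data=df).fit()
        anova = anova_lm(model, typ=2)
        day_slices = [(d, df[df["day"] == d]) for d in days]

    rows = []
    for day, sub in day_slices:
        present = sorted(sub["group"].unique())
        if len(present) < 2:
            continue
        if posthoc is PostHoc.TUKEY:
            res = pairwise_tukeyhsd(sub["value"].to_numpy(),
                                    sub["group"].to_numpy(), alpha=0.05)
            data = res.summary().data
            header = data[0]
            for rec in data[1:]:
                rec = dict(zip(header, rec))
                rows.append({
                    "group_a": str(rec["group2"]), "group_b": str(rec["group1"]),
                    "day": day, "estimate": float(rec["meandiff"]),
                    "p_adj": float(rec["p-adj"]), "method": "tukey",
                })
        else:
            others = [g for g in present if g != reference]
            if reference not in present or not others:
                continue
            control = sub.loc[sub["group"] == reference, "value"].to_numpy()
            samples = [sub.loc[sub["group"] == g, "value"].to_numpy()
                       for g in others]
            res = stats.dunnett(*samples, control=control)
            means = {g: sub.loc[sub["group"] == g, "value"].mean()
                     for g in present}
            for g, p in zip(others, np.atleast_1d(res.pvalue)):
                rows.append({
                    "group_a": g, "group_b": reference, "day": day,
                    "estimate": float(means[g] - means[reference]),
                    "p_adj": float(p), "method": "dunnett",
                })
    pairwise = pd.DataFrame(
        rows, columns=["group_a", "group_b", "day", "estimate", "p_adj", "method"])
    return ComparisonReport(anova=anova, pairwise=pairwise, design=design,
                            posthoc=posthoc, missing_cells=missing_cells)


def longitudinal_profile(
    table: pd.DataFrame, readout: str, group: str
) -> pd.DataFrame:
    """Per-day mean ± SEM series for one readout in one group.

    SEM = sd/√n with sd on n−1 df; with a single animal the SEM is
    reported as missing (NaN), never as 0.
    """
    df = table[table["readout"] == readout] if "readout" in table else table
    df = df[df["group"].astype(str) == str(group)]
    if df.empty:
        raise LungQuantError(f"no records for readout {readout!r} in group {group!r}")
    rows = []
    for day, sub in df.groupby("day", sort=True):
        vals = sub["value"].astype(float).to_numpy()
        n = vals.size
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append({"day": day, "mean": float(vals.mean()), "sem": sem, "n": n})
    return pd.DataFrame(rows)
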