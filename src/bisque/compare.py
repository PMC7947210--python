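"""Kit-comparison statistics: gate tests select the omnibus and post-hoc.

For each metric, per-group normality (Shapiro-Wilk) and homogeneity of
variance (Levene, mean-centred) decide the test pair:

* any group non-normal            -> Kruskal-Wallis + Bonferroni-corrected
                                     pairwise Mann-Whitney U
* all normal, unequal variances   -> Welch's one-way ANOVA + Games-Howell
* all normal, equal variances     -> one-way ANOVA + Tukey's HSD

The normality gate fails if ANY group fails -- the conservative reading.
Pairwise results are reported with the conventional significance tiers
(< 0.05, < 0.01, < 0.001).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Omnibus",
    "PostHoc",
    "ComparisonPlan",
    "ComparisonResult",
    "InsufficientDataError",
    "plan_comparison",
    "run_comparison",
    "significance_tier",
]


class Omnibus(str, enum.Enum):
    KRUSKAL_WALLIS = "KRUSKAL_WALLIS"
    WELCH_ANOVA = "WELCH_ANOVA"
    ONEWAY_ANOVA = "ONEWAY_ANOVA"


class PostHoc(str, enum.Enum):
    BONFERRONI_PAIRWISE = "BONFERRONI_PAIRWISE"
    GAMES_HOWELL = "GAMES_HOWELL"
    TUKEY_HSD = "TUKEY_HSD"


#: the cascade as a pure function of the two boolean gates
CASCADE: dict[tuple[bool, bool], tuple[Omnibus, PostHoc]] = {
    (False, False): (Omnibus.KRUSKAL_WALLIS, PostHoc.BONFERRONI_PAIRWISE),
    (False, True): (Omnibus.KRUSKAL_WALLIS, PostHoc.BONFERRONI_PAIRWISE),
    (True, False): (Omnibus.WELCH_ANOVA, PostHoc.GAMES_HOWELL),
    (True, True): (Omnibus.ONEWAY_ANOVA, PostHoc.TUKEY_HSD),
}


class InsufficientDataError(ValueError):
    """A group is too small for the gate tests."""


@dataclass(frozen=True)
class ComparisonPlan:
    metric: str
    normality_ok: bool
    variance_ok: bool
    omnibus: Omnibus
    posthoc: PostHoc
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "normality_ok": self.normality_ok,
            "variance_ok": self.variance_ok,
            "omnibus": self.omnibus.value,
            "posthoc": self.posthoc.value,
            "alpha": self.alpha,
        }


@dataclass
class ComparisonResult:
    plan: ComparisonPlan
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, statistic, p_adjusted, tier


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _shapiro_p(values: np.ndarray) -> float:
    # a (near-)constant group is maximally non-normal for gating purposes
    if np.ptp(values) == 0 or np.std(values) == 0:
        return 0.0
    return float(stats.shapiro(values).pvalue)


def plan_comparison(
    groups: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    metric: str = "",
) -> ComparisonPlan:
    """Run the gate tests and pick the omnibus/post-hoc pair.

    ``groups`` maps kit label to that kit's per-sample metric values; every
    group needs at least three values for Shapiro-Wilk.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups to compare")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for kit, vals in arrays.items():
        if len(vals) < 3:
            raise InsufficientDataError(
                f"group {kit!r} has {len(vals)} values; need >=3"
            )
    normality_ok = all(_shapiro_p(v) >= alpha for v in arrays.values())
    levene_p = float(stats.levene(*arrays.values(), center="mean").pvalue)
    # identical groups make the Levene statistic 0/0; that is equality
    variance_ok = bool(np.isnan(levene_p)) or levene_p >= alpha
    omnibus, posthoc = CASCADE[(normality_ok, variance_ok)]
    return ComparisonPlan(
        metric=metric,
        normality_ok=normality_ok,
        variance_ok=variance_ok,
        omnibus=omnibus,
        posthoc=posthoc,
        alpha=alpha,
    )


def _long_frame(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.concatenate(list(arrays.values())),
            "group": np.repeat(list(arrays.keys()), [len(v) for v in arrays.values()]),
        }
    )


def run_comparison(
    groups: dict[str, np.ndarray | list[float]], plan: ComparisonPlan
) -> ComparisonResult:
    """Execute the planned omnibus test and matching post-hoc."""
    arrays = {k: np.asarray(v, float) for k, v in sorted(groups.items())}
    names = list(arrays)
    values = list(arrays.values())

    if plan.omnibus == Omnibus.KRUSKAL_WALLIS:
        stat, p = stats.kruskal(*values)
    elif plan.omnibus == Omnibus.ONEWAY_ANOVA:
        stat, p = stats.f_oneway(*values)
    else:
        import pingouin as pg

        aov = pg.welch_anova(data=_long_frame(arrays), dv="value", between="group")
        stat, p = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0])

    # rounding can drive a null F microscopically negative, making p NaN
    if np.isnan(p) and stat <= 0.0:
        stat, p = 0.0, 1.0

    rows: list[dict] = []
    pairs = list(itertools.combinations(names, 2))
    if plan.posthoc == PostHoc.BONFERRONI_PAIRWISE:
        m_tests = len(pairs)
        for a, b in pairs:
            u, p_raw = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
            rows.append(
                {"group1": a, "group2": b, "statistic": float(u),
                 "p_adjusted": min(1.0, m_tests * float(p_raw))}
            )
    elif plan.posthoc == PostHoc.TUKEY_HSD:
        res = stats.tukey_hsd(*values)
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                rows.append(
                    {"group1": a, "group2": names[j],
                     "statistic": float(res.statistic[i, j]),
                     "p_adjusted": float(res.pvalue[i, j])}
                )
    else:
        import pingouin as pg

        gh = pg.pairwise_gameshowell(data=_long_frame(arrays), dv="value", between="group")
        for _, r in gh.iterrows():
            rows.append(
                {"group1": str(r["A"]), "group2": str(r["B"]),
                 "statistic": float(r["T"]), "p_adjusted": float(r["pval"])}
            )

    pairwise = pd.DataFrame(rows)
    pairwise["p_adjusted"] = pairwise["p_adjusted"].clip(0.0, 1.0)
    pairwise["tier"] = pairwise["p_adjusted"].map(significance_tier)
    # canonical pair ordering so results do not depend on input group order
    key = pairwise.apply(lambda r: tuple(sorted((r["group1"], r["group2"]))), axis=1)
    pairwise[["group1", "group2"]] = pd.DataFrame(key.tolist(), index=pairwise.index)
    pairwise = pairwise.sort_values(["group1", "group2"]).reset_index(drop=True)
    return ComparisonResult(
        plan=plan,
        omnibus_statistic=float(stat),
        omnibus_p=float(np.clip(p, 0.0, 1.0)),
        pairwise=pairwise,
    )
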