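"""One-way ANOVA and the Student-Newman-Keuls stepwise procedure.

The SNK test orders the k group means, then tests ranges from widest to
narrowest with the studentized-range statistic

    q = (mean_i - mean_j) / sqrt(MSE/2 * (1/n_i + 1/n_j))

against the alpha quantile of the studentized-range distribution for the
span of the range (number of ordered means it encloses) and the pooled
error degrees of freedom. A range is only tested when every enclosing
range was significant; untested ranges are declared non-significant.
Unequal group sizes use the harmonic-mean (Kramer) denominator above.
Under the complete null the familywise error equals alpha, because only
the widest range is tested at first.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class SnkResult:
    group_means: pd.DataFrame  # columns: group, mean, n — ordered descending
    pairwise: pd.DataFrame  # columns: group_a, group_b, span, q, q_crit, tested, significant
    alpha: float
    mse: float
    df_within: int

    def significant_pairs(self) -> set[frozenset]:
        sig = self.pairwise[self.pairwise["significant"]]
        return {frozenset((a, b)) for a, b in zip(sig["group_a"], sig["group_b"])}


def _as_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for g in out:
        if len(g) < 2:
            raise ValueError("every group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups contain non-finite values")
    return out


def anova_oneway(groups: Sequence[np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA."""
    gs = _as_groups(groups)
    alldata = np.concatenate(gs)
    if np.ptp(alldata) == 0:
        raise ValueError("all observations identical: F undefined")
    grand = alldata.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_between = len(gs) - 1
    df_within = len(alldata) - len(gs)
    if ss_within == 0:
        raise ValueError("zero within-group variance: F undefined")
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sp_stats.f.sf(F, df_between, df_within))
    return AnovaResult(F=float(F), df_between=df_between, df_within=df_within, p=p)


@lru_cache(maxsize=1024)
def studentized_range_quantile(alpha: float, k: int, df: int) -> float:
    """Upper-alpha critical value q of the studentized range for ``k``
    means and ``df`` error degrees of freedom."""
    if k < 2 or df < 1:
        raise ValueError("need k >= 2 and df >= 1")
    return float(sp_stats.studentized_range.ppf(1.0 - alpha, k, df))


def snk_posthoc(
    groups: Sequence[np.ndarray],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> SnkResult:
    """Student-Newman-Keuls stepwise multiple comparison of group means."""
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"group_{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("labels must match the number of groups")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")

    k = len(gs)
    ns = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    df_within = int(ns.sum() - k)
    mse = float(sum(((g - g.mean()) ** 2).sum() for g in gs) / df_within)
    if mse <= 0:
        raise ValueError("zero pooled variance: SNK undefined")

    order = np.argsort(means)  # ascending
    om, on = means[order], ns[order]
    olab = [labels[i] for i in order]

    # tested[i][j]: None = untested, bool = decision; indices in ascending order
    decision: dict[tuple[int, int], tuple[float, float, bool, bool]] = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            # stepwise gate: every enclosing range must have been found
            # significant, otherwise this one is declared NS untested
            blocked = any(
                not dec[3]
                for (a, b), dec in decision.items()
                if a <= i and b >= j and (a, b) != (i, j)
            )
            se = np.sqrt(mse / 2.0 * (1.0 / on[i] + 1.0 / on[j]))
            q_obs = float((om[j] - om[i]) / se)
            q_crit = studentized_range_quantile(alpha, span, df_within)
            if blocked:
                decision[(i, j)] = (q_obs, q_crit, False, False)
            else:
                decision[(i, j)] = (q_obs, q_crit, True, q_obs > q_crit)

    rows = []
    for (i, j), (q_obs, q_crit, tested, sig) in sorted(
        decision.items(), key=lambda kv: (-(kv[0][1] - kv[0][0]), kv[0][0])
    ):
        rows.append(
            {
                "group_a": olab[j],  # larger mean first
                "group_b": olab[i],
                "span": j - i + 1,
                "q": q_obs,
                "q_crit": q_crit,
                "tested": tested,
                "significant": bool(sig),
            }
        )
    desc = np.argsort(-means)
    group_means = pd.DataFrame(
        {
            "group": [labels[i] for i in desc],
            "mean": means[desc],
            "n": ns[desc],
        }
    )
    return SnkResult(
        group_means=group_means,
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
        mse=mse,
        df_within=df_within,
    )


def sem(values: np.ndarray) -> float:
    """Standard error of the mean (sample SD over sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("SEM needs n >= 2")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def summarize(
    wells: pd.DataFrame,
    control_condition: str,
    reference_condition: str | None = None,
    expected_conditions: Sequence[str] | None = None,
    alpha: float = 0.05,
    normalize: bool = True,
) -> dict:
    """Condition-level report: mean +- SEM per assay, values normalized to
    control = 100, and SNK significance annotations.

    Annotations follow figure-caption conventions: ``*``/``**`` mark
    p < 0.05 / p < 0.01 against the control condition and ``#``/``##``
    against ``reference_condition`` when one is given. SNK yields a
    decision rather than an exact p, so the one-star/two-star grade is
    taken from re-testing the pair's range at alpha and alpha/5.
    """
    from .plates import normalize_to_control

    needed = {"condition", "assay", "value"}
    if not needed <= set(wells.columns):
        raise ValueError(f"well table lacks columns {sorted(needed - set(wells.columns))}")
    if expected_conditions is not None:
        bad = wells.loc[~wells["condition"].isin(expected_conditions)]
        if not bad.empty:
            unmatched = sorted(bad["well"].astype(str).unique()) if "well" in bad else []
            raise ValueError(
                "unrecognised condition labels "
                f"{sorted(bad['condition'].unique())} (wells {unmatched})"
            )
    if control_condition not in set(wells["condition"]):
        raise ValueError(f"control condition {control_condition!r} not present")

    table = (
        normalize_to_control(wells, control_condition) if normalize else wells.copy()
    )
    report: dict = {"control_condition": control_condition, "alpha": alpha, "assays": {}}
    for assay, sub in table.groupby("assay"):
        conditions = list(dict.fromkeys(sub["condition"]))
        groups = [sub.loc[sub["condition"] == c, "value"].to_numpy() for c in conditions]
        entry: dict = {"conditions": {}}
        for c, g in zip(conditions, groups):
            entry["conditions"][c] = {
                "mean": float(np.mean(g)),
                "sem": sem(g) if len(g) > 1 else 0.0,
                "n": int(len(g)),
            }
        if len(conditions) >= 2 and all(len(g) >= 2 for g in groups):
            try:
                anova = anova_oneway(groups)
            except ValueError:
                anova = None
            if anova is not None:
                entry["anova"] = {
                    "F": anova.F,
                    "p": anova.p,
                    "df": [anova.df_between, anova.df_within],
                }
                snk05 = snk_posthoc(groups, alpha=alpha, labels=conditions)
                snk01 = snk_posthoc(groups, alpha=alpha / 5.0, labels=conditions)
                for c in conditions:
                    marks = ""
                    if c != control_condition:
                        pair = frozenset((c, control_condition))
                        if pair in snk01.significant_pairs():
                            marks += "**"
                        elif pair in snk05.significant_pairs():
                            marks += "*"
                    if reference_condition and c not in (
                        reference_condition,
                        control_condition,
                    ):
                        pair = frozenset((c, reference_condition))
                        if pair in snk01.significant_pairs():
                            marks += "##"
                        elif pair in snk05.significant_pairs():
                            marks += "#"
                    entry["conditions"][c]["annotation"] = marks
        report["assays"][assay] = entry
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a summarize() report into a tidy DataFrame."""
    rows = []
    for assay, entry in report["assays"].items():
        for cond, stats in entry["conditions"].items():
            rows.append(
                {
                    "assay": assay,
                    "condition": cond,
                    "mean": stats["mean"],
                    "sem": stats["sem"],
                    "n": stats["n"],
                    "annotation": stats.get("annotation", ""),
                }
            )
    return pd.DataFrame(rows)
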