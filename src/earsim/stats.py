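"""Statistical comparison battery: Shapiro–Wilk normality gate, then either
the parametric (ANOVA + pairwise t-tests) or the nonparametric branch
(Kruskal–Wallis + pairwise Mann–Whitney U), alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats


@dataclass
class StatReport:
    groups: list[str]
    normal: dict[str, bool]
    parametric: bool
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise_test: str
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (stat, p)
    medians: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def median_order(self) -> list[str]:
        return sorted(self.medians, key=self.medians.get, reverse=True)


def compare_stage_scores(
    groups: dict[str, np.ndarray], alpha: float = 0.05, min_n: int = 3
) -> StatReport:
    """Compare score groups (e.g. JSD-FSI by stage, or kappa by source).

    Every group must pass Shapiro–Wilk for the parametric branch to be
    taken; exactly one branch runs.  Groups smaller than ``min_n`` are
    skipped with a record.
    """
    usable = {}
    skipped = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_n:
            skipped.append(name)
        else:
            usable[name] = vals
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough values")

    normal = {}
    for name, vals in usable.items():
        if np.ptp(vals) == 0:  # Shapiro undefined on constant data
            normal[name] = False
        else:
            normal[name] = stats.shapiro(vals).pvalue > alpha
    parametric = all(normal.values())

    names = list(usable)
    samples = [usable[n] for n in names]
    if parametric:
        omnibus = stats.f_oneway(*samples)
        omnibus_name = "ANOVA"
        pairwise_name = "t-test"
    else:
        omnibus = stats.kruskal(*samples)
        omnibus_name = "Kruskal-Wallis"
        pairwise_name = "Mann-Whitney U"

    pairwise = {}
    for a, b in combinations(names, 2):
        if parametric:
            res = stats.ttest_ind(usable[a], usable[b])
        else:
            res = stats.mannwhitneyu(usable[a], usable[b], alternative="two-sided")
        pairwise[(a, b)] = (float(res.statistic), float(res.pvalue))

    return StatReport(
        groups=names,
        normal=normal,
        parametric=parametric,
        omnibus_test=omnibus_name,
        omnibus_stat=float(omnibus.statistic),
        omnibus_p=float(omnibus.pvalue),
        pairwise_test=pairwise_name,
        pairwise=pairwise,
        medians={n: float(np.median(usable[n])) for n in names},
        skipped=skipped,
    )


def stat_report_to_dict(rep: StatReport) -> dict:
    return {
        "groups": rep.groups,
        "normal": rep.normal,
        "parametric": rep.parametric,
        "omnibus_test": rep.omnibus_test,
        "omnibus_stat": rep.omnibus_stat,
        "omnibus_p": rep.omnibus_p,
        "pairwise_test": rep.pairwise_test,
        "pairwise": {f"{a} vs {b}": {"stat": s, "p": p} for (a, b), (s, p) in rep.pairwise.items()},
        "medians": rep.medians,
        "skipped": rep.skipped,
    }
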