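"""Gated univariate group comparisons for process quantities.

Titers, integrals of viable cell density, cell-specific rates and glycan
indices are compared across feeding strategies with the conventional
assumption gate: Shapiro-Wilk on the ANOVA residuals for normality and
Levene's test for variance homogeneity. When both pass at the gate alpha,
a one-way ANOVA with Tukey's HSD post-hoc is used; otherwise the
non-parametric Kruskal-Wallis test followed by Dunn's post-hoc with
multiple-comparison correction. Pairwise adjusted p-values get the usual
significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import assign_stars

__all__ = ["GroupComparisonResult", "compare_groups", "dunn_test"]


@dataclass
class GroupComparisonResult:
    shapiro_p: float
    levene_p: float
    branch: Literal["parametric", "nonparametric"]
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, estimate, p, adj_p, stars


def dunn_test(
    values: np.ndarray,
    groups: np.ndarray,
    p_adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Dunn's rank-based post-hoc test after Kruskal-Wallis.

    Pairwise z statistics on mean ranks with the standard tie correction::

        z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b))

    where ``T = sum(t^3 - t)`` over tie groups. Two-sided p-values are
    corrected with the requested ``statsmodels`` multipletests method.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    labels = np.unique(groups)
    rows = []
    for a, b in combinations(labels, 2):
        ma, mb = groups == a, groups == b
        diff = ranks[ma].mean() - ranks[mb].mean()
        se = np.sqrt(var_base * (1.0 / ma.sum() + 1.0 / mb.sum()))
        z = diff / se
        rows.append({"group_a": a, "group_b": b, "estimate": diff, "z": z,
                     "p": 2.0 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method=p_adjust)[1]
    return out


def compare_groups(
    values: Sequence[float],
    groups: Sequence,
    alpha_gate: float = 0.05,
    *,
    reference: str | None = None,
    dunn_adjust: str = "fdr_bh",
) -> GroupComparisonResult:
    """Compare a process quantity across groups with the assumption gate.

    Shapiro-Wilk is run on the pooled ANOVA residuals (group-mean-centered
    values) and Levene's test on the raw groups; both must pass at
    ``alpha_gate`` for the parametric branch (one-way ANOVA + Tukey HSD),
    else the Kruskal-Wallis + Dunn branch is taken. When ``reference`` is
    given only pairs involving that group are kept (comparisons against the
    standard strategy); otherwise all pairs are reported.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups length mismatch")
    labels = list(np.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lab] for lab in labels]
    small = [lab for lab, s in zip(labels, samples) if len(s) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    if reference is not None and reference not in labels:
        raise ValueError(f"reference group {reference!r} not among {labels}")

    resid = np.concatenate([s - s.mean() for s in samples])
    shapiro_p = float(stats.shapiro(resid).pvalue)
    levene_p = float(stats.levene(*samples).pvalue)

    if shapiro_p >= alpha_gate and levene_p >= alpha_gate:
        branch = "parametric"
        F, p = stats.f_oneway(*samples)
        hsd = stats.tukey_hsd(*samples)
        rows = []
        for i, j in combinations(range(len(labels)), 2):
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "estimate": samples[i].mean() - samples[j].mean(),
                "p": float(hsd.pvalue[i, j]), "adj_p": float(hsd.pvalue[i, j]),
            })
        pairwise = pd.DataFrame(rows)
        omnibus, omnibus_p = float(F), float(p)
    else:
        branch = "nonparametric"
        H, p = stats.kruskal(*samples)
        pairwise = dunn_test(values, groups, p_adjust=dunn_adjust)[
            ["group_a", "group_b", "estimate", "p", "adj_p"]
        ]
        omnibus, omnibus_p = float(H), float(p)

    if reference is not None:
        keep = (pairwise["group_a"] == reference) | (pairwise["group_b"] == reference)
        pairwise = pairwise.loc[keep].reset_index(drop=True)
    pairwise["stars"] = [assign_stars(p) for p in pairwise["adj_p"]]
    return GroupComparisonResult(
        shapiro_p=shapiro_p, levene_p=levene_p, branch=branch,
        omnibus_statistic=omnibus, omnibus_p=omnibus_p, pairwise=pairwise,
    )
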