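"""Stage-wise comparison of cell-shape descriptors.

Developmental stages are compared non-parametrically: a Kruskal–Wallis
one-way ANOVA on ranks across all stages, followed by Dunn's all-pairs
post hoc test with the standard tie correction.  Both unadjusted and
Bonferroni-adjusted p-values are reported, with significance flagged at
the chosen alpha.  The chi-square approximation for the Kruskal–Wallis
p-value is used throughout; group sizes of at least 5 are advisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparisonResult:
    H: float
    df: int
    p_value: float
    pairwise: pd.DataFrame  # group_i, group_j, z, p_unadjusted, p_bonferroni, significant


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("every group needs at least 1 observation")
    if sum(len(g) for g in gs) < 3:
        raise ValueError("need at least 3 observations in total")
    return gs


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (df = g − 1).

    All observations identical across groups is a defined degenerate case:
    H = 0, p = 1.
    """
    gs = _check_groups(groups)
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*gs)
    return float(h), df, float(p)


def dunn_posthoc(groups, alpha: float = 0.05, labels=None) -> pd.DataFrame:
    """Dunn's all-pairs rank comparison with tie correction.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)(1/n_i + 1/n_j)] with the
    tie term T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values, plus
    a Bonferroni-adjusted column and a significance flag at ``alpha``
    (applied to the adjusted p).  A zero variance (all pooled values tied)
    yields z = 0, p = 1.
    """
    gs = _check_groups(groups)
    g = len(gs)
    if labels is None:
        labels = list(range(g))
    n = np.array([len(x) for x in gs])
    N = int(n.sum())
    pooled = np.concatenate(gs)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for ni in n:
        mean_ranks.append(ranks[start : start + ni].mean())
        start += ni

    _, counts = np.unique(pooled, return_counts=True)
    T = float(((counts**3 - counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - T

    m = g * (g - 1) // 2
    rows = []
    for i, j in combinations(range(g), 2):
        se2 = base_var * (1.0 / n[i] + 1.0 / n[j])
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        p = 2.0 * stats.norm.sf(abs(z))
        p_bonf = min(1.0, p * m)
        rows.append(
            {
                "group_i": labels[i],
                "group_j": labels[j],
                "z": float(z),
                "p_unadjusted": float(p),
                "p_bonferroni": float(p_bonf),
                "significant": bool(p_bonf < alpha),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(groups, alpha: float = 0.05, labels=None) -> GroupComparisonResult:
    """Kruskal–Wallis omnibus test plus Dunn's all-pairs post hoc."""
    h, df, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, alpha=alpha, labels=labels)
    return GroupComparisonResult(H=h, df=df, p_value=p, pairwise=pairwise)


def summarize_stages(
    records: pd.DataFrame,
    group_col: str = "stage",
    descriptors=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stage descriptor summaries plus all-pairs Dunn flags.

    For each stage and descriptor: n, mean, sd, median, quartiles, and the
    1.5·IQR whisker bounds used in the box plots.  With at least two
    stages, a Dunn pairwise table per descriptor is returned as well
    (empty otherwise).
    """
    if group_col not in records.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if descriptors is None:
        descriptors = [
            c
            for c in records.columns
            if c != group_col and np.issubdtype(records[c].dtype, np.number)
        ]
    stages = sorted(records[group_col].unique())
    summary_rows = []
    pairwise_frames = []
    for desc in descriptors:
        groups = [records.loc[records[group_col] == s, desc].dropna().to_numpy() for s in stages]
        for s, vals in zip(stages, groups):
            if len(vals) == 0:
                continue
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            iqr = q75 - q25
            summary_rows.append(
                {
                    "descriptor": desc,
                    group_col: s,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "median": float(med),
                    "q25": float(q25),
                    "q75": float(q75),
                    "whisker_low": float(q25 - 1.5 * iqr),
                    "whisker_high": float(q75 + 1.5 * iqr),
                }
            )
        if len(stages) >= 2 and all(len(v) >= 1 for v in groups) and sum(map(len, groups)) >= 3:
            pw = dunn_posthoc(groups, alpha=alpha, labels=stages)
            pw.insert(0, "descriptor", desc)
            pairwise_frames.append(pw)
    summary = pd.DataFrame(summary_rows)
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(
            columns=[
                "descriptor", "group_i", "group_j", "z",
                "p_unadjusted", "p_bonferroni", "significant",
            ]
        )
    )
    return summary, pairwise
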