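"""Group comparison of DEP-derived cell parameters.

One-way ANOVA (classical between/within sums-of-squares decomposition)
followed by Tukey's honest-significant-difference test for all pairwise
comparisons, with the usual star annotation: ``*``, ``**``, ``***`` for
p < 0.05, 0.01, 0.001 (strict inequalities) and ``ns`` otherwise.
Unequal group sizes are handled by the Tukey–Kramer form (as implemented
by :func:`scipy.stats.tukey_hsd`).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateInputError, DomainError

GroupTable = dict[str, np.ndarray]


def _validate(t: GroupTable) -> dict[str, np.ndarray]:
    if len(t) < 2:
        raise DomainError("need at least 2 groups")
    out = {}
    for label, values in t.items():
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise DomainError(f"group {label!r} needs at least 2 values")
        if not np.all(np.isfinite(v)):
            raise DomainError(f"group {label!r} contains non-finite values")
        out[str(label)] = v
    return out


def one_way_anova(t: GroupTable) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p).

    F = (SS_between/df_between) / (SS_within/df_within).  If every group
    has zero internal variance and all means are equal the decomposition
    is degenerate and an error is raised; zero within-variance with
    unequal means yields F = inf, p = 0.
    """
    groups = _validate(t)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise DegenerateInputError("all values identical: ANOVA undefined")
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def star_label(p: float) -> str:
    """Significance stars: p<0.001 -> ***, p<0.01 -> **, p<0.05 -> *, else ns."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey HSD pairwise comparison."""

    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    stars: str


def tukey_hsd(t: GroupTable) -> list[PairwiseResult]:
    """All pairwise Tukey HSD comparisons, in input group order (a before b).

    Adjusted p-values come from the studentized range distribution;
    ``mean_diff`` is mean(a) - mean(b).
    """
    groups = _validate(t)
    labels = list(groups.keys())
    values = [groups[k] for k in labels]
    if all(float(np.sum((v - v.mean()) ** 2)) == 0.0 for v in values):
        means = [v.mean() for v in values]
        if len(set(means)) == 1:
            raise DegenerateInputError("all values identical: Tukey HSD undefined")
    res = sps.tukey_hsd(*values)
    out = []
    for i, j in combinations(range(len(labels)), 2):
        p = float(min(1.0, res.pvalue[i, j]))
        out.append(
            PairwiseResult(
                group_a=labels[i],
                group_b=labels[j],
                mean_diff=float(values[i].mean() - values[j].mean()),
                p_adj=p,
                stars=star_label(p),
            )
        )
    return out


def compare_groups(table: GroupTable, parameter: str = "") -> pd.DataFrame:
    """ANOVA + Tukey HSD in one long-format table (one row per pair)."""
    f_stat, p_anova = one_way_anova(table)
    rows = [
        {
            "parameter": parameter,
            "group_a": r.group_a,
            "group_b": r.group_b,
            "mean_diff": r.mean_diff,
            "p_adj": r.p_adj,
            "stars": r.stars,
            "anova_F": f_stat,
            "anova_p": p_anova,
        }
        for r in tukey_hsd(table)
    ]
    return pd.DataFrame(rows)


def compare_fit_parameters(
    fits: pd.DataFrame,
    parameters: tuple[str, ...] = (
        "mem_rel_permittivity",
        "mem_conductivity_S_per_m",
        "int_conductivity_S_per_m",
        "co_first_hz",
        "co_second_hz",
    ),
) -> pd.DataFrame:
    """Per-parameter group comparisons from a fits table (rejected rows excluded).

    Each parameter is its own comparison family, mirroring per-panel
    annotation practice; parameters with fewer than 2 usable groups are
    skipped.
    """
    usable = fits[~fits["rejected"].astype(bool)]
    frames = []
    for param in parameters:
        if param not in usable.columns:
            continue
        table = {
            str(g): sub[param].dropna().to_numpy()
            for g, sub in usable.groupby("group", sort=False)
            if sub[param].dropna().size >= 2
        }
        if len(table) < 2:
            continue
        try:
            frames.append(compare_groups(table, parameter=param))
        except DegenerateInputError:
            continue
    if not frames:
        return pd.DataFrame(
            columns=["parameter", "group_a", "group_b", "mean_diff", "p_adj", "stars", "anova_F", "anova_p"]
        )
    return pd.concat(frames, ignore_index=True)
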