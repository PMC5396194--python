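"""One-way ANOVA and Scheffe post hoc contrasts for synergist bioassays.

Synergist experiments challenge a resistant strain at a fixed LC50 dose with
and without enzyme inhibitors (PBO, DEM, TPP); each replicate jar or vial
contributes one mortality proportion.  Groups are compared by the classical
between/within sum-of-squares decomposition, and pairwise differences are
judged against the Scheffe bound

    sqrt((k - 1) * F_{alpha; k-1, N-k}) * sqrt(MSW * (1/n_i + 1/n_j)),

which controls the family-wise error over all contrasts.  Both procedures are
implemented directly from the sums of squares (no wrapper around a stats
package) so they can serve as an explicit, auditable reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaResult",
    "Contrast",
    "SynergismReport",
    "one_way_anova",
    "scheffe_posthoc",
    "synergism_report",
]


@dataclass(frozen=True)
class Contrast:
    group_a: str
    group_b: str
    difference: float
    bound: float
    significant: bool


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float
    group_means: dict
    group_ns: dict
    scheffe_contrasts: list = field(default_factory=list)


def _validate_groups(groups):
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates, got {arr.size}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {name!r} contains non-finite values")
        out[str(name)] = arr
    return out


def one_way_anova(groups) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    ``groups`` maps group name to replicate observations.  Returns the F
    statistic, degrees of freedom and p-value; Scheffe contrasts are filled in
    by :func:`scheffe_posthoc`.
    """
    g = _validate_groups(groups)
    k = len(g)
    all_values = np.concatenate(list(g.values()))
    n_total = all_values.size
    grand = all_values.mean()
    means = {name: arr.mean() for name, arr in g.items()}
    ns = {name: arr.size for name, arr in g.items()}
    ss_between = sum(ns[name] * (means[name] - grand) ** 2 for name in g)
    ss_within = sum(float(np.sum((arr - means[name]) ** 2)) for name, arr in g.items())
    df_between = k - 1
    df_within = n_total - k
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else np.inf
    else:
        f_stat = ms_between / ms_within
    p_value = float(stats.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p_value,
        ms_within=float(ms_within),
        group_means=means,
        group_ns=ns,
    )


def scheffe_posthoc(groups, alpha: float = 0.05) -> AnovaResult:
    """All pairwise Scheffe contrasts at family-wise level alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    result = one_way_anova(groups)
    k = result.df_between + 1
    f_crit = stats.f.ppf(1.0 - alpha, result.df_between, result.df_within)
    names = list(result.group_means)
    contrasts = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diff = result.group_means[a] - result.group_means[b]
            bound = np.sqrt(
                (k - 1)
                * f_crit
                * result.ms_within
                * (1.0 / result.group_ns[a] + 1.0 / result.group_ns[b])
            )
            contrasts.append(
                Contrast(a, b, float(diff), float(bound), bool(abs(diff) > bound))
            )
    result.scheffe_contrasts = contrasts
    return result


@dataclass
class SynergismReport:
    anova: AnovaResult
    reference: str
    table: pd.DataFrame


def synergism_report(groups, reference: str, alpha: float = 0.05) -> SynergismReport:
    """Flag synergists whose mortality differs from the unsynergized reference.

    Each non-reference group is compared to ``reference`` with its Scheffe
    contrast; ``direction`` is "increase" when the synergist raised mortality
    significantly, "decrease" when it lowered it, "none" otherwise.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not among groups {list(groups)}")
    for name, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError(f"group {name!r}: mortality proportions must lie in [0, 1]")
    result = scheffe_posthoc(groups, alpha=alpha)
    rows = []
    for contrast in result.scheffe_contrasts:
        if reference not in (contrast.group_a, contrast.group_b):
            continue
        other = contrast.group_b if contrast.group_a == reference else contrast.group_a
        diff = result.group_means[other] - result.group_means[reference]
        direction = "none"
        if contrast.significant:
            direction = "increase" if diff > 0 else "decrease"
        rows.append(
            {
                "synergist": other,
                "mean_difference": float(diff),
                "scheffe_bound": contrast.bound,
                "significant": contrast.significant,
                "direction": direction,
            }
        )
    table = pd.DataFrame(rows).set_index("synergist")
    return SynergismReport(anova=result, reference=reference, table=table)
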