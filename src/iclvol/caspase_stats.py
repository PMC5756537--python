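"""Caspase-3/7 luminescence plates: synthetic generation, fold changes vs the
control group, and many-to-one comparisons.

Luminescent caspase readouts are positive with roughly multiplicative noise,
so wells are generated lognormally around group geometric means expressed as
fold changes relative to control.  Analysis normalizes every well to the
control-group mean of its own plate, then compares groups against control
with the shared Monte-Carlo Dunnett procedure; the 2-week vs 4-week contrast
is reported as a planned comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import mean_ci, mc_dunnett

__all__ = [
    "GROUPS",
    "GroupSummary",
    "generate_plate",
    "fold_change",
    "compare_groups",
]

#: Canonical group labels of the assay design.
GROUPS = ("control", "aclt2w", "aclt4w", "tnfa", "dcpib", "tnfa_dcpib")


def generate_plate(
    folds: dict[str, float],
    n_per_group: int | dict[str, int] = 20,
    cv: float = 0.06,
    baseline_lum: float = 10_000.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Synthetic plate: lognormal luminescence per well.

    ``folds`` maps group label -> geometric-mean fold vs control (the control
    entry should be 1).  ``cv`` is the per-well coefficient of variation.
    Returns a tidy frame (group, replicate, luminescence).
    """
    if "control" not in folds:
        raise ValueError("plate config must include a control group")
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be positive")
    ns = (
        {g: n_per_group for g in folds}
        if isinstance(n_per_group, int)
        else dict(n_per_group)
    )
    if any(ns[g] < 2 for g in folds):
        raise ValueError("need at least two replicates per group")
    sigma = math.sqrt(math.log(1.0 + cv**2))
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in folds.items():
        lum = baseline_lum * fold * np.exp(sigma * rng.standard_normal(ns[group]))
        rows += [
            {"group": group, "replicate": r, "luminescence": float(v)}
            for r, v in enumerate(lum)
        ]
    return pd.DataFrame(rows)


def fold_change(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well fold change: luminescence divided by the control-group mean.

    Normalization is per plate, so a common scale factor (gain, reagent lot)
    cancels exactly.
    """
    if "control" not in set(plate["group"]):
        raise ValueError("plate has no control group to normalize against")
    if (plate["luminescence"] <= 0).any():
        raise ValueError("luminescence readings must be positive")
    ctrl_mean = plate.loc[plate["group"] == "control", "luminescence"].mean()
    out = plate.copy()
    out["fold"] = out["luminescence"] / ctrl_mean
    return out


@dataclass
class GroupSummary:
    """Fold-change summary of one group with its comparison against control."""

    group: str
    mean_fold: float
    ci_low: float
    ci_high: float
    n: int
    p_raw: float
    p_adjusted: float


def compare_groups(
    folds: pd.DataFrame,
    n_draws: int = 100_000,
    seed: int | None = 0,
) -> tuple[list[GroupSummary], float]:
    """Group summaries plus the planned 2-week vs 4-week contrast p-value.

    Each non-control group is compared against control with the Monte-Carlo
    Dunnett procedure (family-wise adjusted p).  Because a fold is a ratio of
    the group mean to the control mean, its 95 % CI propagates the control
    mean's own uncertainty via the delta method; the control group's CI simply
    reflects the spread of its wells around 1.  The planned aclt2w-vs-aclt4w
    contrast is a two-sided t test.  A group whose replicates are identical
    (zero variance with n > 1) is rejected as a degenerate input.
    """
    groups = list(dict.fromkeys(folds["group"]))
    if "control" not in groups or len(groups) < 2:
        raise ValueError("need a control group and at least one other group")
    values = {g: folds.loc[folds["group"] == g, "fold"].to_numpy() for g in groups}
    for g, v in values.items():
        if v.size > 1 and float(np.var(v)) == 0.0:
            raise ValueError(f"group {g!r} has zero variance across replicates")
    treatment_names = [g for g in groups if g != "control"]
    res = mc_dunnett(
        [values[g] for g in treatment_names],
        values["control"],
        n_draws=n_draws,
        seed=seed,
    )
    summaries = []
    ctrl = values["control"]
    m, lo, hi = mean_ci(ctrl)
    summaries.append(GroupSummary("control", m, lo, hi, ctrl.size, np.nan, np.nan))
    cv_ctrl = float(np.std(ctrl, ddof=1) / np.mean(ctrl))
    for g, praw, padj in zip(treatment_names, res.raw_pvalues, res.pvalues):
        v = values[g]
        f = float(np.mean(v))
        cv_g = float(np.std(v, ddof=1) / np.mean(v))
        se = f * np.sqrt(cv_g**2 / v.size + cv_ctrl**2 / ctrl.size)
        tcrit = float(sps.t.ppf(0.975, v.size + ctrl.size - 2))
        summaries.append(
            GroupSummary(g, f, f - tcrit * se, f + tcrit * se, v.size,
                         float(praw), float(padj))
        )

    p_2w_vs_4w = float("nan")
    if "aclt2w" in values and "aclt4w" in values:
        a, b = values["aclt2w"], values["aclt4w"]
        t, p_2w_vs_4w = sps.ttest_ind(a, b)
        p_2w_vs_4w = float(p_2w_vs_4w)
    return summaries, p_2w_vs_4w
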