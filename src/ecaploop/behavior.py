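"""Behavioral endpoints and their statistical comparisons.

Endpoints: the graded von Frey withdrawal threshold (first filament force
with >= 3/5 withdrawals, 26 g cutoff, reported on a Weber-law log10 scale
after x10,000) and the acetone withdrawal latency. Comparisons: a two-way
(group x timepoint) ANOVA with planned Welch post-hoc t-tests under
Bonferroni correction, and windowed trapezoidal AUC with a one-way ANOVA
across groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .exceptions import DesignError
from .synth import GROUPS, TIMEPOINT_MINUTES, VON_FREY_CUTOFF_G

__all__ = ["VON_FREY_FORCES_G", "withdrawal_threshold", "log_transform",
           "inverse_log_transform", "AnovaResult", "anova_timegroup",
           "auc", "AUCResult", "auc_anova", "DEFAULT_CONTRASTS",
           "DEFAULT_AUC_PAIRS"]

#: graded filament bending forces, ascending, in grams
VON_FREY_FORCES_G = (0.07, 0.16, 0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0,
                     10.0, 15.0, 26.0)

#: planned (group A, group B, timepoint) contrasts: injury confirmation at
#: BS2 and the stimulation rescue at 15/30 min
DEFAULT_CONTRASTS = (
    ("sham", "SNI", "BS2"),
    ("sham SCS-OFF", "SNI SCS-OFF", "BS2"),
    ("sham SCS-ON", "SNI SCS-ON", "BS2"),
    ("SNI SCS-ON", "SNI", "15"),
    ("SNI SCS-ON", "SNI", "30"),
    ("SNI SCS-ON", "SNI SCS-OFF", "15"),
    ("SNI SCS-ON", "SNI SCS-OFF", "30"),
)

DEFAULT_AUC_PAIRS = (("SNI SCS-ON", "SNI"), ("SNI SCS-ON", "SNI SCS-OFF"))


def withdrawal_threshold(responses: Sequence[int],
                         forces_g: Sequence[float] = VON_FREY_FORCES_G) -> float:
    """Mechanical withdrawal threshold from per-filament withdrawal counts.

    ``responses[i]`` is the number of withdrawals out of 5 applications of
    ``forces_g[i]`` (ascending). The threshold is the force of the first
    filament reaching >= 3/5; the 26 g cutoff is returned if none qualifies.
    """
    forces = np.asarray(forces_g, dtype=float)
    counts = np.asarray(responses)
    if counts.shape != forces.shape or counts.ndim != 1:
        raise ValueError("one response count per filament required")
    if np.any((counts < 0) | (counts > 5) | (counts != counts.astype(int))):
        raise ValueError("withdrawal counts must be integers in 0..5")
    if np.any(np.diff(forces) <= 0):
        raise ValueError("filament forces must be strictly ascending")
    hits = np.nonzero(counts >= 3)[0]
    return float(forces[hits[0]]) if hits.size else VON_FREY_CUTOFF_G


def log_transform(threshold_g: float):
    """Weber-law scale: log10(threshold x 10,000)."""
    t = np.asarray(threshold_g, dtype=float)
    if np.any(t <= 0):
        raise ValueError("threshold must be positive")
    out = np.log10(t * 10_000.0)
    return float(out) if np.isscalar(threshold_g) else out


def inverse_log_transform(log_units: float):
    """Inverse of :func:`log_transform`: grams from log10 units."""
    out = 10.0 ** np.asarray(log_units, dtype=float) / 10_000.0
    return float(out) if np.isscalar(log_units) else out


# ---------------------------------------------------------------------------
# omnibus + post-hoc statistics
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_interaction: float
    df_interaction: float
    df_residual: float
    p_interaction: float
    posthoc: pd.DataFrame  # group_a, group_b, timepoint, t, df, p_raw, p_bonferroni


def _check_cells(table: pd.DataFrame, endpoint: str, min_n: int = 2) -> None:
    counts = table.groupby(["group", "timepoint"], observed=True)[endpoint].count()
    if counts.empty or (counts < min_n).any():
        raise DesignError(f"every group x timepoint cell needs >= {min_n} observations")


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df, two-sided p."""
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def anova_timegroup(table: pd.DataFrame, endpoint: str = "vf_log_threshold",
                    contrasts: Sequence[tuple[str, str, str]] = DEFAULT_CONTRASTS,
                    ) -> AnovaResult:
    """Two-way (group x timepoint) ANOVA with planned Welch post-hoc tests.

    Returns the omnibus interaction statistic and the planned group-pair
    contrasts at their timepoints, Bonferroni-corrected over the contrast
    family. Welch (unequal-variance) t-tests are used throughout.
    """
    _check_cells(table, endpoint)
    data = table[["group", "timepoint", endpoint]].rename(columns={endpoint: "value"})
    model = ols("value ~ C(group) * C(timepoint)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    inter = aov.loc["C(group):C(timepoint)"]

    rows = []
    m = len(contrasts)
    for ga, gb, tp in contrasts:
        a = data.loc[(data.group == ga) & (data.timepoint == tp), "value"].to_numpy()
        b = data.loc[(data.group == gb) & (data.timepoint == tp), "value"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise DesignError(f"contrast ({ga} vs {gb} @ {tp}) has an empty/singleton cell")
        t, df, p = _welch(a, b)
        rows.append((ga, gb, tp, t, df, p, min(1.0, p * m)))

    return AnovaResult(
        f_interaction=float(inter["F"]),
        df_interaction=float(inter["df"]),
        df_residual=float(aov.loc["Residual", "df"]),
        p_interaction=float(inter["PR(>F)"]),
        posthoc=pd.DataFrame(rows, columns=["group_a", "group_b", "timepoint",
                                            "t", "df", "p_raw", "p_bonferroni"]),
    )


# ---------------------------------------------------------------------------
# area under the curve
# ---------------------------------------------------------------------------

def auc(times_min: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under an endpoint time course."""
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("need matching times and values (>= 2 points)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


@dataclass
class AUCResult:
    window: tuple[float, float]
    f_group: float
    df_between: float
    df_within: float
    p_group: float
    per_animal: pd.DataFrame  # animal_id, group, auc
    posthoc: pd.DataFrame


def auc_anova(table: pd.DataFrame, endpoint: str = "vf_log_threshold",
              window: tuple[float, float] = (0.0, 30.0),
              pairs: Sequence[tuple[str, str]] = DEFAULT_AUC_PAIRS) -> AUCResult:
    """Per-animal windowed AUC, one-way ANOVA across groups, Bonferroni
    Welch post-hocs on the requested group pairs."""
    tps = [tp for tp, minute in TIMEPOINT_MINUTES.items()
           if window[0] <= minute <= window[1]]
    sub = table[table.timepoint.isin(tps)]
    per_animal = []
    for (animal, group), rows in sub.groupby(["animal_id", "group"], observed=True):
        rows = rows.set_index("timepoint")
        missing = [tp for tp in tps if tp not in rows.index]
        if missing:
            raise ValueError(f"animal {animal} is missing timepoints {missing}")
        times = [TIMEPOINT_MINUTES[tp] for tp in tps]
        order = np.argsort(times)
        per_animal.append((animal, group,
                           auc(np.asarray(times)[order],
                               rows.loc[np.asarray(tps)[order], endpoint].to_numpy())))
    df = pd.DataFrame(per_animal, columns=["animal_id", "group", "auc"])
    groups_present = [g for g in GROUPS if g in set(df.group)]
    samples = [df.loc[df.group == g, "auc"].to_numpy() for g in groups_present]
    if len(samples) < 2:
        raise DesignError("need at least two groups for the AUC ANOVA")
    f, p = stats.f_oneway(*samples)

    rows = []
    m = len(pairs)
    for ga, gb in pairs:
        a = df.loc[df.group == ga, "auc"].to_numpy()
        b = df.loc[df.group == gb, "auc"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise DesignError(f"AUC pair ({ga}, {gb}) has an empty/singleton group")
        t, dof, praw = _welch(a, b)
        rows.append((ga, gb, t, dof, praw, min(1.0, praw * m)))

    n_total = sum(s.size for s in samples)
    return AUCResult(
        window=window, f_group=float(f),
        df_between=float(len(samples) - 1), df_within=float(n_total - len(samples)),
        p_group=float(p), per_animal=df,
        posthoc=pd.DataFrame(rows, columns=["group_a", "group_b", "t", "df",
                                            "p_raw", "p_bonferroni"]),
    )
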