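"""Variable construction for the survey pipeline.

Covers the standard cleaning and derived-variable steps applied to the
farmer microdata before index construction and model fitting:

* percentile winsorization of continuous variables (1st/99th by default);
* log transforms (strict, or log1p for zero-bearing counts);
* the high-intensity work flag: hours strictly above the sample mean;
* the leave-one-out village share of high-intensity workers, used as an
  instrument for work intensity (peer effect within village);
* a grouped mean-difference screen with two-sample t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TreatmentFlags",
    "truncate_percentiles",
    "log_transform",
    "binarize_work_intensity",
    "leave_one_out_share",
    "group_mean_difference",
    "significance_stars",
]


@dataclass(frozen=True)
class TreatmentFlags:
    """High-intensity work flags plus the threshold that produced them."""

    flags: pd.Series  # int8, indexed like the input hours
    threshold: float

    @property
    def n_treated(self) -> int:
        return int(self.flags.sum())


def truncate_percentiles(
    values,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    mode: str = "clip",
) -> np.ndarray:
    """Winsorize (default) or trim values at empirical percentiles.

    ``clip`` preserves length: values beyond the [lower, upper]
    percentile bounds are set to the bounds.  ``trim`` drops them
    instead (length may shrink).  Bounds are order statistics (no
    interpolation), which makes clip mode exactly idempotent.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if not 0.0 <= lower_pct < upper_pct <= 100.0:
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    if mode not in ("clip", "trim"):
        raise ValueError("mode must be 'clip' or 'trim'")
    lo = np.percentile(x, lower_pct, method="lower")
    hi = np.percentile(x, upper_pct, method="higher")
    if mode == "clip":
        return np.clip(x, lo, hi)
    return x[(x >= lo) & (x <= hi)]


def log_transform(values, mode: str = "strict") -> np.ndarray:
    """Natural log (strict: requires x > 0) or log1p (shift mode)."""
    x = np.asarray(values, dtype=float)
    if mode == "strict":
        if np.any(x <= 0.0):
            raise ValueError("log_transform in strict mode requires positive values")
        return np.log(x)
    if mode == "shift":
        if np.any(x < 0.0):
            raise ValueError("log1p requires nonnegative values")
        return np.log1p(x)
    raise ValueError("mode must be 'strict' or 'shift'")


def binarize_work_intensity(hours) -> TreatmentFlags:
    """Flag high-intensity work: weekly hours strictly above the sample mean.

    The threshold is the mean of all supplied hours; a farmer exactly at
    the mean counts as low-intensity (the flag requires *exceeding* the
    threshold).  Adding a constant to every farmer's hours leaves the
    flags unchanged.
    """
    h = pd.Series(hours, dtype=float)
    if h.size == 0:
        raise ValueError("empty hours vector")
    if h.isna().any():
        raise ValueError("hours contain missing values")
    if (h < 0).any():
        raise ValueError("hours must be nonnegative")
    threshold = float(h.mean())
    flags = (h > threshold).astype(np.int8)
    return TreatmentFlags(flags=flags, threshold=threshold)


def leave_one_out_share(
    flags,
    village_ids,
    on_singleton: str = "missing",
) -> pd.Series:
    """Share of *other* same-village members flagged as high-intensity.

    For farmer i in a village of size T with N_(-i) flagged co-villagers,
    the instrument is ``N_(-i) / (T - 1)``, guaranteed to lie in [0, 1].
    Singleton villages have no peers: the value is missing (default),
    or the row is dropped, or an error is raised, per ``on_singleton``.
    Invariant to the ordering of farmers within a village.
    """
    if on_singleton not in ("missing", "drop", "error"):
        raise ValueError("on_singleton must be 'missing', 'drop' or 'error'")
    f = pd.Series(flags).astype(float)
    v = pd.Series(village_ids)
    if len(f) != len(v):
        raise ValueError("flags and village_ids differ in length")
    v.index = f.index
    grp = f.groupby(v)
    total = grp.transform("size").astype(float)
    vsum = grp.transform("sum")
    singleton = total < 2
    if singleton.any():
        if on_singleton == "error":
            raise ValueError("singleton village: leave-one-out share undefined")
        warnings.warn(
            f"{int(singleton.sum())} farmer(s) in singleton villages: "
            "leave-one-out share undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        iv = (vsum - f) / (total - 1.0)
    iv = iv.where(~singleton, np.nan).rename("iv")
    if on_singleton == "drop":
        iv = iv.dropna()
    return iv


def significance_stars(p: float) -> str:
    """***, **, * at the 1, 5 and 10 percent levels."""
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def group_mean_difference(
    table: pd.DataFrame,
    columns,
    group,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-variable means by treatment group with two-sample t-tests.

    ``diff`` is oriented as mean(group 0) - mean(group 1), i.e.
    low-intensity minus high-intensity.  The pooled-variance t-test is
    the default; ``equal_var=False`` selects Welch.  Variables with zero
    variance in both groups report the difference with the test
    suppressed.
    """
    g = np.asarray(group).astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in columns:
        x = table[col].to_numpy(dtype=float)
        x0, x1 = x[g == 0], x[g == 1]
        m0, m1 = x0.mean(), x1.mean()
        if x0.std() == 0.0 and x1.std() == 0.0:
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(x0, x1, equal_var=equal_var)
        rows.append(
            {
                "variable": col,
                "mean_low": m0,
                "mean_high": m1,
                "diff": m0 - m1,
                "t_stat": t,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
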