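"""Paired pre-post comparison of per-user measures.

Each active user contributes one averaged value for the 8 weeks before the
intervention and one for the 8 weeks after; the paired differences
(post − pre) feed a paired t test, Cohen's d on the differences
(d = mean / sd, with t = d·√n), and achieved power.

Power uses the two-sided normal approximation

    power = Φ(|d|·√n − z_{1−α/2})

which treats the observed standardized effect as the noncentrality and
ignores the (negligible-at-n≈50) probability mass of rejecting on the
wrong side.  An exact noncentral-t alternative is available via
``method="nct"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from math import sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateVarianceError,
    InsufficientPairsError,
)
from .io import Dataset
from .quality import Grouping, MeasureSeries, assign_window


@dataclass
class PrePostResult:
    """Paired comparison summary for one measure (a Table-4-style row)."""

    measure_name: str
    n_pairs: int
    mean_pre: float
    mean_post: float
    mean_change: float  # post − pre, averaged over users
    t_stat: float
    p_value: float
    cohen_d: float
    power: float
    alpha: float
    n_excluded: int = 0  # users lacking records in one of the windows

    def to_frame(self) -> pd.DataFrame:
        """One-row frame mirroring the study-table columns."""
        return pd.DataFrame(
            [
                {
                    "measure": self.measure_name,
                    "pre": self.mean_pre,
                    "post": self.mean_post,
                    "change": self.mean_change,
                    "t": self.t_stat,
                    "p_value": self.p_value,
                    "power": self.power,
                    "cohen_d": self.cohen_d,
                    "n_pairs": self.n_pairs,
                    "n_excluded": self.n_excluded,
                    "alpha": self.alpha,
                }
            ]
        )


def paired_t(diffs: Sequence[float]) -> tuple[float, float]:
    """Paired t statistic and two-sided p for a vector of differences.

    t = mean / (sd/√n) with the n−1 (sample) standard deviation; p from
    Student's t with n−1 degrees of freedom.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise InsufficientPairsError(f"need at least 2 differences, got {d.size}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError(
            "paired differences have zero variance; t is undefined"
        )
    t = d.mean() / (sd / sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def cohen_d_paired(diffs: Sequence[float]) -> float:
    """Standardized paired difference: mean(diffs)/sd(diffs), sd with n−1."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise InsufficientPairsError(f"need at least 2 differences, got {d.size}")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError(
            "paired differences have zero variance; d is undefined"
        )
    return float(d.mean() / sd)


def power_normal_approx(
    d: float, n: int, alpha: float = 0.05, method: str = "normal"
) -> float:
    """Achieved power of a two-sided paired t test at standardized effect d.

    ``method="normal"`` (default): Φ(|d|·√n − z_{1−α/2}).  At d = 0 this
    equals α/2, the one-sided share of the type-I error.
    ``method="nct"``: exact two-sided power from the noncentral t
    distribution with noncentrality |d|·√n and n−1 degrees of freedom.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    if n < 2:
        raise ConfigurationError(f"n must be >= 2, got {n}")
    nc = abs(d) * sqrt(n)
    if method == "normal":
        return float(stats.norm.cdf(nc - stats.norm.ppf(1.0 - alpha / 2.0)))
    if method == "nct":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
        return float(
            stats.nct.sf(tcrit, df=n - 1, nc=nc)
            + stats.nct.cdf(-tcrit, df=n - 1, nc=nc)
        )
    raise ConfigurationError(f"unknown power method {method!r}")


def _paired_result(
    measure_name: str,
    pre: np.ndarray,
    post: np.ndarray,
    alpha: float,
    n_excluded: int,
    power_method: str,
) -> PrePostResult:
    diffs = post - pre
    t, p = paired_t(diffs)
    d = cohen_d_paired(diffs)
    return PrePostResult(
        measure_name=measure_name,
        n_pairs=int(diffs.size),
        mean_pre=float(pre.mean()),
        mean_post=float(post.mean()),
        mean_change=float(diffs.mean()),
        t_stat=t,
        p_value=p,
        cohen_d=d,
        power=power_normal_approx(d, diffs.size, alpha, method=power_method),
        alpha=alpha,
        n_excluded=n_excluded,
    )


def compare_prepost(
    series: MeasureSeries,
    measure_name: str,
    alpha: float = 0.05,
    power_method: str = "normal",
) -> PrePostResult:
    """Paired pre-post comparison of a quality measure across users.

    ``series`` must use ``by_user_and_window`` grouping.  Users with
    records in only one window are excluded from pairing and counted in
    ``n_excluded``.
    """
    if series.grouping is not Grouping.BY_USER_AND_WINDOW:
        raise ConfigurationError(
            "compare_prepost requires a by_user_and_window MeasureSeries, "
            f"got {series.grouping.value}"
        )
    col = f"pct_{measure_name}"
    if col not in series.table.columns:
        raise ConfigurationError(
            f"unknown measure {measure_name!r}; expected same_day, complete or valid"
        )
    wide = series.table.pivot(index="user_id", columns="window", values=col)
    for w in ("pre", "post"):
        if w not in wide.columns:
            wide[w] = np.nan
    paired = wide.dropna(subset=["pre", "post"])
    n_excluded = len(wide) - len(paired)
    if len(paired) < 2:
        raise InsufficientPairsError(
            f"only {len(paired)} user(s) have records in both windows"
        )
    return _paired_result(
        measure_name,
        paired["pre"].to_numpy(),
        paired["post"].to_numpy(),
        alpha,
        n_excluded,
        power_method,
    )


def compare_volume(
    dataset: Dataset,
    intervention_date: date,
    alpha: float = 0.05,
    power_method: str = "normal",
) -> PrePostResult:
    """Paired pre-post comparison of per-user entry counts.

    Answers "did the intervention change how much data users recorded?" —
    units are entries per user per 8-week window.
    """
    frame = dataset.frame
    window = assign_window(
        pd.Series(frame["appointment_date"].to_numpy()), intervention_date
    )
    work = pd.DataFrame(
        {"user_id": frame["user_id"].to_numpy(), "window": window}
    ).dropna(subset=["window"])
    counts = (
        work.groupby(["user_id", "window"], observed=True)
        .size()
        .unstack("window")
    )
    for w in ("pre", "post"):
        if w not in counts.columns:
            counts[w] = np.nan
    paired = counts.dropna(subset=["pre", "post"])
    n_excluded = len(counts) - len(paired)
    if len(paired) < 2:
        raise InsufficientPairsError(
            f"only {len(paired)} user(s) have entries in both windows"
        )
    return _paired_result(
        "volume",
        paired["pre"].to_numpy(dtype=float),
        paired["post"].to_numpy(dtype=float),
        alpha,
        n_excluded,
        power_method,
    )
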