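"""XmR (individuals / moving-range) control charts.

The X chart plots a measure over time with center line X̄ and control
limits X̄ ± 2.66·m̄R, where m̄R is the mean moving range (mean absolute
successive difference).  The mR chart plots the moving ranges with upper
limit 3.267·m̄R.  The constants are the standard individuals-chart scale
factors 3/d2 (d2 = 1.128 for subgroups of two) and D4 for n = 2.

Points strictly outside the limits are assignable-cause signals; points on
or within the limits are chance variation.  Only the beyond-limits rule is
applied — no run/zone rules.

By default ALL points feed the limit statistics (retrospective charting of
a fixed study window); a frozen baseline of the first *k* points is
available for prospective monitoring.  Limits are deliberately not clamped
to [0, 100] for percentage data: a negative LCL simply means no lower
signal is reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

#: 3/d2 with d2 = 1.128 (subgroup size 2): X-chart limit half-width per m̄R.
XMR_X_CONSTANT = 2.66
#: D4 for subgroup size 2: mR-chart upper limit per m̄R.
XMR_MR_CONSTANT = 3.267


@dataclass
class XmRChart:
    """An individuals + moving-range chart with limits and signal indices."""

    x: np.ndarray
    period_labels: list[str]
    x_bar: float
    x_ucl: float
    x_lcl: float
    mr: np.ndarray
    mr_bar: float
    mr_ucl: float
    x_signals: list[int] = field(default_factory=list)
    mr_signals: list[int] = field(default_factory=list)
    #: optional event marker: (label, period index)
    annotation: Optional[tuple[str, int]] = None


def build_xmr(
    series: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    baseline_n: Optional[int] = None,
    annotation: Optional[tuple[str, int]] = None,
) -> XmRChart:
    """Build an XmR chart from an ordered series.

    Parameters
    ----------
    series
        Time-ordered values (at least two, all finite).
    labels
        Period labels; defaults to "1", "2", ...
    baseline_n
        If given, only the first ``baseline_n`` points (and their moving
        ranges) feed X̄, m̄R and the limits — a frozen baseline.  Default:
        every point contributes.
    annotation
        Optional ``(label, period_index)`` event marker, e.g. the month an
        intervention was deployed.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InsufficientDataError(
            f"an XmR chart needs at least 2 points, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise ConfigurationError("series contains non-finite values")
    if labels is None:
        labels = [str(i + 1) for i in range(x.size)]
    labels = [str(l) for l in labels]
    if len(labels) != x.size:
        raise ConfigurationError(
            f"{len(labels)} labels for {x.size} points"
        )
    if baseline_n is not None and not (2 <= baseline_n <= x.size):
        raise ConfigurationError(
            f"baseline_n must be in [2, {x.size}], got {baseline_n}"
        )
    if annotation is not None and not (0 <= annotation[1] < x.size):
        raise ConfigurationError("annotation index outside the series")

    mr = np.abs(np.diff(x))
    k = x.size if baseline_n is None else baseline_n
    x_bar = float(np.mean(x[:k]))
    mr_bar = float(np.mean(mr[: k - 1]))
    chart = XmRChart(
        x=x,
        period_labels=labels,
        x_bar=x_bar,
        x_ucl=x_bar + XMR_X_CONSTANT * mr_bar,
        x_lcl=x_bar - XMR_X_CONSTANT * mr_bar,
        mr=mr,
        mr_bar=mr_bar,
        mr_ucl=XMR_MR_CONSTANT * mr_bar,
        annotation=annotation,
    )
    chart.x_signals, chart.mr_signals = detect_signals(chart)
    return chart


def detect_signals(chart: XmRChart) -> tuple[list[int], list[int]]:
    """Indices of points strictly outside the control limits.

    A value exactly on a limit is chance variation, not a signal.
    """
    x_signals = np.flatnonzero((chart.x > chart.x_ucl) | (chart.x < chart.x_lcl))
    mr_signals = np.flatnonzero(chart.mr > chart.mr_ucl)
    return x_signals.tolist(), mr_signals.tolist()


def chart_to_table(chart: XmRChart) -> pd.DataFrame:
    """One row per period: values, limits, moving range, signal flags."""
    n = chart.x.size
    mr_col = np.concatenate([[np.nan], chart.mr])
    mr_sig = np.zeros(n, dtype=bool)
    for j in chart.mr_signals:
        mr_sig[j + 1] = True
    x_sig = np.zeros(n, dtype=bool)
    x_sig[chart.x_signals] = True
    ann = [""] * n
    if chart.annotation is not None:
        ann[chart.annotation[1]] = chart.annotation[0]
    return pd.DataFrame(
        {
            "period": chart.period_labels,
            "x": chart.x,
            "x_bar": chart.x_bar,
            "x_ucl": chart.x_ucl,
            "x_lcl": chart.x_lcl,
            "mr": mr_col,
            "mr_bar": chart.mr_bar,
            "mr_ucl": chart.mr_ucl,
            "x_signal": x_sig,
            "mr_signal": mr_sig,
            "annotation": ann,
        }
    )


def plot_xmr(chart: XmRChart, title: str = "", path: Optional[str] = None):
    """Render the two stacked panels (X above, mR below).

    Cosmetic: all analysis is on the numeric table.  Returns the figure;
    writes to ``path`` (SVG/PNG by extension) when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = chart.x.size
    idx = np.arange(n)
    fig, (ax_x, ax_mr) = plt.subplots(
        2, 1, figsize=(max(6, n * 0.6), 6), sharex=True
    )
    ax_x.plot(idx, chart.x, "o-", color="tab:blue", lw=1)
    ax_x.axhline(chart.x_bar, color="gray", lw=1, label="CL")
    ax_x.axhline(chart.x_ucl, color="firebrick", ls="--", lw=1, label="UCL")
    ax_x.axhline(chart.x_lcl, color="firebrick", ls="--", lw=1, label="LCL")
    if chart.x_signals:
        ax_x.plot(chart.x_signals, chart.x[chart.x_signals], "o",
                  color="firebrick", ms=9, mfc="none")
    ax_x.set_ylabel("X")
    ax_x.legend(loc="best", fontsize=8)

    ax_mr.plot(idx[1:], chart.mr, "o-", color="tab:blue", lw=1)
    ax_mr.axhline(chart.mr_bar, color="gray", lw=1)
    ax_mr.axhline(chart.mr_ucl, color="firebrick", ls="--", lw=1)
    if chart.mr_signals:
        sig = np.asarray(chart.mr_signals)
        ax_mr.plot(sig + 1, chart.mr[sig], "o", color="firebrick", ms=9,
                   mfc="none")
    ax_mr.set_ylabel("mR")

    for ax in (ax_x, ax_mr):
        if chart.annotation is not None:
            ax.axvline(chart.annotation[1], color="black", lw=1.5)
    if chart.annotation is not None:
        ax_x.text(chart.annotation[1], ax_x.get_ylim()[1],
                  f" {chart.annotation[0]}", va="top", fontsize=8)
    ax_mr.set_xticks(idx)
    ax_mr.set_xticklabels(chart.period_labels, rotation=45, ha="right",
                          fontsize=8)
    if title:
        ax_x.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
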