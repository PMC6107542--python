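"""Plot utilities for the evidence bundle.

All functions return a matplotlib Figure and never call show(); callers save
them where they want. The estimate-versus-SE scatter draws the significance
boundary se = |log hr| / 1.96: points below it have a 95% CI excluding 1, and
a corpus shaped by publication bias shows a sharp edge along that line.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_ps_distribution", "plot_balance", "plot_calibration_scatter",
           "plot_i2_histogram", "plot_estimate_se"]

_Z = 1.959963984540054


def plot_ps_distribution(ps, arms, ax=None):
    """Preference-score-style histogram of the propensity score per arm."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 4))
    ps = np.asarray(ps, float)
    arms = np.asarray(arms)
    bins = np.linspace(0, 1, 41)
    for arm in ("target", "comparator"):
        ax.hist(ps[arms == arm], bins=bins, alpha=0.5, density=True, label=arm)
    ax.set_xlabel("propensity score")
    ax.set_ylabel("density")
    ax.legend()
    return fig


def plot_balance(report, ax=None):
    """Before-versus-after |SDM| scatter with the 0.1 adequacy threshold."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(5, 5))
    t = report.table
    ax.scatter(np.abs(t["sdm_before"]), np.abs(t["sdm_after"]), s=8, alpha=0.5)
    lim = max(0.12, float(np.nanmax(np.abs(t[["sdm_before", "sdm_after"]].to_numpy()))) * 1.05)
    ax.axhline(0.1, ls="--", c="red", lw=0.8)
    ax.plot([0, lim], [0, lim], c="grey", lw=0.8)
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("|SDM| before stratification")
    ax.set_ylabel("|SDM| after stratification")
    return fig


def plot_calibration_scatter(log_hrs, ses, truths, ax=None, title=None):
    """Control estimates versus SE, colored by true hazard ratio."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 4))
    log_hrs, ses, truths = map(np.asarray, (log_hrs, ses, truths))
    for t in np.unique(truths):
        sel = truths == t
        ax.scatter(np.exp(log_hrs[sel]), ses[sel], s=10, alpha=0.6,
                   label=f"true HR {np.exp(t):.2g}")
    x = np.exp(np.linspace(np.log(0.1), np.log(10), 200))
    ax.plot(x, np.abs(np.log(x)) / _Z, "r--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio")
    ax.set_ylabel("standard error")
    ax.invert_yaxis()
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return fig


def plot_i2_histogram(i2_calibrated, i2_uncalibrated=None, ax=None):
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 1, 21)
    if i2_uncalibrated is not None:
        ax.hist(i2_uncalibrated, bins=bins, alpha=0.5, label="uncalibrated")
    ax.hist(i2_calibrated, bins=bins, alpha=0.5, label="calibrated")
    ax.set_xlabel(r"$I^2$")
    ax.set_ylabel("count")
    ax.legend()
    return fig


def plot_estimate_se(values, ses, ax=None, title=None):
    """Estimate-versus-SE scatter with the CI-excludes-1 boundary."""
    fig, ax = (ax.figure, ax) if ax is not None else plt.subplots(figsize=(6, 4))
    values, ses = np.asarray(values, float), np.asarray(ses, float)
    ok = np.isfinite(values) & np.isfinite(ses) & (values > 0)
    ax.scatter(values[ok], ses[ok], s=6, alpha=0.4)
    x = np.exp(np.linspace(np.log(0.1), np.log(10), 200))
    ax.plot(x, np.abs(np.log(x)) / _Z, "r--", lw=0.8, label="CI excludes 1 below")
    ax.set_xscale("log")
    ax.set_xlim(0.1, 10)
    ax.set_ylim(0, 1.5)
    ax.invert_yaxis()
    ax.set_xlabel("effect estimate")
    ax.set_ylabel("standard error")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return fig
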