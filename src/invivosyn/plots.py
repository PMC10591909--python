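"""Optional figure generation (headless-safe; matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .bootstrap import SynergyInference
from .study_data import GROUPS, StudyDataset


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_growth_curves(ds: StudyDataset, path) -> None:
    """Per-group spaghetti plot of log-scale tumor growth curves with the
    group mean eGR exponential overlaid."""
    from .egr import group_egr

    plt = _plt()
    egrs = group_egr(ds)
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2), sharey=True)
    for ax, g in zip(axes, GROUPS):
        tv0s = []
        for c in ds.curves_by_group(g):
            ax.plot(c.days, c.volumes, "o-", color="grey", alpha=0.5, ms=3, lw=1)
            if c.n_points:
                tv0s.append(c.volumes[0])
        if tv0s:
            d_max = max(c.duration for c in ds.curves_by_group(g))
            t = np.linspace(0, d_max, 50)
            ax.plot(t, np.mean(tv0s) * np.exp(egrs.means[g] * t), "r-", lw=2)
        ax.set_yscale("log")
        ax.set_title(f"{g} (eGR = {egrs.means[g]:.4f}/day)")
        ax.set_xlabel("day")
    axes[0].set_ylabel("tumor volume (mm$^3$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bootstrap(inference: SynergyInference, path) -> None:
    """Bootstrap histograms for CI and SS with the additivity null (dashed
    line), the point estimate (triangle) and the BCa interval (bar)."""
    plt = _plt()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, stat in zip(axes, (inference.ci, inference.ss)):
        ax.hist(stat.boot, bins=40, color="steelblue", alpha=0.8)
        ax.axvline(stat.null_value, color="red", ls="--")
        y = ax.get_ylim()[1]
        ax.plot([stat.observed], [0.02 * y], marker="v", color="black", ms=9)
        ax.plot([stat.lower, stat.upper], [0.06 * y] * 2, color="blue", lw=3)
        label = stat.statistic.upper()
        p = stat.p_value
        ax.set_title(f"{label} = {stat.observed:.3g}, P = " +
                     ("n/a" if np.isnan(p) else f"{p:.3g}"))
        ax.set_xlabel(label)
    fig.suptitle(f"{inference.estimate.model} model, t = {inference.estimate.t_eval:g} d")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_power_curves(frame, x: str, path, group_by: str | None = None) -> None:
    """Power-versus-``x`` curves (one line per value of ``group_by``)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    if group_by and group_by in frame.columns:
        for key, sub in frame.groupby(group_by):
            sub = sub.sort_values(x)
            ax.errorbar(
                sub[x], sub["power"],
                yerr=[sub["power"] - sub["ci_low"], sub["ci_high"] - sub["power"]],
                marker="o", capsize=3, label=f"{group_by}={key:g}",
            )
        ax.legend(fontsize=8)
    else:
        sub = frame.sort_values(x)
        ax.errorbar(
            sub[x], sub["power"],
            yerr=[sub["power"] - sub["ci_low"], sub["ci_high"] - sub["power"]],
            marker="o", capsize=3,
        )
    ax.set_xlabel(x)
    ax.set_ylabel("empirical power")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
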