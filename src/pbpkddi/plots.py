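"""Plot helpers: predictive-check bands and DDI-ratio summaries (PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import vpc_bands

__all__ = ["plot_vpc", "plot_ddi_ratios"]


def plot_vpc(
    times,
    profiles,
    path: str | Path,
    observed: tuple | None = None,
    title: str = "",
    ylabel: str = "concentration (ng/mL)",
):
    """Shade the 5th-95th percentile band over simulated profiles.

    ``profiles`` is (n_profiles, n_times); ``observed`` an optional
    (times, concs) pair overlaid as points.
    """
    mean, lo, hi = vpc_bands(np.asarray(profiles))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(times, lo, hi, alpha=0.3, label="5th-95th percentile")
    ax.plot(times, mean, lw=2, label="mean prediction")
    if observed is not None:
        ax.plot(observed[0], observed[1], "o", ms=4, label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ddi_ratios(
    ratios: dict[str, dict[str, float]],
    path: str | Path,
    reference_band: tuple[float, float] | None = None,
    title: str = "DDI AUC ratio by age group",
):
    """Dot plot of DDI ratios per scenario (x) and age group (marker).

    ``ratios`` maps scenario name -> {age_group: ratio}.  An optional
    horizontal band (e.g. the 1.25-fold interval for normalized ratios)
    is shaded.
    """
    scenarios = list(ratios)
    groups = sorted({g for r in ratios.values() for g in r})
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(scenarios), 4))
    markers = ["o", "s", "^", "d"]
    for gi, group in enumerate(groups):
        xs, ys = [], []
        for si, sc in enumerate(scenarios):
            if group in ratios[sc]:
                xs.append(si + (gi - (len(groups) - 1) / 2) * 0.15)
                ys.append(ratios[sc][group])
        ax.plot(xs, ys, markers[gi % len(markers)], label=group)
    if reference_band is not None:
        ax.axhspan(*reference_band, alpha=0.15, color="grey",
                   label="acceptance band")
    ax.set_xticks(range(len(scenarios)))
    ax.set_xticklabels(scenarios, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("AUC ratio")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
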