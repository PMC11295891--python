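"""Optional matplotlib figures for the cluster and QC analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .age import CLUSTER_ORDER, RegressionResult

__all__ = ["plot_cluster_ages", "plot_scree_curve"]


def plot_cluster_ages(
    summary: pd.DataFrame,
    regressions: dict[str, RegressionResult],
    path=None,
):
    """Scatter of per-participant median pupil vs age per light cluster,
    with the fitted age-regression line."""
    clusters = [c for c in CLUSTER_ORDER if c in set(summary["light_cluster"])]
    fig, axes = plt.subplots(1, len(clusters), figsize=(3.2 * len(clusters), 3.2), sharey=True)
    if len(clusters) == 1:
        axes = [axes]
    for ax, cluster in zip(axes, clusters):
        one = summary[summary["light_cluster"] == cluster]
        ax.errorbar(
            one["age_years"], one["median_pupil_mm"], yerr=one["iqr_mm"] / 2.0,
            fmt="s", ms=4, alpha=0.6, lw=0.8,
        )
        if cluster in regressions:
            r = regressions[cluster]
            xs = [one["age_years"].min(), one["age_years"].max()]
            ax.plot(xs, [r.intercept + r.slope * x for x in xs], "k-")
            ax.set_title(f"{cluster}: {r.slope_per_decade:+.3f} mm/decade")
        ax.set_xlabel("age [years]")
    axes[0].set_ylabel("median pupil [mm]")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_scree_curve(curve: dict[float, int], threshold: float | None = None, path=None):
    """Excluded-participant count versus candidate data-loss threshold."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ts = sorted(curve)
    ax.plot(ts, [curve[t] for t in ts], "o-")
    if threshold is not None:
        ax.axvline(threshold, color="k", ls="--", label=f"adopted {threshold:.0%}")
        ax.legend()
    ax.set_xlabel("data-loss threshold")
    ax.set_ylabel("participants excluded")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
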