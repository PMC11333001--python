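"""Figures for the evaluation harness.

Three standard views: per-method AXB accuracy bars with bootstrap CIs and
attainable-bound lines, the disagreement-MDS scatter of methods, and the
binned choice-calibration curve.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .evaluation import EvaluationReport

__all__ = ["accuracy_bars", "mds_scatter", "calibration_curve"]


def accuracy_bars(
    reports: list[EvaluationReport],
    path,
    bound_cycle: float | None = None,
    bound_consistency: float | None = None,
) -> None:
    """Per-method accuracy with 95% bootstrap CIs and attainable bounds."""
    fig, ax = plt.subplots(figsize=(1.2 * len(reports) + 2, 4))
    names = [r.method for r in reports]
    accs = [r.accuracy for r in reports]
    err_lo = [r.accuracy - r.ci_low for r in reports]
    err_hi = [r.ci_high - r.accuracy for r in reports]
    ax.bar(names, accs, color="#4878a8")
    ax.errorbar(names, accs, yerr=[err_lo, err_hi], fmt="none", ecolor="k",
                capsize=4)
    ax.axhline(0.5, ls=":", c="grey", label="chance")
    if bound_cycle is not None:
        ax.axhline(bound_cycle, ls="--", c="#c44e52",
                   label="attainable (cycle accuracy)")
    if bound_consistency is not None:
        ax.axhline(bound_consistency, ls="--", c="#dd8452",
                   label="attainable (consistency)")
    ax.set_ylabel("AXB agreement with bird decisions")
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def mds_scatter(coords: pd.DataFrame, path) -> None:
    """2-D disagreement-MDS configuration of methods."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords["mds1"], coords["mds2"], c="#4878a8")
    for name, row in coords.iterrows():
        ax.annotate(str(name), (row["mds1"], row["mds2"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=9)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def calibration_curve(table: pd.DataFrame, path) -> None:
    """Binned relative rank distance vs side-bias-adjusted choice log-odds."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["bin_centre"], table["log_odds_right"], "o-", c="#4878a8")
    ax.axhline(0.0, ls=":", c="grey")
    ax.axvline(0.0, ls=":", c="grey")
    ax.set_xlabel("relative rank distance (left - right) / (left + right)")
    ax.set_ylabel("adjusted log-odds of choosing right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
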