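"""Volcano, ROC and Kaplan-Meier panels (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .survival import RocCurve, km_estimate

__all__ = ["volcano_plot", "roc_plot", "km_plot"]


def volcano_plot(table, path, lfc_threshold: float = 1.0,
                 nlp_threshold: float = 1.3) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = table["evaluable"]
    sig = table["significant"] & ok
    ax.scatter(table.loc[ok & ~sig, "log2_fc"], table.loc[ok & ~sig, "neg_log10_p"],
               s=12, c="grey", alpha=0.6)
    ax.scatter(table.loc[sig, "log2_fc"], table.loc[sig, "neg_log10_p"],
               s=16, c="crimson")
    for fid in table.index[sig]:
        ax.annotate(fid, (table.loc[fid, "log2_fc"], table.loc[fid, "neg_log10_p"]),
                    fontsize=6, xytext=(2, 2), textcoords="offset points")
    ax.axhline(nlp_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(lfc_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(-lfc_threshold, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_plot(roc: RocCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    fpr = 1.0 - roc.specificity
    order = np.argsort(fpr)
    ax.plot(fpr[order], roc.sensitivity[order], lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}; cutoff = {roc.youden_optimal:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_plot(frame, scores, cutoff: float, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    high = np.asarray(scores) > cutoff
    for ax, (outcome, tcol, ecol) in zip(
        axes, [("PFS", "pfs_days", "pfs_event"), ("OS", "os_days", "os_event")]
    ):
        for mask, label, color in ((high, "high", "tab:blue"),
                                   (~high, "low", "tab:orange")):
            km = km_estimate(frame.loc[mask, tcol], frame.loc[mask, ecol])
            t = np.concatenate([[0.0], np.repeat(km.times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]]) \
                if len(km.times) else np.array([1.0])
            if len(km.times):
                ax.plot(t, s, label=label, color=color)
            else:
                ax.axhline(1.0, label=label, color=color)
        ax.set_title(outcome)
        ax.set_xlabel("days")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
    axes[0].set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
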