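"""Plot helpers for CV results: ability-vs-size panels and the
ability-vs-bias scatter with its phenotypic reference line.

Both functions consume the tidy long-format records emitted by
``evaluation.cv_bias_report`` (columns: model, trait, location, size,
rep, fold, ability, bias, reference).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_ability_vs_size", "plot_bias_scatter"]


def plot_ability_vs_size(records: pd.DataFrame, out_path=None):
    """Mean prediction ability (whiskers: min-max) per model and size."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, (model, sub) in enumerate(records.groupby("model")):
        g = sub.groupby("size")["ability"]
        sizes = g.mean().index.to_numpy(dtype=float) + 2.0 * i
        ax.errorbar(sizes, g.mean(),
                    yerr=[g.mean() - g.min(), g.max() - g.mean()],
                    marker="o", capsize=3, label=model)
    ax.set_xlabel("population size (lines)")
    ax.set_ylabel("prediction ability (r)")
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def plot_bias_scatter(records: pd.DataFrame, out_path=None):
    """Per-fold ability vs bias (correlation of predictions with the
    secondary trait); the dashed line marks the phenotypic reference."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for model, sub in records.groupby("model"):
        ax.scatter(sub["bias"], sub["ability"], s=12, alpha=0.5, label=model)
    if "reference" in records.columns and len(records):
        ax.axvline(records["reference"].iloc[0], ls="--", c="k", lw=1,
                   label="phenotypic reference")
    ax.set_xlabel("correlation of predictions with secondary trait")
    ax.set_ylabel("prediction ability (r)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
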