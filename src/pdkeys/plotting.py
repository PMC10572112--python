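"""Optional ROC figure output (numeric CSV reports are the contract)."""

from __future__ import annotations

from pathlib import Path

__all__ = ["plot_roc"]


def plot_roc(results, path: str | Path, title: str = "") -> Path:
    """Plot one or more screening results as ROC curves and save the figure.

    Requires matplotlib (the ``plot`` extra); raises ImportError otherwise.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(results, (list, tuple)):
        results = [results]
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        # threshold-descending order walks the staircase left to right
        fpr = (1.0 - r.roc.specificity)[::-1]
        ax.plot(fpr, r.roc.sensitivity[::-1], drawstyle="steps-post",
                label=f"{r.feature_name} (AUC {r.auc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
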