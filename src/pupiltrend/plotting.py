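"""Optional figures: per-contrast box plots of participant mean trends.

Matplotlib is an optional dependency; import errors surface only when a
plot is actually requested.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_contrast_boxes"]


def plot_contrast_boxes(means: pd.DataFrame, contrast: str, out_path) -> None:
    """Box plots of per-participant mean trends, one panel per method/scale.

    ``means`` is the output of :func:`pupiltrend.participant_means`
    (columns participant, group, method, scale_ms, value_px).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    combos = sorted(means.groupby(["method", "scale_ms"]).groups)
    fig, axes = plt.subplots(1, len(combos), figsize=(3 * len(combos), 4), squeeze=False)
    for ax, (method, scale) in zip(axes[0], combos):
        sub = means[(means["method"] == method) & (means["scale_ms"] == scale)]
        groups = sorted(sub["group"].unique())
        ax.boxplot([sub.loc[sub["group"] == g, "value_px"] for g in groups], tick_labels=groups)
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(f"{method} {scale / 1000:g} s")
        ax.set_ylabel("trend (px)")
    fig.suptitle(contrast)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
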