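"""Optional plotting helpers (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .amplicon import BASE_COLUMNS, WindowReport  # noqa: E402


def plot_window_report(report: WindowReport, path: str) -> None:
    """Per-position base-composition heatmap over the analysis window."""
    counts = report.per_position_counts[list(BASE_COLUMNS)]
    frac = counts.div(counts.sum(axis=1).replace(0, 1), axis=0)
    fig, ax = plt.subplots(figsize=(10, 2.6))
    im = ax.imshow(frac.T.values, aspect="auto", cmap="viridis",
                   vmin=0, vmax=1)
    ax.set_yticks(range(len(BASE_COLUMNS)), BASE_COLUMNS)
    ax.set_xticks(range(len(frac)),
                  report.per_position_counts["ref"], fontsize=7)
    ax.set_xlabel("analysis-window position (reference base shown)")
    fig.colorbar(im, ax=ax, label="base fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
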