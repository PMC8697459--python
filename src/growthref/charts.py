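"""Growth-chart rendering: percentile isopleths from reference tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .records import ReferenceTable

_LEVEL_LABELS = {"p5": "5th", "p25": "25th", "p50": "50th",
                 "p75": "75th", "p95": "95th"}

_UNITS = {"stature": "cm", "weight": "kg", "head_circumference": "cm"}


def _panel(ax, table: ReferenceTable, lo: float, hi: float) -> None:
    d = table.data[(table.data["index"] >= lo) & (table.data["index"] <= hi)]
    for col, label in _LEVEL_LABELS.items():
        ax.plot(d["index"], d[col], lw=1.2, label=label)
    ax.grid(True, lw=0.3, alpha=0.5)


def plot_reference(table: ReferenceTable, path, title: str | None = None) -> None:
    """Five-isopleth chart; age charts get 0-36 month and full-range panels,
    weight-for-height charts are split at 80 and 110 cm."""
    unit = _UNITS.get(table.measure, "")
    if table.index_kind == "height_cm":
        g = table.grid
        splits = [(g[0], 80), (80, 110), (110, g[-1])]
        splits = [(a, b) for a, b in splits if b > a]
        fig, axes = plt.subplots(1, len(splits), figsize=(4 * len(splits), 4))
        for ax, (a, b) in zip(axes, splits):
            _panel(ax, table, a, b)
            ax.set_xlabel("height (cm)")
            ax.set_ylabel(f"weight (kg)")
        axes[-1].legend(fontsize=7)
    else:
        g = table.grid
        if g[-1] > 60:
            splits = [(0, 36), (0, g[-1])]
        else:
            splits = [(0, g[-1])]
        fig, axes = plt.subplots(len(splits), 1, figsize=(6, 4 * len(splits)),
                                 squeeze=False)
        for ax, (a, b) in zip(axes[:, 0], splits):
            _panel(ax, table, a, b)
            ax.set_xlabel("age (months)")
            ax.set_ylabel(f"{table.measure} ({unit})")
        axes[0, 0].legend(fontsize=7)
    fig.suptitle(title or f"{table.sex} {table.measure} ({table.index_kind})")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
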