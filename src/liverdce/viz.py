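"""Percent-enhancement curve output (CSV table + static plot)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .study import StudyData, percent_enhancement


def write_enhancement_curves(study: StudyData, path_base) -> tuple[Path, Path]:
    """Write per-ROI percent-enhancement curves as ``<base>.csv`` and a
    ``<base>.png`` overview plot; returns both paths."""
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    any_series = next(iter(study.signals.values()))
    table = pd.DataFrame({"time_s": any_series.times})
    fig, ax = plt.subplots(figsize=(7, 4))
    for roi, series in study.signals.items():
        pe = percent_enhancement(series)
        table[roi] = pe
        ax.plot(series.times / 60.0, pe, label=roi, lw=1)
    ax.set_xlabel("time since bolus (min)")
    ax.set_ylabel("enhancement (%)")
    ax.axhline(0.0, color="0.7", lw=0.5)
    ax.legend(frameon=False)
    ax.set_title(f"{study.species} / {study.agent}")
    csv_path = base.with_suffix(".csv")
    png_path = base.with_suffix(".png")
    table.to_csv(csv_path, index=False)
    fig.savefig(png_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return csv_path, png_path
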