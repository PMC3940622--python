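"""Box-plot summaries of results tables (one box per level of the predictor)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_LABELS = {
    "max_distance": "maximum distance from nest (grid units)",
    "n_switches": "number of habitat switches",
    "prop_wild": "proportion of time in wild habitat",
}


def plot_boxplots(
    table: pd.DataFrame, response: str, predictor: str, path: str | Path
) -> Path:
    """Per-level box plot (median, quartiles, whiskers) of one statistic."""
    data = table.dropna(subset=[response])
    if data.empty:
        raise ValueError("results table has no rows for the requested response")
    levels = sorted(data[predictor].unique())
    groups = [data.loc[data[predictor] == lev, response].to_numpy() for lev in levels]

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(groups, tick_labels=[f"{lev:g}" if isinstance(lev, float) else str(lev)
                                    for lev in levels])
    ax.set_xlabel(predictor)
    ax.set_ylabel(_LABELS.get(response, response))
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
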