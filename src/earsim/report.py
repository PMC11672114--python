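"""Summary tables and figures: per-subject x stage "mean ± std" JSD-FSI
tables (two decimals, dash for absent stages), stage-count tables with
percentages, and the blue-vs-red score-distribution histograms.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import STAGES3

ABSENT = "-"


def format_mean_std(values: np.ndarray) -> str:
    """Render scores as ``x.xx ± x.xx`` (population std, two decimals)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return ABSENT
    return f"{values.mean():.2f} ± {values.std():.2f}"


def summarize(sim_scores: pd.DataFrame, pair_class: str = "PSG-to-in-ear") -> pd.DataFrame:
    """Per subject x stage mean ± std of JSD-FSI scores of one pair class,
    with a grand-average row pooling all scores per stage."""
    if sim_scores.empty:
        raise ValueError("empty similarity report")
    df = sim_scores[sim_scores["pair_class"] == pair_class]
    subjects = sorted(df["subject"].unique())
    rows = {}
    for subject in subjects:
        sub = df[df["subject"] == subject]
        rows[subject] = {
            stage: format_mean_std(sub.loc[sub["stage"] == stage, "score"].to_numpy())
            for stage in STAGES3
        }
    rows["Average"] = {
        stage: format_mean_std(df.loc[df["stage"] == stage, "score"].to_numpy())
        for stage in STAGES3
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STAGES3))


def stage_count_table(counts_by_row: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Stage-count table with per-stage percentages and row totals.

    ``counts_by_row`` maps a row label (e.g. "PSG", "In-ear-EEG",
    "PSG ∩ In-ear-EEG") to per-stage counts.  Percentages are of the row
    total, printed to one decimal.
    """
    out = {}
    for row, counts in counts_by_row.items():
        total = sum(counts.get(s, 0) for s in STAGES3)
        cells = {}
        for stage in STAGES3:
            c = counts.get(stage, 0)
            pct = 100.0 * c / total if total else 0.0
            cells[stage] = f"{c} ({pct:.1f}%)"
        cells["Total"] = total
        out[row] = cells
    return pd.DataFrame.from_dict(out, orient="index", columns=list(STAGES3) + ["Total"])


def plot_score_distributions(
    sim_scores: pd.DataFrame, out_dir: str | Path, bins: int = 15
) -> list[Path]:
    """Histogram of in-ear-vs-PSG scores (blue) over the PSG-to-PSG
    reference (red), one figure per (subject, stage)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for (subject, stage), grp in sim_scores.groupby(["subject", "stage"]):
        blue = grp.loc[grp["pair_class"] == "PSG-to-in-ear", "score"]
        red = grp.loc[grp["pair_class"] != "PSG-to-in-ear", "score"]
        if blue.empty and red.empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if not red.empty:
            ax.hist(red, bins=bins, range=(0, 1), color="tab:red", alpha=0.6,
                    label="PSG-to-PSG", density=True)
        if not blue.empty:
            ax.hist(blue, bins=bins, range=(0, 1), color="tab:blue", alpha=0.6,
                    label="PSG-to-in-ear", density=True)
        ax.set_xlabel("JSD-FSI")
        ax.set_ylabel("density")
        ax.set_title(f"{subject} — {stage}")
        ax.legend(frameon=False)
        fig.tight_layout()
        path = out_dir / f"scores_{subject}_{stage}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
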