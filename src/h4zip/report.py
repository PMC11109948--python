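"""Report tables summarizing motif abundances the way the figures do.

Two layouts: the motif x time "heatmap" table (mean over replicates per
motif and time point), and the aggregate bar-plot table that partitions the
motifs into unmod / K16ac / other mono-ac / di-/tri-ac / fully acetylated
categories with mean and s.e.m. over replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import TimeCourseDataset

__all__ = ["heatmap_table", "aggregate_motifs", "AGGREGATE_CATEGORIES"]

AGGREGATE_CATEGORIES = ["unmod", "K16ac", "other mono-ac", "di-/tri-ac", "tetra-ac"]


def _category(label: str, n_sites: int) -> str:
    n_ac = label.count("ac") if label != "unmod" else 0
    if n_ac == 0:
        return "unmod"
    if n_ac == 1:
        return "K16ac" if label == "K16ac" else "other mono-ac"
    if n_ac == n_sites:
        return "tetra-ac"
    return "di-/tri-ac"


def heatmap_table(ds: TimeCourseDataset) -> pd.DataFrame:
    """Motif x time table of replicate-mean relative abundances."""
    mean = ds.y.mean(axis=2)
    return pd.DataFrame(mean, index=ds.motifs, columns=ds.times)


def aggregate_motifs(ds: TimeCourseDataset, n_sites: int | None = None) -> pd.DataFrame:
    """Partition motif abundances into the figure's summary categories.

    Returns a long DataFrame (category, time_min, mean, sem).  The
    categories partition the motifs, so per (time, replicate) the category
    sums equal the total abundance.  For a K16-less (3-site) space the
    "K16ac" row is absent and "tetra-ac" denotes the fully acetylated tail.
    """
    if n_sites is None:
        # infer from the largest acetyl count among labels
        n_sites = max(
            (lab.count("ac") if lab != "unmod" else 0) for lab in ds.motifs
        )
    cats = np.array([_category(lab, n_sites) for lab in ds.motifs])
    n_reps = ds.y.shape[2]

    rows = []
    for cat in AGGREGATE_CATEGORIES:
        sel = cats == cat
        if not sel.any():
            continue
        per_rep = ds.y[sel].sum(axis=0)  # (n_times, n_reps)
        mean = per_rep.mean(axis=1)
        sem = per_rep.std(axis=1, ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.zeros_like(mean)
        for j, t in enumerate(ds.times):
            rows.append({"category": cat, "time_min": t, "mean": mean[j], "sem": sem[j]})
    return pd.DataFrame(rows)
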