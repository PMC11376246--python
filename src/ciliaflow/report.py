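"""Group-level aggregation of per-movie / per-specimen metrics.

Pipelines emit tidy metric rows (specimen_id, group, batch, metric,
value); this module summarizes them per group (mean, SD, n) and offers a
seeded two-sided permutation test on the difference of group means as a
distribution-free check of group differences.  Heavier models (ANOVA with
experiment and genotype factors, mixed effects) are deliberately left to
external statistics packages — the tables are shaped for direct import.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize_groups", "permutation_group_test", "plot_metric_strip"]

_KEYS = ["group", "metric"]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("group", "metric", "value") if c not in table.columns]
    if missing:
        raise ValueError(f"metrics table lacks columns: {missing}")
    # empty group labels round-trip through CSV as NaN; keep them groupable
    table = table.assign(group=table["group"].fillna(""))
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("metric values must be finite")
    return table


def summarize_groups(
    table: pd.DataFrame, groups: list[str] | None = None
) -> pd.DataFrame:
    """Per-(batch, group, metric) mean, SD and n.

    ``groups``, when given, is the closed set of expected group labels; any
    other label in the table raises.  SD uses ddof=1 (sample SD) and is
    NaN for singleton groups.
    """
    table = _check_table(table)
    if groups is not None:
        unknown = set(table["group"]) - set(groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    keys = (["batch"] if "batch" in table.columns else []) + _KEYS
    out = (
        table.groupby(keys, sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def permutation_group_test(
    table: pd.DataFrame,
    metric: str,
    groups: tuple[str, str] | None = None,
    n_perm: int = 5000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Specimen labels are shuffled ``n_perm`` times with a seeded generator;
    the p-value uses the add-one estimator (p >= 1 / (n_perm + 1)), so it
    is never exactly zero and is reproducible for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    table = _check_table(table)
    sub = table[table["metric"] == metric]
    if groups is None:
        labels = sorted(sub["group"].unique())
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, found {labels}")
        groups = (labels[0], labels[1])
    a = sub.loc[sub["group"] == groups[0], "value"].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == groups[1], "value"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 specimens per group")
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:na].mean() - perm[na:].mean())
        if d >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def plot_metric_strip(table: pd.DataFrame, metric: str, path: str) -> str:
    """Per-group strip plot with group means; returns the written path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = _check_table(table)
    sub = table[table["metric"] == metric]
    labels = sorted(sub["group"].unique())
    fig, ax = plt.subplots(figsize=(1.2 + len(labels), 3.2))
    rng = np.random.default_rng(0)
    for i, g in enumerate(labels):
        vals = sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
        ax.plot(
            i + rng.uniform(-0.12, 0.12, len(vals)), vals, "o", alpha=0.7, ms=5
        )
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="k", lw=2)
    ax.set_xticks(range(len(labels)), labels)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
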