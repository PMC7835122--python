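"""Summaries and contrasts over the benchmark table.

Split-level d' is first averaged within (feature set, n_pos, category); the
category is the random-effect unit, so the grand mean and its uncertainty are
taken *over categories*: a percentile bootstrap resampling categories gives
the 95% CI of the cross-category mean, and pairwise feature-set comparisons
are paired per-category mean differences tested with a two-sided sign-flip
permutation. Under the balanced, fully paired design the paired mean
difference coincides with the marginal-mean difference a mixed model would
estimate; the permutation test replaces its parametric inference.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["summarize", "contrast", "contrast_all_pairs", "write_report"]

_REQUIRED = {"feature_set", "category", "n_pos", "split_index", "dprime"}


def _check_complete(results: pd.DataFrame) -> None:
    missing_cols = _REQUIRED - set(results.columns)
    if missing_cols:
        raise ValueError(f"results table lacks columns: {sorted(missing_cols)}")
    counts = results.groupby(["feature_set", "n_pos", "category"]).size()
    if counts.nunique() != 1:
        bad = counts[counts != counts.iloc[0]]
        raise ValueError(f"incomplete factorial design; uneven cells:\n{bad}")
    # every feature set must cover every (n_pos, category) cell
    cells = counts.reset_index().groupby("feature_set").size()
    if cells.nunique() != 1:
        raise ValueError(f"missing cells for some feature sets:\n{cells}")


def summarize(results: pd.DataFrame, n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Per-category means plus bootstrapped grand means.

    Returns one row per (feature_set, n_pos, category) with the mean d' over
    splits, and columns ``grand_mean``, ``ci_lo``, ``ci_hi`` repeated within
    each (feature_set, n_pos) group: the cross-category mean and its 95%
    percentile bootstrap CI obtained by resampling categories with
    replacement.
    """
    _check_complete(results)
    per_cat = (
        results.groupby(["feature_set", "n_pos", "category"], sort=True)["dprime"]
        .mean()
        .rename("mean_dprime")
        .reset_index()
    )
    out = []
    rng = np.random.default_rng(seed)
    for (fs, n_pos), grp in per_cat.groupby(["feature_set", "n_pos"], sort=True):
        vals = grp["mean_dprime"].to_numpy()
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_means = vals[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        g = grp.copy()
        g["grand_mean"] = vals.mean()
        g["ci_lo"] = lo
        g["ci_hi"] = hi
        out.append(g)
    return pd.concat(out, ignore_index=True)


def contrast(
    results: pd.DataFrame,
    set_a: str,
    set_b: str,
    n_pos: int,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired per-category contrast of two feature sets at one size.

    The statistic is the mean over categories of (mean d' under A - mean d'
    under B); the two-sided p-value comes from ``n_perm`` random sign flips
    of the paired differences (the identity assignment is included in the
    null set, so p is never 0).
    """
    for s in (set_a, set_b):
        if s not in set(results["feature_set"]):
            raise ValueError(f"feature set {s!r} absent from results")
    sub = results[results["n_pos"] == n_pos]
    a = sub[sub["feature_set"] == set_a].groupby("category")["dprime"].mean()
    b = sub[sub["feature_set"] == set_b].groupby("category")["dprime"].mean()
    if set(a.index) != set(b.index):
        raise ValueError("category sets differ between the two feature sets")
    diffs = (a - b.reindex(a.index)).to_numpy()
    observed = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    null = (signs * diffs).mean(axis=1)
    p = (1 + np.sum(np.abs(null) >= abs(observed) - 1e-15)) / (n_perm + 1)
    return {
        "feature_set_a": set_a,
        "feature_set_b": set_b,
        "n_pos": n_pos,
        "mean_diff": float(observed),
        "p_value": float(p),
        "n_permutations": n_perm,
        "seed": seed,
        "n_categories": diffs.size,
    }


def contrast_all_pairs(
    results: pd.DataFrame, n_perm: int = 10000, seed: int = 0
) -> pd.DataFrame:
    """All ordered feature-set pairs at every training size."""
    sets = sorted(set(results["feature_set"]))
    sizes = sorted(set(results["n_pos"]))
    rows = [
        contrast(results, a, b, n_pos, n_perm=n_perm, seed=seed)
        for n_pos in sizes
        for i, a in enumerate(sets)
        for b in sets[i + 1 :]
    ]
    return pd.DataFrame(rows)


def _figure(summary: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sets = sorted(summary["feature_set"].unique())
    sizes = sorted(summary["n_pos"].unique())
    cmap = plt.get_cmap("tab10")
    fig, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.8 / len(sets)
    for si, fs in enumerate(sets):
        color = cmap(si % 10)
        for xi, n_pos in enumerate(sizes):
            grp = summary[(summary["feature_set"] == fs) & (summary["n_pos"] == n_pos)]
            if grp.empty:
                continue
            x = xi + (si - (len(sets) - 1) / 2) * width
            jitter = (np.arange(len(grp)) / max(len(grp) - 1, 1) - 0.5) * width * 0.5
            ax.plot(x + jitter, grp["mean_dprime"], ".", color=color, alpha=0.45, ms=4)
            g = grp.iloc[0]
            ax.errorbar(
                x,
                g["grand_mean"],
                yerr=[[g["grand_mean"] - g["ci_lo"]], [g["ci_hi"] - g["grand_mean"]]],
                fmt="_",
                color=color,
                ms=14,
                capsize=3,
                lw=1.5,
                label=fs if xi == 0 else None,
            )
    ax.set_xticks(range(len(sizes)))
    ax.set_xticklabels([str(s) for s in sizes])
    ax.set_xlabel("positive training examples")
    ax.set_ylabel("d'")
    ax.axhline(0, color="0.7", lw=0.8, zorder=0)
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(
    summary: pd.DataFrame,
    contrasts: pd.DataFrame | None,
    out_dir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write summary/contrast TSVs, the dot-and-crossbar figure, and a
    run manifest. TSV bytes are stable for identical inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"summary": out / "summary.tsv", "figure": out / "figure_dprime.png"}
    summary.to_csv(paths["summary"], sep="\t", index=False, float_format="%.10g")
    if contrasts is not None and len(contrasts):
        paths["contrasts"] = out / "contrasts.tsv"
        contrasts.to_csv(paths["contrasts"], sep="\t", index=False, float_format="%.10g")
    _figure(summary, paths["figure"])
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest or {}, indent=2, sort_keys=True) + "\n")
    return paths
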