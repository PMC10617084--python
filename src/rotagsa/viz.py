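"""Diagnostic graphics: ordered-statistic panels, the KS enrichment walk,
the effective-signature-size curve, and a per-set expression heatmap —
plus a self-contained HTML report combining them for the top sets.

All plot functions are pure: they take data, write one image file and
return its path.
"""

from __future__ import annotations

import base64
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from rotagsa.effsize import EffSizeCurve
from rotagsa.io import DesignSpec, ExpressionData, GeneSet
from rotagsa.linmod import ModeratedStats
from rotagsa.scores import COMPETITIVE, ScoreInput, ScoreSpec, compute_score

__all__ = [
    "plot_ordered_stats",
    "plot_ks_walk",
    "plot_effsize_curve",
    "plot_heatmap",
    "html_report",
]


def _mask_for(set_: GeneSet, gene_ids) -> np.ndarray:
    members = set(set_.genes)
    mask = np.array([g in members for g in gene_ids])
    if not mask.any():
        raise ValueError(f"gene set {set_.name!r} has no overlap with the data")
    return mask


def _delta(stats: ModeratedStats, hypothesis: str) -> np.ndarray:
    z = stats.z
    if hypothesis == COMPETITIVE:
        return (z - z.mean()) / z.std(ddof=1)
    return z


def plot_ordered_stats(
    stats: ModeratedStats,
    set_: GeneSet,
    gene_ids,
    hypothesis: str = "self-contained",
    path: str | Path = "ordered_stats.png",
) -> Path:
    """Area, barcode and density panels of the ordered per-gene statistics,
    with the testing set highlighted.  Statistics are centered and scaled
    when the hypothesis is competitive."""
    mask = _mask_for(set_, gene_ids)
    delta = _delta(stats, hypothesis)
    order = np.argsort(-delta)
    ordered = delta[order]
    in_set_pos = np.flatnonzero(mask[order])

    fig, axes = plt.subplots(3, 1, figsize=(7, 7), height_ratios=[3, 1, 2])
    x = np.arange(ordered.size)
    axes[0].fill_between(x, 0, ordered, where=ordered >= 0, color="#c23b22", alpha=0.6)
    axes[0].fill_between(x, 0, ordered, where=ordered < 0, color="#2a6f97", alpha=0.6)
    zero_cross = int(np.searchsorted(-ordered, 0))
    axes[0].axvline(zero_cross, ls="--", c="grey", lw=1)
    axes[0].set_ylabel("moderated t (z)")
    axes[0].set_title(f"{set_.name}: ordered statistics")
    axes[1].vlines(in_set_pos, 0, 1, color="black", lw=0.7)
    axes[1].set_yticks([])
    axes[1].set_ylabel("set")
    axes[2].hist(delta, bins=50, density=True, color="lightgrey", label="all genes")
    axes[2].hist(
        delta[mask], bins=25, density=True, color="#c23b22", alpha=0.6,
        label=set_.name,
    )
    axes[2].legend(frameon=False, fontsize=8)
    axes[2].set_xlabel("moderated t (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_ks_walk(
    stats: ModeratedStats,
    set_: GeneSet,
    gene_ids,
    k: float = 1.0,
    path: str | Path = "ks_walk.png",
) -> Path:
    """Classic enrichment plot: the weighted KS running difference over the
    full ranking, peak (the ksmax score) annotated."""
    mask = _mask_for(set_, gene_ids)
    delta = stats.z
    inp = ScoreInput(delta=delta, member_mask=mask)
    ranks = inp.ranks
    gamma = np.abs(delta - delta.mean()) ** k if k != 0 else np.ones_like(delta)
    q, m0 = delta.size, int(mask.sum())

    order = np.argsort(ranks)
    in_sorted = mask[order]
    w_sorted = np.where(in_sorted, gamma[order], 0.0)
    in_cdf = np.cumsum(w_sorted) / w_sorted.sum()
    out_cdf = np.cumsum(~in_sorted) / (q - m0)
    walk = in_cdf - out_cdf

    in_positions = np.flatnonzero(in_sorted)
    walk_at_set = walk[in_positions]
    peak_idx = in_positions[int(np.argmax(np.abs(walk_at_set)))]
    ksmax = compute_score(inp, ScoreSpec("ksmax", ks_exponent=k))

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(np.arange(1, q + 1), walk, color="#2a6f97")
    ax.axhline(0, c="grey", lw=0.5)
    ax.vlines(in_positions + 1, -0.03, 0.0, transform=ax.get_xaxis_transform(),
              color="black", lw=0.5)
    ax.plot(peak_idx + 1, walk[peak_idx], "o", color="#c23b22")
    ax.annotate(f"ksmax = {ksmax:.3f}", (peak_idx + 1, walk[peak_idx]),
                textcoords="offset points", xytext=(8, 5), fontsize=9)
    ax.set_xlabel("gene rank (decreasing statistic)")
    ax.set_ylabel("running KS difference")
    ax.set_title(f"{set_.name}: enrichment walk (k={k:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_effsize_curve(
    curve: EffSizeCurve, path: str | Path = "effsize_curve.png", set_name: str = ""
) -> Path:
    """pval(m) against candidate size m with the point estimate marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.m_grid, curve.pvals, "o-", color="#2a6f97")
    ax.axvline(curve.estimate, ls="--", color="#c23b22",
               label=f"effective size = {curve.estimate}")
    ax.set_ylim(-0.02, 1.05)
    ax.set_xlabel("random set size m")
    ax.set_ylabel("pval(m)")
    title = "effective signature size"
    if set_name:
        title = f"{set_name}: {title}"
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_heatmap(
    expr: ExpressionData,
    set_: GeneSet,
    design: DesignSpec,
    stats: ModeratedStats | None = None,
    path: str | Path = "heatmap.png",
) -> Path:
    """Row-scaled in-set expression, samples annotated by the contrasted
    covariate, genes ordered by moderated t."""
    mask = _mask_for(set_, expr.gene_ids)
    idx = np.flatnonzero(mask)
    if stats is not None:
        idx = idx[np.argsort(-stats.modt[idx])]
    values = expr.values[idx]
    scaled = (values - values.mean(axis=1, keepdims=True)) / (
        values.std(axis=1, keepdims=True) + 1e-12
    )
    group = design.X @ design.contrast

    fig, (ax_grp, ax) = plt.subplots(
        2, 1, figsize=(7, 0.6 + 0.18 * len(idx)), height_ratios=[1, max(len(idx), 2)]
    )
    ax_grp.imshow(group[None, :], aspect="auto", cmap="Greys")
    ax_grp.set_yticks([0])
    ax_grp.set_yticklabels(["group"], fontsize=7)
    ax_grp.set_xticks([])
    im = ax.imshow(scaled, aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_yticks(range(len(idx)))
    ax.set_yticklabels([expr.gene_ids[i] for i in idx], fontsize=6)
    ax.set_xticks(range(expr.n_samples))
    ax.set_xticklabels(expr.sample_ids, fontsize=6, rotation=90)
    fig.colorbar(im, ax=ax, shrink=0.6, label="row z-score")
    ax.set_title(f"{set_.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def html_report(
    results_frame,
    plot_paths: dict[str, dict[str, Path]],
    path: str | Path = "report.html",
    title: str = "rotation GSA report",
) -> Path:
    """Single-file HTML: the results table plus embedded (base64) plots per
    set, keyed ``plot_paths[set_name][plot_kind]``."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{title}</title>",
        "<style>body{font-family:sans-serif;margin:2em} table{border-collapse:"
        "collapse} td,th{border:1px solid #ccc;padding:4px 8px;font-size:13px}"
        "</style></head><body>",
        f"<h1>{title}</h1>",
        results_frame.to_html(index=False, float_format=lambda v: f"{v:.4g}"),
    ]
    for set_name, plots in plot_paths.items():
        parts.append(f"<h2>{set_name}</h2>")
        for kind, p in plots.items():
            data = base64.b64encode(Path(p).read_bytes()).decode()
            parts.append(
                f"<h3>{kind}</h3><img src='data:image/png;base64,{data}' "
                "style='max-width:750px'>"
            )
    parts.append("</body></html>")
    path = Path(path)
    path.write_text("\n".join(parts), encoding="utf-8")
    return path
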