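"""Effective signature size of a gene set.

Correlated genes carry less independent information than their count
suggests: the variance of a set-level summary statistic grows with the
intra-set correlation, as if the set contained fewer independent genes.
The *effective signature size* makes this concrete — it is the number m of
randomly selected genes whose rotation-score variance matches the observed
rotation-score variance ``v_s`` of the testing set.

For every candidate size m, L random sets are drawn from all q measured
genes and scored on the SAME rotations as the testing set; the two-sided
agreement p-value

    pval(m) = 2 * min(p_R(m), 1 - p_R(m)),
    p_R(m)  = (1/L) * sum_l I(v_R(m)^(l) > v_s)

is near 1 when v_s sits in the middle of the random-set variances and near
0 when it is extreme.  The full curve is the primary output; the reported
point estimate is the argmax of the curve (smallest m on ties), a
deliberately least-committal summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rotagsa.scores import ScoreSpec, decreasing_ranks, score_rows

__all__ = [
    "EffSizeCurve",
    "rotation_score_variance",
    "default_m_grid",
    "effective_size_curve",
]


@dataclass(frozen=True)
class EffSizeCurve:
    """pval(m) over a grid of candidate sizes, plus the point estimate."""

    m_grid: np.ndarray
    pvals: np.ndarray
    v_s: float
    L: int
    estimate: int

    def to_dict(self) -> dict:
        return {
            "m_grid": self.m_grid.tolist(),
            "pvals": self.pvals.tolist(),
            "v_s": self.v_s,
            "L": self.L,
            "estimate": self.estimate,
        }


def rotation_score_variance(null_scores: np.ndarray) -> float:
    """Sample variance (n-1 divisor) of the rotation score values."""
    x = np.asarray(null_scores, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 rotation scores")
    return float(np.var(x, ddof=1))


def default_m_grid(m0: int, q: int, n_points: int = 15) -> np.ndarray:
    """About ``n_points`` log-spaced integers from 1 to min(q-1, 4*m0),
    always including m0.  Correlation can only shrink the effective size
    below m0, but headroom above it is kept since the definition does not
    forbid exceeding it."""
    upper = min(q - 1, 4 * m0)
    grid = np.unique(
        np.round(np.geomspace(1, upper, n_points)).astype(int)
    )
    grid = np.unique(np.append(grid, m0))
    return grid[(grid >= 1) & (grid <= upper)]


def _linear_transform(
    gene_stats: np.ndarray, ranks: np.ndarray | None, spec: ScoreSpec
) -> np.ndarray | None:
    """Per-gene transform G such that the set score equals the set-average
    of G's columns, for the scores where one exists (None otherwise)."""
    if spec.name == "meanrank":
        q = ranks.shape[1]
        return ((q + 1) / 2.0 - ranks) / q
    if spec.name not in ("mean", "absmean"):
        return None
    base = np.abs(gene_stats) if spec.name == "absmean" else gene_stats
    if spec.hypothesis == "self-contained":
        return base
    sd = np.std(base, axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("degenerate rotation statistics (zero spread)")
    return (base - base.mean(axis=1, keepdims=True)) / sd


def effective_size_curve(
    gene_stats: np.ndarray,
    target_mask: np.ndarray,
    spec: ScoreSpec,
    m_grid: np.ndarray | None = None,
    L: int = 50,
    seed: int = 0,
    v_s: float | None = None,
) -> EffSizeCurve:
    """Effective-signature-size p-value curve for one testing set.

    Parameters
    ----------
    gene_stats
        (n_rot, q) rotated per-gene statistics retained from the roast run
        (``store_gene_matrix=True``); the random sets are scored on these
        same rotations so their variances are directly comparable.
    target_mask
        Boolean membership of the testing set over the q genes.
    v_s
        Observed rotation-score variance of the testing set; computed here
        from ``gene_stats`` if not supplied.
    """
    if gene_stats is None:
        raise ValueError(
            "rotated gene statistics are required; re-run roast_gsa with "
            "store_gene_matrix=True"
        )
    gene_stats = np.asarray(gene_stats, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool).ravel()
    n_rot, q = gene_stats.shape
    if target_mask.size != q:
        raise ValueError("target mask length does not match gene_stats columns")
    m0 = int(target_mask.sum())
    if L < 20:
        raise ValueError("need L >= 20 random sets per size")
    if m_grid is None:
        m_grid = default_m_grid(m0, q)
    m_grid = np.asarray(sorted(set(int(m) for m in m_grid)))
    if np.any(m_grid < 1) or np.any(m_grid > q):
        raise ValueError("m_grid values must lie in [1, q]")

    needs_ranks = spec.name in ("meanrank", "ksmax", "ksmean")
    ranks = decreasing_ranks(gene_stats) if needs_ranks else None
    if v_s is None:
        v_s = rotation_score_variance(
            score_rows(gene_stats, target_mask, spec, ranks=ranks)
        )

    # mean, absmean and meanrank are set-averages of a per-gene transform,
    # so all L random sets of one size reduce to a single matrix product
    G = _linear_transform(gene_stats, ranks, spec)

    rng = np.random.default_rng(seed)
    pvals = np.empty(m_grid.size)
    for j, m in enumerate(m_grid):
        masks = np.zeros((L, q), dtype=float)
        for l in range(L):
            masks[l, rng.choice(q, size=int(m), replace=False)] = 1.0
        if G is not None:
            set_scores = (G @ masks.T) / m           # (n_rot, L)
            v_r = np.var(set_scores, axis=0, ddof=1)
        else:
            v_r = np.empty(L)
            for l in range(L):
                v_r[l] = rotation_score_variance(
                    score_rows(gene_stats, masks[l] > 0, spec, ranks=ranks)
                )
        p_r = float(np.mean(v_r > v_s))
        pvals[j] = 2.0 * min(p_r, 1.0 - p_r)
    estimate = int(m_grid[int(np.argmax(pvals))])  # argmax -> smallest m on ties
    return EffSizeCurve(
        m_grid=m_grid, pvals=pvals, v_s=float(v_s), L=int(L), estimate=estimate
    )
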