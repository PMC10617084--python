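"""Enrichment score functions for rotation-based gene set analysis.

Seven scalar summaries of the per-gene statistics ``delta_i`` (z-transformed
moderated t by default) over a testing set S of size m0 out of q genes:

========  ===========================  =================================
name      self-contained (SC)          competitive (CO)
========  ===========================  =================================
mean      avg_S delta                  avg_S (delta - mean)/sd
absmean   avg_S |delta|                avg_S (|delta| - mean|.|)/sd|.|
median    med_S delta                  med_S (delta - med)/mad
maxmean   avg_S delta*                 avg_S standardized delta*
meanrank  --                           avg_S ((q+1)/2 - rank_i)/q
ksmax     --                           signed extreme of a weighted KS walk
ksmean    --                           max + min of a weighted KS walk
========  ===========================  =================================

``delta*`` zeroes genes whose sign opposes the sign of the mean score, so
maxmean follows the dominant direction only.  Competitive centering and
scaling always uses all q genes (the set included).  Ranks are taken in
decreasing order of ``delta`` with average-rank ties; the KS running sum is
evaluated at the in-set ranks, where its extremes occur.

All functions accept a single statistic vector or a matrix with one row per
rotation; the matrix form is what the rotation engine uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SCORE_NAMES",
    "DIRECTIONAL_SCORES",
    "COMPETITIVE_ONLY",
    "ScoreSpec",
    "ScoreInput",
    "compute_score",
    "score_rows",
    "score_mean",
    "score_absmean",
    "score_median",
    "score_maxmean",
    "score_meanrank",
    "score_ksmax",
    "score_ksmean",
    "ks_running",
    "decreasing_ranks",
]

SCORE_NAMES = ("mean", "absmean", "median", "maxmean", "meanrank", "ksmax", "ksmean")
#: scores whose sign carries the direction of regulation
DIRECTIONAL_SCORES = ("mean", "median", "maxmean", "meanrank", "ksmax", "ksmean")
#: rank-based scores are defined only against the rest of the genome
COMPETITIVE_ONLY = ("meanrank", "ksmax", "ksmean")

SELF_CONTAINED = "self-contained"
COMPETITIVE = "competitive"


@dataclass(frozen=True)
class ScoreSpec:
    """Which score to compute and under which null.

    ``ks_exponent`` is the weight exponent k of the KS scores (k=0 is the
    classical unweighted KS walk; the default k=1 matches the usual GSEA
    weighting).  ``ksmean_centered_weights`` switches the ksmean weights
    from the half-rank form (2*rank + q + 1)/2 to the centered rank
    (q+1)/2 - rank.
    """

    name: str
    hypothesis: str = COMPETITIVE
    ks_exponent: float = 1.0
    ksmean_centered_weights: bool = False

    def __post_init__(self) -> None:
        if self.name not in SCORE_NAMES:
            raise ValueError(f"unknown score {self.name!r}; choose from {SCORE_NAMES}")
        if self.hypothesis not in (SELF_CONTAINED, COMPETITIVE):
            raise ValueError(
                f"hypothesis must be {SELF_CONTAINED!r} or {COMPETITIVE!r}"
            )
        if self.name in COMPETITIVE_ONLY and self.hypothesis != COMPETITIVE:
            raise ValueError(f"{self.name} is defined for competitive testing only")
        if self.ks_exponent < 0:
            raise ValueError("ks_exponent must be non-negative")

    @property
    def directional(self) -> bool:
        return self.name in DIRECTIONAL_SCORES


def decreasing_ranks(delta: np.ndarray) -> np.ndarray:
    """Ranks of delta in decreasing order (largest gets rank 1), average ties.

    Works row-wise on matrices.
    """
    delta = np.asarray(delta, dtype=float)
    return rankdata(-delta, axis=-1, method="average")


@dataclass(frozen=True)
class ScoreInput:
    """Per-gene statistics plus set membership, ready for scoring."""

    delta: np.ndarray
    member_mask: np.ndarray
    ranks: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float).ravel()
        mask = np.asarray(self.member_mask, dtype=bool).ravel()
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "member_mask", mask)
        if delta.shape != mask.shape:
            raise ValueError("delta and member_mask length mismatch")
        if not np.all(np.isfinite(delta)):
            raise ValueError("non-finite per-gene statistics")
        m0 = int(mask.sum())
        if not 1 <= m0 < delta.size:
            raise ValueError("need 1 <= |S| < q")
        if self.ranks is None:
            object.__setattr__(self, "ranks", decreasing_ranks(delta))
        else:
            object.__setattr__(self, "ranks", np.asarray(self.ranks, float).ravel())

    @property
    def m0(self) -> int:
        return int(self.member_mask.sum())

    @property
    def q(self) -> int:
        return self.delta.size


# ---------------------------------------------------------------------------
# row engine: delta has shape (R, q); one score value per row


def _sd(x: np.ndarray) -> np.ndarray:
    return np.std(x, axis=1, ddof=1)


def _mean_rows(delta: np.ndarray, mask: np.ndarray, hypothesis: str) -> np.ndarray:
    set_mean = delta[:, mask].mean(axis=1)
    if hypothesis == SELF_CONTAINED:
        return set_mean
    sd = _sd(delta)
    if np.any(sd == 0):
        raise ValueError("sd(delta) is zero; competitive centering is degenerate")
    return (set_mean - delta.mean(axis=1)) / sd


def _absmean_rows(delta: np.ndarray, mask: np.ndarray, hypothesis: str) -> np.ndarray:
    a = np.abs(delta)
    set_mean = a[:, mask].mean(axis=1)
    if hypothesis == SELF_CONTAINED:
        return set_mean
    sd = _sd(a)
    if np.any(sd == 0):
        raise ValueError("sd(|delta|) is zero; competitive centering is degenerate")
    return (set_mean - a.mean(axis=1)) / sd


def _median_rows(delta: np.ndarray, mask: np.ndarray, hypothesis: str) -> np.ndarray:
    set_med = np.median(delta[:, mask], axis=1)
    if hypothesis == SELF_CONTAINED:
        return set_med
    med = np.median(delta, axis=1)
    mad = np.median(np.abs(delta - med[:, None]), axis=1)
    if np.any(mad == 0):
        raise ValueError("mad(delta) is zero; competitive centering is degenerate")
    return (set_med - med) / mad


def _maxmean_rows(delta: np.ndarray, mask: np.ndarray, hypothesis: str) -> np.ndarray:
    t_mean = _mean_rows(delta, mask, hypothesis)
    sign = np.sign(t_mean)
    if np.any(sign == 0):
        warnings.warn(
            "mean score is exactly zero; maxmean keeps all genes",
            RuntimeWarning,
            stacklevel=2,
        )
        sign = np.where(sign == 0, np.nan, sign)
    # delta* zeroes genes opposing the dominant direction; delta_i = 0 is
    # inert either way, and sign = nan (mean exactly 0) keeps everything
    keep = (np.sign(delta) == sign[:, None]) | (delta == 0) | np.isnan(sign[:, None])
    dstar = np.where(keep, delta, 0.0)
    set_mean = dstar[:, mask].mean(axis=1)
    if hypothesis == SELF_CONTAINED:
        return set_mean
    sd = _sd(dstar)
    if np.any(sd == 0):
        raise ValueError("sd(delta*) is zero; competitive centering is degenerate")
    return (set_mean - dstar.mean(axis=1)) / sd


def _meanrank_rows(ranks: np.ndarray, mask: np.ndarray) -> np.ndarray:
    q = ranks.shape[1]
    return (((q + 1) / 2.0 - ranks[:, mask]) / q).mean(axis=1)


def _ks_extremes_rows(
    ranks: np.ndarray, mask: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Extremes (A, a) of the KS running difference per row.

    ``ks(l|S)`` is the weighted fraction of in-set genes at rank <= l minus
    the plain fraction of out-of-set genes at rank <= l, evaluated at every
    in-set rank l.
    """
    R, q = ranks.shape
    m0 = int(mask.sum())
    w_in = weights[:, mask]
    if np.any(w_in.sum(axis=1) == 0):
        raise ValueError("all in-set KS weights are zero")
    r_in = ranks[:, mask]
    order = np.argsort(r_in, axis=1, kind="stable")
    l_sorted = np.take_along_axis(r_in, order, axis=1)
    w_sorted = np.take_along_axis(w_in, order, axis=1)
    in_cdf = np.cumsum(w_sorted, axis=1) / w_sorted.sum(axis=1, keepdims=True)

    untied = np.allclose(ranks, np.round(ranks))
    if untied:
        # ranks form the permutation 1..q, so #\{any gene <= l_j\} = l_j and
        # the out-of-set count is l_j minus the j in-set genes seen so far
        j = np.arange(1, m0 + 1)[None, :]
        out_count = l_sorted - j
    else:
        r_out_sorted = np.sort(ranks[:, ~mask], axis=1)
        out_count = (r_out_sorted[:, None, :] <= l_sorted[:, :, None]).sum(axis=2)
    out_cdf = out_count / (q - m0)
    walk = in_cdf - out_cdf
    return walk.max(axis=1), walk.min(axis=1)


def _ksmax_rows(
    delta: np.ndarray, ranks: np.ndarray, mask: np.ndarray, k: float
) -> np.ndarray:
    gamma = delta - delta.mean(axis=1, keepdims=True)
    weights = np.abs(gamma) ** k if k != 0 else np.ones_like(delta)
    A, a = _ks_extremes_rows(ranks, mask, weights)
    return np.where(A > np.abs(a), A, a)


def _ksmean_rows(
    delta: np.ndarray,
    ranks: np.ndarray,
    mask: np.ndarray,
    k: float,
    centered: bool,
) -> np.ndarray:
    q = ranks.shape[1]
    eta = ((q + 1) / 2.0 - ranks) if centered else (2.0 * ranks + q + 1) / 2.0
    weights = np.abs(eta) ** k if k != 0 else np.ones_like(ranks)
    A, a = _ks_extremes_rows(ranks, mask, weights)
    return A + a


def score_rows(
    delta: np.ndarray,
    mask: np.ndarray,
    spec: ScoreSpec,
    ranks: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate one score on every row of a (rotations x genes) matrix.

    ``ranks`` may be passed to share the ranking across several sets or
    score specs computed on the same rows.
    """
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    mask = np.asarray(mask, dtype=bool).ravel()
    if delta.shape[1] != mask.size:
        raise ValueError("delta columns and mask length mismatch")
    name = spec.name
    if name == "mean":
        return _mean_rows(delta, mask, spec.hypothesis)
    if name == "absmean":
        return _absmean_rows(delta, mask, spec.hypothesis)
    if name == "median":
        return _median_rows(delta, mask, spec.hypothesis)
    if name == "maxmean":
        return _maxmean_rows(delta, mask, spec.hypothesis)
    if ranks is None:
        ranks = decreasing_ranks(delta)
    else:
        ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    if name == "meanrank":
        return _meanrank_rows(ranks, mask)
    if name == "ksmax":
        return _ksmax_rows(delta, ranks, mask, spec.ks_exponent)
    if name == "ksmean":
        return _ksmean_rows(
            delta, ranks, mask, spec.ks_exponent, spec.ksmean_centered_weights
        )
    raise ValueError(f"unknown score {name!r}")  # pragma: no cover


def compute_score(inp: ScoreInput, spec: ScoreSpec) -> float:
    """Score a single per-gene statistic vector."""
    return float(
        score_rows(
            inp.delta[None, :], inp.member_mask, spec, ranks=inp.ranks[None, :]
        )[0]
    )


# ---------------------------------------------------------------------------
# spec-level convenience wrappers


def score_mean(inp: ScoreInput, hypothesis: str = SELF_CONTAINED) -> float:
    return compute_score(inp, ScoreSpec("mean", hypothesis))


def score_absmean(inp: ScoreInput, hypothesis: str = SELF_CONTAINED) -> float:
    return compute_score(inp, ScoreSpec("absmean", hypothesis))


def score_median(inp: ScoreInput, hypothesis: str = SELF_CONTAINED) -> float:
    return compute_score(inp, ScoreSpec("median", hypothesis))


def score_maxmean(inp: ScoreInput, hypothesis: str = SELF_CONTAINED) -> float:
    return compute_score(inp, ScoreSpec("maxmean", hypothesis))


def score_meanrank(inp: ScoreInput) -> float:
    return compute_score(inp, ScoreSpec("meanrank"))


def score_ksmax(inp: ScoreInput, k: float = 1.0) -> float:
    return compute_score(inp, ScoreSpec("ksmax", ks_exponent=k))


def score_ksmean(inp: ScoreInput, k: float = 1.0, centered: bool = False) -> float:
    return compute_score(
        inp, ScoreSpec("ksmean", ks_exponent=k, ksmean_centered_weights=centered)
    )


def ks_running(inp: ScoreInput, weights: np.ndarray) -> tuple[float, float]:
    """Extremes (max, min) of the KS walk with caller-supplied weights."""
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape != inp.delta.shape:
        raise ValueError("weights must have one entry per gene")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    A, a = _ks_extremes_rows(
        inp.ranks[None, :], inp.member_mask, weights[None, :]
    )
    return float(A[0]), float(a[0])
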