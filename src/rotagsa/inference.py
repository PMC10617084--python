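"""Rotation GSA inference: observed scores vs the rotation null, battery
testing over a gene set collection, and multiple-testing adjustment.

One call to :func:`roast_gsa` draws a single series of rotations and scores
every retained gene set (and every requested score) on it, so the null is
shared across sets; p-values use the (1 + exceedances) / (n_rot + 1)
convention, making the smallest attainable p equal to 1/(n_rot+1).
Directional scores are tested two-sided by default and annotated with the
direction of the observed score; the non-directional absmean is tested
upper-tail.  Benjamini-Hochberg FDR is computed per score across the
retained sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from rotagsa.io import DesignSpec, ExpressionData, GeneSet, GeneSetCollection
from rotagsa.linmod import ModeratedStats, moderated_t, squeeze_variances, z_transform
from rotagsa.rotation import (
    EffectSpace,
    RotationConfig,
    RotationNull,
    reduce_to_effect_space,
    rotation_gene_stats,
)
from rotagsa.scores import ScoreSpec, decreasing_ranks, score_rows

__all__ = [
    "RoastResult",
    "RoastRun",
    "rotation_pvalue",
    "adjust_fdr",
    "roast_gsa",
    "match_sets",
]

TWO_SIDED = "two-sided"
UPPER = "upper"


@dataclass(frozen=True)
class RoastResult:
    """Outcome for one gene set under one score."""

    set_name: str
    size_total: int
    size_used: int
    score_name: str
    hypothesis: str
    observed: float
    pvalue: float
    fdr: float
    direction: str
    n_rot: int


@dataclass(frozen=True)
class RoastRun:
    """Everything one battery run produced.

    ``results`` is the flat list of per-set outcomes (one entry per set and
    score).  ``rotation_null`` holds the per-rotation score matrix and,
    when requested, the rotated per-gene statistics needed by the
    effective-signature-size diagnostic.  ``stats`` are the observed
    moderated statistics.
    """

    results: tuple[RoastResult, ...]
    rotation_null: RotationNull
    stats: ModeratedStats
    masks: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "set_name": r.set_name,
                    "size_total": r.size_total,
                    "size_used": r.size_used,
                    "score_name": r.score_name,
                    "hypothesis": r.hypothesis,
                    "observed_score": r.observed,
                    "pvalue": r.pvalue,
                    "fdr": r.fdr,
                    "direction": r.direction,
                }
                for r in self.results
            ]
        )

    def null_scores(self, set_name: str, score_name: str | None = None) -> np.ndarray:
        names = list(self.rotation_null.set_names)
        key = set_name if score_name is None else f"{score_name}:{set_name}"
        return self.rotation_null.scores[:, names.index(key)]


def rotation_pvalue(
    observed: float, null_scores: np.ndarray, sidedness: str = TWO_SIDED
) -> float:
    """Resampling p-value of the observed score against rotation scores.

    two-sided: (1 + #\\{|T_r| >= |T_obs|\\}) / (n_rot + 1); upper uses the
    raw values.  The +1 makes the p-value exactly valid and never zero.
    """
    null_scores = np.asarray(null_scores, dtype=float).ravel()
    if null_scores.size < 1:
        raise ValueError("need at least one rotation score")
    if not np.isfinite(observed) or not np.all(np.isfinite(null_scores)):
        raise ValueError("non-finite scores")
    if sidedness == TWO_SIDED:
        count = int(np.sum(np.abs(null_scores) >= abs(observed)))
    elif sidedness == UPPER:
        count = int(np.sum(null_scores >= observed))
    else:
        raise ValueError(f"sidedness must be {TWO_SIDED!r} or {UPPER!r}")
    return (1 + count) / (null_scores.size + 1)


def adjust_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def match_sets(
    sets: GeneSetCollection | Sequence[GeneSet],
    gene_ids: Sequence[str],
    min_set_size: int = 5,
    max_set_size: int = 500,
    case_insensitive: bool = False,
) -> dict[str, np.ndarray]:
    """Boolean membership masks over the expression rows for each retained
    set.  Sets overlapping fewer than ``min_set_size`` or more than
    ``max_set_size`` measured genes are dropped with a warning.  Matching
    is exact string equality; ``case_insensitive`` folds case on both
    sides.
    """
    fold = (lambda s: s.lower()) if case_insensitive else (lambda s: s)
    index = {fold(g): i for i, g in enumerate(gene_ids)}
    q = len(gene_ids)
    masks: dict[str, np.ndarray] = {}
    for s in sets:
        idx = [index[fold(g)] for g in s.genes if fold(g) in index]
        used = len(set(idx))
        if used < min_set_size or used > max_set_size:
            warnings.warn(
                f"gene set {s.name!r}: {used} of {len(s.genes)} genes measured, "
                f"outside [{min_set_size}, {max_set_size}]; dropped",
                UserWarning,
                stacklevel=2,
            )
            continue
        mask = np.zeros(q, dtype=bool)
        mask[idx] = True
        masks[s.name] = mask
    return masks


def _default_sidedness(spec: ScoreSpec) -> str:
    return TWO_SIDED if spec.directional else UPPER


def _direction(spec: ScoreSpec, observed: float) -> str:
    if not spec.directional:
        return "mixed"
    if observed > 0:
        return "up"
    if observed < 0:
        return "down"
    return "mixed"


def _observed_moderated(
    reduced: EffectSpace,
) -> tuple[ModeratedStats, tuple[float, float]]:
    d = reduced.df_residual
    s2 = reduced.s2
    if np.allclose(s2, 0):
        raise ValueError("all residual variances are zero; model is saturated")
    d0, s2_prior, s2_post = squeeze_variances(s2, d)
    modt = moderated_t(reduced.effect, s2_post, reduced.stdev_unscaled)
    z = z_transform(modt, d + d0)
    stats = ModeratedStats(
        effect=reduced.effect,
        stdev_unscaled=reduced.stdev_unscaled,
        s2=s2,
        df_residual=d,
        df_prior=d0,
        s2_prior=s2_prior,
        s2_post=s2_post,
        modt=modt,
        z=z,
    )
    return stats, (d0, s2_prior)


def roast_gsa(
    expr: ExpressionData,
    design: DesignSpec,
    sets: GeneSetCollection | Sequence[GeneSet] | GeneSet,
    spec: ScoreSpec | Sequence[ScoreSpec] = ScoreSpec("mean"),
    config: RotationConfig = RotationConfig(),
    use_z: bool = True,
    min_set_size: int = 5,
    max_set_size: int = 500,
    alternative: str | None = None,
    case_insensitive: bool = False,
) -> RoastRun:
    """Battery rotation GSA over a collection.

    Parameters
    ----------
    spec
        One :class:`~rotagsa.scores.ScoreSpec` or several; all scores are
        evaluated on the same rotations.
    use_z
        Score the z-transformed moderated t (default) rather than the raw
        moderated t.
    alternative
        Force "two-sided" or "upper" testing for every score instead of
        the per-score default.

    Returns a :class:`RoastRun`; results are deterministic given
    ``config.seed``.
    """
    if isinstance(sets, GeneSet):
        sets = [sets]
    specs = [spec] if isinstance(spec, ScoreSpec) else list(spec)
    if not specs:
        raise ValueError("no score specified")
    set_list = list(sets)
    sizes_total = {s.name: len(s.genes) for s in set_list}
    masks = match_sets(
        set_list,
        expr.gene_ids,
        min_set_size=min_set_size,
        max_set_size=max_set_size,
        case_insensitive=case_insensitive,
    )
    if not masks:
        raise ValueError("no gene set retained after matching to the data")

    reduced = reduce_to_effect_space(expr, design)
    stats, prior = _observed_moderated(reduced)
    delta_obs = stats.z if use_z else stats.modt
    rng = np.random.default_rng(config.seed)
    gene_stats = rotation_gene_stats(
        reduced, prior[0], prior[1], config, use_z=use_z, rng=rng
    )

    needs_ranks = any(s.name in ("meanrank", "ksmax", "ksmean") for s in specs)
    ranks_obs = decreasing_ranks(delta_obs)[None, :] if needs_ranks else None
    ranks_rot = decreasing_ranks(gene_stats) if needs_ranks else None

    results: list[RoastResult] = []
    null_columns: list[np.ndarray] = []
    null_names: list[str] = []
    multi = len(specs) > 1
    for sp in specs:
        side = alternative or _default_sidedness(sp)
        per_spec: list[RoastResult] = []
        for name, mask in masks.items():
            obs = float(
                score_rows(delta_obs[None, :], mask, sp, ranks=ranks_obs)[0]
            )
            null = score_rows(gene_stats, mask, sp, ranks=ranks_rot)
            pval = rotation_pvalue(obs, null, side)
            per_spec.append(
                RoastResult(
                    set_name=name,
                    size_total=sizes_total[name],
                    size_used=int(mask.sum()),
                    score_name=sp.name,
                    hypothesis=sp.hypothesis,
                    observed=obs,
                    pvalue=pval,
                    fdr=np.nan,
                    direction=_direction(sp, obs),
                    n_rot=config.n_rot,
                )
            )
            null_columns.append(null)
            null_names.append(f"{sp.name}:{name}" if multi else name)
        fdr = adjust_fdr([r.pvalue for r in per_spec])
        for i, r in enumerate(per_spec):
            results.append(
                RoastResult(**{**r.__dict__, "fdr": float(fdr[i])})
            )

    null = RotationNull(
        scores=np.column_stack(null_columns),
        seed=config.seed,
        set_names=tuple(null_names),
        gene_stats=gene_stats if config.store_gene_matrix else None,
    )
    return RoastRun(
        results=tuple(results), rotation_null=null, stats=stats, masks=masks
    )
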