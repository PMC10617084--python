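"""Evaluation machinery: recovery rates over simulation instances, and
weighted-rank benchmark measures M1/M2 with a permutation p-value.

``recovery_rate`` is the fraction of simulation instances rejected at a
significance level alpha — under the null scenario it estimates the
empirical size of the test, under signal scenarios its power.

M1 compares a GSA ranking (1 = most significant of p sets) to non-negative
relevance scores rho:

    M1 = sum_i rho_i * (1 - I(i)/p)

and M2 is the same sum restricted to sets ranked in the top ``cutoff``
(default 50), down-weighting the bottom of the ranking.  The permutation
p-value is the fraction of random rankings whose M1 strictly exceeds the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rotagsa.inference import roast_gsa
from rotagsa.rotation import RotationConfig
from rotagsa.scores import ScoreSpec
from rotagsa.synthetic_data import ScenarioSampler, ScenarioSpec

__all__ = [
    "BenchmarkRanking",
    "recovery_rate",
    "m1_measure",
    "m2_measure",
    "ranking_permutation_pvalue",
    "rank_methods",
    "simulate_pvalues",
    "recovery_sweep",
]


@dataclass(frozen=True)
class BenchmarkRanking:
    """Relevance scores rho_i >= 0 paired with GSA outcome ranks I(i)
    (a permutation of 1..p, 1 = most significant)."""

    relevance: np.ndarray
    rank_index: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.relevance, dtype=float).ravel()
        I = np.asarray(self.rank_index, dtype=int).ravel()
        object.__setattr__(self, "relevance", rho)
        object.__setattr__(self, "rank_index", I)
        if rho.shape != I.shape:
            raise ValueError("relevance and rank_index length mismatch")
        if np.any(rho < 0):
            raise ValueError("relevance scores must be non-negative")
        if sorted(I) != list(range(1, I.size + 1)):
            raise ValueError("rank_index must be a permutation of 1..p")

    @property
    def p(self) -> int:
        return self.relevance.size


def recovery_rate(pvalues: Sequence[float], alpha: float = 0.05) -> float:
    """Fraction of instances with p <= alpha."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.mean(p <= alpha))


def m1_measure(b: BenchmarkRanking) -> float:
    """Weighted-rank agreement over all sets."""
    return float(np.sum(b.relevance * (1.0 - b.rank_index / b.p)))


def m2_measure(b: BenchmarkRanking, cutoff: int = 50) -> float:
    """M1 restricted to sets ranked within the top ``cutoff``."""
    top = b.rank_index <= cutoff
    return float(np.sum(b.relevance[top] * (1.0 - b.rank_index[top] / b.p)))


def ranking_permutation_pvalue(
    b: BenchmarkRanking,
    n_perm: int = 1000,
    seed: int = 0,
    plus_one: bool = False,
) -> float:
    """Probability of a random ranking beating the observed M1.

    Counts permutations whose M1 strictly exceeds the observed value (ties
    count as non-exceedances); ``plus_one`` switches to the
    (1 + count)/(n_perm + 1) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = m1_measure(b)
    count = 0
    for _ in range(n_perm):
        perm = BenchmarkRanking(b.relevance, rng.permutation(b.p) + 1)
        if obs < m1_measure(perm):
            count += 1
    if plus_one:
        return (1 + count) / (n_perm + 1)
    return count / n_perm


def rank_methods(measures: pd.DataFrame) -> pd.DataFrame:
    """Rank methods (columns) per dataset (rows) by an M1/M2 table:
    1 = best (largest measure)."""
    return measures.rank(axis=1, ascending=False, method="min").astype(int)


# ---------------------------------------------------------------------------
# simulation sweeps


def simulate_pvalues(
    spec: ScenarioSpec,
    score_specs: Sequence[ScoreSpec],
    n_instances: int = 200,
    n_rot: int = 500,
    use_z: bool = True,
) -> pd.DataFrame:
    """p-values of the target set over independent scenario instances.

    Returns a (n_instances x scores) table; each instance draws fresh
    expression and fresh rotations, all scores sharing the rotations
    within an instance.
    """
    sampler = ScenarioSampler(spec)
    seeds = np.random.default_rng(spec.seed).integers(0, 2**31 - 1, n_instances)
    rows = []
    for inst in range(n_instances):
        ds = sampler.draw()
        run = roast_gsa(
            ds.expr,
            ds.design,
            ds.target_set,
            spec=list(score_specs),
            config=RotationConfig(n_rot=n_rot, seed=int(seeds[inst])),
            use_z=use_z,
        )
        rows.append({r.score_name: r.pvalue for r in run.results})
    return pd.DataFrame(rows, columns=[s.name for s in score_specs])


def recovery_sweep(
    scenarios: Sequence[ScenarioSpec],
    score_specs: Sequence[ScoreSpec],
    n_instances: int = 200,
    n_rot: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Recovery-rate table over scenarios x scores.

    One row per (scenario, n, score) combination with the proportion of
    instances rejected at ``alpha``.
    """
    out = []
    for sc in scenarios:
        pvals = simulate_pvalues(sc, score_specs, n_instances, n_rot)
        for name in pvals.columns:
            out.append(
                {
                    "scenario": sc.scenario,
                    "n": sc.n,
                    "rho_within": sc.rho_within,
                    "effect_size": sc.effect_size,
                    "score_name": name,
                    "alpha": alpha,
                    "n_instances": n_instances,
                    "recovery": recovery_rate(pvals[name], alpha),
                }
            )
    return pd.DataFrame(out)
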