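"""The rotation null for gene set analysis.

The rotation (roast) test works in the space spanned by the contrast of
interest and the residuals of the fitted linear model.  For each gene g the
data reduce to a (d+1)-vector

    t_g = (u_g, r_g1, ..., r_gd),     d = n - p,

where ``u_g = effect_g / stdev_unscaled`` is the scaled contrast estimate
(variance sigma_g^2 under the model) and ``r_g`` are the residual
coordinates in a fixed orthonormal basis (``||r_g||^2 = RSS_g``).  Under
the null, t_g is spherically symmetric, so pre-multiplying every gene's
t_g by one shared random orthogonal matrix yields a new, equally likely
data set *with the gene-gene correlation structure intact*.  Re-computing
the moderated statistics on each rotated data set gives the empirical null
of any enrichment score, valid even at very small sample sizes.

The prior parameters (d0, s0^2) of the variance shrinkage and the z-score
degrees of freedom are estimated once on the observed data and held fixed
across rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from rotagsa.io import DesignSpec, ExpressionData
from rotagsa.linmod import squeeze_variances, z_transform

__all__ = [
    "RotationConfig",
    "RotationNull",
    "EffectSpace",
    "reduce_to_effect_space",
    "draw_rotation",
    "rotation_gene_stats",
    "rotate_and_score",
]


@dataclass(frozen=True)
class RotationConfig:
    """How many rotations to draw, with which seed.

    500 rotations give p-value granularity 1/501; ``store_gene_matrix``
    keeps the full (n_rot x q) matrix of rotated per-gene statistics for
    the effective-signature-size diagnostic.
    """

    n_rot: int = 500
    seed: int = 0
    store_gene_matrix: bool = False

    def __post_init__(self) -> None:
        if self.n_rot < 1:
            raise ValueError("n_rot must be >= 1")


@dataclass(frozen=True)
class RotationNull:
    """Per-rotation score values (n_rot x n_sets) defining the empirical
    null, plus optionally the rotated per-gene statistics."""

    scores: np.ndarray
    seed: int
    set_names: tuple[str, ...] = ()
    gene_stats: np.ndarray | None = None

    @property
    def n_rot(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class EffectSpace:
    """Reduced representation of the data for rotation.

    ``components`` is (q, d+1): column 0 the scaled effect u_g, the rest
    the residual coordinates.  The same orthonormal basis is used for all
    genes, preserving gene-gene correlation.
    """

    components: np.ndarray
    stdev_unscaled: float
    df_residual: int

    @property
    def n_genes(self) -> int:
        return self.components.shape[0]

    @property
    def u(self) -> np.ndarray:
        return self.components[:, 0]

    @property
    def effect(self) -> np.ndarray:
        return self.u * self.stdev_unscaled

    @property
    def s2(self) -> np.ndarray:
        return np.sum(self.components[:, 1:] ** 2, axis=1) / self.df_residual

    @property
    def norm2(self) -> np.ndarray:
        return np.sum(self.components**2, axis=1)


def reduce_to_effect_space(
    expr: ExpressionData | np.ndarray, design: DesignSpec
) -> EffectSpace:
    """Project every gene onto the contrast direction plus residual space.

    The design is re-parameterized so the contrast of interest becomes the
    last coefficient; the full QR of that design then splits each gene's
    sample vector into p fitted coordinates (the last being the scaled
    effect) and d = n - p residual coordinates.
    """
    Y = expr.values if isinstance(expr, ExpressionData) else np.atleast_2d(expr)
    X, c = design.X, design.contrast
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"expression has {Y.shape[1]} samples, design has {n}")
    d = n - p
    if d < 1:
        raise ValueError("no residual degrees of freedom")
    cnorm = float(np.linalg.norm(c))
    # orthogonal change of coefficients putting the contrast first ...
    Qc, Rc = np.linalg.qr(c.reshape(p, 1), mode="complete")
    if Rc[0, 0] < 0:
        Qc = -Qc
    Xt = X @ Qc
    # ... then reorder so it is the LAST fitted coordinate in the QR
    Xstar = np.column_stack([Xt[:, 1:], Xt[:, 0]])
    Q, R = np.linalg.qr(Xstar, mode="complete")
    rpp = R[p - 1, p - 1]
    if abs(rpp) < 1e-12:
        raise ValueError("contrast not estimable from the design")
    QtY = Q.T @ Y.T                                  # (n, q)
    u = np.sign(rpp) * QtY[p - 1, :]
    components = np.column_stack([u, QtY[p:, :].T])  # (q, d+1)
    stdev_unscaled = cnorm / abs(rpp)
    return EffectSpace(
        components=components, stdev_unscaled=stdev_unscaled, df_residual=d
    )


def draw_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    """One Haar-distributed random orthogonal matrix of size dim x dim.

    QR of a standard normal matrix with the sign of R's diagonal forced
    positive; without the sign correction plain QR is not Haar.
    """
    if dim < 2:
        raise ValueError("rotation dimension must be >= 2")
    A = rng.standard_normal((dim, dim))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))[None, :]


def _first_rows(dim: int, n_rot: int, rng: np.random.Generator) -> np.ndarray:
    """First rows of n_rot independent Haar rotations (uniform on the
    unit sphere); only the first row is needed to recover the rotated
    effect, and the rotated residual variance follows from norm
    conservation."""
    W = np.empty((n_rot, dim))
    for r in range(n_rot):
        W[r] = draw_rotation(dim, rng)[0]
    return W


def rotation_gene_stats(
    reduced: EffectSpace,
    df_prior: float,
    s2_prior: float,
    config: RotationConfig,
    use_z: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rotated per-gene moderated statistics, one row per rotation.

    Each rotation applies one shared orthogonal matrix to every gene's
    (d+1)-vector; the rotated effect is the first coordinate, the rotated
    residual variance follows from ``||t_g||^2`` conservation, and the
    moderated t / z is recomputed with the FIXED observed-data prior
    (df_prior, s2_prior).
    """
    d = reduced.df_residual
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W = _first_rows(d + 1, config.n_rot, rng)
    u_rot = W @ reduced.components.T                 # (n_rot, q)
    s2_rot = (reduced.norm2[None, :] - u_rot**2) / d
    s2_rot = np.maximum(s2_rot, 0.0)                 # guard fp round-off
    if np.isfinite(df_prior):
        s2_post = (df_prior * s2_prior + d * s2_rot) / (df_prior + d)
        df_total = d + df_prior
    else:
        s2_post = np.full_like(s2_rot, s2_prior)
        df_total = np.inf
    if np.any(s2_post <= 0):
        raise ValueError(
            "zero posterior variance under rotation; prior fit is degenerate"
        )
    modt = u_rot / np.sqrt(s2_post)
    return z_transform(modt, df_total) if use_z else modt


def rotate_and_score(
    reduced: EffectSpace,
    linfo: tuple[float, float] | None,
    config: RotationConfig,
    score_fn: Callable[[np.ndarray], float | np.ndarray],
    use_z: bool = True,
    set_names: Sequence[str] = (),
) -> RotationNull:
    """Evaluate ``score_fn`` on the per-gene statistic vector of every
    rotation.

    ``linfo`` is the frozen prior ``(df_prior, s2_prior)``; if None it is
    estimated here from the observed residual variances.  ``score_fn``
    receives one per-gene vector (length q) and returns a scalar or a
    vector of per-set scores.
    """
    if linfo is None:
        linfo = squeeze_variances(reduced.s2, reduced.df_residual)[:2]
    df_prior, s2_prior = linfo
    gene_stats = rotation_gene_stats(
        reduced, df_prior, s2_prior, config, use_z=use_z
    )
    rows = []
    for r in range(config.n_rot):
        try:
            rows.append(np.atleast_1d(score_fn(gene_stats[r])))
        except Exception as exc:
            raise RuntimeError(f"score function failed on rotation {r}") from exc
    scores = np.vstack(rows)
    return RotationNull(
        scores=scores,
        seed=config.seed,
        set_names=tuple(set_names),
        gene_stats=gene_stats if config.store_gene_matrix else None,
    )
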