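"""Per-gene linear models with empirical-Bayes moderated t-statistics.

Each gene g is fit by ordinary least squares through one shared QR
decomposition of the design, giving a contrast estimate ``effect_g`` and a
residual variance ``s2_g`` on ``d = n - p`` degrees of freedom.  The
residual variances are then shrunk towards a common prior: a scaled
F-distribution is fitted to the sample variances by matching the first two
moments of ``log s2`` (digamma/trigamma inversion), yielding prior degrees
of freedom ``d0`` and prior variance ``s0^2``.  The posterior variance is
the precision-weighted average

    s2_post_g = (d0 * s0^2 + d * s2_g) / (d0 + d),

and the moderated t-statistic ``effect_g / (sqrt(s2_post_g) * sqrt(v))``
has d + d0 degrees of freedom (v = c'(X'X)^{-1}c is the contrast variance
factor).  Moderated t-values are mapped to z-scores through the Student-t
CDF and the normal quantile; the z-scale is preferable for the enrichment
scores downstream when the residual degrees of freedom are small and the t
distribution heavy-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import digamma, polygamma

from rotagsa.io import DesignSpec, ExpressionData

__all__ = [
    "ModeratedStats",
    "fit_qr",
    "squeeze_variances",
    "moderated_t",
    "z_transform",
    "moderated_stats",
    "trigamma_inverse",
]

#: prior df above this value are reported as infinite (variances pooled)
D0_CAP = 1e7


@dataclass(frozen=True)
class ModeratedStats:
    """Per-gene moderated statistics for one contrast.

    ``z`` is the z-transformed moderated t — the per-gene statistic all
    enrichment scores consume by default.
    """

    effect: np.ndarray
    stdev_unscaled: float
    s2: np.ndarray
    df_residual: float
    df_prior: float
    s2_prior: float
    s2_post: np.ndarray
    modt: np.ndarray
    z: np.ndarray

    @property
    def df_total(self) -> float:
        return self.df_residual + self.df_prior


def fit_qr(
    expr: ExpressionData | np.ndarray, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least-squares fit of every gene against the shared design via QR.

    Returns ``(effect, s2, stdev_unscaled, df_residual)`` where
    ``effect_g = c' beta_hat_g``, ``s2_g = RSS_g / (n - p)`` and
    ``stdev_unscaled = sqrt(c'(X'X)^{-1}c)``.
    """
    Y = expr.values if isinstance(expr, ExpressionData) else np.atleast_2d(expr)
    X, c = design.X, design.contrast
    n, p = X.shape
    if Y.shape[1] != n:
        raise ValueError(f"expression has {Y.shape[1]} samples, design has {n}")
    Q, R = np.linalg.qr(X, mode="reduced")
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise ValueError("design matrix is (numerically) rank deficient")
    QtY = Q.T @ Y.T                       # (p, q)
    beta = np.linalg.solve(R, QtY)        # (p, q)
    fitted = X @ beta
    rss = np.sum((Y.T - fitted) ** 2, axis=0)
    d = n - p
    s2 = rss / d
    effect = c @ beta
    XtX_inv_c = np.linalg.solve(R.T @ R, c)
    stdev_unscaled = float(np.sqrt(c @ XtX_inv_c))
    return np.asarray(effect, float), np.asarray(s2, float), stdev_unscaled, d


def trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the monotone decrease of trigamma and the asymptotic start
    ``y ~ 1/x`` for small x, ``y ~ 1/sqrt(x)`` near zero argument.
    Tolerance 1e-8, at most 50 iterations.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if np.max(-dif / y) < 1e-8:
            break
    return y


def squeeze_variances(
    s2: np.ndarray, df_residual: float
) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of sample variances.

    Fits a scaled F prior to ``s2`` by matching mean and variance of
    ``log s2`` to the log-F distribution, then returns
    ``(df_prior, s2_prior, s2_post)`` with posterior variances
    ``(d0*s0^2 + d*s2) / (d0 + d)``.  Genes with ``s2 == 0`` are excluded
    from the prior fit and given posterior ``d0*s0^2/(d0+d)``.  When the
    moment match yields a non-positive excess variance the prior df is
    infinite and all posteriors equal ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    d = float(df_residual)
    if s2.ndim != 1 or s2.size < 2:
        raise ValueError("need a vector of at least 2 sample variances")
    if np.any(s2 < 0):
        raise ValueError("sample variances must be non-negative")
    positive = s2 > 0
    if not np.any(positive):
        raise ValueError("all sample variances are zero; cannot fit a prior")

    x = s2[positive]
    # log s2 = log s0^2 + log(chi2_d/d) + log(chi2_d0/d0)^{-1} under the
    # scaled-F model; digamma/trigamma give its exact mean and variance.
    e = np.log(x) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if x.size > 1 else 0.0
    excess = e_var - float(polygamma(1, d / 2.0))
    if excess > 0:
        d0 = float(2.0 * trigamma_inverse(excess)[0])
        if d0 > D0_CAP:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isfinite(d0):
        s2_prior = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s2_prior + d * s2) / (d0 + d)
    else:
        # point-mass prior: all variances equal s0^2; the arithmetic mean
        # is the natural (unbiased) estimate since E[s2] = s0^2
        s2_prior = float(np.mean(x))
        s2_post = np.full_like(s2, s2_prior)
    return d0, s2_prior, s2_post


def moderated_t(
    effect: np.ndarray, s2_post: np.ndarray, stdev_unscaled: float
) -> np.ndarray:
    """Moderated t: contrast estimate over its posterior standard error."""
    effect = np.asarray(effect, float)
    s2_post = np.asarray(s2_post, float)
    if np.any(s2_post <= 0):
        bad = np.flatnonzero(s2_post <= 0)
        raise ValueError(
            f"zero posterior variance for gene indices {bad.tolist()[:10]}"
        )
    return effect / (np.sqrt(s2_post) * stdev_unscaled)


def z_transform(modt: np.ndarray, df_total: float) -> np.ndarray:
    """Map t-statistics to z-scores: z = Phi^{-1}(F_t(t; df)).

    Monotone in ``modt`` and exact at the median (t=0 -> z=0).  With
    infinite df the map is the identity.  Computed tail-symmetrically to
    stay accurate for large |t|.
    """
    modt = np.asarray(modt, dtype=float)
    if not np.all(np.isfinite(modt)):
        raise ValueError("non-finite moderated t-statistics")
    if not df_total > 0:
        raise ValueError("df_total must be positive")
    if np.isinf(df_total):
        return modt.copy()
    # work on |t| through the upper tail: sf keeps precision where cdf loses it
    tail = stats.t.sf(np.abs(modt), df_total)
    z = stats.norm.isf(tail) * np.sign(modt)
    z[modt == 0] = 0.0
    return z


def moderated_stats(
    expr: ExpressionData | np.ndarray, design: DesignSpec
) -> ModeratedStats:
    """Full pipeline: QR fit, variance shrinkage, moderated t, z-scores."""
    effect, s2, stdev_unscaled, d = fit_qr(expr, design)
    if np.allclose(s2, 0):
        raise ValueError("all residual variances are zero; model is saturated")
    d0, s2_prior, s2_post = squeeze_variances(s2, d)
    modt = moderated_t(effect, s2_post, stdev_unscaled)
    df_total = d + d0
    z = z_transform(modt, df_total)
    return ModeratedStats(
        effect=effect,
        stdev_unscaled=stdev_unscaled,
        s2=s2,
        df_residual=d,
        df_prior=d0,
        s2_prior=s2_prior,
        s2_post=s2_post,
        modt=modt,
        z=z,
    )
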