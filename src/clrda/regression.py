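"""CLR transform and per-taxon ordinary-least-squares regression.

The centered log-ratio (CLR) transform maps each sample's positive vector
to logs centered on the sample's log geometric mean, so per-sample CLR
values sum to zero and only ratio information is retained.  Regressing the
CLR value of taxon *i* on the covariate of interest ``u`` (plus intercept
and adjusters) estimates ``alpha_i - mean(alpha)``: each coefficient is
shifted by a common compositional bias that is removed downstream.

The design matrix has the covariate of interest in the FIRST column, the
intercept second, and adjusters after, so that the design scalar ``rho_hat``
is the (1,1) element of ``(Z'Z / n)^{-1}`` and the variance of the ``u``
coefficient is ``rho_hat * sigma2 / n``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import SampleFrame, ValidationError


@dataclass
class ClrMatrix:
    """CLR-transformed values, taxa as rows; columns sum to zero."""

    W: np.ndarray


def clr_transform(P: np.ndarray) -> ClrMatrix:
    """Centered log-ratio transform of a strictly positive matrix.

    ``W[i, s] = log P[i, s] - mean_j log P[j, s]``.  Multiplying a sample's
    column by any positive constant leaves its CLR column unchanged, so
    counts and proportions give identical results.
    """
    P = np.asarray(P, dtype=float)
    if (P <= 0).any() or not np.isfinite(P).all():
        raise ValueError("CLR requires strictly positive finite entries")
    logP = np.log(P)
    return ClrMatrix(logP - logP.mean(axis=0, keepdims=True))


@dataclass
class DesignInfo:
    """Fixed-effects design shared by all taxa."""

    Z: np.ndarray  # n x (d + 2), columns (u, 1, c_1..c_d)
    names: list[str]
    n: int
    d: int
    rho_hat: float
    df: int


def build_design(sf: SampleFrame) -> DesignInfo:
    """Build the shared design matrix with columns ``(u, 1, adjusters)``."""
    n, d = sf.n, sf.d
    if n <= d + 2:
        raise ValidationError(f"need n > d + 2 samples (n={n}, d={d})")
    Z = np.column_stack([sf.u, np.ones(n), sf.covariates.to_numpy(dtype=float)]) \
        if d else np.column_stack([sf.u, np.ones(n)])
    names = [sf.var_name, "intercept", *map(str, sf.covariates.columns)]
    p = d + 2
    if np.ptp(sf.u) == 0:
        raise ValidationError(f"covariate of interest {sf.var_name!r} is constant")
    sv = np.linalg.svd(Z, compute_uv=False)
    if sv[-1] <= max(Z.shape) * np.finfo(float).eps * sv[0]:
        raise ValidationError(
            f"design matrix is rank deficient; check for collinear columns among {names}"
        )
    rho_hat = float(np.linalg.inv(Z.T @ Z / n)[0, 0])
    return DesignInfo(Z=Z, names=names, n=n, d=d, rho_hat=rho_hat, df=n - d - 2)


@dataclass
class OlsFit:
    """Per-taxon OLS estimates on the CLR scale (shared design)."""

    alpha_tilde: np.ndarray  # coefficient of u; estimates alpha_i - mean(alpha)
    beta_tilde: np.ndarray   # (m, d+1) intercept + adjuster coefficients
    sigma2_hat: np.ndarray   # residual variance, divisor n - d - 2
    se_tilde: np.ndarray     # sqrt(rho_hat * sigma2_hat / n)
    df: int


def fit_all_taxa(W: ClrMatrix, di: DesignInfo) -> OlsFit:
    """One numerically stable least-squares solve shared across all taxa."""
    Wm = W.W
    if Wm.shape[1] != di.n:
        raise ValueError(f"CLR matrix has {Wm.shape[1]} samples, design has {di.n}")
    coef, _, _, _ = np.linalg.lstsq(di.Z, Wm.T, rcond=None)  # (p, m)
    resid = Wm.T - di.Z @ coef
    rss = np.einsum("sm,sm->m", resid, resid)
    sigma2 = rss / di.df
    se = np.sqrt(di.rho_hat * sigma2 / di.n)
    return OlsFit(
        alpha_tilde=coef[0].copy(),
        beta_tilde=coef[1:].T.copy(),
        sigma2_hat=sigma2,
        se_tilde=se,
        df=di.df,
    )


def estimator_covariance(sigma2: np.ndarray, di: DesignInfo) -> np.ndarray:
    """Closed-form conditional covariance of the ``u`` coefficients.

    With per-taxon error variances ``sigma2`` in the underlying log-linear
    model, the CLR-induced covariance of the coefficient estimators is

    ``var  = rho/n * 1/m * {(m-2) s_i^2 + mean(s^2)}``
    ``cov  = rho/n * 1/m * {-(s_i^2 + s_j^2) + mean(s^2)}``  (i != j).

    Used by diagnostics and the test suite, not by the pipeline itself.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    m = sigma2.size
    if m < 2:
        raise ValueError("need at least 2 taxa")
    if (sigma2 <= 0).any():
        raise ValueError("variances must be positive")
    mean_s2 = sigma2.mean()
    scale = di.rho_hat / (di.n * m)
    cov = scale * (-(sigma2[:, None] + sigma2[None, :]) + mean_s2)
    np.fill_diagonal(cov, scale * ((m - 2) * sigma2 + mean_s2))
    return cov
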