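"""Regression engines shared across the pipeline.

Two fitters live here:

* a batched gamma-family GLM with logit link, fit by iteratively reweighted
  least squares (IRLS).  The response is a (0,1)-bounded density, the
  variance function is V(mu) = mu^2 and the mean is mu = expit(X beta).
  Batching solves many responses sharing one design matrix in a single
  vectorised loop, which is what makes 1000-permutation refits affordable;

* empirical-Bayes variance moderation for ordinary least squares fits
  (shrinking per-feature residual variances toward a pooled inverse-gamma
  prior whose parameters come from a method-of-moments fit on log s^2),
  yielding moderated t-statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

_EPS = 1e-6


def guard_unit_interval(y: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Clip a proportion-like response into (eps, 1 - eps) for the logit link."""
    return np.clip(y, eps, 1.0 - eps)


@dataclass
class GammaLogitFit:
    coef: np.ndarray        # (batch, p)
    se: np.ndarray          # (batch, p)
    pvalues: np.ndarray     # (batch, p) Wald, normal reference
    dispersion: np.ndarray  # (batch,)
    converged: np.ndarray   # (batch,) bool
    loglik: np.ndarray      # (batch,)


def gamma_logit_irls(
    X: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    squeeze_dispersion: bool = False,
) -> GammaLogitFit:
    """Fit gamma/logit GLMs for each row of ``Y`` against the shared ``X``.

    Y must already be guarded into (0, 1).  Returns Wald p-values against the
    standard normal (matching the usual GLM large-sample test), a Pearson
    dispersion estimate, and a gamma log-likelihood evaluated at the fitted
    means with shape 1/dispersion (used for AICc model ranking).
    ``squeeze_dispersion`` shrinks the per-row Pearson dispersions toward a
    pooled prior (empirical Bayes, as for OLS variances); rows whose
    residuals happen to be near zero then cannot produce arbitrarily large
    Wald statistics — used by the batched differential-correlation fits
    where thousands of permuted refits would otherwise generate an extreme
    null tail.  Non-converged rows are flagged; their p-values are NaN.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = Y.shape
    p = X.shape[1]

    def link_inv(eta):
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        return np.clip(mu, 1e-9, 1 - 1e-9)

    def deviance(mu):
        # gamma deviance: 2 sum(-log(y/mu) + (y - mu)/mu)
        r = Y / mu
        return 2.0 * (-np.log(r) + r - 1.0).sum(axis=1)

    mu = np.clip(Y, 0.01, 0.99)
    eta = np.log(mu / (1 - mu))
    beta = np.zeros((m, p))
    dev = deviance(mu)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        dmu = mu * (1 - mu)                      # d mu / d eta
        w = (1 - mu) ** 2                        # dmu^2 / V(mu), V = mu^2
        z = eta + (Y - mu) / np.maximum(dmu, 1e-12)
        # batched weighted least squares: (X^T W X) beta = X^T W z
        xtwx = np.einsum("ki,mk,kj->mij", X, w, X)
        xtwz = np.einsum("ki,mk,mk->mi", X, w, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(xtwx[i], xtwz[i], rcond=None)[0] for i in range(m)]
            )
        # step halving where the gamma deviance would increase
        delta = new_beta - beta
        frac = np.ones(m)
        for _half in range(8):
            cand = beta + frac[:, None] * delta
            new_dev = deviance(link_inv(cand @ X.T))
            worse = new_dev > dev + 1e-12
            if not worse.any():
                break
            frac[worse] *= 0.5
        beta = beta + frac[:, None] * delta
        eta = np.clip(beta @ X.T, -30, 30)
        mu = link_inv(eta)
        new_dev = deviance(mu)
        converged = np.abs(new_dev - dev) < tol * (np.abs(dev) + 0.1)
        dev = new_dev
        if converged.all():
            break
    resid_pearson = (Y - mu) / mu
    dof = max(n - p, 1)
    phi = (resid_pearson**2).sum(axis=1) / dof
    phi = np.maximum(phi, 1e-12)
    if squeeze_dispersion and m > 1:
        phi, _, _ = squeeze_variances(phi, dof)
    dmu = mu * (1 - mu)
    w = (1 - mu) ** 2
    xtwx = np.einsum("ki,mk,kj->mij", X, w, X)
    se = np.empty((m, p))
    for i in range(m):
        try:
            cov = phi[i] * np.linalg.inv(xtwx[i])
            se[i] = np.sqrt(np.maximum(np.diag(cov), 0))
        except np.linalg.LinAlgError:
            se[i] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals[~converged[:, None] & np.ones((m, p), bool)] = np.nan
    shape = 1.0 / phi
    loglik = stats.gamma.logpdf(
        Y, a=shape[:, None], scale=mu * phi[:, None]
    ).sum(axis=1)
    return GammaLogitFit(
        coef=beta, se=se, pvalues=pvals, dispersion=phi,
        converged=converged, loglik=loglik,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation (moderated t)
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink residual variances toward a pooled prior (empirical Bayes).

    A scaled inverse-chi-square prior with df d0 and scale s0^2 is fit by the
    method of moments on log s^2; the posterior variances are
    (d0 s0^2 + df s^2) / (d0 + df).  Returns (squeezed s^2, d0, s0^2); d0 may
    be inf when the observed variances show no excess spread, in which case
    all variances equal s0^2.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return s2, np.inf, float(np.median(s2[ok]) if ok.any() else 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean, evar = e.mean(), e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s02 = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


@dataclass
class ModeratedFit:
    coef: np.ndarray      # (features, p)
    t: np.ndarray         # moderated (or plain) t per coefficient
    pvalues: np.ndarray
    s2: np.ndarray        # residual variances (possibly squeezed)
    df_total: np.ndarray  # per-feature residual + prior df


def moderated_ols(
    Y: np.ndarray,
    X: np.ndarray,
    moderation: bool = True,
    groups: np.ndarray | None = None,
) -> ModeratedFit:
    """Feature-wise least squares with optional moderated-t inference.

    Each row of ``Y`` is regressed on the shared design ``X``; with
    ``moderation`` the residual variances are squeezed toward a pooled
    prior before t statistics are formed (t has df = residual + prior df).
    ``groups`` restricts the pooling to features measured on the same scale
    (e.g. log2 expression vs splicing ratios), one prior per group.
    Features with zero residual variance and zero coefficient yield t = 0,
    p = 1.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (empty design cell?)")
    xtx_inv = np.linalg.inv(X.T @ X)
    proj = xtx_inv @ X.T
    B = Y @ proj.T
    resid = Y - B @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    df_total = np.full(len(s2), float(df))
    if moderation:
        s2_used = np.empty_like(s2)
        if groups is None:
            groups = np.zeros(len(s2), dtype=int)
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            sq, d0, _ = squeeze_variances(s2[sel], df)
            s2_used[sel] = sq
            df_total[sel] = df + d0  # may be inf
    else:
        s2_used = s2
    cjj = np.diag(xtx_inv)
    se = np.sqrt(np.outer(s2_used, cjj))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, 0.0)
    dft = df_total[:, None]
    pv = np.where(
        np.isinf(dft),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(dft), 1.0, dft)),
    )
    pv = np.where((se == 0) & (np.abs(B) < 1e-12), 1.0, pv)
    return ModeratedFit(coef=B, t=t, pvalues=pv, s2=s2_used, df_total=df_total)
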