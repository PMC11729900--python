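"""Second stage: multivariate random-effects meta-regression by REML.

Each city contributes a reduced coefficient vector ``eta_i`` (the overall
cumulative exposure-response, dimension v) with within-city covariance
``S_i``.  The model is

    eta_i ~ MVN(X_i B, S_i + Psi),      X_i = x_i' kron I_v,

with ``x_i`` the city's meta-predictors (intercept only for plain pooling),
``B`` the fixed effects and ``Psi`` the unstructured between-city covariance.
``B`` is profiled out by GLS; ``Psi`` is parameterised by its Cholesky factor
(log-diagonal) and found by quasi-Newton maximisation of the restricted
likelihood.  Heterogeneity is summarised by the multivariate Cochran Q
(GLS fixed-effects residuals, Psi = 0), with I^2 = max(0, (Q - df)/Q) * 100,
and meta-predictors are tested with Wald statistics on their v-coefficient
blocks.  BLUPs shrink each city's eta towards its fixed-effect prediction in
proportion to Psi (S_i + Psi)^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

_LOG2PI = np.log(2.0 * np.pi)


def _as_arrays(etas, Ss):
    eta = np.asarray(etas, dtype=float)
    S = np.asarray(Ss, dtype=float)
    if eta.ndim == 1:
        eta = eta[:, None]
    if S.ndim == 1:
        S = S[:, None, None]
    elif S.ndim == 2 and eta.shape[1] == 1:
        S = S[:, :, None]
    k, v = eta.shape
    if S.shape != (k, v, v):
        raise ValueError(f"S must have shape {(k, v, v)}, got {S.shape}")
    return eta, S


def design_matrix(predictors=None, k=None, standardize=True):
    """Meta-regression design: intercept plus optional city-level predictors.

    ``predictors`` is a mapping name -> length-k values; continuous columns
    are standardised (mean 0, sd 1), string-valued columns expand to
    indicator contrasts against the first level.  Returns (X, names).
    """
    if predictors is None or len(predictors) == 0:
        if k is None:
            raise ValueError("k required when no predictors given")
        return np.ones((k, 1)), ["intercept"]
    cols, names = [], []
    for name, vals in predictors.items():
        vals = np.asarray(vals)
        if k is None:
            k = len(vals)
        if vals.dtype.kind in "OUS":
            levels = sorted(set(vals.tolist()))
            if len(levels) < 2:
                raise ValueError(f"meta-predictor {name!r} has no contrast")
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{name}[{lev}]")
        else:
            x = vals.astype(float)
            if np.std(x) == 0:
                raise ValueError(f"meta-predictor {name!r} is constant across cities")
            if standardize:
                x = (x - x.mean()) / x.std()
            cols.append(x)
            names.append(name)
    X = np.column_stack([np.ones(k)] + cols)
    return X, ["intercept"] + names


@dataclass
class MetaFit:
    B: np.ndarray            # (m, v) fixed effects
    vcov_B: np.ndarray       # (m*v, m*v), row-major over (predictor, outcome)
    psi: np.ndarray          # (v, v) between-city covariance
    loglik: float            # restricted log-likelihood at the optimum
    converged: bool
    X: np.ndarray
    names: list
    eta: np.ndarray = field(repr=False, default=None)
    S: np.ndarray = field(repr=False, default=None)

    @property
    def k(self):
        return self.X.shape[0]

    @property
    def v(self):
        return self.B.shape[1]

    def pooled_eta(self):
        """Fixed-effect prediction at the reference covariate pattern
        (intercept row; standardised predictors make this the panel mean)."""
        return self.B[0]

    def pooled_cov(self):
        v = self.v
        return self.vcov_B[:v, :v]


def _gls(eta, S_inv, X):
    """Profile the fixed effects by generalised least squares.

    Returns (Bvec, A) with A = sum_i Xi' Wi Xi the GLS precision of Bvec,
    where Xi = kron(x_i', I_v) and Wi = S_inv[i] (stacked (k, v, v))."""
    k, v = eta.shape
    m = X.shape[1]
    S_inv = np.asarray(S_inv)
    A = np.einsum("ki,kj,kab->iajb", X, X, S_inv).reshape(m * v, m * v)
    b = np.einsum("ki,kab,kb->ia", X, S_inv, eta).reshape(m * v)
    Bvec = np.linalg.solve(A, b)
    return Bvec, A


def _restricted_loglik(psi, eta, S, X):
    k, v = eta.shape
    m = X.shape[1]
    Sig = S + psi[None, :, :]
    try:
        L = np.linalg.cholesky(Sig)  # batched; fails if any not PD
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdets = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
    S_inv = np.linalg.inv(Sig)
    Bvec, A = _gls(eta, S_inv, X)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf, None, None
    r = eta - X @ Bvec.reshape(m, v)
    quad = np.einsum("ka,kab,kb->", r, S_inv, r)
    ll = -0.5 * ((k - m) * v * _LOG2PI + logdets + logdetA + quad)
    return ll, Bvec, A


def _psi_from_theta(theta, v):
    L = np.zeros((v, v))
    idx = 0
    for i in range(v):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L @ L.T


def _theta_from_psi(psi, v, floor=1e-5):
    psi = psi + floor * np.eye(v)
    L = np.linalg.cholesky(psi)
    theta = []
    for i in range(v):
        for j in range(i + 1):
            theta.append(np.log(max(L[i, j], floor)) if i == j else L[i, j])
    return np.array(theta)


def mvmeta_reml(etas, Ss, X=None, names=None, maxiter=200,
                tol=1e-6) -> MetaFit:
    """Fit the multivariate random-effects meta-regression by REML.

    Parameters
    ----------
    etas : (k, v) array of city coefficient vectors.
    Ss : (k, v, v) array of within-city covariances.
    X : (k, m) design (defaults to intercept-only pooling).
    """
    eta, S = _as_arrays(etas, Ss)
    k, v = eta.shape
    if X is None:
        X = np.ones((k, 1))
        names = names or ["intercept"]
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if k < m:
        raise ValueError(f"need at least as many cities (k={k}) as meta-predictors (m={m})")
    if names is None:
        names = [f"x{j}" for j in range(m)]
    if k == m:
        # saturated fixed effects: no residual df, Psi pinned at 0
        S_inv = np.linalg.inv(S + 1e-12 * np.eye(v)[None])
        Bvec, A = _gls(eta, S_inv, X)
        return MetaFit(B=Bvec.reshape(m, v), vcov_B=np.linalg.inv(A),
                       psi=np.zeros((v, v)), loglik=0.0, converged=True, X=X,
                       names=list(names), eta=eta, S=S)

    # moment start: between-city covariance of residuals minus mean S
    Xpinv = np.linalg.pinv(X)
    resid = eta - X @ (Xpinv @ eta)
    emp = resid.T @ resid / max(k - m, 1)
    psi0 = emp - S.mean(axis=0)
    w, V = np.linalg.eigh((psi0 + psi0.T) / 2.0)
    psi0 = (V * np.clip(w, 1e-4, None)) @ V.T
    theta0 = _theta_from_psi(psi0, v)

    def negll(theta):
        ll, _, _ = _restricted_loglik(_psi_from_theta(theta, v), eta, S, X)
        return -ll if np.isfinite(ll) else 1e12

    res = optimize.minimize(negll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": tol * 1e-2,
                                     "gtol": 1e-7})
    psi = _psi_from_theta(res.x, v)
    ll, Bvec, A = _restricted_loglik(psi, eta, S, X)
    # also try Psi = 0 explicitly; REML can sit on the boundary
    ll0, Bvec0, A0 = _restricted_loglik(np.zeros((v, v)), eta, S, X)
    if np.isfinite(ll0) and ll0 >= ll:
        psi, ll, Bvec, A = np.zeros((v, v)), ll0, Bvec0, A0
    vcov = np.linalg.inv(A)
    # reorder from (x kron outcome) row-major: Bvec is stacked kron(x_i, W)
    B = Bvec.reshape(m, v)
    return MetaFit(B=B, vcov_B=vcov, psi=psi, loglik=float(ll),
                   converged=bool(res.success or np.isfinite(ll)), X=X,
                   names=list(names), eta=eta, S=S)


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    pvalue: float
    I2: float


def heterogeneity(etas, Ss, X=None) -> HeterogeneityStats:
    """Multivariate Cochran Q from the GLS fixed-effects (Psi = 0) fit:
    Q = sum_i r_i' S_i^{-1} r_i, df = (k - m) v, I^2 = max(0, (Q-df)/Q)*100."""
    eta, S = _as_arrays(etas, Ss)
    k, v = eta.shape
    if X is None:
        X = np.ones((k, 1))
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    S_inv = np.linalg.inv(S)
    Bvec, _ = _gls(eta, S_inv, X)
    r = eta - X @ Bvec.reshape(m, v)
    Q = float(np.einsum("ka,kab,kb->", r, S_inv, r))
    df = (k - m) * v
    p = float(stats.chi2.sf(Q, df)) if df > 0 else float("nan")
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return HeterogeneityStats(Q=Q, df=df, pvalue=p, I2=I2)


def wald_test(fit: MetaFit, which: str):
    """Wald chi-square test that the v coefficients of predictor ``which``
    (all its contrast columns jointly, for categorical predictors) are zero."""
    cols = [j for j, n in enumerate(fit.names)
            if n == which or n.startswith(which + "[")]
    if not cols:
        raise KeyError(f"predictor {which!r} not in fit ({fit.names})")
    v = fit.v
    idx = np.concatenate([np.arange(j * v, (j + 1) * v) for j in cols])
    b = fit.B.reshape(-1)[idx]
    Vb = fit.vcov_B[np.ix_(idx, idx)]
    W = float(b @ np.linalg.solve(Vb, b))
    df = len(idx)
    return W, df, float(stats.chi2.sf(W, df))


@dataclass
class BLUPSet:
    coefs: np.ndarray   # (k, v)
    covs: np.ndarray    # (k, v, v)


def blup(fit: MetaFit) -> BLUPSet:
    """City-level best linear unbiased predictions.

    BLUP_i = X_i B + Psi (S_i + Psi)^{-1} (eta_i - X_i B); the covariance is
    the conditional variance Psi - Psi Sig_i^{-1} Psi plus the propagated
    fixed-effect uncertainty through (I - Psi Sig_i^{-1}) X_i.
    """
    eta, S, X = fit.eta, fit.S, fit.X
    k, v = eta.shape
    m = X.shape[1]
    Bvec = fit.B.reshape(-1)
    coefs = np.empty((k, v))
    covs = np.empty((k, v, v))
    for i in range(k):
        Xi = np.kron(X[i][None, :], np.eye(v))  # (v, m*v)
        pred = Xi @ Bvec
        Sig = S[i] + fit.psi
        G = fit.psi @ np.linalg.inv(Sig)
        coefs[i] = pred + G @ (eta[i] - pred)
        Imat = np.eye(v) - G
        cov = fit.psi - G @ fit.psi + Imat @ Xi @ fit.vcov_B @ Xi.T @ Imat.T
        covs[i] = (cov + cov.T) / 2.0
    return BLUPSet(coefs=coefs, covs=covs)


def pooled_curve(fit: MetaFit, var_spec, grid, reference: float = 0.0,
                 alpha: float = 0.05):
    """Pooled exposure-response curve from the intercept-level coefficients,
    relative to ``reference`` (CEHWI = 0 on non-event days)."""
    from .dlnm import ReducedFit, predict_overall_curve

    red = ReducedFit(eta=fit.pooled_eta(), S=fit.pooled_cov(), var_spec=var_spec)
    return predict_overall_curve(red, grid, reference=reference, alpha=alpha)
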