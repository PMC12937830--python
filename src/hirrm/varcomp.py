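"""REML estimation of genetic and permanent-environmental covariances.

The second hierarchy treats the n x d matrix P of fitted curve parameters as
correlated quantitative traits following the multivariate linear mixed model

    P = X B + G + E,   G ~ MN(0, Vg, K),   E ~ MN(0, Vpe, I_n),

i.e. rows of G covary through the genomic relationship matrix K and columns
through the d x d genetic covariance Vg, while E carries the iid permanent-
environmental (plus stage-1 estimation) covariance Vpe.  Rotating everything
by the eigenvectors of K = Uk Sk Uk' decouples the rows: row i of Uk'P is an
independent d-variate normal with covariance s_i Vg + Vpe, which is what the
restricted likelihood below exploits.

Estimation maximizes the REML log-likelihood over Cholesky-parameterized
(Vg, Vpe) with a short EM warm start followed by quasi-Newton iterations with
an analytic gradient; elementwise standard deviations come from the inverse
observed information computed by central differences on the (vech Vg,
vech Vpe) scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import Kinship

logger = logging.getLogger(__name__)

__all__ = [
    "rotate_by_kinship",
    "CovarianceComponents",
    "MultiTraitKinshipModel",
    "estimate_null_components",
    "wald_test_components",
    "univariate_reml",
]


def rotate_by_kinship(P: np.ndarray, X: np.ndarray, kinship: Kinship):
    """Rotate phenotypes and fixed-effect design by the eigenvectors of K.

    Returns (P_rot, X_rot, s) with P_rot = Uk'P, X_rot = Uk'X and s the
    eigenvalues of K; after rotation row i has covariance s_i*Vg + Vpe and
    rows are independent.
    """
    P = np.asarray(P, dtype=float)
    X = np.asarray(X, dtype=float)
    if P.shape[0] != kinship.n or X.shape[0] != kinship.n:
        raise ValueError("row count of P/X must match the kinship matrix")
    s, u = kinship.eigen()
    return u.T @ P, u.T @ X, s


# -- Cholesky (un)packing ----------------------------------------------------

def _tril_indices(d):
    return np.tril_indices(d)


def _pack(V: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    L = np.linalg.cholesky(V + floor * np.eye(V.shape[0]))
    i, j = _tril_indices(V.shape[0])
    vals = L[i, j].copy()
    diag = i == j
    vals[diag] = np.log(np.maximum(vals[diag], 1e-154))
    return vals


def _unpack(theta: np.ndarray, d: int) -> np.ndarray:
    L = np.zeros((d, d))
    i, j = _tril_indices(d)
    L[i, j] = theta
    L[np.diag_indices(d)] = np.exp(np.diag(L))
    return L @ L.T


def _chol_grad(G_sym: np.ndarray, theta_part: np.ndarray, d: int) -> np.ndarray:
    """Chain rule from d ll/dV (symmetric G) to the packed Cholesky scale."""
    L = np.zeros((d, d))
    i, j = _tril_indices(d)
    L[i, j] = theta_part
    diag_exp = np.exp(np.diag(L).copy())
    L[np.diag_indices(d)] = diag_exp
    dL = 2.0 * G_sym @ L
    g = dL[i, j].copy()
    diag = i == j
    g[diag] *= diag_exp  # log-diagonal reparameterization
    return g


@dataclass
class CovarianceComponents:
    """Fitted null-model covariance components and their uncertainties."""

    Vg: np.ndarray
    Vpe: np.ndarray
    se_Vg: np.ndarray | None
    se_Vpe: np.ndarray | None
    loglik_reml: float
    converged: bool
    n_iter: int
    trait_names: tuple[str, ...]
    beta: np.ndarray | None = None
    em_loglik_path: np.ndarray | None = field(default=None, repr=False)

    @property
    def d(self) -> int:
        return self.Vg.shape[0]

    def heritability(self) -> np.ndarray:
        """Per-trait regression heritability diag(Vg)/(diag(Vg)+diag(Vpe))."""
        vg, vpe = np.diag(self.Vg), np.diag(self.Vpe)
        return vg / (vg + vpe)

    def wald(self) -> pd.DataFrame:
        return wald_test_components(self)

    def summary(self) -> str:
        names = self.trait_names

        def mat(v, se, label):
            rows = [label]
            for i in range(self.d):
                cells = []
                for j in range(self.d):
                    cell = f"{v[i, j]:8.4f}"
                    if se is not None:
                        cell += f" ({se[i, j]:.4f})"
                    cells.append(cell)
                rows.append(f"  {names[i]:>4s}  " + "  ".join(cells))
            return rows

        lines = ["Null multivariate kinship model (REML)"]
        lines += mat(self.Vg, self.se_Vg, "Genetic covariance Vg:")
        lines += mat(self.Vpe, self.se_Vpe, "Permanent-environmental covariance Vpe:")
        h2 = self.heritability()
        lines.append("Regression heritability: "
                     + "  ".join(f"{n}={h:.3f}" for n, h in zip(names, h2)))
        lines.append(f"REML loglik = {self.loglik_reml:.4f}  "
                     f"converged={self.converged}  iterations={self.n_iter}")
        return "\n".join(lines)


class MultiTraitKinshipModel:
    """Null multivariate mixed model for regression phenotypes.

    Parameters
    ----------
    P : (n, d) array or DataFrame
        Fitted curve parameters, one row per individual, aligned with K.
    kinship : Kinship
    exog : (n, c) array, optional
        Fixed-effect covariates; an intercept is always prepended.
    trait_names : names for the d columns (taken from the DataFrame if given).
    """

    def __init__(self, P, kinship: Kinship, exog=None, trait_names=None):
        if isinstance(P, pd.DataFrame):
            if trait_names is None:
                trait_names = tuple(map(str, P.columns))
            P = P.to_numpy(dtype=float)
        self.P = np.asarray(P, dtype=float)
        if self.P.ndim != 2:
            raise ValueError("P must be 2-d (individuals x traits)")
        if not np.all(np.isfinite(self.P)):
            raise ValueError("P contains non-finite entries; drop failed fits upstream")
        n, d = self.P.shape
        self.trait_names = tuple(trait_names) if trait_names is not None else \
            tuple(f"trait{i}" for i in range(d))
        X = np.ones((n, 1))
        if exog is not None:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != n:
                exog = exog.T
            X = np.column_stack([X, exog])
        self.X = X
        self.kinship = kinship
        if n <= d + np.linalg.matrix_rank(X):
            raise ValueError("too few individuals for the requested model")
        self.Pr, self.Xr, self.s = rotate_by_kinship(self.P, X, kinship)
        s_spread = self.s.max() - self.s.min()
        if s_spread < 0.05:
            logger.warning(
                "kinship eigenvalue spread %.3g < 0.05: Vg and Vpe nearly confounded",
                s_spread)

    # -- restricted likelihood ----------------------------------------------

    def _siginv(self, Vg, Vpe):
        n, d = self.Pr.shape
        Sig = self.s[:, None, None] * Vg[None] + Vpe[None]
        try:
            chol = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return None, None
        logdet = 2.0 * np.sum(np.log(np.einsum("ijj->ij", chol)))
        siginv = np.linalg.inv(Sig)
        siginv = 0.5 * (siginv + np.swapaxes(siginv, 1, 2))
        return siginv, logdet

    def _core(self, Vg, Vpe):
        """REML pieces shared by loglik and gradient."""
        X, P = self.Xr, self.Pr
        n, d = P.shape
        c = X.shape[1]
        siginv, logdet = self._siginv(Vg, Vpe)
        if siginv is None:
            return None
        M = np.einsum("ij,ik,iab->jakb", X, X, siginv).reshape(c * d, c * d)
        rhs = np.einsum("ij,iab,ib->ja", X, siginv, P).reshape(c * d)
        try:
            beta = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            return None
        B = beta.reshape(c, d)
        resid = P - X @ B
        sir = np.einsum("iab,ib->ia", siginv, resid)
        quad = float(np.einsum("ia,ia->", resid, sir))
        sign, logdet_m = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        ll = -0.5 * (logdet + logdet_m + quad) - 0.5 * (n - c) * d * np.log(2 * np.pi)
        return dict(siginv=siginv, resid=resid, sir=sir, ll=ll, M=M, B=B, c=c)

    def reml_loglik(self, Vg: np.ndarray, Vpe: np.ndarray) -> float:
        """Restricted log-likelihood at given covariance components."""
        core = self._core(Vg, Vpe)
        return -np.inf if core is None else core["ll"]

    def _ll_grad(self, theta):
        d = self.P.shape[1]
        npar = d * (d + 1) // 2
        Vg = _unpack(theta[:npar], d)
        Vpe = _unpack(theta[npar:], d)
        core = self._core(Vg, Vpe)
        if core is None:
            return np.inf, np.zeros_like(theta)
        siginv, sir = core["siginv"], core["sir"]
        X, c = self.Xr, core["c"]
        Minv = np.linalg.inv(core["M"]).reshape(c, d, c, d)
        # A_i = sum_jk x_ij x_ik Minv[j,:,k,:]
        A = np.einsum("ij,ik,jakb->iab", X, X, Minv)
        W = siginv - np.einsum("ia,ib->iab", sir, sir) \
            - np.einsum("iab,ibc,icd->iad", siginv, A, siginv)
        Gg = -0.5 * np.einsum("i,iab->ab", self.s, W)
        Gp = -0.5 * np.einsum("iab->ab", W)
        g = np.concatenate([
            _chol_grad(0.5 * (Gg + Gg.T), theta[:npar], d),
            _chol_grad(0.5 * (Gp + Gp.T), theta[npar:], d),
        ])
        return -core["ll"], -g

    # -- EM warm start -------------------------------------------------------

    def _em_step(self, Vg, Vpe):
        core = self._core(Vg, Vpe)
        if core is None:
            return Vg, Vpe, -np.inf
        sir = core["sir"]
        siginv = core["siginv"]
        s = self.s
        n = self.Pr.shape[0]
        Eg = s[:, None] * (sir @ Vg.T)          # E[g_i] = s_i Vg siginv r_i
        Ee = sir @ Vpe.T
        VgSiVg = np.einsum("ab,ibc,cd->iad", Vg, siginv, Vg)
        VpSiVp = np.einsum("ab,ibc,cd->iad", Vpe, siginv, Vpe)
        # E[g g']/s_i = Eg Eg'/s_i + Vg - s_i Vg siginv Vg  (-> Vg as s_i -> 0)
        pos = s > 1e-12
        gg = np.einsum("ia,ib->iab", Eg, Eg)
        gg[pos] /= s[pos, None, None]
        gg[~pos] = 0.0
        Vg_new = (gg + Vg[None] - s[:, None, None] * VgSiVg).mean(axis=0)
        Vpe_new = (np.einsum("ia,ib->iab", Ee, Ee) + Vpe[None] - VpSiVp).mean(axis=0)
        Vg_new = 0.5 * (Vg_new + Vg_new.T)
        Vpe_new = 0.5 * (Vpe_new + Vpe_new.T)
        return Vg_new, Vpe_new, core["ll"]

    # -- driver ---------------------------------------------------------------

    def fit(self, em_steps: int = 5, maxiter: int = 500,
            gtol: float = 1e-5, ftol: float = 1e-10,
            compute_se: bool = True) -> CovarianceComponents:
        n, d = self.P.shape
        npar = d * (d + 1) // 2
        # moment start: split the OLS residual covariance evenly
        Bols, *_ = np.linalg.lstsq(self.X, self.P, rcond=None)
        R = self.P - self.X @ Bols
        S0 = (R.T @ R) / max(n - self.X.shape[1], 1)
        S0 += 1e-8 * np.trace(S0) / d * np.eye(d)
        Vg, Vpe = 0.5 * S0, 0.5 * S0
        em_path = []
        for _ in range(em_steps):
            Vg, Vpe, ll = self._em_step(Vg, Vpe)
            em_path.append(ll)
        theta0 = np.concatenate([_pack(Vg), _pack(Vpe)])
        idx_i, idx_j = _tril_indices(d)
        diag_mask = np.concatenate([idx_i == idx_j] * 2)
        bounds = [(-15.0, 15.0) if m else (-1e3, 1e3) for m in diag_mask]
        res = optimize.minimize(
            self._ll_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=bounds, options=dict(maxiter=maxiter, ftol=ftol, gtol=gtol),
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if not (res.success and grad_norm < 1e-2):  # one polishing restart
            res2 = optimize.minimize(
                self._ll_grad, res.x, jac=True, method="L-BFGS-B",
                bounds=bounds,
                options=dict(maxiter=maxiter, ftol=1e-12, gtol=gtol),
            )
            if res2.fun <= res.fun:
                res = res2
            grad_norm = float(np.max(np.abs(res.jac)))
        Vg = _unpack(res.x[:npar], d)
        Vpe = _unpack(res.x[npar:], d)
        converged = bool(res.success) and grad_norm < 1e-2
        ll = -res.fun
        se_Vg = se_Vpe = None
        if compute_se:
            se_Vg, se_Vpe = self._standard_errors(Vg, Vpe)
        return CovarianceComponents(
            Vg=Vg, Vpe=Vpe, se_Vg=se_Vg, se_Vpe=se_Vpe,
            loglik_reml=ll, converged=converged, n_iter=int(res.nit),
            trait_names=self.trait_names, beta=None,
            em_loglik_path=np.asarray(em_path),
        )

    def _vech_loglik_grad(self, v, d, npar):
        """Gradient of the REML loglik on the (vech Vg, vech Vpe) scale."""
        i, j = _tril_indices(d)

        def build(vals):
            V = np.zeros((d, d))
            V[i, j] = vals
            V[j, i] = vals
            return V

        Vg, Vpe = build(v[:npar]), build(v[npar:])
        core = self._core(Vg, Vpe)
        if core is None:
            return None
        siginv, sir = core["siginv"], core["sir"]
        X, c = self.Xr, core["c"]
        Minv = np.linalg.inv(core["M"]).reshape(c, d, c, d)
        A = np.einsum("ij,ik,jakb->iab", X, X, Minv)
        W = siginv - np.einsum("ia,ib->iab", sir, sir) \
            - np.einsum("iab,ibc,icd->iad", siginv, A, siginv)
        Gg = -0.5 * np.einsum("i,iab->ab", self.s, W)
        Gp = -0.5 * W.sum(axis=0)
        mult = np.where(i == j, 1.0, 2.0)
        return np.concatenate([Gg[i, j] * mult, Gp[i, j] * mult])

    def _standard_errors(self, Vg, Vpe, rel_step: float = 1e-4):
        """Observed-information standard deviations of every Vg/Vpe element,
        from central differences of the analytic gradient on the vech scale."""
        d = Vg.shape[0]
        npar = d * (d + 1) // 2
        i, j = _tril_indices(d)
        v0 = np.concatenate([Vg[i, j], Vpe[i, j]])
        p = v0.size
        # steps respect per-trait units, so heterogeneous scales stay PD
        scale = np.sqrt(np.diag(Vg) + np.diag(Vpe)) + 1e-12
        unit = np.concatenate([scale[i] * scale[j]] * 2)
        H = np.zeros((p, p))
        for a in range(p):
            h = rel_step * max(abs(v0[a]), 0.1 * unit[a])
            gp = gm = None
            for _ in range(3):  # shrink the step if PD is lost
                vp, vm = v0.copy(), v0.copy()
                vp[a] += h
                vm[a] -= h
                gp = self._vech_loglik_grad(vp, d, npar)
                gm = self._vech_loglik_grad(vm, d, npar)
                if gp is not None and gm is not None:
                    break
                h /= 10.0
            if gp is None or gm is None:
                logger.warning("information matrix unavailable (singular covariance)")
                return None, None
            H[a] = (gp - gm) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            logger.warning("singular information matrix; standard errors unavailable")
            return None, None
        var = np.diag(cov)
        if np.any(var <= 0):
            logger.warning("non-positive information; standard errors unavailable")
            return None, None
        se = np.sqrt(var)

        def to_mat(vals):
            S = np.zeros((d, d))
            S[i, j] = vals
            S[j, i] = vals
            return S

        return to_mat(se[:npar]), to_mat(se[npar:])


def estimate_null_components(P, X_fixed, kinship: Kinship,
                             trait_names=None, **fit_kw) -> CovarianceComponents:
    """Functional wrapper: REML (Vg, Vpe) under the null genomic model."""
    exog = None
    if X_fixed is not None:
        X_fixed = np.asarray(X_fixed, dtype=float)
        # drop a constant column if the caller passed one; the model adds it
        keep = [k for k in range(X_fixed.shape[1])
                if np.ptp(X_fixed[:, k]) > 0]
        exog = X_fixed[:, keep] if keep else None
    model = MultiTraitKinshipModel(P, kinship, exog=exog, trait_names=trait_names)
    return model.fit(**fit_kw)


def wald_test_components(cc: CovarianceComponents) -> pd.DataFrame:
    """Wald-type z tests of every (co)variance component.

    z is the estimate over its standard deviation; variances get a one-sided
    normal p (variance > 0), covariances a two-sided one.
    """
    if cc.se_Vg is None or cc.se_Vpe is None:
        raise ValueError("standard deviations unavailable for this fit")
    rows = []
    names = cc.trait_names
    for label, V, SE in (("Vg", cc.Vg, cc.se_Vg), ("Vpe", cc.Vpe, cc.se_Vpe)):
        for i in range(cc.d):
            for j in range(i + 1):
                est, sd = V[i, j], SE[i, j]
                z = est / sd if sd > 0 else np.nan
                if i == j:
                    p = float(stats.norm.sf(z))
                else:
                    p = float(2 * stats.norm.sf(abs(z))) if est != 0 else 1.0
                rows.append({
                    "component": f"{label}[{names[i]},{names[j]}]",
                    "kind": "variance" if i == j else "covariance",
                    "estimate": est, "sd": sd, "z": z, "p": p,
                })
    return pd.DataFrame(rows)


def univariate_reml(y: np.ndarray, X: np.ndarray, s: np.ndarray,
                    lam0: float | None = None,
                    grid=(1e-5, 1e5), n_grid: int = 40):
    """Single-trait REML on kinship-rotated data.

    Model: y_i ~ N(x_i'beta, sigma2*(lam*s_i + 1)) with independent rows;
    lam is the ratio of genetic to residual variance.  Returns a dict with
    lam, sigma2, beta, cov_beta and the profiled REML loglik.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, c = X.shape

    def neg_ll(log_lam):
        lam = np.exp(log_lam)
        v = lam * s + 1.0
        if np.any(v <= 0):
            return np.inf
        Xw = X / v[:, None]
        xtvx = X.T @ Xw
        try:
            beta = np.linalg.solve(xtvx, Xw.T @ y)
        except np.linalg.LinAlgError:
            return np.inf
        r = y - X @ beta
        rss = float(r @ (r / v))
        sign, ld = np.linalg.slogdet(xtvx)
        if sign <= 0 or rss <= 0:
            return np.inf
        return 0.5 * (np.sum(np.log(v)) + ld + (n - c) * np.log(rss))

    lo, hi = np.log(grid[0]), np.log(grid[1])
    grid_pts = list(np.linspace(lo, hi, n_grid))
    if lam0 is not None and lam0 > 0:
        grid_pts.append(np.log(lam0))
    vals = [neg_ll(g) for g in grid_pts]
    g0 = grid_pts[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_ll, bounds=(max(g0 - 2.5, lo), min(g0 + 2.5, hi)), method="bounded",
        options=dict(xatol=1e-8))
    log_lam = res.x if res.fun <= min(vals) else g0
    lam = float(np.exp(log_lam))
    v = lam * s + 1.0
    Xw = X / v[:, None]
    xtvx = X.T @ Xw
    beta = np.linalg.solve(xtvx, Xw.T @ y)
    r = y - X @ beta
    sigma2 = float(r @ (r / v)) / (n - c)
    cov_beta = sigma2 * np.linalg.inv(xtvx)
    ll = -neg_ll(log_lam) - 0.5 * (n - c) * (1 + np.log(2 * np.pi) - np.log(n - c))
    return dict(lam=lam, sigma2=sigma2, beta=beta, cov_beta=cov_beta,
                loglik=ll, converged=bool(np.isfinite(res.fun)))
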