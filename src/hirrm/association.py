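"""EMMAX-style genome scan for growth-curve parameters.

Each canonically transformed pseudo-trait l has phenotypic covariance
s_lambda_l * K + I_n under the null.  With K = Uk Sk Uk' the whitening map

    D_l = (s_lambda_l * Sk + I)^{-1/2} Uk'

turns the mixed model into ordinary regression with unit residual variance,
so a marker test reduces to least squares on the whitened genotype:
chi2_l = (a_l*)^2 / V(a_l*) with V(a_l*) = 1/(z'z) on the whitened scale.
Summing the d independent single-trait statistics gives the pleiotropy test,
chi-squared with d degrees of freedom.

Fixing the variance ratio at its genome-wide (null) value is the EMMAX
approximation; it can cost power at strong QTLs, so markers passing a
suggestive threshold are re-tested exactly, re-estimating the per-trait
variance ratio by univariate REML with the marker as a fixed covariate.
At most one refinement pass is made (two rounds in total).

A marker that itself enters the relationship matrix is partly corrected
away by the polygenic term ("proximal contamination"), which deflates its
statistic appreciably when the marker count is not much larger than the
sample size.  The scan therefore removes the candidate marker's own
contribution from K when testing it -- a rank-one downdate of V applied
through the Sherman-Morrison identity, so the cost stays O(n) per marker.
This is done only when the supplied kinship verifiably equals the
standardized cross-product of the scanned panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .canonical import CanonicalTransform, build_transform, transform_phenotypes
from .genotypes import GenotypeMatrix, Kinship
from .varcomp import CovarianceComponents, univariate_reml

logger = logging.getLogger(__name__)

__all__ = [
    "whiten", "score_marker", "pleiotropy_test", "bonferroni_threshold",
    "genomic_control", "GenomeScan", "ScanResult",
]

NEGLOG10_CAP = 320.0
_LN10 = np.log(10.0)


def whiten(kinship: Kinship, s_lambda_l: float) -> np.ndarray:
    """Whitening matrix D = (s_lambda*Sk + I)^{-1/2} Uk' for one pseudo-trait.

    Applied to the phenotype and every design column it leaves a model with
    identity residual covariance.
    """
    if s_lambda_l < 0:
        raise ValueError("canonical value s_lambda must be non-negative")
    sk, uk = kinship.eigen()
    return uk.T / np.sqrt(s_lambda_l * sk + 1.0)[:, None]


def score_marker(y_wh: np.ndarray, z_wh: np.ndarray,
                 min_var: float = 1e-12):
    """Least-squares score of one whitened, covariate-residualized marker.

    Returns (effect, effect variance, chi2); the whitened residual variance
    is fixed at 1 (the EMMAX convention).  A marker with (numerically) no
    variance left after whitening scores chi2 = 0.
    """
    ztz = float(z_wh @ z_wh)
    if ztz < min_var:
        return 0.0, np.inf, 0.0
    effect = float(z_wh @ y_wh) / ztz
    return effect, 1.0 / ztz, effect * effect * ztz


def pleiotropy_test(chi2_per_trait: np.ndarray):
    """Summed chi-squared pleiotropy test over the d pseudo-traits.

    Returns (chi2_sum, neglog10 p) with p from the upper tail of chi2_d;
    -log10 p is computed on the log scale and capped at 320.
    """
    chi2_per_trait = np.atleast_2d(np.asarray(chi2_per_trait, dtype=float))
    if not np.all(np.isfinite(chi2_per_trait)):
        raise ValueError("chi2 values must be finite")
    d = chi2_per_trait.shape[1]
    chi2_sum = chi2_per_trait.sum(axis=1)
    neglog10 = np.minimum(-stats.chi2.logsf(chi2_sum, df=d) / _LN10, NEGLOG10_CAP)
    if neglog10.size == 1:
        return float(chi2_sum[0]), float(neglog10[0])
    return chi2_sum, neglog10


def bonferroni_threshold(m_markers: int, alpha: float = 0.05) -> float:
    """Family-wise -log10 significance bound, -log10(alpha/m)."""
    if m_markers < 1:
        raise ValueError("need at least one marker")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / m_markers))


def genomic_control(chi2_sum: np.ndarray, df: int) -> float:
    """Median-based inflation factor median(chi2)/median(chi2_df)."""
    chi2_sum = np.asarray(chi2_sum, dtype=float)
    if chi2_sum.size < 100:
        raise ValueError("genomic control needs at least 100 markers")
    return float(np.median(chi2_sum) / stats.chi2.ppf(0.5, df=df))


@dataclass
class ScanResult:
    """Genome-scan results.

    ``records`` holds one row per marker: position metadata, MAF,
    back-transformed effect and standard error per curve parameter,
    per-pseudo-trait chi2, the summed statistic and -log10 p.
    """

    records: pd.DataFrame
    lambda_gc: float
    threshold_neglog10: float
    rounds_used: int
    df: int
    transform: CanonicalTransform | None = field(default=None, repr=False)

    def significant(self) -> pd.DataFrame:
        return self.records[self.records["neglog10_p"] >= self.threshold_neglog10]

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n_sig = int((self.records["neglog10_p"] >= self.threshold_neglog10).sum())
        return "\n".join([
            f"Genome scan: {len(self.records)} markers, df={self.df}",
            f"  lambda_gc = {self.lambda_gc:.4f}" if np.isfinite(self.lambda_gc)
            else "  lambda_gc = NA (fewer than 100 markers)",
            f"  Bonferroni -log10 threshold (alpha=0.05) = "
            f"{self.threshold_neglog10:.3f}",
            f"  markers above threshold: {n_sig}",
            f"  EMMAX rounds used: {self.rounds_used}",
        ])


class GenomeScan:
    """Marker-by-marker association scan of regression phenotypes.

    Parameters
    ----------
    P : (n, d) array or DataFrame of fitted curve parameters.
    genotypes : GenotypeMatrix aligned with P.
    kinship : Kinship (typically from :func:`hirrm.genotypes.compute_grm`).
    components : fitted null CovarianceComponents (defines the canonical
        transform), or pass a prebuilt ``transform``.
    exog : optional fixed covariates (intercept always included).
    exclude_candidate : True, False or "auto"
        Remove the tested marker's own share of the kinship when scoring it
        (see module docstring).  "auto" switches the correction on when the
        kinship matches the scanned panel's standardized cross-product.
    """

    def __init__(self, P, genotypes: GenotypeMatrix, kinship: Kinship,
                 components: CovarianceComponents | None = None,
                 transform: CanonicalTransform | None = None,
                 exog=None, trait_names=None,
                 exclude_candidate: bool | str = "auto"):
        if isinstance(P, pd.DataFrame):
            if trait_names is None:
                trait_names = tuple(map(str, P.columns))
            P = P.to_numpy(dtype=float)
        self.P = np.asarray(P, dtype=float)
        n, d = self.P.shape
        if genotypes.n_individuals != n or kinship.n != n:
            raise ValueError("phenotype, genotype and kinship sizes disagree")
        if list(genotypes.ids) != list(kinship.ids):
            raise ValueError("genotype and kinship individual ids disagree")
        if transform is None:
            if components is None:
                raise ValueError("supply fitted components or a transform")
            transform = build_transform(components)
        if transform.d != d:
            raise ValueError("transform dimension does not match P")
        self.transform = transform
        self.genotypes = genotypes
        self.kinship = kinship
        self.trait_names = tuple(trait_names) if trait_names is not None else \
            tuple(f"p{i}" for i in range(d))
        X = np.ones((n, 1))
        if exog is not None:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != n:
                exog = exog.T
            X = np.column_stack([X, exog])
        self.X = X
        self.exclude_candidate = exclude_candidate

    def _standardized_panel(self):
        """Column-standardized genotype matrix W, or None if degenerate."""
        x = self.genotypes.imputed()
        p = x.mean(axis=0) / 2.0
        if np.any((p <= 0) | (p >= 1)):
            return None
        return (x - 2 * p) / np.sqrt(2 * p * (1 - p))

    def _resolve_exclusion(self):
        """Decide whether the kinship is the panel's W W'/m (so the
        candidate's share can be downdated)."""
        if self.exclude_candidate is False:
            return None
        W = self._standardized_panel()
        if W is None:
            if self.exclude_candidate is True:
                raise ValueError("candidate exclusion needs a polymorphic panel")
            return None
        m = W.shape[1]
        probe = (W @ W[:2].T).T / m  # first two rows of W W'/m
        if np.max(np.abs(probe - self.kinship.matrix[:2])) > 1e-6:
            if self.exclude_candidate is True:
                raise ValueError(
                    "kinship does not equal the scanned panel's GRM; cannot "
                    "exclude candidate markers")
            logger.info("kinship not derived from this panel; candidate "
                        "exclusion disabled")
            return None
        return W

    def _score_plain(self, Pr, Xr, Zr, sk):
        """EMMAX scoring with the genome-wide kinship (whiten + least
        squares, unit residual variance)."""
        d = Pr.shape[1]
        m = Zr.shape[1]
        t = self.transform
        chi2 = np.empty((m, d))
        eff = np.empty((m, d))
        var = np.empty((m, d))
        mono = np.zeros(m, dtype=bool)
        for l in range(d):
            w = 1.0 / np.sqrt(t.s_lambda[l] * sk + 1.0)
            yw = w * Pr[:, l]
            Xw = w[:, None] * Xr
            Zw = w[:, None] * Zr
            q, _ = np.linalg.qr(Xw)
            yw = yw - q @ (q.T @ yw)
            Zw = Zw - q @ (q.T @ Zw)
            ztz = np.einsum("ij,ij->j", Zw, Zw)
            zty = Zw.T @ yw
            bad = ztz < 1e-12
            mono |= bad
            ztz_safe = np.where(bad, 1.0, ztz)
            a = np.where(bad, 0.0, zty / ztz_safe)
            eff[:, l] = a
            var[:, l] = np.where(bad, np.inf, 1.0 / ztz_safe)
            chi2[:, l] = np.where(bad, 0.0, a * a * ztz)
        return chi2, eff, var, mono

    def _score_excluding_candidate(self, Pr, Xr, Zr, Wr, sk):
        """GLS per marker under V_-j = V - (s_lambda/m) w_j w_j', evaluated
        with the Sherman-Morrison identity in the eigenbasis of K."""
        n, d = Pr.shape
        m = Zr.shape[1]
        c = Xr.shape[1]
        t = self.transform
        chi2 = np.empty((m, d))
        eff = np.empty((m, d))
        var = np.empty((m, d))
        mono = np.zeros(m, dtype=bool)
        for l in range(d):
            s_l = t.s_lambda[l]
            vinv = 1.0 / (s_l * sk + 1.0)           # V^{-1} is diagonal here
            Vy = vinv * Pr[:, l]
            VX = vinv[:, None] * Xr
            alpha0 = s_l / m
            wVw = np.einsum("ij,ij->j", Wr, vinv[:, None] * Wr)
            gamma = alpha0 / (1.0 - alpha0 * wVw)   # SM factor, > 0 since V-aw w' >= I
            wVy = Wr.T @ Vy                          # (m,)
            wVX = Wr.T @ VX                          # (m, c)
            wVz = np.einsum("ij,ij->j", Wr, vinv[:, None] * Zr)
            # normal equations of y ~ [X, z] under V_-j^{-1}
            S = np.empty((m, c + 1, c + 1))
            rhs = np.empty((m, c + 1))
            XX = Xr.T @ VX                           # (c, c)
            Xy = VX.T @ Pr[:, l]                     # (c,)
            zz = np.einsum("ij,ij->j", Zr, vinv[:, None] * Zr)
            zy = Zr.T @ Vy
            zX = Zr.T @ VX                           # (m, c)
            S[:, :c, :c] = XX[None] + gamma[:, None, None] * \
                np.einsum("ja,jb->jab", wVX, wVX)
            S[:, :c, c] = zX + gamma[:, None] * wVX * wVz[:, None]
            S[:, c, :c] = S[:, :c, c]
            S[:, c, c] = zz + gamma * wVz ** 2
            rhs[:, :c] = Xy[None] + gamma[:, None] * wVX * wVy[:, None]
            rhs[:, c] = zy + gamma * wVz * wVy
            bad = S[:, c, c] < 1e-12
            mono |= bad
            S[bad, c, c] = 1.0
            beta = np.linalg.solve(S, rhs[..., None])[..., 0]
            cov_zz = np.linalg.inv(S)[:, c, c]
            a = np.where(bad, 0.0, beta[:, c])
            eff[:, l] = a
            var[:, l] = np.where(bad, np.inf, cov_zz)
            chi2[:, l] = np.where(bad, 0.0, a * a / np.where(bad, 1.0, cov_zz))
        return chi2, eff, var, mono

    def fit(self, refine: bool = True, suggestive_p: float = 1e-4,
            suggestive_top_frac: float = 1e-3, alpha: float = 0.05) -> ScanResult:
        g, t = self.genotypes, self.transform
        n, d = self.P.shape
        m = g.n_markers
        P_star = transform_phenotypes(self.P, t)
        freq = g.allele_freq()
        Zc = g.imputed() - 2.0 * freq
        sk, uk = self.kinship.eigen()
        Zr = uk.T @ Zc
        Pr = uk.T @ P_star
        Xr = uk.T @ self.X
        W = self._resolve_exclusion()
        if W is not None:
            chi2, eff_star, var_star, mono = self._score_excluding_candidate(
                Pr, Xr, Zr, uk.T @ W, sk)
        else:
            chi2, eff_star, var_star, mono = self._score_plain(Pr, Xr, Zr, sk)
        refined = np.zeros(m, dtype=bool)
        rounds_used = 1
        if refine:
            chi2_sum = chi2.sum(axis=1)
            with np.errstate(divide="ignore"):
                p1 = stats.chi2.sf(chi2_sum, df=d)
            select = p1 < suggestive_p
            if suggestive_top_frac > 0:
                n_top = max(int(np.ceil(suggestive_top_frac * m)), 1)
                top_cut = np.partition(chi2_sum, m - n_top)[m - n_top] \
                    if m > 1 else np.inf
                select |= chi2_sum >= top_cut
            select &= ~mono
            if select.any():
                rounds_used = 2
                cache: dict[bytes, np.ndarray] = {}
                for j in np.nonzero(select)[0]:
                    key = Zc[:, j].tobytes()
                    if key in cache:
                        chi2[j] = cache[key]
                        refined[j] = True
                        continue
                    new = self._refine_marker(Pr, Xr, Zr[:, j], sk, chi2[j])
                    if new is not None:
                        chi2[j] = new
                        cache[key] = new
                        refined[j] = True
        chi2_sum, neglog10 = pleiotropy_test(chi2)
        chi2_sum = np.atleast_1d(chi2_sum)
        neglog10 = np.atleast_1d(neglog10)
        effects, vars_orig = t.back_transform_effects(eff_star, var_star)
        records = pd.DataFrame({
            "chrom": g.markers["chrom"].to_numpy(),
            "snp": g.markers["snp"].to_numpy(),
            "pos": g.markers["pos"].to_numpy(),
            "maf": np.minimum(freq, 1 - freq),
        })
        for j, name in enumerate(self.trait_names):
            records[f"effect_{name}"] = effects[:, j]
            records[f"se_{name}"] = np.sqrt(vars_orig[:, j])
        for l in range(d):
            records[f"chi2_{l + 1}"] = chi2[:, l]
        records["chi2_sum"] = chi2_sum
        records["neglog10_p"] = neglog10
        records["monomorphic"] = mono
        records["refined"] = refined
        lam = genomic_control(chi2_sum, d) if m >= 100 else np.nan
        return ScanResult(
            records=records, lambda_gc=lam,
            threshold_neglog10=bonferroni_threshold(m, alpha),
            rounds_used=rounds_used, df=d, transform=t,
        )

    def _refine_marker(self, Pr, Xr, zr, sk, chi2_old):
        """Exact per-trait GLS re-test with marker-conditional variance ratio.

        The per-trait ratio is re-estimated by univariate REML with the
        marker in the design (warm-started at the genome-wide s_lambda);
        non-convergence keeps the EMMAX statistic.
        """
        d = Pr.shape[1]
        out = np.empty(d)
        X_full = np.column_stack([Xr, zr])
        for l in range(d):
            try:
                res = univariate_reml(Pr[:, l], X_full, sk,
                                      lam0=float(self.transform.s_lambda[l]))
            except np.linalg.LinAlgError:
                return None
            if not res["converged"]:
                logger.warning("refinement did not converge; EMMAX statistic kept")
                return None
            beta = res["beta"][-1]
            var = res["cov_beta"][-1, -1]
            if var <= 0:
                return None
            out[l] = beta * beta / var
        return out
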