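"""Canonical transformation of correlated regression phenotypes.

Given the fitted covariance pair (Vg, Vpe), a d x d matrix L is built that
simultaneously whitens the permanent-environmental covariance and
diagonalizes the genetic one:

    L Vpe L' = I_d,      L Vg L' = diag(s_lambda).

Construction: eigendecompose Vpe = Upe Spe Upe', set A = Spe^{-1/2} Upe',
eigendecompose A Vg A' = U_lam S_lam U_lam', and take L = U_lam' A.  The
transformed traits P* = P L' then decompose the multivariate mixed model into
d mutually independent univariate models, the l-th with phenotypic covariance
s_lambda_l * K + I_n.

Canonical values are returned in descending order and each row of L is
scaled so its largest-magnitude entry is positive, making output
reproducible (eigenvectors are sign-ambiguous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CanonicalTransform", "build_transform", "transform_phenotypes"]


@dataclass
class CanonicalTransform:
    """Whitening/diagonalizing map for one (Vg, Vpe) pair."""

    L: np.ndarray
    s_lambda: np.ndarray
    trait_names: tuple[str, ...] | None = None

    @property
    def d(self) -> int:
        return self.L.shape[0]

    def back_transform_effects(self, effects_star: np.ndarray,
                               var_star: np.ndarray):
        """Map per-pseudo-trait effects and variances back to the original
        curve parameters.

        With a* = a L' and independent transformed estimators, a = a* L'^{-1}
        and Cov(a) = L^{-1} diag(var*) L^{-T}; only the variances (diagonal)
        are returned.
        """
        Linv = np.linalg.inv(self.L)
        effects = np.atleast_2d(effects_star) @ Linv.T
        var = np.atleast_2d(var_star) @ (Linv ** 2).T
        return effects, var


def build_transform(Vg, Vpe=None, trait_names=None,
                    max_cond: float = 1e12) -> CanonicalTransform:
    """Build the canonical transform from covariance components.

    Accepts either a fitted :class:`~hirrm.varcomp.CovarianceComponents`
    (single argument) or the two matrices (Vg, Vpe).  A nearly singular Vpe
    is repaired with a relative ridge of 1e-8*trace/d; a condition number
    beyond ``max_cond`` after repair raises.
    """
    if Vpe is None:  # CovarianceComponents-like object
        cc = Vg
        Vg, Vpe = cc.Vg, cc.Vpe
        if trait_names is None:
            trait_names = cc.trait_names
    Vg = np.asarray(Vg, dtype=float)
    Vpe = np.asarray(Vpe, dtype=float)
    d = Vg.shape[0]
    if Vg.shape != (d, d) or Vpe.shape != (d, d):
        raise ValueError("Vg and Vpe must be square and of equal size")
    spe, upe = np.linalg.eigh(0.5 * (Vpe + Vpe.T))
    if spe.min() <= 0:
        ridge = 1e-8 * np.trace(Vpe) / d
        logger.warning(
            "Vpe not positive definite (min eigenvalue %.3g); ridged by %.3g",
            spe.min(), ridge)
        spe, upe = np.linalg.eigh(0.5 * (Vpe + Vpe.T) + ridge * np.eye(d))
    if spe.min() <= 0 or spe.max() / spe.min() > max_cond:
        raise ValueError(
            f"Vpe singular beyond repair: eigenvalues {spe}")
    A = (upe / np.sqrt(spe)).T          # Spe^{-1/2} Upe'
    B = A @ (0.5 * (Vg + Vg.T)) @ A.T
    s_lam, u_lam = np.linalg.eigh(0.5 * (B + B.T))
    order = np.argsort(s_lam)[::-1]     # descending canonical values
    s_lam = np.maximum(s_lam[order], 0.0)
    L = u_lam[:, order].T @ A
    # deterministic row signs: largest-magnitude entry positive
    signs = np.sign(L[np.arange(d), np.argmax(np.abs(L), axis=1)])
    signs[signs == 0] = 1.0
    L = L * signs[:, None]
    return CanonicalTransform(L=L, s_lambda=s_lam,
                              trait_names=tuple(trait_names) if trait_names else None)


def transform_phenotypes(P: np.ndarray, t: CanonicalTransform) -> np.ndarray:
    """Map regression phenotypes to independent pseudo-traits, P* = P L'."""
    P = np.asarray(P, dtype=float)
    if P.shape[1] != t.d:
        raise ValueError("column count of P must equal the transform dimension")
    return P @ t.L.T
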