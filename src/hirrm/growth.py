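"""Growth-curve models for longitudinal phenotypes.

This module implements the first hierarchy of the growth-trajectory GWAS:
each individual's repeated measurements are condensed into the parameters of
a parametric growth curve, which then serve as multivariate "regression
phenotypes" for the second, genomic hierarchy.

Five curve families are supported:

* ``richards``     y(t) = a * (1 + b*exp(-r*t)) ** (1/(1-k))
* ``bertalanffy``  y(t) = a * (1 - b*exp(-r*t))
* ``gompertz``     y(t) = a * exp(-b*exp(-r*t))
* ``logistic``     y(t) = a / (1 + b*exp(-r*t))
* ``legendre``     y(t) = sum_i c_i * psi_i(s(t)),  s an affine map to [-1,1]

Here ``a`` is the asymptotic (mature) size, ``b`` an integration constant
fixing the initial condition, ``r`` the intrinsic growth rate and ``k`` a
shape parameter moving the inflection point.  The Richards family nests the
others: k=0 gives the Bertalanffy form (with the sign of b flipped), k->1
the Gompertz limit and k=2 the Logistic curve.  Gompertz is implemented as
its own family because the Richards exponent 1/(1-k) is singular at k=1.

The Legendre basis uses the normalized polynomials of the random-regression
literature, psi_i(s) = sqrt((2i+1)/2) * P_i(s), orthonormal on [-1, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalSeries",
    "CurveParams",
    "GrowthCurveFit",
    "GrowthCurveModel",
    "FAMILIES",
    "evaluate_curve",
    "legendre_basis",
    "fit_curve",
    "fit_population_curve",
    "select_model",
    "genetic_effect_trajectory",
    "read_phenotypes",
    "write_curve_fits",
    "read_curve_fits",
]

#: parameter names of the biological families
FAMILIES = {
    "richards": ("a", "b", "r", "k"),
    "bertalanffy": ("a", "b", "r"),
    "gompertz": ("a", "b", "r"),
    "logistic": ("a", "b", "r"),
    "legendre": None,  # order-dependent
}

_RICHARDS_K_BAND = 1e-4  # exclusion band around the k=1 singularity


@dataclass
class LongitudinalSeries:
    """Repeated measurements of one individual.

    ``times`` must be strictly increasing and ``values`` finite, of the same
    length.
    """

    individual_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d and of equal length")
        if self.times.size < 1:
            raise ValueError("series must contain at least one observation")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"times of {self.individual_id!r} not strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError(f"non-finite data in series {self.individual_id!r}")

    @property
    def n_obs(self) -> int:
        return self.times.size


@dataclass
class CurveParams:
    """Coefficients of one growth-curve family.

    For ``legendre`` the coefficients are c_0..c_order and ``t_range`` records
    the affine time window mapped onto [-1, 1].
    """

    family: str
    coefficients: np.ndarray
    t_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown curve family {self.family!r}")
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        names = FAMILIES[self.family]
        if names is not None and self.coefficients.size != len(names):
            raise ValueError(
                f"{self.family} expects {len(names)} coefficients, "
                f"got {self.coefficients.size}"
            )
        if self.family == "richards" and abs(self.coefficients[3] - 1.0) <= _RICHARDS_K_BAND:
            raise ValueError("richards shape parameter k must differ from 1; use gompertz")

    @property
    def d(self) -> int:
        """Number of curve parameters."""
        return self.coefficients.size

    @property
    def names(self) -> tuple[str, ...]:
        fixed = FAMILIES[self.family]
        if fixed is not None:
            return fixed
        return tuple(f"c{i}" for i in range(self.d))


def legendre_basis(t: np.ndarray, order: int, t_range: tuple[float, float]) -> np.ndarray:
    """Normalized Legendre design matrix psi_0..psi_order at ages ``t``.

    Ages are affinely mapped from ``t_range`` onto [-1, 1]; the basis is
    psi_i(s) = sqrt((2i+1)/2) P_i(s), orthonormal under the L2 inner product
    on [-1, 1].
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lo, hi = t_range
    if hi <= lo:
        raise ValueError("t_range must have positive width")
    s = 2.0 * (t - lo) / (hi - lo) - 1.0
    cols = []
    for i in range(order + 1):
        coef = np.zeros(i + 1)
        coef[i] = 1.0
        cols.append(math.sqrt((2 * i + 1) / 2.0) * npleg.legval(s, coef))
    return np.column_stack(cols)


def evaluate_curve(params: CurveParams, t) -> np.ndarray:
    """Evaluate a growth curve at ages ``t``."""
    t = np.asarray(t, dtype=float)
    c = params.coefficients
    fam = params.family
    if fam == "richards":
        a, b, r, k = c
        base = 1.0 + b * np.exp(-r * t)
        if np.any(base <= 0):
            raise ValueError("richards base 1 + b*exp(-r*t) must be positive")
        return a * base ** (1.0 / (1.0 - k))
    if fam == "bertalanffy":
        a, b, r = c
        return a * (1.0 - b * np.exp(-r * t))
    if fam == "gompertz":
        a, b, r = c
        return a * np.exp(-b * np.exp(-r * t))
    if fam == "logistic":
        a, b, r = c
        return a / (1.0 + b * np.exp(-r * t))
    # legendre
    if params.t_range is None:
        raise ValueError("legendre curve requires t_range")
    basis = legendre_basis(t, params.d - 1, params.t_range)
    return basis @ c


@dataclass
class GrowthCurveFit:
    """Result of fitting one growth curve.

    ``residual_variance`` uses the unbiased denominator (n_obs - d); ``aic``
    and ``bic`` use the Gaussian-likelihood forms
    n*ln(RSS/n) + 2*(d+1) and n*ln(RSS/n) + (d+1)*ln(n), where d+1 counts the
    residual variance as a parameter.
    """

    params: CurveParams
    n_obs: int
    rss: float
    residual_variance: float
    r_squared: float
    aic: float
    bic: float
    converged: bool
    individual_id: str | None = None

    def fitted(self, t) -> np.ndarray:
        return evaluate_curve(self.params, t)

    def summary(self) -> str:
        lines = [
            f"Growth curve fit: family={self.params.family}"
            + (f", id={self.individual_id}" if self.individual_id else ""),
            "  " + "  ".join(
                f"{n}={v:.6g}" for n, v in zip(self.params.names, self.params.coefficients)
            ),
            f"  n_obs={self.n_obs}  RSS={self.rss:.6g}  "
            f"resid_var={self.residual_variance:.6g}",
            f"  R2={self.r_squared:.4f}  AIC={self.aic:.3f}  BIC={self.bic:.3f}  "
            f"converged={self.converged}",
        ]
        return "\n".join(lines)


def _metrics(values: np.ndarray, resid: np.ndarray, d: int) -> dict:
    n = values.size
    rss = float(resid @ resid)
    tss = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else np.nan)
    mean_sq = max(rss / n, 1e-300)  # guard exact interpolation
    return {
        "rss": rss,
        "residual_variance": rss / (n - d),
        "r_squared": r2,
        "aic": n * math.log(mean_sq) + 2 * (d + 1),
        "bic": n * math.log(mean_sq) + (d + 1) * math.log(n),
    }


def _initial_guess(family: str, t: np.ndarray, y: np.ndarray,
                   r0: float | None = None, k0: float = 1.5):
    """Self-starting values: a0 slightly above the max, r0 from a log-linear
    regression of log(a0 - y) on t, b0 from the first observation."""
    a0 = 1.05 * np.max(np.abs(y)) if np.max(y) > 0 else 1.0
    if r0 is None:
        z = a0 - y
        ok = z > 0
        if ok.sum() >= 2:
            slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
            r0 = max(-slope, 1e-3)
        else:
            r0 = 1.0 / max(t.max() - t.min(), 1.0)
    t1, y1 = t[0], max(y[0], 1e-8 * a0)
    frac = min(y1 / a0, 1.0 - 1e-8)
    e1 = math.exp(min(r0 * t1, 200.0))
    if family == "bertalanffy":
        b0 = (1.0 - frac) * e1
        return np.array([a0, b0, r0])
    if family == "gompertz":
        b0 = -math.log(frac) * e1
        return np.array([a0, b0, r0])
    if family == "logistic":
        b0 = (1.0 / frac - 1.0) * e1
        return np.array([a0, b0, r0])
    # richards: b0 consistent with the requested shape start k0
    b0 = (frac ** (1.0 - k0) - 1.0) * e1
    if k0 > 1:
        b0 = max(b0, 1e-6)
    return np.array([a0, b0, r0, k0])


def _residual_fn(family: str):
    def fn(theta, t, y):
        p = CurveParams(family, theta) if family != "richards" else None
        if family == "richards":
            a, b, r, k = theta
            with np.errstate(over="ignore"):
                base = 1.0 + b * np.exp(-r * t)
                base = np.maximum(base, 1e-12)
                pred = np.minimum(a * base ** (1.0 / (1.0 - k)), 1e150)
        else:
            pred = evaluate_curve(p, t)
        return pred - y

    return fn


def _family_bounds(family: str, branch: str = "upper"):
    if family == "richards":
        if branch == "upper":
            lo = [1e-8, -np.inf, -np.inf, 1.0 + _RICHARDS_K_BAND]
            hi = [np.inf, np.inf, np.inf, 20.0]
        else:
            lo = [1e-8, -np.inf, -np.inf, -20.0]
            hi = [np.inf, np.inf, np.inf, 1.0 - _RICHARDS_K_BAND]
        return lo, hi
    return [1e-8, -np.inf, -np.inf], [np.inf, np.inf, np.inf]


class GrowthCurveModel:
    """Nonlinear (or, for Legendre, ordinary) least-squares growth-curve model
    for one series of repeated measurements.

    Parameters
    ----------
    series : LongitudinalSeries
    family : str
        One of ``richards``, ``bertalanffy``, ``gompertz``, ``logistic``,
        ``legendre``.
    order : int
        Polynomial order for the Legendre family (ignored otherwise).
    """

    def __init__(self, series: LongitudinalSeries, family: str, order: int = 4):
        if family not in FAMILIES:
            raise ValueError(f"unknown curve family {family!r}")
        self.series = series
        self.family = family
        self.order = order
        names = FAMILIES[family]
        self.d = len(names) if names is not None else order + 1
        if series.n_obs < self.d + 1:
            raise ValueError(
                f"series {series.individual_id!r}: {series.n_obs} observations "
                f"cannot identify {self.d} parameters plus a residual variance"
            )

    def fit(self, maxfev: int = 2000) -> GrowthCurveFit:
        t, y = self.series.times, self.series.values
        if self.family == "legendre":
            t_range = (float(t.min()), float(t.max()))
            X = legendre_basis(t, self.order, t_range)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = X @ coef - y
            params = CurveParams("legendre", coef, t_range=t_range)
            return GrowthCurveFit(
                params=params, n_obs=t.size, converged=True,
                individual_id=self.series.individual_id, **_metrics(y, resid, self.d),
            )
        fn = _residual_fn(self.family)
        # the Richards likelihood has local optima along the b-k ridge, so a
        # small grid of shape starts spans both k branches
        if self.family == "richards":
            starts = [(None, 1.5, "upper"), (None, 1.2, "upper"),
                      (None, 3.0, "upper"), (None, 0.0, "lower")]
        else:
            starts = [(None, 1.5, "upper")]
        best = None
        for r0, k0, branch in starts:
            theta0 = _initial_guess(self.family, t, y, r0, k0=k0)
            lo, hi = _family_bounds(self.family, branch)
            theta_b = np.clip(theta0, lo, hi)
            try:
                res = least_squares(
                    fn, theta_b, args=(t, y), bounds=(lo, hi),
                    max_nfev=maxfev, method="trf",
                )
            except Exception:  # pragma: no cover - defensive
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.success and 2 * best.cost <= 1e-10 * max(y @ y, 1.0):
                break
            # multi-start on r from a 3-point grid if the first start struggled
            if r0 is None and not res.success:
                base_r = theta0[2]
                starts.extend([(base_r * f, k0, branch) for f in (0.3, 3.0, 10.0)])
        if best is None:
            raise RuntimeError("all least-squares starts failed")
        resid = fn(best.x, t, y)
        params = CurveParams(self.family, best.x)
        return GrowthCurveFit(
            params=params, n_obs=t.size, converged=bool(best.success),
            individual_id=self.series.individual_id, **_metrics(y, resid, self.d),
        )


def fit_curve(series: LongitudinalSeries, family: str, order: int = 4) -> GrowthCurveFit:
    """Fit one individual's trajectory; see :class:`GrowthCurveModel`."""
    return GrowthCurveModel(series, family, order=order).fit()


def _align_times(all_series: list[LongitudinalSeries], tol: float) -> np.ndarray:
    """Cluster the pooled time points; error if a cluster is wider than tol."""
    pooled = np.sort(np.concatenate([s.times for s in all_series]))
    groups = [[pooled[0]]]
    for x in pooled[1:]:
        if x - groups[-1][-1] <= tol:
            groups[-1].append(x)
        else:
            groups.append([x])
    for g in groups:
        if g[-1] - g[0] > tol:
            raise ValueError("time grids not alignable within tolerance")
    return np.array([np.mean(g) for g in groups])


def fit_population_curve(
    all_series: list[LongitudinalSeries],
    family: str,
    order: int = 4,
    align_tol: float = 1e-6,
) -> GrowthCurveFit:
    """Fit the population mean trajectory.

    Mean phenotypes are computed at each (aligned) age across individuals and
    the mean trajectory is fitted exactly like an individual one.
    """
    if not all_series:
        raise ValueError("no series supplied")
    grid = _align_times(all_series, align_tol)
    sums = np.zeros_like(grid)
    counts = np.zeros_like(grid)
    for s in all_series:
        idx = np.searchsorted(grid, s.times - align_tol / 2)
        idx = np.clip(idx, 0, grid.size - 1)
        sums[idx] += s.values
        counts[idx] += 1
    keep = counts > 0
    means = sums[keep] / counts[keep]
    mean_series = LongitudinalSeries("population_mean", grid[keep], means)
    return fit_curve(mean_series, family, order=order)


def select_model(fits: list[GrowthCurveFit]) -> pd.DataFrame:
    """Rank candidate curve fits of the same data by BIC (ascending).

    Ties in BIC are broken in favour of fewer parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    rows = []
    for f in fits:
        rows.append({
            "family": f.params.family,
            "n_params": f.params.d,
            "bic": f.bic,
            "aic": f.aic,
            "r_squared": f.r_squared,
            "residual_variance": f.residual_variance,
            "converged": f.converged,
        })
    table = pd.DataFrame(rows).sort_values(
        ["bic", "n_params"], kind="stable"
    ).reset_index(drop=True)
    return table


def genetic_effect_trajectory(
    pop: CurveParams, qtl_effects: np.ndarray, t_grid
) -> np.ndarray:
    """Time course of a QTL's effect on the phenotype.

    The curve parameters act linearly and additively at the second hierarchy
    but enter the growth function nonlinearly, so a QTL's effect on the
    phenotype is the difference between the curve evaluated at the population
    parameters shifted by the QTL's per-parameter effects and the population
    curve itself:  g(t) = f(pop + effects, t) - f(pop, t).
    """
    qtl_effects = np.asarray(qtl_effects, dtype=float)
    if qtl_effects.shape != pop.coefficients.shape:
        raise ValueError("effect vector length must match curve parameter count")
    shifted = CurveParams(pop.family, pop.coefficients + qtl_effects, t_range=pop.t_range)
    t_grid = np.asarray(t_grid, dtype=float)
    return evaluate_curve(shifted, t_grid) - evaluate_curve(pop, t_grid)


# ---------------------------------------------------------------------------
# text I/O: long-format phenotypes and curve-fit tables


def read_phenotypes(path, sep: str | None = None) -> list[LongitudinalSeries]:
    """Read long-format phenotypes (columns id, time, value; header required).

    Malformed rows are logged and skipped; their count is reported in a single
    warning. The delimiter is sniffed (tab or comma) unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    expected = {"id", "time", "value"}
    cols = {c.lower(): c for c in df.columns}
    if not expected.issubset(cols):
        raise ValueError(f"phenotype file must have columns id,time,value; got {list(df.columns)}")
    df = df.rename(columns={cols["id"]: "id", cols["time"]: "time", cols["value"]: "value"})
    df["time"] = pd.to_numeric(df["time"], errors="coerce")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    bad = df["time"].isna() | df["value"].isna() | df["id"].isna()
    if bad.any():
        logger.warning("skipped %d malformed phenotype rows", int(bad.sum()))
        df = df[~bad]
    if df.empty:
        raise ValueError("no valid phenotype rows")
    out = []
    for iid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("time")
        out.append(LongitudinalSeries(str(iid), grp["time"].to_numpy(), grp["value"].to_numpy()))
    return out


def write_curve_fits(fits: list[GrowthCurveFit], path) -> None:
    """Write per-individual curve fits as TSV."""
    d_max = max(f.params.d for f in fits)
    rows = []
    for f in fits:
        row = {"id": f.individual_id, "family": f.params.family}
        for j in range(d_max):
            row[f"coefficient_{j + 1}"] = (
                f.params.coefficients[j] if j < f.params.d else np.nan
            )
        row.update(
            n_obs=f.n_obs, residual_variance=f.residual_variance,
            r_squared=f.r_squared, aic=f.aic, bic=f.bic, converged=f.converged,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_curve_fits(path) -> pd.DataFrame:
    """Read a curve-fit TSV back into a DataFrame (ids as strings)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return df
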