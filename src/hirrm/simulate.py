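"""Synthetic longitudinal GWAS datasets and power evaluation.

The generator emulates the simulation design of the growth-trajectory GWAS:
an LD-structured SNP panel, QTLs placed at random among the markers,
correlated genetic and permanent-environmental deviations of the growth-curve
parameters (all pairwise correlations 0.5, permanent-environmental variances
4.0, regression heritability 0.5 by default), 16-time-point trajectories and
Gaussian measurement error with variance 4.0.

Regression deviations are drawn on a standardized scale carrying exactly the
covariances above and mapped onto natural curve parameters through a linear
parameter map S.  By default S = c * (J'J)^{-1/2}, with J the Jacobian of the
population curve on the time grid: the effective basis functions of the d
regression traits are then orthogonal with squared norm c^2 (``info_scale``),
so stage-1 curve fitting measures every regression trait with error variance
residual_variance / info_scale.  At the defaults (c^2 = 50, residual variance
4.0) the stage-1 error is 0.08 -- two percent of the permanent-environmental
variance -- the dense-measurement regime the hierarchical model presumes.
The default population curve is a large-phenotype (maize-like) Richards
curve; a diagonal ``parameter_map`` can be supplied to place effects on
named parameters directly.

Genotypes follow a haplotype copying model: within an LD block each haplotype
allele copies its left neighbour with probability ``copy_prob`` and is
otherwise drawn fresh at the marker's own frequency, giving first-order
correlation that decays geometrically with distance; blocks are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import ScanResult
from .genotypes import GenotypeMatrix, Kinship, compute_grm, filter_markers
from .growth import CurveParams, FAMILIES, LongitudinalSeries, evaluate_curve, fit_curve
from .varcomp import CovarianceComponents, MultiTraitKinshipModel

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig", "SimulatedDataset", "simulate_genotypes",
    "simulate_effects_and_phenotypes", "simulate_dataset", "fit_stage1",
    "estimate_null_from_dataset", "call_qtls", "evaluate_power_roc",
    "power_from_records", "default_parameter_map",
]


@dataclass
class SimulationConfig:
    """Generative settings of one simulated study.

    Defaults reproduce the stated simulation conditions: 16 time points,
    regression heritability 0.5, permanent-environmental variances 4.0,
    all effect correlations 0.5, measurement-error variance 4.0.
    """

    n_individuals: int = 500
    n_markers: int = 2000
    n_qtls: int = 20
    n_timepoints: int = 16
    regression_heritability: float = 0.5
    pe_variance: float = 4.0
    effect_correlation: float = 0.5
    residual_variance: float = 4.0
    qtl_variance_fraction: float = 0.3
    family: str = "richards"
    population_coefficients: tuple = (220.0, 4.0, 0.35, 1.5)
    info_scale: float = 50.0
    parameter_map: np.ndarray | None = None
    ld_block_length: int = 20
    copy_prob: float = 0.9
    n_chromosomes: int = 10
    marker_spacing: int = 5000
    allele_freq_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.regression_heritability < 1:
            raise ValueError("regression heritability must lie in (0, 1)")
        if min(self.pe_variance, self.residual_variance) <= 0:
            raise ValueError("variances must be positive")
        if not 0 <= self.qtl_variance_fraction <= 1:
            raise ValueError(
                "QTL variance fraction must lie in [0, 1] (cannot exceed the "
                "total genetic variance)")
        if self.n_qtls > self.n_markers:
            raise ValueError("cannot place more QTLs than markers")
        if not -1 < self.effect_correlation < 1:
            raise ValueError("effect correlation must lie in (-1, 1)")
        if self.family not in FAMILIES or self.family == "legendre":
            raise ValueError("simulation supports the biological curve families")

    @property
    def d(self) -> int:
        return len(FAMILIES[self.family])

    @property
    def times(self) -> np.ndarray:
        return np.arange(1.0, self.n_timepoints + 1.0)

    def population_params(self) -> CurveParams:
        return CurveParams(self.family, np.asarray(self.population_coefficients))

    def genetic_variance(self) -> float:
        """Per-trait genetic regression variance implied by h2 and Vpe."""
        h2 = self.regression_heritability
        return self.pe_variance * h2 / (1.0 - h2)

    def corr_matrix(self) -> np.ndarray:
        d = self.d
        R = np.full((d, d), self.effect_correlation)
        np.fill_diagonal(R, 1.0)
        return R

    def Vg(self) -> np.ndarray:
        return self.genetic_variance() * self.corr_matrix()

    def Vpe(self) -> np.ndarray:
        return self.pe_variance * self.corr_matrix()


@dataclass
class SimulatedDataset:
    """One simulated study with full truth records."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray          # (n_qtls, d), standardized regression units
    Vg_true: np.ndarray
    Vpe_true: np.ndarray
    parameter_map: np.ndarray        # S: standardized units -> natural units
    regressions_true: np.ndarray     # (n, d) standardized deviations
    pe_true: np.ndarray              # (n, d) permanent-environmental part
    params_natural: np.ndarray       # (n, d) natural curve parameters
    series: list[LongitudinalSeries]
    seed: int


def _curve_jacobian(params: CurveParams, t: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the curve w.r.t. its parameters."""
    c0 = params.coefficients
    J = np.empty((t.size, c0.size))
    for j in range(c0.size):
        h = 1e-6 * max(abs(c0[j]), 1.0)
        up = c0.copy(); up[j] += h
        dn = c0.copy(); dn[j] -= h
        J[:, j] = (evaluate_curve(CurveParams(params.family, up), t)
                   - evaluate_curve(CurveParams(params.family, dn), t)) / (2 * h)
    return J


def default_parameter_map(config: SimulationConfig) -> np.ndarray:
    """Default map from standardized regression units to curve parameters.

    Preferred form: information whitening, S = c (J'J)^{-1/2} with
    c^2 = ``info_scale``, which measures every regression trait with equal
    stage-1 precision.  When the curve has a weakly identified direction
    (Richards' b-k ridge), whitening would place deviations far outside the
    curve's domain; in that case a bounded diagonal map is used instead,
    with 3-sigma natural deviations capped at a quarter of each population
    coefficient's magnitude.
    """
    pop = np.abs(np.asarray(config.population_coefficients, dtype=float))
    total_var = config.genetic_variance() + config.pe_variance
    sd_cap = 0.25 * np.maximum(pop, 1.0)      # allowed natural-scale sd
    J = _curve_jacobian(config.population_params(), config.times)
    evals, evecs = np.linalg.eigh(J.T @ J)
    if evals.min() <= 0:
        raise ValueError("population curve Jacobian is rank deficient")
    S = np.sqrt(config.info_scale) * (evecs / np.sqrt(evals)) @ evecs.T
    sd_nat = np.sqrt(total_var * np.diag(S @ S.T))
    if np.all(sd_nat <= sd_cap):
        return S
    logger.info("information-whitened map infeasible for %s; using bounded "
                "diagonal parameter map", config.family)
    return np.diag(sd_cap / (3.0 * np.sqrt(total_var)))


def simulate_genotypes(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """LD-structured biallelic SNP panel (haplotype copying model)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers
    freqs = rng.uniform(*config.allele_freq_range, size=m)
    haps = np.empty((2 * n, m), dtype=np.int8)
    block = max(config.ld_block_length, 1)
    for j in range(m):
        fresh = rng.random(2 * n) < freqs[j]
        if j % block == 0:
            haps[:, j] = fresh
        else:
            copy = rng.random(2 * n) < config.copy_prob
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    counts = (haps[:n] + haps[n:]).astype(float)
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chrom = 1 + np.arange(m) // per_chrom
    within = np.arange(m) % per_chrom
    markers = pd.DataFrame({
        "chrom": chrom.astype(str),
        "snp": [f"snp{j + 1}" for j in range(m)],
        "cm": 0.0,
        "pos": (within + 1) * config.marker_spacing,
        "a1": "A", "a2": "B",
    })
    ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(counts, markers, ids)


def simulate_effects_and_phenotypes(
        genotypes: GenotypeMatrix, config: SimulationConfig,
        rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw QTL/polygenic/permanent-environmental effects and trajectories."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, m = genotypes.genotypes.shape
    d = config.d
    Vg, Vpe = config.Vg(), config.Vpe()
    f = config.qtl_variance_fraction
    S = config.parameter_map if config.parameter_map is not None \
        else default_parameter_map(config)
    S = np.asarray(S, dtype=float)
    if S.shape != (d, d):
        raise ValueError("parameter_map must be d x d")

    freq = genotypes.allele_freq()
    x = genotypes.imputed()
    het = 2.0 * freq * (1.0 - freq)
    if np.any(het <= 0):
        raise ValueError("monomorphic markers in the simulated panel")

    # QTL effects: MVN with the stated correlation, scaled so the summed
    # QTL variance is the requested fraction of the genetic variance
    q_idx = np.sort(rng.choice(m, size=config.n_qtls, replace=False))
    chol_g = np.linalg.cholesky(Vg)
    raw = rng.standard_normal((config.n_qtls, d)) @ chol_g.T
    scale_q = np.sqrt(f / (config.n_qtls * het[q_idx]))[:, None] \
        if config.n_qtls else np.zeros((0, 1))
    beta = raw * scale_q
    zc = x[:, q_idx] - 2.0 * freq[q_idx]
    g_qtl = zc @ beta

    # polygenic completion: iid marker effects through the standardized panel
    w = (x - 2.0 * freq) / np.sqrt(het)
    chol_poly = np.linalg.cholesky((1.0 - f) * Vg / m + 1e-300 * np.eye(d))
    gamma = rng.standard_normal((m, d)) @ chol_poly.T
    g_poly = w @ gamma

    pe = rng.standard_normal((n, d)) @ np.linalg.cholesky(Vpe).T
    delta = g_qtl + g_poly + pe                       # standardized units
    pop = np.asarray(config.population_coefficients, dtype=float)
    params_nat = pop + delta @ S.T

    t = config.times
    sigma_e = np.sqrt(config.residual_variance)
    series = []
    for i, iid in enumerate(genotypes.ids):
        mean = evaluate_curve(CurveParams(config.family, params_nat[i]), t)
        y = mean + sigma_e * rng.standard_normal(t.size)
        series.append(LongitudinalSeries(iid, t, y))
    return SimulatedDataset(
        config=config, genotypes=genotypes, qtl_indices=q_idx,
        qtl_effects=beta, Vg_true=Vg, Vpe_true=Vpe, parameter_map=S,
        regressions_true=delta, pe_true=pe, params_natural=params_nat,
        series=series,
        seed=config.seed,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes plus effects and trajectories from a single seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    return simulate_effects_and_phenotypes(genotypes, config, rng)


def fit_stage1(dataset: SimulatedDataset, family: str | None = None):
    """Fit every individual's curve and return standardized regressions.

    Returns (regressions (n_kept, d), kept boolean mask, fits).  Fitted
    natural-scale parameters are mapped back to the standardized regression
    scale with the inverse parameter map, so the recovered traits carry the
    generative covariances; individuals whose fit fails to converge are
    dropped (with a log note), as the second hierarchy requires complete
    rows.
    """
    config = dataset.config
    family = family or config.family
    pop = np.asarray(config.population_coefficients, dtype=float)
    S_inv = np.linalg.inv(dataset.parameter_map)
    fits, kept, rows = [], [], []
    for i, s in enumerate(dataset.series):
        fit = fit_curve(s, family)
        fits.append(fit)
        if fit.converged and np.all(np.isfinite(fit.params.coefficients)):
            kept.append(True)
            rows.append(S_inv @ (fit.params.coefficients - pop))
        else:
            kept.append(False)
    kept = np.asarray(kept)
    if not kept.all():
        logger.info("stage 1: dropped %d of %d individuals (non-converged fits)",
                    int((~kept).sum()), kept.size)
    return np.asarray(rows), kept, fits


def estimate_null_from_dataset(dataset: SimulatedDataset,
                               compute_se: bool = False):
    """Convenience pipeline: stage-1 fits, GRM, null REML.

    Returns (components, regressions, kept mask, kinship).
    """
    reg, kept, _ = fit_stage1(dataset)
    g = dataset.genotypes
    g_kept = GenotypeMatrix(g.genotypes[kept], g.markers,
                            [i for i, k in zip(g.ids, kept) if k])
    kin = compute_grm(filter_markers(g_kept, maf_min=0.01, missing_max=0.1))
    names = CurveParams(dataset.config.family,
                        dataset.config.population_coefficients).names
    model = MultiTraitKinshipModel(reg, kin, trait_names=names)
    return model.fit(compute_se=compute_se), reg, kept, kin


def call_qtls(scan, threshold_neglog10: float | None = None,
              window: int = 20) -> np.ndarray:
    """Designate QTLs: significant markers that carry the highest test
    statistic among their ``window`` closest positional neighbours.

    The window is centred on the candidate (window/2 markers each side,
    truncated at chromosome ends); plateaus of equal statistics are resolved
    in favour of the leftmost marker.  Returns a boolean mask over markers.
    """
    records = scan.records if isinstance(scan, ScanResult) else scan
    if threshold_neglog10 is None:
        if not isinstance(scan, ScanResult):
            raise ValueError("threshold required when passing a plain table")
        threshold_neglog10 = scan.threshold_neglog10
    chrom = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy()
    stat = records["chi2_sum"].to_numpy()
    neglog = records["neglog10_p"].to_numpy()
    m = len(records)
    order_ok = all(
        np.all(np.diff(pos[chrom == c]) > 0) for c in pd.unique(chrom))
    if not order_ok:
        raise ValueError("scan must be sorted by position within chromosome")
    half = window // 2
    called = np.zeros(m, dtype=bool)
    for c in pd.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        st = stat[idx]
        for k in range(idx.size):
            if neglog[idx[k]] < threshold_neglog10:
                continue
            lo, hi = max(k - half, 0), min(k + half + 1, idx.size)
            win = st[lo:hi]
            mx = win.max()
            if st[k] == mx and lo + int(np.argmax(win)) == k:
                called[idx[k]] = True
    return called


def replicate_recovery_study(config: SimulationConfig, n_replicates: int = 50,
                             base_seed: int = 0) -> pd.DataFrame:
    """Repeat the full generate-fit-estimate pipeline and summarize recovery.

    Each replicate redraws genotypes, QTL positions/effects and phenotypes,
    fits every individual's curve, estimates (Vg, Vpe) under the null model,
    and records the mean regression heritability, the mean estimated
    permanent-environmental variance, the mean pairwise permanent-
    environmental correlation and the stage-1 mean residual variance.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=int(base_seed + 1000 * rep) % (2 ** 31 - 1))
        ds = simulate_dataset(cfg)
        cc, reg, kept, _ = estimate_null_from_dataset(ds)
        vg, vpe = np.diag(cc.Vg), np.diag(cc.Vpe)
        corr = cc.Vpe / np.sqrt(np.outer(vpe, vpe))
        off = corr[np.triu_indices(cc.d, 1)]
        rows.append({
            "replicate": rep, "seed": cfg.seed,
            "n_kept": int(kept.sum()),
            "heritability_mean": float(np.mean(vg / (vg + vpe))),
            "vg_mean": float(vg.mean()),
            "vpe_mean": float(vpe.mean()),
            "pe_correlation_mean": float(off.mean()),
            "reml_converged": bool(cc.converged),
        })
    return pd.DataFrame(rows)


def power_from_records(records: pd.DataFrame, qtl_snps, thresholds,
                       window: int = 20) -> pd.DataFrame:
    """Power and type-I error of a scan table against known QTL markers.

    A simulated QTL counts as identified when a called marker lies within its
    ``window`` closest neighbours (window/2 each side, truncated at chromosome
    ends); type-I error is the fraction of called markers among markers
    outside every QTL window.
    """
    snp = records["snp"].to_numpy()
    chrom = records["chrom"].to_numpy()
    m = len(records)
    lookup = {s: i for i, s in enumerate(snp)}
    missing = [s for s in qtl_snps if s not in lookup]
    if missing:
        raise ValueError(f"{len(missing)} QTL markers absent from the scan "
                         f"(e.g. {missing[:3]})")
    q_idx = np.array([lookup[s] for s in qtl_snps], dtype=int)
    half = window // 2
    in_window = np.zeros(m, dtype=bool)
    windows = []
    for q in q_idx:
        idx = np.nonzero(chrom == chrom[q])[0]
        k = int(np.nonzero(idx == q)[0][0])
        lo, hi = max(k - half, 0), min(k + half + 1, idx.size)
        windows.append(idx[lo:hi])
        in_window[idx[lo:hi]] = True
    n_null = int((~in_window).sum())
    rows = []
    for th in np.atleast_1d(np.asarray(thresholds, dtype=float)):
        called = call_qtls(records, threshold_neglog10=float(th), window=window)
        identified = sum(bool(called[w].any()) for w in windows)
        fp = int((called & ~in_window).sum())
        rows.append({
            "threshold_neglog10": float(th),
            "power": identified / max(len(q_idx), 1),
            "type1_error": fp / max(n_null, 1),
            "n_called": int(called.sum()),
        })
    return pd.DataFrame(rows)


def evaluate_power_roc(dataset: SimulatedDataset, scan,
                       thresholds, window: int = 20) -> pd.DataFrame:
    """Power/ROC table of a scan over this dataset's simulated QTLs."""
    records = scan.records if isinstance(scan, ScanResult) else scan
    qtl_snps = [str(dataset.genotypes.markers["snp"].iloc[q])
                for q in dataset.qtl_indices]
    return power_from_records(records, qtl_snps, thresholds, window)
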