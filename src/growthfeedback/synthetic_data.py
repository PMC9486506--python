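"""Synthetic data with the statistical structure the analysis assumes.

The generator closes the growth-expression feedback loop self-consistently:
the expression level chi follows a growth-rate-linear regulation law
(rising toward a fixed maximum at zero growth) blended toward a common
convergence level as drug is added, while the growth rate follows the
resource-allocation model given chi. The emitted (growth, expression)
pairs are the unique fixed point of this loop, so every downstream stage
(growth fitting, regulation-surface construction, two-stage model fitting,
checkerboard contours, mutant-screen correlations) can be exercised against
known ground truth.

Noise is multiplicative lognormal with a configurable coefficient of
variation (plate-reader day-to-day CVs are a few percent), with a small
additive OD floor for time series. All randomness is driven by the config
seed; identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import Checkerboard, NormalizationMode
from .growth_quant import Medium, SignalKind, WellTimeSeries
from .resource_model import (ModelParams, RegulationModeKind, drug_free_growth,
                             growth_rate_model)

__all__ = [
    "RegulationParams",
    "SynthConfig",
    "regulation_law",
    "solve_growth_fixed_point",
    "generate_regulation_dataset",
    "generate_surface_dataset",
    "generate_growth_timeseries",
    "generate_checkerboard",
    "generate_mutant_ensemble",
]


@dataclass(frozen=True)
class RegulationParams:
    """Growth-rate-dependent expression law of the drug target.

    Drug-free expression declines linearly with growth rate from a fixed
    maximum ``chi_max`` at zero growth:  chi(lambda) = chi_max -
    slope_lambda * lambda.  As drug concentration rises toward ``clamp_c``
    the expression blends linearly (in c) toward the common convergence
    level reached at clamp_c, and stays there beyond — expression across
    all limitation levels converges once the drug response saturates.
    """

    chi_max: float  # a.u., expression at zero growth
    slope_lambda: float  # a.u. per (1/h)
    converge_level: float  # a.u., common level at c >= clamp_c
    clamp_c: float = 0.4  # ug/ml

    def __post_init__(self) -> None:
        if self.chi_max <= 0 or self.converge_level <= 0:
            raise ValueError("expression levels must be positive")
        if self.slope_lambda < 0:
            raise ValueError("slope_lambda must be non-negative")

    def baseline(self, lam):
        """Drug-free expression at growth rate ``lam``."""
        return self.chi_max - self.slope_lambda * np.asarray(lam, dtype=float)


def regulation_law(lam, c, reg: RegulationParams):
    """Expression chi(lambda, c): growth-linear baseline blended toward the
    convergence level linearly in c over [0, clamp_c], constant beyond."""
    lam = np.asarray(lam, dtype=float)
    c = np.asarray(c, dtype=float)
    base = reg.baseline(lam)
    w = np.clip(c / reg.clamp_c, 0.0, 1.0)
    out = (1.0 - w) * base + w * reg.converge_level
    return float(out) if out.ndim == 0 else out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic pipeline."""

    truth: ModelParams
    regulation: RegulationParams
    seed: int = 0
    noise_cv: float = 0.05  # multiplicative measurement noise
    sampling_interval: float = 10.0  # minutes
    a_grid: Tuple[float, ...] = (0.0, 2.5, 5.0, 10.0)
    c_grid: Tuple[float, ...] = (0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.6, 0.9)
    n_replicates: int = 1  # replicate measurements per (a, c) condition
    n_mutants: int = 500
    mutant_g0_mean: float = 0.75  # 1/h
    mutant_g0_cv: float = 0.25
    rate_noise_cv: float = 0.03  # day-to-day CV of fitted growth rates
    od_floor: float = 1e-4  # additive OD noise floor, a.u.


def solve_growth_fixed_point(a: float, c: float, truth: ModelParams,
                             reg: RegulationParams) -> Tuple[float, float]:
    """Self-consistent (growth rate, expression) at one (a, c) condition.

    Solves lambda = lambda0(a) * min(1, chi(lambda, c)/chi_X / (1 + c/K_Mc))
    by bracketed root finding on [0, lambda0(a)]. The right-hand side is
    non-increasing in lambda (expression falls with growth), so the fixed
    point is unique.
    """
    lam0 = drug_free_growth(a, truth)

    def chi_of(lam):
        return regulation_law(lam, c, reg)

    def gap(lam):
        return lam - growth_rate_model(a, c, chi_of(lam), truth)

    if reg.baseline(lam0) < 0:
        raise ValueError("regulation law gives negative expression over the "
                         "feasible growth range; degenerate regulation")
    g_hi = gap(lam0)
    if g_hi <= 0:  # unaffected regime: lambda = lambda0 exactly
        return lam0, float(chi_of(lam0))
    g_lo = gap(0.0)
    if g_lo > 0:
        raise ValueError("no sign change on [0, lambda0]; degenerate regulation")
    if g_lo == 0.0:
        return 0.0, float(chi_of(0.0))
    lam = brentq(gap, 0.0, lam0, xtol=1e-14, rtol=1e-14)
    return float(lam), float(chi_of(lam))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative noise with coefficient of variation ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_regulation_dataset(config: SynthConfig) -> pd.DataFrame:
    """Measurement records (a, c, growth, expression) over the (a, c) grid.

    Each record is the feedback fixed point with multiplicative lognormal
    noise of the configured CV on both growth and expression. With the
    default regulation the dataset shows the two qualitative signatures of
    growth-mediated target regulation: expression rises as drug-free growth
    falls, and expression across limitation levels converges at high drug.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for a in config.a_grid:
        for c in config.c_grid:
            lam, chi = solve_growth_fixed_point(a, c, config.truth,
                                                config.regulation)
            rows.extend([(a, c, lam, chi)] * config.n_replicates)
    df = pd.DataFrame(rows, columns=["a", "c", "growth", "expression"])
    df["growth"] *= _lognormal_factors(rng, config.noise_cv, len(df))
    df["expression"] *= _lognormal_factors(rng, config.noise_cv, len(df))
    return df


def generate_surface_dataset(surface, params: ModelParams,
                             a_grid=(0.0, 2.5, 5.0, 10.0),
                             c_grid=(0.0, 0.1, 0.15, 0.2, 0.25, 0.3, 0.4, 0.6, 0.9),
                             n_replicates: int = 6, noise_cv: float = 0.02,
                             seed: int = 0) -> pd.DataFrame:
    """Records generated by the growth model itself at a given surface.

    Growth at each (a, c) is the open-loop model evaluated at the surface's
    expression value (no fixed point), with multiplicative lognormal noise
    on both growth and expression. Because the recorded expression and the
    fitting surface coincide exactly, the two-stage fit on this dataset is
    a pure parameter-recovery problem — the route used by the
    parameter-recovery suite.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a in a_grid:
        for c in c_grid:
            chi = float(surface.evaluate(a, c))
            g = growth_rate_model(a, c, chi, params)
            rows.extend([(a, c, g, chi)] * n_replicates)
    df = pd.DataFrame(rows, columns=["a", "c", "growth", "expression"])
    df["growth"] *= _lognormal_factors(rng, noise_cv, len(df))
    df["expression"] *= _lognormal_factors(rng, noise_cv, len(df))
    return df


def generate_growth_timeseries(rate: float, od0: float = 0.001,
                               blank: float = 0.04,
                               config: Optional[SynthConfig] = None,
                               duration_min: float = 1200.0,
                               carrying_capacity: float = 0.5,
                               medium: Medium = Medium.MINIMAL,
                               seed: Optional[int] = None) -> WellTimeSeries:
    """Simulated OD600 time course: exponential to a carrying capacity.

    OD(t) grows exponentially at the given rate (1/h) from ``od0`` until it
    reaches the carrying capacity, where it saturates (nutrient exhaustion
    ends exponential growth abruptly, so the exponential window stays
    exactly log-linear). Sampled every ``sampling_interval`` minutes with
    multiplicative lognormal noise and a small additive read-noise floor,
    offset by the blank; noiseless configs give exact curves.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if config is None:
        config = SynthConfig(truth=ModelParams(0.5, 0.5, 0.26, 1.0),
                             regulation=RegulationParams(1.7, 0.7, 1.7))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(0.0, duration_min + 1e-9, config.sampling_interval)
    od = np.minimum(od0 * np.exp(rate * t / 60.0), carrying_capacity)
    if config.noise_cv > 0:
        od = od * _lognormal_factors(rng, config.noise_cv, len(t))
        od = od + rng.normal(0.0, config.od_floor, size=len(t))
    signal = np.clip(od, 0.0, None) + blank
    return WellTimeSeries(time=t, signal=signal, signal_kind=SignalKind.OD,
                          blank=blank, medium=medium,
                          label=f"synthetic rate={rate:g}")


def generate_checkerboard(config: SynthConfig) -> Checkerboard:
    """Growth-rate checkerboard (limitation x drug) from the feedback fixed point."""
    rng = np.random.default_rng(config.seed)
    a_grid = np.asarray(config.a_grid, dtype=float)
    c_grid = np.asarray(config.c_grid, dtype=float)
    growth = np.empty((len(a_grid), len(c_grid)))
    for i, a in enumerate(a_grid):
        for j, c in enumerate(c_grid):
            growth[i, j], _ = solve_growth_fixed_point(a, c, config.truth,
                                                       config.regulation)
    growth *= _lognormal_factors(rng, config.noise_cv, growth.shape)
    return Checkerboard(row_values=a_grid, col_concs=c_grid, growth=growth,
                        normalization_mode=NormalizationMode.PER_ROW_ZERO_DOSE)


def _effective_limitation(g0: float, truth: ModelParams) -> float:
    """Limitation ratio a with drug-free growth g0: inverse of lambda0(a)."""
    a = (1.0 / g0 - truth.omega_R) / truth.omega_C - 1.0
    return max(a, 0.0)


def wildtype_inhibitory_concentration(config: SynthConfig,
                                      inhibition: float = 0.3) -> float:
    """Concentration inhibiting the unlimited (a=0) fixed-point growth by the
    given fraction — the screen's working concentration."""
    lam_ref, _ = solve_growth_fixed_point(0.0, 0.0, config.truth,
                                          config.regulation)
    target = (1.0 - inhibition) * lam_ref

    def gap(c):
        lam, _ = solve_growth_fixed_point(0.0, c, config.truth,
                                          config.regulation)
        return lam - target

    c_hi = 0.1
    while gap(c_hi) > 0 and c_hi < 1e4:
        c_hi *= 2.0
    return brentq(gap, 0.0, c_hi, xtol=1e-10)


def generate_mutant_ensemble(config: SynthConfig,
                             feedback: RegulationModeKind | str = RegulationModeKind.WILDTYPE,
                             drug_conc: Optional[float] = None) -> pd.DataFrame:
    """Gene-deletion-like strain ensemble with growth-mediated drug responses.

    Per-strain drug-free growth rates are drawn from a lognormal with the
    configured mean and CV (truncated to the feasible range). Each strain's
    growth under drug follows from the feedback fixed point at an effective
    limitation ratio solved from lambda0(a) = g0 — the ensemble encodes only
    the growth-mediated pathway, no gene-specific drug interactions. With
    ``feedback="constant"`` the expression is pinned at its unlimited
    drug-free level, switching the feedback off; responses then carry no
    information about g0.
    """
    feedback = RegulationModeKind(feedback)
    rng = np.random.default_rng(config.seed)
    if drug_conc is None:
        drug_conc = wildtype_inhibitory_concentration(config)

    mu, cv = config.mutant_g0_mean, config.mutant_g0_cv
    sigma = np.sqrt(np.log1p(cv**2))
    g0 = mu * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                            size=config.n_mutants)
    g0 = np.clip(g0, 0.02, drug_free_growth(0.0, config.truth) * 0.999)

    if feedback is RegulationModeKind.CONSTANT:
        chi_const = regulation_law(drug_free_growth(0.0, config.truth), 0.0,
                                   config.regulation)

    g_drug = np.empty_like(g0)
    for i, g in enumerate(g0):
        a_eff = _effective_limitation(g, config.truth)
        if feedback is RegulationModeKind.WILDTYPE:
            g_drug[i], _ = solve_growth_fixed_point(a_eff, drug_conc,
                                                    config.truth,
                                                    config.regulation)
        else:  # constant: open-loop with expression pinned
            g_drug[i] = growth_rate_model(a_eff, drug_conc, chi_const,
                                          config.truth)

    # fitted growth rates carry the (smaller) day-to-day rate CV, not the
    # per-read signal CV; the same measured g0 normalizes the response, so
    # its noise enters both screen axes, as in a real screen
    g0_obs = g0 * _lognormal_factors(rng, config.rate_noise_cv, len(g0))
    g_drug_obs = g_drug * _lognormal_factors(rng, config.rate_noise_cv, len(g0))
    return pd.DataFrame({
        "strain_id": [f"mut{i:04d}" for i in range(config.n_mutants)],
        "g0": g0_obs,
        "g_drug": g_drug_obs,
    })
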