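"""Reduced resource-allocation model of trimethoprim action on bacterial growth.

The model coarse-grains the proteome into two sectors: ribosomal/metabolic
(R) and nutrient-scavenging (C), with phi_R + phi_C = 1 and the growth-law
relation phi_R = omega_R * lambda. Glucose limitation is imposed by the
ratio ``a`` of a non-metabolizable glucose analog to glucose, which dilutes
the importable substrate. In the saturated-uptake limit (K_Ma -> 0) the
drug-free growth rate is

    lambda0(a) = 1 / (omega_R + omega_C * (a + 1)).

Trimethoprim (TMP) at concentration ``c`` binds its target enzyme, the
dihydrofolate reductase FolA, with equilibrium constant K_Mc, leaving free
enzyme chi / (1 + c/K_Mc) out of a total expression level chi. Growth is
ribosome-limited until free FolA falls below a fixed demand chi_X, after
which it becomes FolA-limited:

    lambda(a, c, chi) = lambda0(a) * min(1, (chi/chi_X) / (1 + c/K_Mc)).

Rescaling lambda by omega_R, c by K_Mc and chi by chi_X leaves a single
dimensionless parameter A = omega_C / omega_R.

The expression level chi is not free: it is regulated by the cell. Its
measured dependence on limitation and drug, the regulation surface
F_FolA(a, c), is built from per-condition linear regressions of expression
against c on [0, clamp_c] and clamped above clamp_c (where expression
across conditions converges). Feeding the surface back into the growth
equation closes the growth-mediated feedback loop; replacing it with a
constant or inverted surface rewires the loop in silico.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .dose_response import DoseResponseCurve, HillFit, HillFitOptions, fit_hill

__all__ = [
    "ModelParams",
    "RescaledParams",
    "RegulationSurface",
    "RewiredSurface",
    "RegulationMode",
    "proteome_fractions",
    "drug_free_growth",
    "free_fola",
    "growth_rate_model",
    "rescaled_growth",
    "filter_measurements",
    "build_regulation_surface",
    "fit_drug_free",
    "fit_drug_response",
    "rewire_regulation",
    "model_dose_response",
]

# model-fitting filter thresholds
FILTER_MAX_A = 10.0
FILTER_MIN_GROWTH = 0.05  # 1/h
DRUG_FREE_MAX_C = 0.1  # ug/ml: "negligible drug" cutoff for the first-stage fit


@dataclass(frozen=True)
class ModelParams:
    """Dimensional model parameters.

    omega_R, omega_C : h
        Proteome-cost coefficients of the R and C sectors.
    K_Mc : ug/ml
        FolA-TMP binding equilibrium constant.
    chi_demand : expression a.u.
        Cellular demand for FolA (chi_X); only the ratio chi/chi_demand
        enters the growth rate, so its unit is that of the expression data.
    K_Ma : dimensionless
        Substrate-uptake saturation constant; 0 in the saturated limit.
    """

    omega_R: float
    omega_C: float
    K_Mc: float
    chi_demand: float
    K_Ma: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_R", "omega_C", "K_Mc", "chi_demand"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.K_Ma < 0:
            raise ValueError("K_Ma must be non-negative")

    def rescaled(self) -> "RescaledParams":
        return RescaledParams(A=self.omega_C / self.omega_R,
                              scale_lambda=self.omega_R,
                              scale_c=self.K_Mc,
                              scale_chi=self.chi_demand)


@dataclass(frozen=True)
class RescaledParams:
    """Dimensionless reduction: A = omega_C/omega_R plus the three scales."""

    A: float
    scale_lambda: float  # omega_R, h
    scale_c: float  # K_Mc, ug/ml
    scale_chi: float  # chi_demand, a.u.

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")

    def dimensional(self) -> ModelParams:
        return ModelParams(omega_R=self.scale_lambda,
                           omega_C=self.A * self.scale_lambda,
                           K_Mc=self.scale_c,
                           chi_demand=self.scale_chi)


def proteome_fractions(lam: float, params: ModelParams) -> Tuple[float, float]:
    """Proteome fractions (phi_R, phi_C) at growth rate ``lam`` (1/h)."""
    phi_r = params.omega_R * lam
    if np.any(np.asarray(phi_r) > 1.0):
        raise ValueError("allocation infeasible: omega_R * lambda > 1")
    return phi_r, 1.0 - phi_r


def drug_free_growth(a, params: ModelParams):
    """Drug-free growth rate lambda0(a) = 1/(omega_R + omega_C (K_Ma + a + 1))."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("limitation ratio a must be non-negative")
    out = 1.0 / (params.omega_R + params.omega_C * (params.K_Ma + a + 1.0))
    return float(out) if out.ndim == 0 else out


def free_fola(chi, c, K_Mc: float):
    """Free (unbound) FolA: chi / (1 + c / K_Mc)."""
    chi = np.asarray(chi, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.any(chi < 0) or np.any(c < 0):
        raise ValueError("chi and c must be non-negative")
    out = chi / (1.0 + c / K_Mc)
    return float(out) if out.ndim == 0 else out


def growth_rate_model(a, c, chi, params: ModelParams):
    """Growth rate lambda(a, c, chi) of the min-limited resource model."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    chi = np.asarray(chi, dtype=float)
    lam0 = 1.0 / (params.omega_R + params.omega_C * (params.K_Ma + a + 1.0))
    supply = (chi / params.chi_demand) / (1.0 + c / params.K_Mc)
    out = lam0 * np.minimum(1.0, supply)
    return float(out) if out.ndim == 0 else out


def rescaled_growth(a, c_bar, chi_bar, A: float):
    """Dimensionless growth: min(1, chi_bar/(1+c_bar)) / (1 + A (a + 1))."""
    a = np.asarray(a, dtype=float)
    c_bar = np.asarray(c_bar, dtype=float)
    chi_bar = np.asarray(chi_bar, dtype=float)
    out = np.minimum(1.0, chi_bar / (1.0 + c_bar)) / (1.0 + A * (a + 1.0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# regulation surface


class RegulationSurface:
    """Expression surface F_FolA(a, c) from per-condition linear regressions.

    At each limitation node ``a`` the expression level is a fitted line
    intercept + slope * c over c in [0, clamp_c]; evaluation clamps c at
    clamp_c (expression converges across conditions above it) and
    interpolates the node predictions piecewise-linearly across ``a``.
    """

    def __init__(self, a_nodes: Sequence[float], intercepts: Sequence[float],
                 slopes: Sequence[float], clamp_c: float = 0.4,
                 allow_nearest: bool = False):
        order = np.argsort(np.asarray(a_nodes, dtype=float))
        self.a_nodes = np.asarray(a_nodes, dtype=float)[order]
        self.intercepts = np.asarray(intercepts, dtype=float)[order]
        self.slopes = np.asarray(slopes, dtype=float)[order]
        if len(self.a_nodes) < 1:
            raise ValueError("at least one limitation node required")
        if len(np.unique(self.a_nodes)) != len(self.a_nodes):
            raise ValueError("limitation nodes must be distinct")
        self.clamp_c = float(clamp_c)
        self.allow_nearest = allow_nearest

    def evaluate(self, a, c):
        """Expression level at limitation ratio(s) ``a`` and concentration(s) ``c``."""
        a = np.asarray(a, dtype=float)
        c = np.asarray(c, dtype=float)
        if not self.allow_nearest:
            if np.any(a < self.a_nodes[0]) or np.any(a > self.a_nodes[-1]):
                raise ValueError(
                    "limitation ratio outside the node hull; pass allow_nearest=True "
                    "to clamp to the nearest node")
        c_eff = np.minimum(c, self.clamp_c)
        a_b, c_b = np.broadcast_arrays(a, c_eff)
        shape = a_b.shape
        a_f = np.atleast_1d(a_b).ravel()
        c_f = np.atleast_1d(c_b).ravel()
        # node predictions at each point's concentration, then linear interp in a
        nodes = self.a_nodes
        if len(nodes) == 1:
            vals = (self.intercepts[0] + self.slopes[0] * c_f).reshape(shape)
            return float(vals) if vals.ndim == 0 else vals
        a_cl = np.clip(a_f, nodes[0], nodes[-1])
        hi = np.clip(np.searchsorted(nodes, a_cl, side="right"), 1, len(nodes) - 1)
        lo = hi - 1
        with np.errstate(invalid="ignore"):
            w = np.where(nodes[hi] > nodes[lo],
                         (a_cl - nodes[lo]) / (nodes[hi] - nodes[lo]), 0.0)
        v_lo = self.intercepts[lo] + self.slopes[lo] * c_f
        v_hi = self.intercepts[hi] + self.slopes[hi] * c_f
        vals = ((1.0 - w) * v_lo + w * v_hi).reshape(shape)
        return float(vals) if vals.ndim == 0 else vals

    __call__ = evaluate


class RegulationModeKind(str, enum.Enum):
    WILDTYPE = "wildtype"
    CONSTANT = "constant"
    INVERTED = "inverted"


@dataclass
class RegulationMode:
    """A feedback-rewiring prescription anchored at chi1, the wild-type
    expression level at c = 1 ug/ml."""

    mode: RegulationModeKind
    chi1: Optional[float] = None

    def __post_init__(self) -> None:
        self.mode = RegulationModeKind(self.mode)


class RewiredSurface:
    """Expression surface with the growth-mediated feedback rewired.

    constant: expression fixed at chi1 for all (a, c).
    inverted: expression 2*chi1 at c = 0, decreasing linearly to chi1 at
    c = 1 ug/ml and constant beyond — the feedback loop run backwards.
    """

    def __init__(self, mode: RegulationModeKind, chi1: float):
        self.mode = RegulationModeKind(mode)
        if self.mode is RegulationModeKind.WILDTYPE:
            raise ValueError("wildtype mode keeps the original surface")
        self.chi1 = float(chi1)

    def evaluate(self, a, c):
        c = np.asarray(c, dtype=float)
        if self.mode is RegulationModeKind.CONSTANT:
            out = np.broadcast_to(self.chi1, np.broadcast(a, c).shape).copy()
        else:  # inverted
            out = self.chi1 * (2.0 - np.minimum(c, 1.0))
            out = np.broadcast_to(out, np.broadcast(a, c).shape).copy()
        return float(out) if out.ndim == 0 else out

    __call__ = evaluate


def rewire_regulation(surface: RegulationSurface, mode: RegulationMode | str,
                      a_ref: float = 0.0):
    """Rewire the feedback loop encoded in a regulation surface.

    The anchor chi1 is the surface value at (a_ref, c = 1 ug/ml) unless
    given explicitly in ``mode``. Returns the original surface for
    wildtype, otherwise a :class:`RewiredSurface`.
    """
    if isinstance(mode, (str, RegulationModeKind)):
        mode = RegulationMode(mode)
    if mode.mode is RegulationModeKind.WILDTYPE:
        return surface
    chi1 = mode.chi1
    if chi1 is None:
        chi1 = float(surface.evaluate(a_ref, 1.0))
    return RewiredSurface(mode.mode, chi1)


# ---------------------------------------------------------------------------
# measurement filtering and two-stage fitting


def filter_measurements(records: pd.DataFrame) -> pd.DataFrame:
    """Flag measurement records usable for model fitting.

    A record passes iff the limitation ratio a <= 10, growth >= 0.05 1/h,
    and expression > 0 (zero fluorescence intensity indicates a failed
    measurement). Records are retained and flagged, never dropped.
    """
    out = records.copy()
    out["passes_filter"] = ((out["a"] <= FILTER_MAX_A)
                            & (out["growth"] >= FILTER_MIN_GROWTH)
                            & (out["expression"] > 0))
    return out


def build_regulation_surface(records: pd.DataFrame, clamp_c: float = 0.4,
                             allow_nearest: bool = False) -> RegulationSurface:
    """Construct the regulation surface F_FolA(a, c) from expression records.

    Per limitation node ``a``, ordinary least squares of expression against
    c restricted to c in [0, clamp_c]; replicate measurements at one (a, c)
    enter with equal weight. Records failing the fit filter (if flagged)
    are excluded. Points beyond clamp_c do not enter the regression; the
    clamp represents the observed convergence of expression across
    conditions above clamp_c.
    """
    df = records
    if "passes_filter" in df.columns:
        df = df[df["passes_filter"]]
    a_nodes, intercepts, slopes = [], [], []
    for a_val, grp in df.groupby("a"):
        sub = grp[grp["c"] <= clamp_c]
        if sub["c"].nunique() < 2:
            raise ValueError(
                f"limitation node a={a_val} has fewer than 2 distinct "
                f"concentrations in [0, {clamp_c}]")
        slope, intercept = np.polyfit(sub["c"].to_numpy(dtype=float),
                                      sub["expression"].to_numpy(dtype=float), 1)
        a_nodes.append(float(a_val))
        intercepts.append(float(intercept))
        slopes.append(float(slope))
    return RegulationSurface(a_nodes, intercepts, slopes, clamp_c=clamp_c,
                             allow_nearest=allow_nearest)


@dataclass
class DrugFreeFit:
    omega_R: float
    omega_C: float
    sd_omega_R: float
    sd_omega_C: float
    rss: float
    n_points: int


def fit_drug_free(records: pd.DataFrame, max_c: float = DRUG_FREE_MAX_C) -> DrugFreeFit:
    """First-stage fit: (omega_R, omega_C) from near-drug-free measurements.

    Least-squares fit of lambda0(a) = 1/(omega_R + omega_C (a+1)) to
    (a, growth) pairs with c below ``max_c``, using filtered records.
    """
    df = records
    if "passes_filter" in df.columns:
        df = df[df["passes_filter"]]
    df = df[df["c"] < max_c]
    a = df["a"].to_numpy(dtype=float)
    g = df["growth"].to_numpy(dtype=float)
    if len(np.unique(a)) < 2:
        raise ValueError("need at least 2 distinct limitation ratios for the "
                         "drug-free fit")

    def resid(theta):
        wr, wc = np.exp(theta)
        return 1.0 / (wr + wc * (a + 1.0)) - g

    # moment start: lambda0(0) ~ max g
    g_max = max(g.max(), 1e-6)
    x0 = np.log([0.5 / g_max, 0.5 / g_max])
    res = least_squares(resid, x0, method="lm", max_nfev=5000)
    wr, wc = np.exp(res.x)
    rss = float(2 * res.cost)
    dof = max(len(g) - 2, 1)
    try:
        cov = rss / dof * np.linalg.inv(res.jac.T @ res.jac)
        sd_log = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        sd_log = np.array([np.inf, np.inf])
    return DrugFreeFit(float(wr), float(wc), float(wr * sd_log[0]),
                       float(wc * sd_log[1]), rss, len(g))


@dataclass
class DrugResponseFit:
    K_Mc: float
    chi_demand: float
    rss: float
    n_points: int
    n_starts: int


def fit_drug_response(records: pd.DataFrame, omega_R: float, omega_C: float,
                      surface: RegulationSurface, n_starts: int = 8,
                      seed: int = 0) -> DrugResponseFit:
    """Second-stage fit: (K_Mc, chi_demand) with (omega_R, omega_C) fixed.

    Substitutes the regulation surface for the expression level and fits
    the min-limited growth model to (a, c, growth) by derivative-free
    Nelder-Mead over log parameters from seeded multi-starts (the min()
    kink makes the objective non-smooth, so gradient methods are avoided).
    """
    df = records
    if "passes_filter" in df.columns:
        df = df[df["passes_filter"]]
    a = df["a"].to_numpy(dtype=float)
    c = df["c"].to_numpy(dtype=float)
    g = df["growth"].to_numpy(dtype=float)
    chi = np.asarray(surface.evaluate(a, c), dtype=float)
    lam0 = 1.0 / (omega_R + omega_C * (a + 1.0))

    def sse(theta):
        kmc, chix = np.exp(theta)
        pred = lam0 * np.minimum(1.0, (chi / chix) / (1.0 + c / kmc))
        return float(np.sum((pred - g) ** 2))

    rng = np.random.default_rng(seed)
    chi_scale = float(np.median(chi))
    c_pos = c[c > 0]
    c_scale = float(np.median(c_pos)) if len(c_pos) else 1.0
    starts = [np.log([c_scale, chi_scale])]
    for _ in range(n_starts - 1):
        starts.append(np.log([c_scale, chi_scale])
                      + rng.uniform(-2.0, 2.0, size=2))
    best = None
    for x0 in starts:
        res = minimize(sse, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    kmc, chix = np.exp(best.x)
    pred = lam0 * np.minimum(1.0, (chi / chix) / (1.0 + c / kmc))
    if np.allclose(pred, lam0):
        raise ValueError(
            "all records lie in the ribosome-limited regime (min = 1 "
            "everywhere); chi_demand is unidentifiable")
    return DrugResponseFit(float(kmc), float(chix), float(best.fun), len(g),
                           n_starts)


def model_dose_response(params: ModelParams, surface, a: float,
                        c_grid: np.ndarray,
                        hill_options: Optional[HillFitOptions] = None,
                        ) -> Tuple[DoseResponseCurve, HillFit]:
    """Model dose-response curve at limitation ``a`` and its Hill fit.

    Evaluates the growth model with expression taken from the regulation
    surface over ``c_grid``, normalizes by the zero-dose value, and fits a
    Hill function exactly as for experimental curves. Warns if the grid
    does not reach deep inhibition (normalized growth at max c above 0.2).
    """
    c_grid = np.asarray(c_grid, dtype=float)
    chi = np.asarray(surface.evaluate(np.full_like(c_grid, a), c_grid))
    growth = growth_rate_model(np.full_like(c_grid, a), c_grid, chi, params)
    curve = DoseResponseCurve(conc=c_grid, growth=np.asarray(growth))
    if curve.normalized()[-1] > 0.2:
        warnings.warn("dose grid may be too narrow: normalized growth at the "
                      "highest concentration exceeds 0.2", stacklevel=2)
    fit = fit_hill(curve, hill_options)
    return curve, fit
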