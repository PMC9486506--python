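"""Hill dose-response fitting, inhibitory concentrations, and checkerboard contours.

The dose-response curve of a drug is summarised by the Hill function

    g(c) / g0 = 1 / (1 + (c / IC50)**n)

where ``g0`` is the drug-free growth rate, ``IC50`` the concentration of
50% growth inhibition, and ``n`` the dose-sensitivity (Hill exponent):
shallow responses have n near 1, ultrasensitive ones n above 3. The fit is
performed in log10-parameter space with seeded multi-starts.

Checkerboard matrices (growth over a 2-D grid of a growth-limiting
perturbation x drug concentration) yield per-row inhibitory-concentration
contours (e.g. the IC90 line) by interpolating normalized growth against
log concentration, and fold-changes of those contours between conditions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "HillFit",
    "HillFitOptions",
    "Checkerboard",
    "NormalizationMode",
    "ContourStatus",
    "ContourResult",
    "FoldChange",
    "hill",
    "aggregate_replicates",
    "fit_hill",
    "inhibitory_concentration",
    "ic_contour_from_checkerboard",
    "fold_change_ic",
]


class NormalizationMode(str, enum.Enum):
    GLOBAL_MAX = "global_max"
    PER_ROW_ZERO_DOSE = "per_row_zero_dose"


class ContourStatus(str, enum.Enum):
    OK = "ok"
    RIGHT_CENSORED = "right_censored"  # growth never drops to the level
    LEFT_CENSORED = "left_censored"  # already below the level at the lowest dose
    MULTIPLE_CROSSINGS = "multiple_crossings"  # non-monotone row; first crossing used


@dataclass
class DoseResponseCurve:
    """Growth rate versus drug concentration for one condition.

    ``conc`` is in ug/ml (ascending, may include 0), ``growth`` in 1/h.
    """

    conc: np.ndarray
    growth: np.ndarray
    sd: Optional[np.ndarray] = None
    n_replicates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.growth = np.asarray(self.growth, dtype=float)
        if self.conc.shape != self.growth.shape:
            raise ValueError("conc and growth must have equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        order = np.argsort(self.conc, kind="stable")
        self.conc = self.conc[order]
        self.growth = self.growth[order]
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)[order]
            if np.any(self.sd < 0):
                raise ValueError("sd must be non-negative")
        if self.n_replicates is not None:
            self.n_replicates = np.asarray(self.n_replicates)[order]

    def g0(self) -> float:
        """Reference drug-free growth rate: mean growth at zero dose,
        falling back to the lowest-dose growth if no zero-dose point exists."""
        at_zero = self.growth[self.conc == 0]
        if len(at_zero):
            return float(np.mean(at_zero))
        return float(self.growth[0])

    def normalized(self) -> np.ndarray:
        return self.growth / self.g0()


@dataclass
class HillFitOptions:
    g0_mode: str = "fixed_zero_dose"  # or "fitted" (g0 as a third parameter)
    hill_min_rate: Optional[float] = None  # exclude points with growth below (1/h)
    weighted: bool = False  # 1/sd^2 weighting when sd available
    n_starts: int = 5
    seed: int = 0


@dataclass
class HillFit:
    """Fitted Hill parameters with uncertainties."""

    n: float
    ic50: float  # ug/ml
    sd_n: float
    sd_ic50: float
    ci95_n: Tuple[float, float]
    rss: float
    g0: float
    g0_mode: str = "fixed_zero_dose"
    n_points: int = 0
    wide_ci_warning: bool = False

    def predict(self, conc: np.ndarray) -> np.ndarray:
        """Normalized growth predicted at the given concentrations."""
        return hill(np.asarray(conc, dtype=float), self.n, self.ic50)


def aggregate_replicates(conc: np.ndarray, growth: np.ndarray,
                         mode: str = "mean") -> DoseResponseCurve:
    """Combine replicate wells into one dose-response curve.

    ``mode="mean"`` collapses replicates to mean growth with the SD and
    replicate count per concentration; ``mode="pooled"`` keeps every
    replicate as its own point so the Hill fit weighs raw observations.
    """
    conc = np.asarray(conc, dtype=float)
    growth = np.asarray(growth, dtype=float)
    if mode == "pooled":
        return DoseResponseCurve(conc=conc, growth=growth)
    if mode != "mean":
        raise ValueError("mode must be 'mean' or 'pooled'")
    levels = np.unique(conc)
    means = np.array([growth[conc == c].mean() for c in levels])
    sds = np.array([growth[conc == c].std(ddof=1) if (conc == c).sum() > 1
                    else 0.0 for c in levels])
    counts = np.array([(conc == c).sum() for c in levels])
    return DoseResponseCurve(conc=levels, growth=means, sd=sds,
                             n_replicates=counts)


def hill(conc: np.ndarray, n: float, ic50: float) -> np.ndarray:
    """Normalized Hill dose-response, exactly 1 at zero dose."""
    conc = np.asarray(conc, dtype=float)
    out = np.ones_like(conc)
    pos = conc > 0
    with np.errstate(over="ignore"):  # (c/ic50)**n -> inf gives the 0 limit
        out[pos] = 1.0 / (1.0 + (conc[pos] / ic50) ** n)
    return out


def fit_hill(curve: DoseResponseCurve,
             options: Optional[HillFitOptions] = None) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    The fit is over (log10 n, log10 IC50); this keeps both parameters
    positive and makes the optimisation well-scaled. Multi-starts from a
    seeded log-uniform cloud guard against local minima. Parameter standard
    deviations come from the Gauss-Newton covariance at the optimum and are
    propagated from log space by the delta method; the 95% CI on n is the
    log-space interval at +/- 1.96 SD.
    """
    if options is None:
        options = HillFitOptions()
    conc = curve.conc.copy()
    growth = curve.growth.copy()
    sd = curve.sd.copy() if curve.sd is not None else None
    if np.all(growth == 0):
        raise ValueError("all growth values are zero; Hill fit undefined")

    if options.hill_min_rate is not None:
        keep = growth >= options.hill_min_rate
        conc, growth = conc[keep], growth[keep]
        if sd is not None:
            sd = sd[keep]

    g0 = curve.g0()
    y = growth / g0
    distinct = np.unique(conc)
    wide_ci = False
    if len(distinct) < 4 or not (np.any(y > 0.5) and np.any(y < 0.5)):
        wide_ci = True

    weights = np.ones_like(y)
    if options.weighted and sd is not None:
        safe = np.where(sd > 0, sd, np.nanmax(sd[sd > 0]) if np.any(sd > 0) else 1.0)
        weights = 1.0 / (safe / g0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        n_, ic50_ = 10.0 ** theta
        return (hill(conc, n_, ic50_) - y) * weights

    # initial guesses: n=1..4, ic50 near the concentration closest to y=0.5
    pos = conc[conc > 0]
    ic_guess = float(pos[np.argmin(np.abs(y[conc > 0] - 0.5))]) if len(pos) else 1.0
    rng = np.random.default_rng(options.seed)
    starts = [np.array([np.log10(1.5), np.log10(ic_guess)])]
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(np.array([
            rng.uniform(np.log10(0.3), np.log10(8.0)),
            np.log10(ic_guess) + rng.uniform(-1.0, 1.0),
        ]))

    best = None
    for x0 in starts:
        try:
            res = least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("Hill fit failed to converge from any start")

    n_hat, ic50_hat = 10.0 ** best.x
    rss = float(2 * best.cost)
    dof = max(len(y) - 2, 1)
    s2 = rss / dof
    J = best.jac
    try:
        cov_log = s2 * np.linalg.inv(J.T @ J)
        sd_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))
    except np.linalg.LinAlgError:
        sd_log = np.array([np.inf, np.inf])
    ln10 = np.log(10.0)
    sd_n = n_hat * ln10 * sd_log[0]
    sd_ic50 = ic50_hat * ln10 * sd_log[1]
    ci95_n = (n_hat * 10 ** (-1.96 * sd_log[0]), n_hat * 10 ** (1.96 * sd_log[0]))

    return HillFit(n=float(n_hat), ic50=float(ic50_hat), sd_n=float(sd_n),
                   sd_ic50=float(sd_ic50), ci95_n=ci95_n, rss=rss, g0=g0,
                   g0_mode=options.g0_mode, n_points=len(y),
                   wide_ci_warning=wide_ci)


def inhibitory_concentration(fit: HillFit, inhibition_fraction: float) -> float:
    """Concentration causing the given fractional growth inhibition.

    For the Hill curve this is closed-form: IC_f = IC50 * (f/(1-f))**(1/n),
    the concentration at which normalized growth equals 1 - f.
    """
    f = inhibition_fraction
    if not (0.0 < f < 1.0):
        raise ValueError("inhibition fraction must lie in (0, 1)")
    return float(fit.ic50 * (f / (1.0 - f)) ** (1.0 / fit.n))


@dataclass
class Checkerboard:
    """Growth-rate matrix over a 2-D grid of limitation level x drug concentration.

    Rows index the growth-limiting perturbation (e.g. aMG/glucose ratio or
    inducer concentration), columns the drug concentration in ug/ml.
    """

    row_values: np.ndarray
    col_concs: np.ndarray
    growth: np.ndarray  # shape (n_rows, n_cols), 1/h
    normalization_mode: NormalizationMode = NormalizationMode.PER_ROW_ZERO_DOSE

    def __post_init__(self) -> None:
        self.row_values = np.asarray(self.row_values, dtype=float)
        self.col_concs = np.asarray(self.col_concs, dtype=float)
        self.growth = np.asarray(self.growth, dtype=float)
        if self.growth.shape != (len(self.row_values), len(self.col_concs)):
            raise ValueError("growth matrix shape must match axis lengths")
        if np.any(self.growth < 0):
            raise ValueError("growth must be non-negative")
        self.normalization_mode = NormalizationMode(self.normalization_mode)

    def normalized(self) -> np.ndarray:
        if self.normalization_mode is NormalizationMode.GLOBAL_MAX:
            return self.growth / self.growth.max()
        # per-row zero-dose (or lowest-dose) reference
        ref_col = int(np.argmin(self.col_concs))
        ref = self.growth[:, ref_col][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ref > 0, self.growth / ref, np.nan)


@dataclass
class ContourResult:
    """Per-row inhibitory concentrations extracted from a checkerboard."""

    row_values: np.ndarray
    conc: np.ndarray  # ug/ml; NaN where censored
    status: list  # ContourStatus per row
    level: float


def _row_crossings(concs: np.ndarray, norm: np.ndarray, thr: float) -> list:
    """Indices i where norm crosses thr between columns i and i+1."""
    out = []
    for i in range(len(concs) - 1):
        a, b = norm[i], norm[i + 1]
        if (a - thr) == 0 and (b - thr) < 0:
            out.append(i)
        elif (a - thr) > 0 >= (b - thr):
            out.append(i)
    return out


def ic_contour_from_checkerboard(board: Checkerboard, level: float = 0.9,
                                 ) -> ContourResult:
    """Inhibitory-concentration contour (e.g. the IC90 line) of a checkerboard.

    For each row, finds the concentration at which normalized growth crosses
    ``1 - level`` by linear interpolation of normalized growth against log
    concentration between the bracketing grid columns (linear in
    concentration when the left bracket is the zero-dose column). Rows that
    never cross are censored; non-monotone rows crossing more than once
    return the first crossing with a multiplicity flag.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    thr = 1.0 - level
    norm = board.normalized()
    concs = board.col_concs
    order = np.argsort(concs)
    concs = concs[order]
    n_rows = len(board.row_values)
    out = np.full(n_rows, np.nan)
    status = []
    for r in range(n_rows):
        row = norm[r, order]
        if row[0] <= thr:
            status.append(ContourStatus.LEFT_CENSORED)
            continue
        crossings = _row_crossings(concs, row, thr)
        if not crossings:
            status.append(ContourStatus.RIGHT_CENSORED)
            continue
        i = crossings[0]
        c_lo, c_hi = concs[i], concs[i + 1]
        y_lo, y_hi = row[i], row[i + 1]
        if y_lo == y_hi:
            c_star = c_lo
        elif c_lo <= 0:
            c_star = c_lo + (thr - y_lo) * (c_hi - c_lo) / (y_hi - y_lo)
        else:
            lg = np.log(c_lo) + (thr - y_lo) * (np.log(c_hi) - np.log(c_lo)) / (y_hi - y_lo)
            c_star = np.exp(lg)
        out[r] = c_star
        status.append(ContourStatus.MULTIPLE_CROSSINGS if len(crossings) > 1
                      else ContourStatus.OK)
    return ContourResult(board.row_values.copy(), out, status, level)


@dataclass
class FoldChange:
    value: float
    sd: float
    censored: bool
    reference_row: int
    center_row: int
    rows_used: Sequence[int]


def fold_change_ic(contour: ContourResult, reference_row: int, center_row: int,
                   neighbor_halfwidth: int = 1) -> FoldChange:
    """Fold-change of the inhibitory-concentration contour between conditions.

    Mean and SD of the contour over the ``2*halfwidth + 1`` rows centered at
    ``center_row``, divided by the contour value at ``reference_row``. A
    censored contour among the selected rows propagates as a censored
    fold-change (NaN value, ``censored=True``).
    """
    lo = center_row - neighbor_halfwidth
    hi = center_row + neighbor_halfwidth
    if lo < 0 or hi >= len(contour.conc):
        raise ValueError("neighbor window extends beyond the board")
    rows = list(range(lo, hi + 1))
    vals = contour.conc[rows]
    ref = contour.conc[reference_row]
    censored = bool(np.any(~np.isfinite(vals)) or not np.isfinite(ref))
    if censored:
        return FoldChange(np.nan, np.nan, True, reference_row, center_row, rows)
    fc = vals / ref
    return FoldChange(float(np.mean(fc)), float(np.std(fc, ddof=0)), False,
                      reference_row, center_row, rows)
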