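"""Gene-deletion screen statistics: normalized drug response vs drug-free growth.

For each deletion strain the response is the growth rate under a fixed drug
concentration normalized to the strain's own drug-free growth rate; values
above 1 (drug-enhanced growth) are permitted. The association between
drug-free growth rate and response across the screen is summarised by
Spearman's rank correlation with a seeded bootstrap standard error. A
strongly negative correlation indicates growth-mediated negative feedback:
slower-growing strains are proportionally less inhibited by the drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StrainRecord",
    "CorrelationResult",
    "normalized_response",
    "screen_responses",
    "spearman_bootstrap",
]


@dataclass
class StrainRecord:
    strain_id: str
    g0: float  # drug-free growth rate, 1/h
    g_drug: float  # growth rate under the fixed drug concentration, 1/h

    @property
    def response(self) -> float:
        return normalized_response(self.g_drug, self.g0)


@dataclass
class CorrelationResult:
    rho_s: float
    bootstrap_se: float
    n_boot: int
    seed: int
    n_strains: int
    ci95: Tuple[float, float]  # percentile bootstrap interval


def normalized_response(g_drug: float, g0: float) -> float:
    """Growth under drug normalized to the strain's drug-free growth rate.

    Not clipped: values above 1 indicate drug-enhanced growth (rescue).
    Undefined for non-growing strains (g0 <= 0).
    """
    if g0 <= 0:
        raise ValueError("normalized response undefined for g0 <= 0")
    return g_drug / g0


def screen_responses(records: pd.DataFrame) -> pd.DataFrame:
    """Per-strain normalized responses; strains with g0 <= 0 or missing
    values are excluded listwise and counted in the ``excluded`` attribute."""
    df = records.copy()
    valid = (df["g0"] > 0) & np.isfinite(df["g0"]) & np.isfinite(df["g_drug"])
    out = df[valid].copy()
    out["response"] = out["g_drug"] / out["g0"]
    out.attrs["excluded"] = int((~valid).sum())
    return out


def spearman_bootstrap(x: np.ndarray, y: np.ndarray, n_boot: int = 1000,
                       seed: int = 0) -> CorrelationResult:
    """Spearman's rho with a seeded bootstrap standard error.

    Ties receive average ranks (standard Spearman). The bootstrap resamples
    (x, y) pairs with replacement; the SE is the standard deviation of rho
    over resamples and the 95% interval is the 2.5-97.5 percentile range.
    Resamples in which either variable is constant are redrawn implicitly by
    being skipped (rho undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    finite = np.isfinite(x) & np.isfinite(y)
    x, y = x[finite], y[finite]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")

    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            continue
        boots.append(stats.spearmanr(xb, yb).statistic)
    boots = np.asarray(boots, dtype=float)
    se = float(np.std(boots, ddof=1)) if len(boots) > 1 else np.nan
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return CorrelationResult(rho_s=rho, bootstrap_se=se, n_boot=n_boot,
                             seed=seed, n_strains=n, ci95=ci)
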