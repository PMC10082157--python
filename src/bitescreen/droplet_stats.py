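"""Analytic models for droplet encapsulation design and screening performance.

Cell loading into monodisperse droplets follows a Poisson distribution
P(k; λ) = e^-λ λ^k / k!, with λ the mean cells per droplet; the library
arm is typically run dilute (λ ≈ 0.3, so ≥96% of droplets hold zero or one
library cell) and the reporter arm dense (λ ≈ 3). Screening performance is
summarized by the per-copy recovery rate p — estimated from a spike-in
titration by regression — and the binomial screening efficiency
P = 1 - (1 - p)^N, the probability of isolating at least one of N copies
of a clone. Sorting gates are set from the unstimulated reporter signal as
μ + kσ, and two orthogonal reporter channels multiply their individual
false-positive rates under independence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "EncapsulationConfig",
    "GateConfig",
    "RecoveryModel",
    "poisson_pmf",
    "occupancy_probability",
    "coencapsulation_rate",
    "lambda_from_positive_fraction",
    "droplet_volume_pl",
    "concentration_for_lambda",
    "lambda_for_concentration",
    "fit_recovery_model",
    "screening_efficiency",
    "min_copies_for_confidence",
    "gate_threshold",
    "dual_reporter_fpr",
]

#: 1 pL = 10^-12 L and 1 µm^3 = 10^-15 L, hence 1 pL = 1000 µm^3.
UM3_PER_PL = 1000.0


@dataclass(frozen=True)
class EncapsulationConfig:
    """Poisson loading design: mean library / reporter cells per droplet."""

    lambda_library: float = 0.3
    lambda_reporter: float = 3.0
    droplet_diameter_um: float = 77.0

    def __post_init__(self) -> None:
        for name in ("lambda_library", "lambda_reporter", "droplet_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GateConfig:
    """Sorting gate μ + kσ from the unstimulated reporter distribution."""

    mu_negative: float
    sigma: float
    k: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")


# ---------------------------------------------------------------------------
# Poisson occupancy
# ---------------------------------------------------------------------------

def poisson_pmf(lam: float, k: int) -> float:
    """P(K = k) for K ~ Poisson(λ), computed stably in log space."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    return float(stats.poisson.pmf(int(k), lam))


def occupancy_probability(lam: float, predicate: str, k: int) -> float:
    """P over droplet occupancy for predicate in {exactly, at_most, at_least}."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    if predicate == "exactly":
        return float(stats.poisson.pmf(k, lam))
    if predicate == "at_most":
        return float(stats.poisson.cdf(k, lam))
    if predicate == "at_least":
        return float(stats.poisson.sf(k - 1, lam))
    raise ValueError(f"predicate {predicate!r}")


def coencapsulation_rate(lambda_lib: float, lambda_rep: float) -> float:
    """P(≥1 library cell and ≥1 reporter) under independent Poisson loading."""
    if lambda_lib <= 0 or lambda_rep <= 0:
        raise ValueError("both lambdas must be > 0")
    return float(-math.expm1(-lambda_lib) * -math.expm1(-lambda_rep))


def lambda_from_positive_fraction(f: float) -> float:
    """Invert P(≥1 cell) = 1 - e^-λ = f for experiment planning."""
    if not 0 < f < 1:
        raise ValueError("fraction must be in (0, 1)")
    return -math.log1p(-f)


# ---------------------------------------------------------------------------
# Volumes and concentrations
# ---------------------------------------------------------------------------

def droplet_volume_pl(diameter_um: float) -> float:
    """Sphere volume in picolitres from diameter in micrometres."""
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    volume_um3 = math.pi / 6.0 * diameter_um**3
    return volume_um3 / UM3_PER_PL


def concentration_for_lambda(lam: float, diameter_um: float) -> float:
    """Cell concentration (cells/mL) giving mean λ cells per droplet."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    volume_ml = droplet_volume_pl(diameter_um) * 1e-9  # 1 pL = 1e-9 mL
    return lam / volume_ml


def lambda_for_concentration(concentration_per_ml: float, diameter_um: float) -> float:
    if concentration_per_ml <= 0:
        raise ValueError("concentration must be > 0")
    return concentration_per_ml * droplet_volume_pl(diameter_um) * 1e-9


# ---------------------------------------------------------------------------
# Recovery-rate regression
# ---------------------------------------------------------------------------

# ec50 enters through |ec50| so the optimizer cannot wander into complex
# powers; half-max concentrations are positive by definition
def _logistic4(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (x / np.abs(ec50)) ** hill)

def _logistic5(x, bottom, top, ec50, hill, s):
    base = np.maximum(1.0 + (x / np.abs(ec50)) ** hill, 1e-12)
    return bottom + (top - bottom) / base**s


@dataclass
class RecoveryModel:
    """Fitted recovery-rate-vs-abundance model with confidence machinery.

    ``predict_lower(abundance)`` is the one-sided lower confidence limit of
    the predicted mean recovery rate at ``confidence_level`` — the bound
    fed into the binomial screening-efficiency curve.
    """

    model_family: str
    coefficients: Dict[str, float]
    r_squared: float
    p_value: float
    residual_variance: float
    confidence_level: float
    diagnostics: Dict[str, float]
    n_obs: int
    _point: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    _lower: Callable[[np.ndarray], np.ndarray] = field(repr=False, default=None)
    conf_int: Optional[pd.DataFrame] = field(repr=False, default=None)

    def predict(self, abundance_percent) -> np.ndarray:
        return self._point(np.atleast_1d(np.asarray(abundance_percent, dtype=float)))

    def predict_lower(self, abundance_percent) -> np.ndarray:
        out = self._lower(np.atleast_1d(np.asarray(abundance_percent, dtype=float)))
        return np.minimum(out, self.predict(abundance_percent))


def fit_recovery_model(
    observations: pd.DataFrame,
    family: str = "linear",
    confidence: float = 0.90,
) -> RecoveryModel:
    """Fit recovery rate (= recovered/spiked) versus spiked abundance.

    ``observations`` needs columns abundance_percent, copies_spiked,
    copies_recovered. The linear family (default, and the family selected
    on the original titration data) is an OLS fit on the raw proportion
    scale, reporting R², the slope p-value, residual diagnostics
    (Breusch–Pagan heteroscedasticity and Shapiro normality p-values), and
    a one-sided lower confidence limit of the predicted mean. The
    logistic4/logistic5 families are least-squares sigmoid fits with a
    normal-approximation lower bound from the residual spread.
    """
    obs = observations
    required = {"abundance_percent", "copies_spiked", "copies_recovered"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns {sorted(missing)}")
    if len(obs) < 3:
        raise ValueError("need at least 3 observations")
    if (obs["copies_recovered"] > obs["copies_spiked"]).any():
        raise ValueError("copies_recovered exceeds copies_spiked")
    x = obs["abundance_percent"].to_numpy(dtype=float)
    y = (obs["copies_recovered"] / obs["copies_spiked"]).to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("observations must span at least 2 abundances")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")

    if family == "linear":
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        resid = fit.resid
        bp_p = float(het_breuschpagan(resid, X)[1])
        shapiro_p = float(stats.shapiro(resid)[1]) if len(resid) >= 3 else float("nan")

        def point(xq: np.ndarray) -> np.ndarray:
            return fit.predict(sm.add_constant(xq, has_constant="add"))

        def lower(xq: np.ndarray) -> np.ndarray:
            pred = fit.get_prediction(sm.add_constant(xq, has_constant="add"))
            # two-sided interval at alpha = 2(1-level) gives the one-sided bound
            return pred.conf_int(alpha=2 * (1 - confidence))[:, 0]

        ci = pd.DataFrame(
            fit.conf_int(alpha=1 - confidence),
            index=["intercept", "slope"],
            columns=["lower", "upper"],
        )
        return RecoveryModel(
            model_family="linear",
            coefficients={"intercept": float(fit.params[0]), "slope": float(fit.params[1])},
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
            residual_variance=float(np.var(resid, ddof=2)) if len(resid) > 2 else 0.0,
            confidence_level=confidence,
            diagnostics={"breusch_pagan_p": bp_p, "shapiro_p": shapiro_p},
            n_obs=len(obs),
            _point=point,
            _lower=lower,
            conf_int=ci,
        )

    if family in ("logistic4", "logistic5"):
        func = _logistic4 if family == "logistic4" else _logistic5
        names = ["bottom", "top", "ec50", "hill"] + (["s"] if family == "logistic5" else [])
        p0 = [float(y.min()), float(y.max() or 0.1), float(np.median(x)), 1.0]
        if family == "logistic5":
            p0.append(1.0)
        try:
            popt, _ = optimize.curve_fit(func, x, y, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise ValueError(f"{family} fit failed to converge: {exc}") from exc
        resid = y - func(x, *popt)
        ss_res = float((resid**2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        sigma = float(np.std(resid, ddof=min(len(popt), len(y) - 1)))
        z = stats.norm.ppf(confidence)

        def point(xq: np.ndarray, popt=popt) -> np.ndarray:
            return func(xq, *popt)

        def lower(xq: np.ndarray, popt=popt) -> np.ndarray:
            return func(xq, *popt) - z * sigma

        return RecoveryModel(
            model_family=family,
            coefficients=dict(zip(names, (float(v) for v in popt))),
            r_squared=max(0.0, min(1.0, r2)),
            p_value=float("nan"),
            residual_variance=sigma**2,
            confidence_level=confidence,
            diagnostics={},
            n_obs=len(obs),
            _point=point,
            _lower=lower,
        )

    raise ValueError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Binomial screening efficiency
# ---------------------------------------------------------------------------

def screening_efficiency(p: float, n_copies: int) -> float:
    """P = 1 - (1 - p)^N: probability of isolating ≥1 of N copies.

    Computed via log1p/expm1 so that small p with large N stays accurate.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n_copies < 0 or n_copies != int(n_copies):
        raise ValueError("N must be a non-negative integer")
    if p == 1.0:
        return 0.0 if n_copies == 0 else 1.0
    return float(-math.expm1(n_copies * math.log1p(-p)))


def min_copies_for_confidence(p: float, confidence: float) -> int:
    """Smallest integer N with screening_efficiency(p, N) ≥ confidence.

    Closed form ceil(ln(1-c)/ln(1-p)), verified by direct evaluation at N
    and N-1 to absorb floating-point edge cases.
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    n = max(1, math.ceil(math.log1p(-confidence) / math.log1p(-p)))
    while screening_efficiency(p, n) < confidence:
        n += 1
    while n > 1 and screening_efficiency(p, n - 1) >= confidence:
        n -= 1
    return n


def gate_threshold(gate: GateConfig) -> float:
    """Sorting threshold μ_negative + k·σ."""
    return gate.mu_negative + gate.k * gate.sigma


def dual_reporter_fpr(fpr_1: float, fpr_2: float) -> float:
    """Joint false-positive rate of two orthogonal reporter channels.

    Independence of the two channels is assumed, not verified.
    """
    for f in (fpr_1, fpr_2):
        if not 0 <= f <= 1:
            raise ValueError("false-positive rates must be in [0, 1]")
    return fpr_1 * fpr_2


def efficiency_curve(
    model: RecoveryModel,
    abundances_percent: Sequence[float],
    cells_screened: int,
) -> pd.DataFrame:
    """Screening-efficiency curve from a fitted recovery model.

    For each abundance: N = floor(abundance × cells screened), p = the
    model's lower confidence bound (clipped to [0, 1]), P = 1-(1-p)^N.
    """
    rows = []
    for a in abundances_percent:
        n = int(math.floor(a / 100.0 * cells_screened))
        p = float(np.clip(model.predict_lower(a)[0], 0.0, 1.0))
        rows.append(
            {
                "abundance_percent": a,
                "n_copies": n,
                "p_lower": p,
                "efficiency": screening_efficiency(p, n),
            }
        )
    return pd.DataFrame(rows)
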