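"""Enzyme characterization: Michaelis–Menten kinetics and thermal inactivation.

Kinetics
--------
Initial-rate data v([S]) are fit to the Michaelis–Menten model

    v = Vmax [S] / (Km + [S])

either by the classical Lineweaver–Burk linearization (ordinary least squares
of 1/v on 1/[S]: slope = Km/Vmax, intercept = 1/Vmax) or by nonlinear least
squares initialized from the linear estimate.  Rates are specific activities
in U/mg where 1 U releases 1 umol p-nitrophenol per minute; substrate
concentrations are in mM.  Catalytic efficiency is kcat/Km (/s/mM).  Because
published kcat values are frequently on a lab-specific basis (active-site
titration, differing mass assumptions), kcat is accepted as an input; when
absent it is derived as kcat = Vmax * M / 60 (M in kDa == mg/umol) and
labelled "derived".

Thermal inactivation
--------------------
Residual activity after heat treatment is modelled as first-order decay
residual(t) = 100 exp(-k t); the half-life is t1/2 = ln 2 / k from an OLS fit
of ln(residual) on time.  A "nearest-timepoint" read-off (the sampled time
whose residual is closest to 50 %, ties to the earlier time) is provided for
comparison with half-lives read directly off published time courses.

Both fits are exposed as scikit-learn style estimators
(:class:`MichaelisMentenRegressor`, :class:`FirstOrderDecay`) so they compose
with sklearn model-selection utilities; the module-level functions wrap them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "KineticDataset",
    "KineticFit",
    "InactivationSeries",
    "HalfLifeEstimate",
    "MichaelisMentenRegressor",
    "FirstOrderDecay",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "fold_change",
    "estimate_half_life",
    "residual_activity_gain",
    "read_kinetics_csv",
    "read_inactivation_csv",
]

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# containers

@dataclass
class KineticDataset:
    """Initial-rate data for one enzyme: [S] in mM, v in U/mg."""

    enzyme_id: str
    substrate_mM: np.ndarray
    rate_U_per_mg: np.ndarray

    def __post_init__(self) -> None:
        self.substrate_mM = np.asarray(self.substrate_mM, dtype=float)
        self.rate_U_per_mg = np.asarray(self.rate_U_per_mg, dtype=float)
        if self.substrate_mM.shape != self.rate_U_per_mg.shape:
            raise ValueError("substrate and rate arrays differ in length")
        if self.substrate_mM.size < 3 or np.unique(self.substrate_mM).size < 3:
            raise ValueError("need at least 3 distinct substrate concentrations")
        if np.any(self.substrate_mM <= 0):
            raise ValueError("substrate concentrations must be positive")


@dataclass
class KineticFit:
    """Fitted Michaelis–Menten parameters for one enzyme.

    ``kcat_source`` is "supplied" when the turnover number was given by the
    caller, "derived" when computed from Vmax and molar mass, or None.
    """

    enzyme_id: str
    vmax_U_per_mg: float
    km_mM: float
    r2: float
    method: str
    kcat_per_s: float | None = None
    kcat_source: str | None = None
    efficiency_per_s_per_mM: float | None = None

    def __post_init__(self) -> None:
        if self.vmax_U_per_mg <= 0 or self.km_mM <= 0:
            raise ValueError("Vmax and Km must be positive")


@dataclass
class InactivationSeries:
    """Residual-activity time course at one temperature (percent of untreated)."""

    enzyme_id: str
    temperature_C: float
    time_min: np.ndarray
    residual_pct: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.residual_pct = np.asarray(self.residual_pct, dtype=float)
        if self.time_min.shape != self.residual_pct.shape:
            raise ValueError("time and residual arrays differ in length")
        if self.time_min.size == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.time_min[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(self.residual_pct > 110):
            warnings.warn("residual activity exceeds 110%; data kept as-is", stacklevel=2)

    def residual_at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.time_min, t))
        if idx.size == 0:
            raise ValueError(f"time not sampled: {t} min ({self.enzyme_id})")
        return float(self.residual_pct[idx[0]])


@dataclass
class HalfLifeEstimate:
    t_half_min: float
    method: str
    k_per_min: float | None = None

    def __post_init__(self) -> None:
        if self.t_half_min <= 0:
            raise ValueError("half-life must be positive")


# ---------------------------------------------------------------------------
# estimators

class MichaelisMentenRegressor(BaseEstimator, RegressorMixin):
    """Michaelis–Menten rate law fit, Lineweaver–Burk or nonlinear.

    Parameters
    ----------
    method : {"lineweaver-burk", "nonlinear"}
        "lineweaver-burk": unweighted OLS of 1/v on 1/[S] (the double
        reciprocal plot); known to over-weight low-substrate points.
        "nonlinear": Levenberg–Marquardt least squares on the hyperbola,
        initialized from the Lineweaver–Burk estimate (recommended
        cross-check).

    Attributes
    ----------
    vmax_ : float      maximal rate, units of y
    km_ : float        Michaelis constant, units of X
    r2_ : float        coefficient of determination in the fitting space
                       (double-reciprocal space for "lineweaver-burk",
                       rate space for "nonlinear")
    """

    def __init__(self, method: str = "lineweaver-burk") -> None:
        self.method = method

    def fit(self, X, y):
        if self.method not in ("lineweaver-burk", "nonlinear"):
            raise ValueError(f"unknown method {self.method!r}")
        S = np.asarray(X, dtype=float).reshape(-1)
        v = np.asarray(y, dtype=float).reshape(-1)
        if S.size != v.size:
            raise ValueError("X and y differ in length")
        if S.size < 3:
            raise ValueError("need at least 3 points")
        if np.any(S <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(v <= 0):
            raise ValueError("reciprocal undefined: zero or negative rate")

        lb = stats.linregress(1.0 / S, 1.0 / v)
        if lb.intercept <= 0:
            raise ValueError("fit not hyperbolic: non-positive 1/Vmax intercept")
        vmax_lb = 1.0 / lb.intercept
        km_lb = lb.slope / lb.intercept

        if self.method == "lineweaver-burk":
            self.vmax_, self.km_ = float(vmax_lb), float(km_lb)
            self.r2_ = float(lb.rvalue**2)
        else:
            popt, _ = optimize.curve_fit(
                lambda s, vmax, km: vmax * s / (km + s),
                S, v, p0=[vmax_lb, max(km_lb, 1e-9)], maxfev=10000,
            )
            if popt[0] <= 0 or popt[1] <= 0:
                raise ValueError("fit not hyperbolic: non-positive parameter")
            self.vmax_, self.km_ = float(popt[0]), float(popt[1])
            resid = v - self.predict(S)
            ss_tot = float(np.sum((v - v.mean()) ** 2))
            self.r2_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "vmax_")
        S = np.asarray(X, dtype=float).reshape(-1)
        return self.vmax_ * S / (self.km_ + S)


class FirstOrderDecay(BaseEstimator, RegressorMixin):
    """First-order inactivation fit: residual(t) = A0 exp(-k t).

    Fit by OLS of ln(residual) on time.  ``A0`` is the back-transformed
    intercept (close to 100 for well-normalized residual-activity data).

    Attributes
    ----------
    k_ : float          decay constant (/min)
    t_half_ : float     half-life ln2 / k (min)
    a0_ : float         amplitude at t = 0
    r2_ : float         r^2 of the log-linear fit
    """

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        r = np.asarray(y, dtype=float).reshape(-1)
        keep = r > 0
        if np.count_nonzero(keep) < 3:
            raise ValueError("invalid series: need >= 3 points with positive residual")
        res = stats.linregress(t[keep], np.log(r[keep]))
        k = -res.slope
        if k <= 0:
            raise ValueError("no decay detected: non-positive rate constant")
        self.k_ = float(k)
        self.t_half_ = LN2 / self.k_
        self.a0_ = float(np.exp(res.intercept))
        self.r2_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.a0_ * np.exp(-self.k_ * t)


# ---------------------------------------------------------------------------
# operations

def fit_michaelis_menten(
    dataset: KineticDataset,
    method: str = "lineweaver-burk",
    kcat_per_s: float | None = None,
    molar_mass_kDa: float | None = None,
) -> KineticFit:
    """Fit the rate law and attach turnover/efficiency figures.

    If ``kcat_per_s`` is given it is used as-is ("supplied"); otherwise, when
    ``molar_mass_kDa`` is given, kcat = Vmax * M / 60 is computed and labelled
    "derived" (Vmax in U/mg = umol/min/mg, M in kDa = mg/umol, /60 for s).
    """
    est = MichaelisMentenRegressor(method=method).fit(
        dataset.substrate_mM, dataset.rate_U_per_mg
    )
    kcat: float | None = None
    source: str | None = None
    if kcat_per_s is not None:
        kcat, source = float(kcat_per_s), "supplied"
    elif molar_mass_kDa is not None:
        kcat, source = est.vmax_ * molar_mass_kDa / 60.0, "derived"
    return KineticFit(
        enzyme_id=dataset.enzyme_id,
        vmax_U_per_mg=est.vmax_,
        km_mM=est.km_,
        r2=est.r2_,
        method=method,
        kcat_per_s=kcat,
        kcat_source=source,
        efficiency_per_s_per_mM=(
            catalytic_efficiency(kcat, est.km_) if kcat is not None else None
        ),
    )


def catalytic_efficiency(kcat_per_s: float, km_mM: float) -> float:
    """kcat / Km in /s/mM."""
    if km_mM <= 0:
        raise ValueError("invalid Km: must be positive")
    return kcat_per_s / km_mM


def fold_change(value_mutant: float, value_wt: float) -> float:
    """Mutant over wild-type ratio (reports round it to 2 decimals)."""
    if value_wt == 0:
        raise ValueError("undefined ratio: zero denominator")
    return value_mutant / value_wt


def estimate_half_life(
    series: InactivationSeries,
    method: str = "first-order-fit",
) -> HalfLifeEstimate:
    """Half-life from a residual-activity time course.

    "first-order-fit": OLS of ln(residual) on time, t1/2 = ln2/k.
    "nearest-timepoint": the sampled time whose residual is closest to 50 %
    (ties -> earlier time), as used when reading half-lives off published
    time courses.
    """
    if method == "first-order-fit":
        est = FirstOrderDecay().fit(series.time_min, series.residual_pct)
        return HalfLifeEstimate(t_half_min=est.t_half_, method=method, k_per_min=est.k_)
    if method == "nearest-timepoint":
        if np.all(series.residual_pct <= 0):
            raise ValueError("invalid series: no positive residuals")
        dist = np.abs(series.residual_pct - 50.0)
        idx = int(np.argmin(dist))  # argmin takes the first (earliest) minimum
        t = float(series.time_min[idx])
        if t <= 0:
            raise ValueError("no decay detected: nearest-50% point at time 0")
        return HalfLifeEstimate(t_half_min=t, method=method)
    raise ValueError(f"unknown method {method!r}")


def residual_activity_gain(
    series_mut: InactivationSeries,
    series_wt: InactivationSeries,
    t: float,
) -> float:
    """Residual-activity difference mutant - wild type at time t (percentage points)."""
    return series_mut.residual_at(t) - series_wt.residual_at(t)


# ---------------------------------------------------------------------------
# CSV I/O

def read_kinetics_csv(path: str | Path) -> list[KineticDataset]:
    """Read columns enzyme_id,substrate_mM,rate_U_per_mg; one dataset per enzyme."""
    df = pd.read_csv(path)
    required = {"enzyme_id", "substrate_mM", "rate_U_per_mg"}
    if not required.issubset(df.columns):
        raise ValueError(f"kinetics CSV must have columns {sorted(required)}")
    return [
        KineticDataset(
            enzyme_id=str(eid),
            substrate_mM=grp["substrate_mM"].to_numpy(),
            rate_U_per_mg=grp["rate_U_per_mg"].to_numpy(),
        )
        for eid, grp in df.groupby("enzyme_id", sort=False)
    ]


def read_inactivation_csv(path: str | Path) -> list[InactivationSeries]:
    """Read columns enzyme_id,temperature_C,time_min,residual_pct; one series per enzyme+T."""
    df = pd.read_csv(path)
    required = {"enzyme_id", "temperature_C", "time_min", "residual_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"inactivation CSV must have columns {sorted(required)}")
    out = []
    for (eid, temp), grp in df.groupby(["enzyme_id", "temperature_C"], sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            InactivationSeries(
                enzyme_id=str(eid),
                temperature_C=float(temp),
                time_min=grp["time_min"].to_numpy(),
                residual_pct=grp["residual_pct"].to_numpy(),
            )
        )
    return out
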