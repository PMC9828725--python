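"""Fuzzy topological classification of food webs.

Each web's non-cumulative, non-binned degree histogram p(k) is fitted with
two heuristic curves by least squares (Nelder-Mead):

* generalised power law      P_PL(k) = a * k**b + c
* generalised Gaussian       P_G(k)  = a * exp(-(k - mu)**2 / (2 sigma**2)) + b

The goodness statistic R for each fit is the signed Pearson correlation
between fitted and observed frequencies (for an unbiased least-squares fit
this equals sqrt(SSreg/SStot)); the regression and total sums of squares
are kept as diagnostics.  The Gaussian score R_G is censored to 0 unless
both flanks of the bell are inside the observed degree range:

    R_G = R  if  mu + sigma/3 > 0  and  k_max > mu + sigma,   else 0.

After clipping negatives to 0, a web sits at (R_G, R_PL) in the unit
square; its distances to the pure-random corner (1, 0) and the pure
scale-free corner (0, 1) are D2PG and D2PL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import minimize

from .web_model import FoodWeb, degree_sequence

MIN_CELLS_POWER_LAW = 3  # free parameters a, b, c
MIN_CELLS_GAUSSIAN = 4  # free parameters a, b, mu, sigma

PURE_RANDOM_ANCHOR = (1.0, 0.0)  # (R_G, R_PL)
PURE_SCALEFREE_ANCHOR = (0.0, 1.0)


@dataclass
class DegreeHistogram:
    """Relative frequency p(k) over every integer degree k_min..k_max.

    Zero-frequency cells inside the range are materialised: the Gaussian
    heuristic is sensitive to the shape of the full support.
    """

    k_values: np.ndarray
    frequencies: np.ndarray
    n_nodes: int

    @classmethod
    def from_degrees(cls, degrees) -> "DegreeHistogram":
        degrees = np.asarray(degrees, dtype=int)
        if degrees.size == 0:
            raise ValueError("empty degree list")
        if (degrees < 0).any():
            raise ValueError("negative degree")
        k_min, k_max = int(degrees.min()), int(degrees.max())
        k = np.arange(k_min, k_max + 1)
        counts = np.bincount(degrees - k_min, minlength=k.size).astype(float)
        return cls(k_values=k, frequencies=counts / degrees.size, n_nodes=degrees.size)

    @classmethod
    def from_frequencies(cls, k_values, frequencies, n_nodes: int = 0) -> "DegreeHistogram":
        """Trusted constructor for analytic fixtures; frequencies need not
        be normalised (curve fitting is scale-equivariant in a and the
        offset)."""
        k = np.asarray(k_values, dtype=float)
        p = np.asarray(frequencies, dtype=float)
        if k.shape != p.shape:
            raise ValueError("k_values and frequencies differ in length")
        if (p < 0).any():
            raise ValueError("negative frequency")
        return cls(k_values=k, frequencies=p, n_nodes=n_nodes or len(k))

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values)
        self.frequencies = np.asarray(self.frequencies, dtype=float)

    @property
    def n_cells(self) -> int:
        return int(self.k_values.size)

    @property
    def k_max(self) -> float:
        return float(self.k_values.max())


def degree_histogram(degrees) -> DegreeHistogram:
    """Histogram of a degree sequence; see :class:`DegreeHistogram`."""
    return DegreeHistogram.from_degrees(degrees)


@dataclass
class FitResult:
    family: str  # "power_law" | "gaussian"
    params: dict
    R: float
    ss_reg: float
    ss_tot: float
    converged: bool

    def predict(self, k) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        p = self.params
        if self.family == "power_law":
            return p["a"] * np.power(k, p["b"]) + p["c"]
        return p["a"] * np.exp(-((k - p["mu"]) ** 2) / (2 * p["sigma"] ** 2)) + p["b"]


class DegenerateFitError(ValueError):
    """Observed vector is constant: SStot = 0, R undefined (caller maps to 0)."""


def correlation_R(observed, fitted) -> float:
    """Signed Pearson correlation between observed and fitted frequencies.

    Equals 1 for a perfect fit, -1 for perfect anti-correlation.  A constant
    observed vector has no defined correlation and raises
    :class:`DegenerateFitError`.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape or obs.size < 2:
        raise ValueError("observed and fitted must share length >= 2")
    if np.ptp(obs) == 0:
        raise DegenerateFitError("constant observed vector (SStot = 0)")
    if np.ptp(fit) == 0:
        return 0.0
    return float(np.corrcoef(obs, fit)[0, 1])


def _sums_of_squares(observed, fitted):
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    mean = obs.mean()
    return float(np.sum((fit - mean) ** 2)), float(np.sum((obs - mean) ** 2))


def _multistart_nelder_mead(objective, x0, seed, n_restarts=5, jitter=0.3,
                            xatol=1e-10, fatol=1e-10, maxiter=5000):
    """Nelder-Mead from x0 plus seed-controlled jittered restarts; returns
    the best finite solution found and a convergence flag."""
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.asarray(x0, dtype=float)]
    scale = np.maximum(np.abs(x0), 1.0)
    for _ in range(n_restarts):
        starts.append(x0 + rng.normal(0.0, jitter, size=len(x0)) * scale)
    for start in starts:
        res = minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return None, False
    return best, bool(best.success)


def fit_power_law(hist: DegreeHistogram, seed: int = 0) -> FitResult:
    """Least-squares fit of P_PL(k) = a k^b + c to the histogram.

    k = 0 cells are excluded from the objective (0**b is undefined for
    b < 0); degree-0 nodes still count toward S elsewhere.  Histograms
    with fewer cells than free parameters are under-determined:
    converged=False, R=0.
    """
    mask = hist.k_values >= 1
    k = np.asarray(hist.k_values, dtype=float)[mask]
    p = hist.frequencies[mask]
    empty = FitResult("power_law", {"a": np.nan, "b": np.nan, "c": np.nan},
                      0.0, 0.0, 0.0, False)
    if k.size < MIN_CELLS_POWER_LAW:
        return empty

    def curve(theta):
        a, b, c = theta
        return a * np.power(k, b) + c

    def objective(theta):
        resid = curve(theta) - p
        val = float(np.sum(resid * resid))
        return val if np.isfinite(val) else 1e300

    x0 = np.array([p.max(), -1.0, p.min()])
    best, converged = _multistart_nelder_mead(objective, x0, seed)
    if best is None:
        return empty
    a, b, c = best.x
    fitted = curve(best.x)
    ss_reg, ss_tot = _sums_of_squares(p, fitted)
    try:
        R = correlation_R(p, fitted)
    except DegenerateFitError:
        R = 0.0
    return FitResult("power_law", {"a": float(a), "b": float(b), "c": float(c)},
                     R, ss_reg, ss_tot, converged)


def fit_gaussian(hist: DegreeHistogram, seed: int = 0) -> FitResult:
    """Least-squares fit of P_G(k) = a exp(-(k-mu)^2/(2 sigma^2)) + b.

    sigma is kept positive by optimising log(sigma).  Histograms with fewer
    than four cells are under-determined: converged=False, R=0.
    """
    k = np.asarray(hist.k_values, dtype=float)
    p = np.asarray(hist.frequencies, dtype=float)
    empty = FitResult("gaussian",
                      {"a": np.nan, "b": np.nan, "mu": np.nan, "sigma": np.nan},
                      0.0, 0.0, 0.0, False)
    if k.size < MIN_CELLS_GAUSSIAN:
        return empty

    def curve(theta):
        a, b, mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        return a * np.exp(-((k - mu) ** 2) / (2 * sigma**2)) + b

    def objective(theta):
        resid = curve(theta) - p
        val = float(np.sum(resid * resid))
        return val if np.isfinite(val) else 1e300

    w = p / p.sum() if p.sum() > 0 else np.full_like(p, 1.0 / p.size)
    mu0 = float(np.sum(w * k))
    sd0 = float(np.sqrt(np.sum(w * (k - mu0) ** 2)))
    sd0 = max(sd0, 0.5)
    x0 = np.array([p.max() - p.min(), p.min(), mu0, np.log(sd0)])
    best, converged = _multistart_nelder_mead(objective, x0, seed)
    if best is None:
        return empty
    a, b, mu, log_sigma = best.x
    fitted = curve(best.x)
    ss_reg, ss_tot = _sums_of_squares(p, fitted)
    try:
        R = correlation_R(p, fitted)
    except DegenerateFitError:
        R = 0.0
    return FitResult(
        "gaussian",
        {"a": float(a), "b": float(b), "mu": float(mu), "sigma": float(np.exp(log_sigma))},
        R, ss_reg, ss_tot, converged,
    )


def censor_gaussian_R(fit: FitResult, k_max: float) -> float:
    """Zero out R_G unless both flanks of the fitted bell lie in range.

    R_G = R if mu + sigma/3 > 0 and k_max > mu + sigma, else 0.  Only the
    Gaussian score is censored; R_PL never is.
    """
    if fit.family != "gaussian":
        raise ValueError("censoring applies to the Gaussian fit only")
    mu, sigma = fit.params["mu"], fit.params["sigma"]
    if not (np.isfinite(mu) and np.isfinite(sigma)):
        return 0.0
    if mu + sigma / 3.0 > 0 and k_max > mu + sigma:
        return fit.R
    return 0.0


@dataclass
class TopologyProfile:
    """Position in the (R_G, R_PL) unit square and distances to the pure
    corners: D2PG to pure random (1, 0), D2PL to pure scale-free (0, 1)."""

    R_G: float
    R_PL: float
    D2PG: float
    D2PL: float


def topology_profile(R_G: float, R_PL: float) -> TopologyProfile:
    rg = min(max(float(R_G), 0.0), 1.0)
    rpl = min(max(float(R_PL), 0.0), 1.0)
    d2pg = float(np.hypot(rg - PURE_RANDOM_ANCHOR[0], rpl - PURE_RANDOM_ANCHOR[1]))
    d2pl = float(np.hypot(rg - PURE_SCALEFREE_ANCHOR[0], rpl - PURE_SCALEFREE_ANCHOR[1]))
    return TopologyProfile(R_G=rg, R_PL=rpl, D2PG=d2pg, D2PL=d2pl)


def classify_web(
    web: FoodWeb,
    *,
    convention: Literal["undirected", "total_directed"] = "undirected",
    seed: int = 0,
) -> tuple:
    """Full per-web classification chain.

    degree sequence -> histogram -> both heuristic fits -> Eq.-style
    censoring of R_G -> clipping -> plane placement.  Webs too small to fit
    a family get R = 0 on that axis.

    Returns (TopologyProfile, power-law FitResult, gaussian FitResult).
    """
    degrees = degree_sequence(web, convention=convention)
    hist = degree_histogram(degrees)
    pl = fit_power_law(hist, seed=seed)
    ga = fit_gaussian(hist, seed=seed)
    r_pl = pl.R if pl.converged else 0.0
    r_g = censor_gaussian_R(ga, hist.k_max) if ga.converged else 0.0
    return topology_profile(r_g, r_pl), pl, ga
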