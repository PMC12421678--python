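"""Glass-transition estimation from dilatometry curves and WLF rate shifting.

A dilatometry curve is a record of density versus temperature produced by
cooling an amorphous system.  Below the glass transition the thermal
expansivity is small; above it the density falls faster with temperature.
Three estimators of the glass-transition temperature Tg are provided:

``bilinear``
    Fit straight lines to a low-temperature window (default 150-225 K) and a
    high-temperature window (default 500-550 K); Tg is the crossover
    temperature of the two lines.  Uncertainty is propagated to first order
    from the two line-coefficient covariances (a bootstrap alternative is
    available).

``hyperbolic``
    Fit the whole curve with the four-parameter hyperbolic density model

        rho(T) = rho0 - a (T - T0) - b H0(T, T0, c),
        H0 = (T - T0)/2 - sqrt((T - T0)^2 / 4 + e^c),

    whose two asymptotes are straight lines meeting at T0 with a crossover
    of width ~ e^(c/2).  Tg is the temperature at which the magnitude of the
    second derivative of the fitted rho(T) is extremal, located by a numeric
    scan; for this model family that extremum sits exactly at T0.

``onset``
    The lowest temperature at which the hyperbolic fit deviates from the
    glassy (low-temperature) line of the bilinear fit by more than a relative
    threshold (default 2%).  Marks where the expansivity transition begins
    rather than where it is completed, so it reads low for broad transitions.

The Williams-Landel-Ferry (WLF) equation
log10 a_T = C1 (T - Tg) / (C2 + (T - Tg)) maps a rate ratio to a temperature
offset from Tg and back (time-temperature superposition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import io as _io
from .exceptions import (
    DataError,
    DegenerateFitError,
    DomainError,
    FitFailureError,
    NoCrossoverError,
    NoOnsetError,
)

__all__ = [
    "DilatometryCurve",
    "TgEstimate",
    "HyperbolicFit",
    "WlfParams",
    "GlassTransitionModel",
    "GlassTransitionResults",
    "bilinear_tg",
    "fit_hyperbolic",
    "hyperbolic_tg",
    "onset_tg",
    "wlf_log_shift",
    "invert_wlf",
    "effective_cooling_rate",
    "hyperbolic_density",
    "h0",
]

#: Default linear fitting windows (K) for the bilinear estimator.
DEFAULT_LOW_RANGE = (150.0, 225.0)
DEFAULT_HIGH_RANGE = (500.0, 550.0)

#: |b| below this (g/cm^3 per K) marks a hyperbolic fit as degenerate
#: (no resolvable expansivity step).
DEGENERATE_B_TOL = 1e-6


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class DilatometryCurve:
    """Replica-averaged density versus temperature record.

    T in kelvin (strictly monotone), rho in g/cm^3, optional per-point
    spread ``rho_sd`` and replica count.
    """

    T: np.ndarray
    rho: np.ndarray
    rho_sd: np.ndarray | None = None
    n_replicas: int = 1
    moisture_wt_pct: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho_sd is not None:
            self.rho_sd = np.asarray(self.rho_sd, dtype=float)
        if self.T.size != self.rho.size:
            raise DataError("T and rho must have equal length")
        if self.T.size == 0:
            raise DomainError("dilatometry curve is empty")
        dT = np.diff(self.T)
        if not (np.all(dT > 0) or np.all(dT < 0)):
            raise DataError("T must be strictly monotone")
        if np.any(self.rho <= 0):
            raise DataError("densities must be strictly positive")

    def sorted(self) -> "DilatometryCurve":
        """Return a copy with T ascending."""
        order = np.argsort(self.T)
        return DilatometryCurve(
            T=self.T[order], rho=self.rho[order],
            rho_sd=None if self.rho_sd is None else self.rho_sd[order],
            n_replicas=self.n_replicas, moisture_wt_pct=self.moisture_wt_pct,
            meta=dict(self.meta),
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.T.min()), float(self.T.max())

    def to_csv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame({"T_K": self.T, "rho_gcm3": self.rho})
        if self.rho_sd is not None:
            frame["rho_sd"] = self.rho_sd
        frame["n_rep"] = self.n_replicas
        header = {"units": "T_K:K rho_gcm3:g/cm3", **self.meta}
        if self.moisture_wt_pct is not None:
            header["moisture_wt_pct"] = self.moisture_wt_pct
        _io.write_table(path, frame, header)

    @classmethod
    def from_csv(cls, path) -> "DilatometryCurve":
        frame, meta = _io.read_table(path)
        rho_sd = frame["rho_sd"].to_numpy() if "rho_sd" in frame else None
        n_rep = int(frame["n_rep"].iloc[0]) if "n_rep" in frame else 1
        mc = meta.pop("moisture_wt_pct", None)
        meta.pop("units", None)
        return cls(T=frame["T_K"].to_numpy(), rho=frame["rho_gcm3"].to_numpy(),
                   rho_sd=rho_sd, n_replicas=n_rep, moisture_wt_pct=mc, meta=meta)

    @classmethod
    def from_xvg(cls, path) -> "DilatometryCurve":
        x, y, meta = _io.read_xvg(path)
        return cls(T=x, rho=y, meta=meta)


@dataclass
class TgEstimate:
    """A glass-transition estimate with method tag and uncertainty band."""

    method: str
    Tg: float
    uncertainty: float
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (f"Tg ({self.method}): {self.Tg:.1f} K "
                f"+/- {self.uncertainty:.1f} K")


@dataclass
class HyperbolicFit:
    """Converged parameters of the hyperbolic density model."""

    rho0: float
    a: float
    b: float
    T0: float
    c: float
    residual_norm: float
    cov: np.ndarray | None = None
    n_points: int = 0

    @property
    def degenerate(self) -> bool:
        return abs(self.b) < DEGENERATE_B_TOL

    def predict(self, T) -> np.ndarray:
        return hyperbolic_density(np.asarray(T, dtype=float),
                                  self.rho0, self.a, self.b, self.T0, self.c)

    def second_derivative(self, T) -> np.ndarray:
        """Analytic rho''(T) = b e^c / (4 u^(3/2)), u = (T-T0)^2/4 + e^c."""
        s = np.asarray(T, dtype=float) - self.T0
        u = s * s / 4.0 + np.exp(self.c)
        return self.b * np.exp(self.c) / (4.0 * u ** 1.5)


@dataclass(frozen=True)
class WlfParams:
    """WLF coefficients; C2 must be positive (kelvin)."""

    C1: float
    C2: float

    def __post_init__(self):
        if self.C2 <= 0:
            raise DomainError("C2 must be positive")


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------

def h0(T, T0, c):
    """Hyperbolic crossover kernel: -> (T - T0) for T << T0 and 0 for T >> T0."""
    s = np.asarray(T, dtype=float) - T0
    return s / 2.0 - np.sqrt(s * s / 4.0 + np.exp(c))


def hyperbolic_density(T, rho0, a, b, T0, c):
    """Density model rho(T) = rho0 - a (T - T0) - b H0(T, T0, c).

    Asymptotic slopes: -(a + b) in the glass (T << T0) and -a in the melt
    (T >> T0); b < 0 therefore encodes the physical increase of expansivity
    above the transition.
    """
    T = np.asarray(T, dtype=float)
    return rho0 - a * (T - T0) - b * h0(T, T0, c)


# ---------------------------------------------------------------------------
# line fitting with covariance
# ---------------------------------------------------------------------------

def _linefit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """OLS line y = m x + q; returns (m, q, 2x2 covariance of (m, q)).

    With fewer than three points the residual variance is undefined and the
    covariance is reported as zero.
    """
    n = x.size
    if n < 2:
        raise DomainError("need at least two points for a line fit")
    X = np.column_stack([x, np.ones(n)])
    coef, residuals, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, q = coef
    dof = n - 2
    if dof > 0:
        ssr = float(np.sum((y - X @ coef) ** 2))
        sigma2 = ssr / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.zeros((2, 2))
    return float(m), float(q), cov


def _range_mask(T: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo > hi:
        lo, hi = hi, lo
    return (T >= lo) & (T <= hi)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def bilinear_tg(curve: DilatometryCurve,
                low_range: tuple[float, float] = DEFAULT_LOW_RANGE,
                high_range: tuple[float, float] = DEFAULT_HIGH_RANGE,
                uncertainty: str = "propagation",
                n_boot: int = 200,
                seed: int = 0,
                parallel_rtol: float = 1e-8) -> TgEstimate:
    """Tg as the crossover of glassy- and melt-region line fits.

    ``uncertainty="propagation"`` propagates the two line-coefficient
    covariances through the intersection formula to first order;
    ``"bootstrap"`` resamples points within each window ``n_boot`` times.
    """
    curve = curve.sorted()
    lo_mask = _range_mask(curve.T, *low_range)
    hi_mask = _range_mask(curve.T, *high_range)
    if lo_mask.sum() < 2 or hi_mask.sum() < 2:
        raise DomainError("each fitting range must contain at least two points")
    if np.any(lo_mask & hi_mask):
        raise DomainError("fitting ranges must be disjoint")

    m1, q1, cov1 = _linefit(curve.T[lo_mask], curve.rho[lo_mask])
    m2, q2, cov2 = _linefit(curve.T[hi_mask], curve.rho[hi_mask])
    dm = m1 - m2
    scale = max(abs(m1), abs(m2), 1e-30)
    if abs(dm) <= parallel_rtol * scale:
        raise NoCrossoverError("fitted lines are parallel within tolerance")
    Tg = (q2 - q1) / dm

    if uncertainty == "bootstrap":
        rng = np.random.default_rng(seed)
        draws = []
        Tlo, rlo = curve.T[lo_mask], curve.rho[lo_mask]
        Thi, rhi = curve.T[hi_mask], curve.rho[hi_mask]
        for _ in range(n_boot):
            ilo = rng.integers(0, Tlo.size, Tlo.size)
            ihi = rng.integers(0, Thi.size, Thi.size)
            if np.unique(Tlo[ilo]).size < 2 or np.unique(Thi[ihi]).size < 2:
                continue
            bm1, bq1, _ = _linefit(Tlo[ilo], rlo[ilo])
            bm2, bq2, _ = _linefit(Thi[ihi], rhi[ihi])
            if abs(bm1 - bm2) <= parallel_rtol * scale:
                continue
            draws.append((bq2 - bq1) / (bm1 - bm2))
        sigma = float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0
    else:
        # Tg = (q2 - q1)/(m1 - m2); gradient w.r.t. (m1, q1) and (m2, q2)
        g1 = np.array([-Tg / dm, -1.0 / dm])
        g2 = np.array([Tg / dm, 1.0 / dm])
        var = float(g1 @ cov1 @ g1 + g2 @ cov2 @ g2)
        sigma = float(np.sqrt(max(var, 0.0)))

    if Tg - max(low_range) < 100.0 or min(high_range) - Tg < 100.0:
        warnings.warn(
            "bilinear Tg lies within 100 K of a fitting-range edge; the "
            "linear windows may overlap the transition region",
            UserWarning, stacklevel=2,
        )
    diagnostics = {
        "low_line": {"slope": m1, "intercept": q1, "cov": cov1},
        "high_line": {"slope": m2, "intercept": q2, "cov": cov2},
        "low_range": tuple(low_range),
        "high_range": tuple(high_range),
        "uncertainty_method": uncertainty,
    }
    return TgEstimate(method="bilinear", Tg=float(Tg), uncertainty=sigma,
                      diagnostics=diagnostics)


def _hyperbolic_weights(curve: DilatometryCurve, scheme) -> np.ndarray:
    n = curve.T.size
    if scheme is None or scheme == "uniform":
        return np.ones(n)
    if scheme in ("inverse_variance", "low_T_taper"):
        if curve.rho_sd is not None and np.all(curve.rho_sd > 0):
            w = 1.0 / curve.rho_sd ** 2
            w = w / w.mean()
        else:
            w = np.ones(n)
        if scheme == "low_T_taper":
            # linear taper: weight 2 at the coldest point down to 1 at the hottest
            order = np.argsort(curve.T)
            taper = np.empty(n)
            taper[order] = np.linspace(2.0, 1.0, n)
            w = w * taper
        return w
    raise DomainError(f"unknown weight scheme {scheme!r}")


def fit_hyperbolic(curve: DilatometryCurve,
                   weight_scheme=None,
                   t0_starts=None,
                   max_nfev: int = 2000) -> HyperbolicFit:
    """Weighted nonlinear least squares of the hyperbolic density model.

    Multi-start over a grid of T0 (and crossover-width) initial values; the
    best converged start by weighted residual norm wins.
    """
    curve = curve.sorted()
    if curve.T.size < 6:
        raise DomainError("hyperbolic fit needs at least six points")
    T, rho = curve.T, curve.rho
    w = np.sqrt(_hyperbolic_weights(curve, weight_scheme))
    span = T.max() - T.min()
    if span <= 0:
        raise DomainError("degenerate temperature span")

    # slope seeds from the outer thirds of the curve
    third = max(2, T.size // 3)
    m_lo, _, _ = _linefit(T[:third], rho[:third])
    m_hi, _, _ = _linefit(T[-third:], rho[-third:])
    a0 = -m_hi
    b0 = m_hi - m_lo  # negative when expansivity grows above the transition
    if t0_starts is None:
        t0_starts = T.min() + span * np.array([0.25, 0.4, 0.5, 0.6, 0.75])
    c_starts = [2.0 * np.log(0.05 * span), 2.0 * np.log(0.15 * span)]

    def residuals(theta):
        rho0, a, b, T0, c = theta
        return w * (hyperbolic_density(T, rho0, a, b, T0, c) - rho)

    best = None
    attempts = []
    for T0_init in np.atleast_1d(t0_starts):
        for c_init in c_starts:
            rho0_init = float(np.interp(T0_init, T, rho))
            theta0 = np.array([rho0_init, a0, b0, float(T0_init), c_init])
            try:
                sol = least_squares(residuals, theta0, max_nfev=max_nfev,
                                    x_scale=[1.0, 1e-4, 1e-4, span, 1.0])
            except Exception as exc:  # noqa: BLE001 - collected as diagnostics
                attempts.append({"start": theta0.tolist(), "error": str(exc)})
                continue
            if not np.all(np.isfinite(sol.x)) or not sol.success:
                attempts.append({"start": theta0.tolist(),
                                 "status": int(sol.status)})
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError("hyperbolic fit failed to converge from any start",
                              diagnostics={"attempts": attempts})

    rho0, a, b, T0, c = best.x
    # parameter covariance from the Jacobian at the optimum
    try:
        J = best.jac
        dof = max(T.size - 5, 1)
        sigma2 = 2.0 * best.cost / dof
        cov = sigma2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
    resid_norm = float(np.linalg.norm(curve.rho - hyperbolic_density(
        T, rho0, a, b, T0, c)))
    return HyperbolicFit(rho0=float(rho0), a=float(a), b=float(b),
                         T0=float(T0), c=float(c),
                         residual_norm=resid_norm, cov=cov, n_points=T.size)


def hyperbolic_tg(fit: HyperbolicFit,
                  T_span: tuple[float, float],
                  resolution: float = 0.1) -> TgEstimate:
    """Tg from the extremum of the numeric second derivative of the fit.

    The fitted rho(T) is scanned over ``T_span`` at ``resolution`` kelvin; Tg
    is the temperature where |rho''| is largest (for the hyperbolic family
    this coincides with the fitted T0).
    """
    if fit.degenerate:
        raise DegenerateFitError(
            "|b| below tolerance: no expansivity step, Tg undefined")
    lo, hi = min(T_span), max(T_span)
    grid = np.arange(lo, hi + resolution / 2, resolution)
    if grid.size < 5:
        raise DomainError("T_span too narrow for a second-derivative scan")
    rho = fit.predict(grid)
    d2 = np.gradient(np.gradient(rho, grid), grid)
    idx = int(np.argmax(np.abs(d2)))
    Tg = float(grid[idx])
    sigma = 0.0
    if fit.cov is not None and np.isfinite(fit.cov[3, 3]):
        sigma = float(np.sqrt(max(fit.cov[3, 3], 0.0)))
    return TgEstimate(method="hyperbolic", Tg=Tg, uncertainty=sigma,
                      diagnostics={"scan_resolution_K": resolution,
                                   "T0_fit": fit.T0,
                                   "d2_extremum": float(d2[idx])})


def onset_tg(fit: HyperbolicFit,
             lower_line,
             T_span: tuple[float, float],
             threshold_pct: float = 2.0,
             resolution: float = 0.1) -> TgEstimate:
    """Tg-onset: first temperature (scanning upward from the cold end) where
    the hyperbolic fit deviates from the glassy line by > ``threshold_pct``%.

    ``lower_line`` is a ``(slope, intercept)`` pair or the ``low_line``
    diagnostics entry of :func:`bilinear_tg`.
    """
    if threshold_pct <= 0:
        raise DomainError("threshold_pct must be positive")
    if isinstance(lower_line, dict):
        slope, intercept = lower_line["slope"], lower_line["intercept"]
    else:
        slope, intercept = lower_line
    lo, hi = min(T_span), max(T_span)
    grid = np.arange(lo, hi + resolution / 2, resolution)
    rho_fit = fit.predict(grid)
    rho_line = slope * grid + intercept
    deviation = np.abs(rho_fit - rho_line) / np.abs(rho_line)
    exceed = deviation > threshold_pct / 100.0
    if not np.any(exceed):
        raise NoOnsetError(
            f"deviation never exceeds {threshold_pct}% within the span")
    idx = int(np.argmax(exceed))
    return TgEstimate(method="onset", Tg=float(grid[idx]),
                      uncertainty=resolution,
                      diagnostics={"threshold_pct": threshold_pct,
                                   "scan_resolution_K": resolution,
                                   "lower_line": {"slope": slope,
                                                  "intercept": intercept}})


# ---------------------------------------------------------------------------
# WLF
# ---------------------------------------------------------------------------

def effective_cooling_rate(step_K: float, interval_ns: float) -> float:
    """Effective cooling rate (K/ns) of a stepwise quench: temperature drop
    per step divided by the hold interval (e.g. 25 K per 10 ns -> 2.5 K/ns)."""
    if interval_ns <= 0:
        raise DomainError("hold interval must be positive")
    return step_K / interval_ns


def wlf_log_shift(params: WlfParams, T: float, Tg: float) -> float:
    """log10 of the WLF shift factor a_T at temperature T relative to Tg."""
    dT = T - Tg
    denom = params.C2 + dT
    if abs(denom) < 1e-12:
        raise DomainError("WLF pole: T - Tg = -C2")
    return params.C1 * dT / denom


def invert_wlf(params: WlfParams, log_shift: float) -> float:
    """Temperature offset T - Tg producing a given log10 shift factor.

    Closed-form inverse: dT = C2 L / (C1 - L).  To convert a cooling-rate
    ratio, pass L = log10(rate_target / rate_reference): a slower target rate
    gives L < 0 and hence a negative temperature shift.
    """
    denom = params.C1 - log_shift
    if abs(denom) < 1e-12:
        raise DomainError("WLF inverse undefined at log_shift = C1")
    return params.C2 * log_shift / denom


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class GlassTransitionModel:
    """Glass-transition analysis of one dilatometry curve.

    Parameters
    ----------
    curve : DilatometryCurve
    low_range, high_range : (K, K)
        Linear fitting windows for the bilinear estimator.
    """

    def __init__(self, curve: DilatometryCurve,
                 low_range=DEFAULT_LOW_RANGE,
                 high_range=DEFAULT_HIGH_RANGE):
        self.curve = curve.sorted()
        self.low_range = tuple(low_range)
        self.high_range = tuple(high_range)

    def fit(self, methods=("bilinear", "hyperbolic", "onset"),
            onset_threshold_pct: float = 2.0,
            weight_scheme=None,
            uncertainty: str = "propagation") -> "GlassTransitionResults":
        estimates: dict[str, TgEstimate] = {}
        errors: dict[str, str] = {}
        hyp_fit = None
        bilinear = None
        if "bilinear" in methods or "onset" in methods:
            try:
                bilinear = bilinear_tg(self.curve, self.low_range,
                                       self.high_range,
                                       uncertainty=uncertainty)
                if "bilinear" in methods:
                    estimates["bilinear"] = bilinear
            except (DomainError, NoCrossoverError) as exc:
                errors["bilinear"] = str(exc)
        if "hyperbolic" in methods or "onset" in methods:
            try:
                hyp_fit = fit_hyperbolic(self.curve, weight_scheme=weight_scheme)
            except (DomainError, FitFailureError) as exc:
                errors["hyperbolic"] = str(exc)
        if hyp_fit is not None and "hyperbolic" in methods:
            try:
                estimates["hyperbolic"] = hyperbolic_tg(hyp_fit, self.curve.span)
            except (DegenerateFitError, DomainError) as exc:
                errors["hyperbolic"] = str(exc)
        if hyp_fit is not None and bilinear is not None and "onset" in methods:
            try:
                estimates["onset"] = onset_tg(
                    hyp_fit, bilinear.diagnostics["low_line"],
                    self.curve.span, threshold_pct=onset_threshold_pct)
            except (NoOnsetError, DomainError) as exc:
                errors["onset"] = str(exc)
        return GlassTransitionResults(model=self, estimates=estimates,
                                      hyperbolic_fit=hyp_fit, errors=errors)


@dataclass
class GlassTransitionResults:
    """Estimates produced by :class:`GlassTransitionModel.fit`."""

    model: GlassTransitionModel
    estimates: dict
    hyperbolic_fit: HyperbolicFit | None
    errors: dict

    def __getitem__(self, method: str) -> TgEstimate:
        return self.estimates[method]

    def summary(self) -> str:
        curve = self.model.curve
        lines = ["Glass-transition analysis",
                 "=" * 40,
                 f"points: {curve.T.size}   span: "
                 f"{curve.span[0]:.0f}-{curve.span[1]:.0f} K   "
                 f"replicas: {curve.n_replicas}"]
        if curve.moisture_wt_pct is not None:
            lines.append(f"moisture content: {curve.moisture_wt_pct:g} wt %")
        for method in ("bilinear", "hyperbolic", "onset"):
            if method in self.estimates:
                lines.append(self.estimates[method].summary())
            elif method in self.errors:
                lines.append(f"Tg ({method}): failed ({self.errors[method]})")
        if self.hyperbolic_fit is not None:
            f = self.hyperbolic_fit
            lines.append(
                f"hyperbolic fit: rho0={f.rho0:.4f} a={f.a:.3e} b={f.b:.3e} "
                f"T0={f.T0:.1f} c={f.c:.2f} |resid|={f.residual_norm:.2e}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the curve, the hyperbolic fit, and the Tg estimates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.model.curve
        ax.plot(curve.T, curve.rho, "o", ms=4, label="data")
        if self.hyperbolic_fit is not None:
            grid = np.linspace(*curve.span, 400)
            ax.plot(grid, self.hyperbolic_fit.predict(grid), "-",
                    label="hyperbolic fit")
        for method, est in self.estimates.items():
            ax.axvline(est.Tg, ls="--", alpha=0.7, label=f"Tg {method}")
        ax.set_xlabel("T (K)")
        ax.set_ylabel(r"$\rho$ (g/cm$^3$)")
        ax.legend()
        return ax
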