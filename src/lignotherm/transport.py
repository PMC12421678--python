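"""Diffusivity analysis: Einstein relation, Arrhenius fits, density maps.

Diffusion coefficients are obtained from unwrapped per-molecule position
time series via the mean-square displacement (MSD): in three dimensions
MSD(tau) -> 6 D tau at long lag, so D is the fitted MSD slope divided by six
(Einstein relation).  Activation energies come from ordinary least squares on
Arrhenius coordinates, ln D versus 1/T, with Ed = -R * slope; a branch split
at Tg yields separate activation energies for the glassy and rubbery
regimes.  Per-molecule effective diffusivities (squared displacement within a
sampling time, divided by 6 tau) expose mobility heterogeneity such as the
bimodal fast/slow water populations near a polymer matrix, and 2-D mass
density maps averaged along one box axis show where water clusters.

Internal units: positions nm, times ns, diffusivities m^2/s
(1 nm^2/ns = 1e-9 m^2/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import io as _io
from .constants import (
    N_AVOGADRO,
    NM2_PER_NS_TO_M2_PER_S,
    NM3_TO_CM3,
    R_GAS,
    WATER_MOLAR_MASS,
)
from .exceptions import DataError, DomainError, FitFailureError

__all__ = [
    "TrajectorySet",
    "MSDSeries",
    "DiffusivityEstimate",
    "ArrheniusFit",
    "DensityMap",
    "DiffusionModel",
    "DiffusionResults",
    "ArrheniusModel",
    "ArrheniusResults",
    "compute_msd",
    "einstein_diffusivity",
    "arrhenius_fit",
    "per_molecule_diffusivity",
    "diffusivity_distribution_summary",
    "bimodality_coefficient",
    "water_density_map",
]

#: Default molar masses (g/mol) by species for mass-weighted maps.
SPECIES_MOLAR_MASS = {"water": WATER_MOLAR_MASS, "lignin_unit": 180.2}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Unwrapped 3-D position time series for a set of molecules.

    ``positions`` has shape (n_molecules, n_times, 3) in nm; ``times`` in ns
    must be strictly increasing and uniformly spaced.
    """

    times: np.ndarray
    positions: np.ndarray
    molecule_ids: list | None = None
    species: str = "water"
    box: np.ndarray | None = None
    temperature: float | None = None
    moisture_wt_pct: float | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise DataError("positions must have shape (n_mol, n_times, 3)")
        if self.positions.shape[1] != self.times.size:
            raise DataError("positions and times disagree on n_times")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise DataError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise DataError("times must be uniformly spaced")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        if self.molecule_ids is None:
            self.molecule_ids = list(range(self.positions.shape[0]))

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise DataError("trajectory has a single frame")
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def check_unwrapped(self) -> None:
        """Raise if any single-step displacement exceeds half a box edge."""
        if self.box is None or self.times.size < 2:
            return
        steps = np.abs(np.diff(self.positions, axis=1))
        if np.any(steps > self.box / 2.0):
            raise DataError(
                "single-step jump exceeds box/2: coordinates look wrapped")

    def to_csv(self, path) -> None:
        n_mol, n_t, _ = self.positions.shape
        frame = pd.DataFrame({
            "mol_id": np.repeat(self.molecule_ids, n_t),
            "species": self.species,
            "t_ns": np.tile(self.times, n_mol),
            "x_nm": self.positions[:, :, 0].ravel(),
            "y_nm": self.positions[:, :, 1].ravel(),
            "z_nm": self.positions[:, :, 2].ravel(),
        })
        header = {"units": "t:ns xyz:nm"}
        if self.box is not None:
            header["box_nm"] = " ".join(f"{v:g}" for v in self.box)
        if self.temperature is not None:
            header["temperature_K"] = self.temperature
        if self.moisture_wt_pct is not None:
            header["moisture_wt_pct"] = self.moisture_wt_pct
        _io.write_table(path, frame, header)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        frame, meta = _io.read_table(path)
        mol_ids = frame["mol_id"].unique().tolist()
        times = np.sort(frame["t_ns"].unique())
        n_mol, n_t = len(mol_ids), times.size
        positions = np.empty((n_mol, n_t, 3))
        for i, mol in enumerate(mol_ids):
            sub = frame[frame["mol_id"] == mol].sort_values("t_ns")
            positions[i] = sub[["x_nm", "y_nm", "z_nm"]].to_numpy()
        box = meta.get("box_nm")
        if isinstance(box, str):
            box = np.array([float(v) for v in box.split()])
        elif box is not None:
            box = np.array([float(box)] * 3)
        species = frame["species"].iloc[0] if "species" in frame else "water"
        return cls(times=times, positions=positions, molecule_ids=mol_ids,
                   species=species, box=box,
                   temperature=meta.get("temperature_K"),
                   moisture_wt_pct=meta.get("moisture_wt_pct"))


@dataclass
class MSDSeries:
    """Ensemble- and origin-averaged mean-square displacement."""

    lag: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)


@dataclass
class DiffusivityEstimate:
    """Einstein-relation diffusivity with fit metadata."""

    D: float
    stderr: float
    fit_window: tuple[float, float]
    species: str = "water"
    temperature: float | None = None
    moisture_wt_pct: float | None = None
    clamped: bool = False

    def summary(self) -> str:
        tag = " (clamped to 0)" if self.clamped else ""
        return (f"D = {self.D:.3e} +/- {self.stderr:.1e} m^2/s "
                f"[window {self.fit_window[0]:g}-{self.fit_window[1]:g} ns]{tag}")


@dataclass
class ArrheniusFit:
    """ln D vs 1/T line fit: D(T) = D0 exp(-Ed/(R T))."""

    D0: float
    Ed: float
    stderr_Ed: float
    T_range: tuple[float, float]
    branch: str = "single"
    n_points: int = 0

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.D0 * np.exp(-1000.0 * self.Ed / (R_GAS * T))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for Ed (kJ/mol, t distribution)."""
        dof = self.n_points - 2
        if dof <= 0:
            return (-np.inf, np.inf)
        half = stats.t.ppf(0.5 + level / 2.0, dof) * self.stderr_Ed
        return (self.Ed - half, self.Ed + half)

    def summary(self) -> str:
        return (f"Ed ({self.branch}) = {self.Ed:.2f} +/- {self.stderr_Ed:.2f} "
                f"kJ/mol over {self.T_range[0]:.0f}-{self.T_range[1]:.0f} K "
                f"({self.n_points} points)")


@dataclass
class DensityMap:
    """In-plane mass density map averaged along one box axis."""

    grid: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    averaged_axis: str
    time_window: tuple[float, float]
    empty: bool = False

    def total_mass_g(self) -> float:
        cell_area = np.outer(np.diff(self.edges_a), np.diff(self.edges_b))
        return float(np.sum(self.grid * cell_area * self._depth) * NM3_TO_CM3)

    _depth: float = 0.0  # nm, thickness of the averaged axis


# ---------------------------------------------------------------------------
# MSD and the Einstein relation
# ---------------------------------------------------------------------------

def compute_msd(traj: TrajectorySet, max_lag: float | None = None,
                origin_stride: int = 10) -> MSDSeries:
    """MSD(tau) averaged over molecules and sliding time origins.

    Origins are taken every ``origin_stride`` frames (the correlation between
    successive origins makes denser sampling nearly redundant).  MSD(0) = 0
    exactly by construction.
    """
    if traj.times.size < 2:
        raise DomainError("need at least two time points")
    traj.check_unwrapped()
    dt = traj.dt
    span = traj.span
    if max_lag is None:
        max_lag = 0.5 * span
    if max_lag > span + 1e-12:
        raise DomainError("max_lag exceeds the trajectory span")
    n_lag = int(round(max_lag / dt))
    pos = traj.positions
    n_t = pos.shape[1]
    lags = np.arange(n_lag + 1) * dt
    msd = np.zeros(n_lag + 1)
    n_pairs = np.zeros(n_lag + 1, dtype=int)
    n_pairs[0] = pos.shape[0] * len(range(0, n_t, origin_stride))
    for k in range(1, n_lag + 1):
        origins = np.arange(0, n_t - k, origin_stride)
        if origins.size == 0:
            break
        disp = pos[:, origins + k, :] - pos[:, origins, :]
        sq = np.sum(disp * disp, axis=2)
        msd[k] = float(sq.mean())
        n_pairs[k] = sq.size
    used = n_pairs > 0
    return MSDSeries(lag=lags[used], msd=msd[used], n_pairs=n_pairs[used])


def einstein_diffusivity(msd: MSDSeries,
                         fit_window: tuple[float, float] | None = None,
                         species: str = "water",
                         temperature: float | None = None,
                         moisture_wt_pct: float | None = None
                         ) -> DiffusivityEstimate:
    """D from the least-squares MSD slope over ``fit_window`` (ns), /6.

    Default window: 10-50% of the available lag span, excluding short-lag
    ballistic/caging behaviour and the noisy long-lag tail.  A fitted slope
    negative beyond two standard errors is clamped to zero with a warning.
    """
    lag_max = float(msd.lag.max())
    if fit_window is None:
        fit_window = (0.1 * lag_max, 0.5 * lag_max)
    lo, hi = fit_window
    if lo < 0 or hi > lag_max + 1e-12 or hi <= lo:
        raise DomainError("fit window must lie within the lag span")
    mask = (msd.lag >= lo) & (msd.lag <= hi)
    if mask.sum() < 3:
        raise DomainError("fit window must contain at least three lags")
    res = stats.linregress(msd.lag[mask], msd.msd[mask])
    slope, slope_err = res.slope, res.stderr
    D = slope / 6.0 * NM2_PER_NS_TO_M2_PER_S
    stderr = (slope_err / 6.0 * NM2_PER_NS_TO_M2_PER_S
              if np.isfinite(slope_err) else 0.0)
    clamped = False
    if slope < 0 and np.isfinite(slope_err) and abs(slope) > 2 * slope_err:
        warnings.warn("fitted MSD slope significantly negative; clamping D to 0",
                      UserWarning, stacklevel=2)
        D, clamped = 0.0, True
    return DiffusivityEstimate(D=float(D), stderr=float(stderr),
                               fit_window=(float(lo), float(hi)),
                               species=species, temperature=temperature,
                               moisture_wt_pct=moisture_wt_pct, clamped=clamped)


class DiffusionModel:
    """Einstein-relation diffusivity analysis of one trajectory set."""

    def __init__(self, traj: TrajectorySet):
        self.traj = traj

    def fit(self, max_lag: float | None = None, origin_stride: int = 10,
            fit_window: tuple[float, float] | None = None) -> "DiffusionResults":
        msd = compute_msd(self.traj, max_lag=max_lag,
                          origin_stride=origin_stride)
        estimate = einstein_diffusivity(
            msd, fit_window=fit_window, species=self.traj.species,
            temperature=self.traj.temperature,
            moisture_wt_pct=self.traj.moisture_wt_pct)
        return DiffusionResults(model=self, msd=msd, estimate=estimate)


@dataclass
class DiffusionResults:
    model: DiffusionModel
    msd: MSDSeries
    estimate: DiffusivityEstimate

    @property
    def D(self) -> float:
        return self.estimate.D

    def summary(self) -> str:
        traj = self.model.traj
        lines = ["Einstein diffusivity", "=" * 40,
                 f"molecules: {traj.n_molecules}  frames: {traj.times.size}  "
                 f"span: {traj.span:g} ns  species: {traj.species}",
                 self.estimate.summary()]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.msd.lag, self.msd.msd, ".", ms=3, label="MSD")
        lo, hi = self.estimate.fit_window
        slope_nm = self.estimate.D / NM2_PER_NS_TO_M2_PER_S * 6.0
        grid = np.linspace(lo, hi, 50)
        offset = np.interp(lo, self.msd.lag, self.msd.msd) - slope_nm * lo
        ax.plot(grid, slope_nm * grid + offset, "-", label="fit window")
        ax.set_xlabel("lag (ns)")
        ax.set_ylabel(r"MSD (nm$^2$)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Arrhenius fits
# ---------------------------------------------------------------------------

def _fit_branch(T: np.ndarray, D: np.ndarray, branch: str) -> ArrheniusFit:
    if T.size < 2:
        raise FitFailureError(f"fewer than two usable points for {branch} branch")
    res = stats.linregress(1.0 / T, np.log(D))
    Ed = -R_GAS * res.slope / 1000.0
    stderr = (R_GAS * res.stderr / 1000.0
              if np.isfinite(res.stderr) else 0.0)
    return ArrheniusFit(D0=float(np.exp(res.intercept)), Ed=float(Ed),
                        stderr_Ed=float(stderr),
                        T_range=(float(T.min()), float(T.max())),
                        branch=branch, n_points=int(T.size))


def arrhenius_fit(T, D, branch_split: float | None = None):
    """OLS of ln D vs 1/T; Ed = -R * slope in kJ/mol.

    Non-positive D values are excluded with a warning.  With ``branch_split``
    (kelvin, typically a Tg estimate) two independent fits are returned as a
    ``{"below_Tg": ..., "above_Tg": ...}`` dict.
    """
    T = np.asarray(T, dtype=float)
    D = np.asarray(D, dtype=float)
    if T.size != D.size:
        raise DomainError("T and D must have equal length")
    usable = D > 0
    if not np.all(usable):
        warnings.warn(f"excluding {int((~usable).sum())} non-positive "
                      "diffusivity value(s) from the Arrhenius fit",
                      UserWarning, stacklevel=2)
    T, D = T[usable], D[usable]
    if branch_split is None:
        return _fit_branch(T, D, "single")
    below = T <= branch_split
    return {
        "below_Tg": _fit_branch(T[below], D[below], "below_Tg"),
        "above_Tg": _fit_branch(T[~below], D[~below], "above_Tg"),
    }


class ArrheniusModel:
    """Activation-energy analysis of a (T, D) diffusivity table."""

    def __init__(self, T, D):
        self.T = np.asarray(T, dtype=float)
        self.D = np.asarray(D, dtype=float)

    @classmethod
    def from_estimates(cls, estimates) -> "ArrheniusModel":
        T = [e.temperature for e in estimates]
        D = [e.D for e in estimates]
        return cls(T, D)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       t_col: str = "T_K", d_col: str = "D_m2_s"):
        return cls(frame[t_col].to_numpy(), frame[d_col].to_numpy())

    def fit(self, branch_split: float | None = None) -> "ArrheniusResults":
        fits = arrhenius_fit(self.T, self.D, branch_split=branch_split)
        if isinstance(fits, ArrheniusFit):
            fits = {"single": fits}
        return ArrheniusResults(model=self, fits=fits,
                                branch_split=branch_split)


@dataclass
class ArrheniusResults:
    model: ArrheniusModel
    fits: dict
    branch_split: float | None = None

    def __getitem__(self, branch: str) -> ArrheniusFit:
        return self.fits[branch]

    @property
    def Ed(self) -> float:
        """Activation energy of the single-branch fit (kJ/mol)."""
        return self.fits["single"].Ed

    def summary(self) -> str:
        lines = ["Arrhenius activation energy", "=" * 40]
        if self.branch_split is not None:
            lines.append(f"branch split at {self.branch_split:.1f} K")
        for fit in self.fits.values():
            lines.append(fit.summary())
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(1000.0 / self.model.T, self.model.D, "o", label="data")
        for fit in self.fits.values():
            grid = np.linspace(*fit.T_range, 50)
            ax.semilogy(1000.0 / grid, fit.predict(grid), "-",
                        label=f"{fit.branch}: {fit.Ed:.1f} kJ/mol")
        ax.set_xlabel("1000/T (1/K)")
        ax.set_ylabel(r"D (m$^2$/s)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# per-molecule diffusivity distributions
# ---------------------------------------------------------------------------

def per_molecule_diffusivity(traj: TrajectorySet, sampling_times,
                             origin_stride: int = 10) -> pd.DataFrame:
    """Effective per-molecule diffusivity at each sampling time.

    For each molecule and sampling time tau, D_eff = <|r(t0+tau) - r(t0)|^2>
    / (6 tau) averaged over sliding origins; short tau resolves mobility
    heterogeneity (fast water in clusters vs slow matrix-bound water), long
    tau converges to the ensemble Einstein estimate.
    """
    dt = traj.dt
    rows = []
    for tau in np.atleast_1d(np.asarray(sampling_times, dtype=float)):
        if tau <= 0:
            raise DomainError("sampling times must be positive")
        if tau > traj.span + 1e-12:
            raise DomainError("sampling time exceeds the trajectory span")
        k = max(1, int(round(tau / dt)))
        tau_eff = k * dt
        n_t = traj.positions.shape[1]
        origins = np.arange(0, n_t - k, origin_stride)
        if origins.size == 0:
            origins = np.array([0])
        disp = traj.positions[:, origins + k, :] - traj.positions[:, origins, :]
        sq = np.sum(disp * disp, axis=2).mean(axis=1)  # per molecule, nm^2
        d_eff = sq / (6.0 * tau_eff) * NM2_PER_NS_TO_M2_PER_S
        for mol, d in zip(traj.molecule_ids, d_eff):
            rows.append({"molecule_id": mol, "species": traj.species,
                         "tau_ns": float(tau_eff), "D_eff_m2_s": float(d)})
    return pd.DataFrame(rows)


def bimodality_coefficient(x) -> float:
    """Sarle's bimodality coefficient (> ~0.555 hints at bimodality)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float("nan")
    g1 = stats.skew(x, bias=False)
    g2 = stats.kurtosis(x, bias=False)  # excess kurtosis
    return float((g1 ** 2 + 1.0) /
                 (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def diffusivity_distribution_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Histogram-style summaries per sampling time.

    Reports mean, median, quartiles, the bimodality coefficient of
    log10(D_eff), and a valley statistic: the minimum histogram height
    between the two tallest separated modes of log10(D_eff), relative to the
    smaller mode (0 = deep valley / clear bimodality; NaN = unimodal).
    """
    out = []
    for tau, group in table.groupby("tau_ns"):
        d = group["D_eff_m2_s"].to_numpy()
        positive = d[d > 0]
        logd = np.log10(positive) if positive.size else np.array([])
        valley = float("nan")
        bc = float("nan")
        if logd.size >= 10:
            bc = bimodality_coefficient(logd)
            counts, _ = np.histogram(logd, bins="fd")
            # locate interior local maxima of the (lightly smoothed) histogram
            smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")
            peaks = [i for i in range(1, len(smoothed) - 1)
                     if smoothed[i] >= smoothed[i - 1]
                     and smoothed[i] >= smoothed[i + 1]
                     and smoothed[i] > 0]
            if len(peaks) >= 2:
                peaks = sorted(peaks, key=lambda i: smoothed[i])[-2:]
                i, j = sorted(peaks)
                valley = float(smoothed[i:j + 1].min() /
                               min(smoothed[i], smoothed[j]))
        out.append({
            "tau_ns": tau,
            "n": int(d.size),
            "mean": float(d.mean()),
            "median": float(np.median(d)),
            "q25": float(np.quantile(d, 0.25)),
            "q75": float(np.quantile(d, 0.75)),
            "bimodality_coefficient": bc,
            "valley_ratio": valley,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# density maps
# ---------------------------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def water_density_map(traj: TrajectorySet, axis: str = "z", grid_n: int = 50,
                      time_window: tuple[float, float] | None = None,
                      molar_mass: float | None = None) -> DensityMap:
    """Mass density map on the in-plane grid, averaged along ``axis``.

    Positions are wrapped into the box per frame, binned on a grid_n x grid_n
    grid over the two in-plane axes, mass-weighted, and averaged over frames
    in ``time_window`` (ns; default: whole trajectory).  The map conserves
    the total species mass: sum(cell density * cell volume) = n_mol * m_mol.
    """
    if traj.box is None:
        raise DomainError("density map requires box dimensions")
    if grid_n < 1:
        raise DomainError("grid_n must be at least 1")
    if axis not in _AXIS_INDEX:
        raise DomainError("axis must be one of x, y, z")
    if molar_mass is None:
        molar_mass = SPECIES_MOLAR_MASS.get(traj.species, WATER_MOLAR_MASS)
    k = _AXIS_INDEX[axis]
    in_plane = [i for i in range(3) if i != k]
    if time_window is None:
        time_window = (float(traj.times[0]), float(traj.times[-1]))
    mask = (traj.times >= time_window[0]) & (traj.times <= time_window[1])
    frames = np.nonzero(mask)[0]
    edges_a = np.linspace(0.0, traj.box[in_plane[0]], grid_n + 1)
    edges_b = np.linspace(0.0, traj.box[in_plane[1]], grid_n + 1)
    depth = float(traj.box[k])
    if frames.size == 0 or traj.n_molecules == 0:
        empty = DensityMap(grid=np.zeros((grid_n, grid_n)), edges_a=edges_a,
                           edges_b=edges_b, averaged_axis=axis,
                           time_window=time_window, empty=True)
        empty._depth = depth
        return empty
    counts = np.zeros((grid_n, grid_n))
    for f in frames:
        wrapped = np.mod(traj.positions[:, f, :], traj.box)
        hist, _, _ = np.histogram2d(wrapped[:, in_plane[0]],
                                    wrapped[:, in_plane[1]],
                                    bins=[edges_a, edges_b])
        counts += hist
    mean_counts = counts / frames.size
    cell_volume_cm3 = (np.outer(np.diff(edges_a), np.diff(edges_b)) * depth
                       * NM3_TO_CM3)
    mass_per_molecule_g = molar_mass / N_AVOGADRO
    density = mean_counts * mass_per_molecule_g / cell_volume_cm3
    dm = DensityMap(grid=density, edges_a=edges_a, edges_b=edges_b,
                    averaged_axis=axis, time_window=time_window)
    dm._depth = depth
    return dm
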