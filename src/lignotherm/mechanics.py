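"""Elastic constants from uniaxial deformation records.

A deformation record carries engineering strain, axial true stress (derived
from the pressure tensor: tensile positive, sigma = -(P_axial -
mean(P_transverse))), and the transverse box-edge series of one pulling
direction.  Young's modulus E is the least-squares stress/strain slope over
a small-strain interval (default 0.3-9.9% strain, where the response is
linear); Poisson's ratio nu is the mean ratio of transverse contraction to
axial elongation (default 2-10% strain, excluding the noisy sub-2% zone);
the bulk modulus follows from the Lame relation K = -E / (6 (nu - 1/2)) =
E / (3 (1 - 2 nu)).  Pulls along x, y and z are aggregated into a mean and
sample standard deviation per quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import io as _io
from .exceptions import DataError, DomainError

__all__ = [
    "DeformationRecord",
    "AxisElasticity",
    "ElasticConstants",
    "ElasticityModel",
    "ElasticConstantsResults",
    "strain_rate_per_s",
    "stress_from_pressure",
    "smooth_stress",
    "youngs_modulus",
    "poisson_ratio",
    "bulk_modulus",
    "aggregate_triplicate",
]

DEFAULT_E_INTERVAL = (0.003, 0.099)
DEFAULT_NU_INTERVAL = (0.02, 0.10)
INCOMPRESSIBLE_TOL = 1e-6


@dataclass
class DeformationRecord:
    """Strain, stress and box-dimension series for one pulling direction."""

    axis: str
    strain: np.ndarray
    stress: np.ndarray
    box_axial: np.ndarray | None = None
    box_transverse: np.ndarray | None = None  # shape (2, n)
    rate: float | None = None  # m/s
    temperature: float | None = None
    moisture_wt_pct: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.size != self.stress.size:
            raise DataError("strain and stress must have equal length")
        if self.strain.size == 0:
            raise DomainError("empty deformation record")
        if abs(self.strain[0]) > 1e-12:
            raise DataError("strain series must start at 0")
        if self.box_axial is not None:
            self.box_axial = np.asarray(self.box_axial, dtype=float)
            if self.box_axial.size != self.strain.size:
                raise DataError("box_axial length mismatch")
        if self.box_transverse is not None:
            self.box_transverse = np.asarray(self.box_transverse, dtype=float)
            if (self.box_transverse.ndim != 2
                    or self.box_transverse.shape != (2, self.strain.size)):
                raise DataError("box_transverse must have shape (2, n)")
        if self.strain.max() < 0.20:
            warnings.warn("strain does not reach 20%; elastic fits still run "
                          "but the record is shorter than recommended",
                          UserWarning, stacklevel=2)

    def to_csv(self, path) -> None:
        import pandas as pd

        data = {"strain": self.strain, "stress_GPa": self.stress}
        if self.box_axial is not None:
            data["L_axial_nm"] = self.box_axial
        if self.box_transverse is not None:
            data["L_trans1_nm"] = self.box_transverse[0]
            data["L_trans2_nm"] = self.box_transverse[1]
        header = {"axis": self.axis, **self.meta}
        if self.rate is not None:
            header["rate_m_s"] = self.rate
        if self.temperature is not None:
            header["temperature_K"] = self.temperature
        if self.moisture_wt_pct is not None:
            header["moisture_wt_pct"] = self.moisture_wt_pct
        _io.write_table(path, pd.DataFrame(data), header)

    @classmethod
    def from_csv(cls, path) -> "DeformationRecord":
        frame, meta = _io.read_table(path)
        box_axial = frame.get("L_axial_nm")
        trans = None
        if "L_trans1_nm" in frame and "L_trans2_nm" in frame:
            trans = np.vstack([frame["L_trans1_nm"], frame["L_trans2_nm"]])
        return cls(axis=str(meta.pop("axis", "x")),
                   strain=frame["strain"].to_numpy(),
                   stress=frame["stress_GPa"].to_numpy(),
                   box_axial=None if box_axial is None else box_axial.to_numpy(),
                   box_transverse=trans,
                   rate=meta.pop("rate_m_s", None),
                   temperature=meta.pop("temperature_K", None),
                   moisture_wt_pct=meta.pop("moisture_wt_pct", None),
                   meta=meta)


def strain_rate_per_s(rate_m_s: float, box_edge_nm: float) -> float:
    """Engineering strain rate (1/s) of a pull at ``rate_m_s`` applied to a
    box edge of ``box_edge_nm`` (e.g. 0.1 m/s over 21 nm -> ~5e6 1/s)."""
    if box_edge_nm <= 0:
        raise DomainError("box edge must be positive")
    return rate_m_s / (box_edge_nm * 1e-9)


def stress_from_pressure(p_axial, p_trans_1, p_trans_2):
    """Axial true stress from pressure-tensor diagonals, tensile positive."""
    p_axial = np.asarray(p_axial, dtype=float)
    return -(p_axial - 0.5 * (np.asarray(p_trans_1, dtype=float)
                              + np.asarray(p_trans_2, dtype=float)))


def smooth_stress(record: DeformationRecord, window: float = 0.01
                  ) -> DeformationRecord:
    """Centered moving average of the stress over a strain-width window.

    Each point averages all samples within ``window/2`` strain on either
    side, so endpoint windows shrink naturally.  Idempotent on constant
    series; a single-sample window is the identity.
    """
    if window <= 0:
        raise DomainError("window must be positive")
    span = record.strain.max() - record.strain.min()
    if window > span:
        raise DomainError("window wider than the recorded strain span")
    strain = record.strain
    smoothed = np.empty_like(record.stress)
    half = window / 2.0
    for i, eps in enumerate(strain):
        mask = np.abs(strain - eps) <= half + 1e-15
        smoothed[i] = record.stress[mask].mean()
    return DeformationRecord(
        axis=record.axis, strain=strain.copy(), stress=smoothed,
        box_axial=None if record.box_axial is None else record.box_axial.copy(),
        box_transverse=(None if record.box_transverse is None
                        else record.box_transverse.copy()),
        rate=record.rate, temperature=record.temperature,
        moisture_wt_pct=record.moisture_wt_pct,
        meta={**record.meta, "smoothed_window": window})


def youngs_modulus(record: DeformationRecord,
                   interval: tuple[float, float] = DEFAULT_E_INTERVAL,
                   mode: str = "regression") -> tuple[float, float]:
    """Young's modulus (GPa) over the strain interval, with standard error.

    ``mode="regression"`` (default) fits a least-squares line through the
    interval; ``"secant"`` takes the endpoint stress ratio instead.
    """
    lo, hi = interval
    if lo >= hi:
        raise DomainError("interval must be increasing")
    if lo < record.strain.min() - 1e-12 or hi > record.strain.max() + 1e-12:
        raise DomainError("interval outside the recorded strain range")
    mask = (record.strain >= lo) & (record.strain <= hi)
    if mask.sum() < 3:
        raise DomainError("need at least three samples in the interval")
    eps, sig = record.strain[mask], record.stress[mask]
    if mode == "regression":
        res = stats.linregress(eps, sig)
        stderr = res.stderr if np.isfinite(res.stderr) else 0.0
        return float(res.slope), float(stderr)
    if mode == "secant":
        e = (sig[-1] - sig[0]) / (eps[-1] - eps[0])
        return float(e), 0.0
    raise DomainError(f"unknown mode {mode!r}")


def poisson_ratio(record: DeformationRecord,
                  interval: tuple[float, float] = DEFAULT_NU_INTERVAL
                  ) -> tuple[float, float]:
    """Poisson's ratio over the strain interval, with standard error.

    nu = (transverse contraction)/(axial elongation), both as engineering
    strains from the initial box edges, averaged over both transverse axes
    and over samples in the interval.  Samples at zero axial strain are
    inadmissible (division by zero).
    """
    if record.box_transverse is None:
        raise DomainError("record has no transverse box series")
    lo, hi = interval
    mask = (record.strain >= lo) & (record.strain <= hi)
    mask &= record.strain > 0
    if mask.sum() < 1:
        raise DomainError("no usable samples with nonzero axial strain "
                          "in the interval")
    eps_a = record.strain[mask]
    ratios = []
    for t in range(2):
        l0 = record.box_transverse[t, 0]
        if l0 <= 0:
            raise DataError("non-positive initial transverse box edge")
        eps_p = (l0 - record.box_transverse[t, mask]) / l0
        ratios.append(eps_p / eps_a)
    ratios = np.concatenate(ratios)
    nu = float(ratios.mean())
    stderr = (float(ratios.std(ddof=1) / np.sqrt(ratios.size))
              if ratios.size > 1 else 0.0)
    return nu, stderr


def bulk_modulus(E: float, nu: float) -> float:
    """Lame relation K = -E / (6 (nu - 1/2)), equal to E / (3 (1 - 2 nu))."""
    if nu >= 0.5 - INCOMPRESSIBLE_TOL:
        raise DomainError("Poisson ratio at the incompressible limit: "
                          "bulk modulus diverges")
    return -E / (6.0 * (nu - 0.5))


@dataclass
class AxisElasticity:
    """Elastic constants extracted from one pulling direction."""

    axis: str
    E: float
    E_stderr: float
    nu: float
    nu_stderr: float
    K: float


@dataclass
class ElasticConstants:
    """Triplicate-aggregated elastic constants (mean +/- sample sd)."""

    E: float
    E_sd: float
    nu: float
    nu_sd: float
    K: float
    K_sd: float
    n_directions: int
    rate: float | None = None

    def summary(self) -> str:
        rate = f"  rate: {self.rate:g} m/s" if self.rate is not None else ""
        return (f"E = {self.E:.3f} +/- {self.E_sd:.3f} GPa   "
                f"nu = {self.nu:.3f} +/- {self.nu_sd:.3f}   "
                f"K = {self.K:.3f} +/- {self.K_sd:.3f} GPa   "
                f"({self.n_directions} directions){rate}")


def aggregate_triplicate(axis_results) -> ElasticConstants:
    """Mean and sample standard deviation across 1-3 pulling directions.

    The aggregate K is recomputed from the aggregated E and nu so that the
    Lame identity K * 3 * (1 - 2 nu) = E holds exactly for the reported
    triple; K_sd is the spread of the per-axis K values.
    """
    axis_results = list(axis_results)
    if not axis_results:
        raise DomainError("need at least one axis result")
    if len(axis_results) > 3:
        raise DomainError("at most three orthogonal directions")

    def _agg(values):
        arr = np.asarray(values, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    E, E_sd = _agg([r.E for r in axis_results])
    nu, nu_sd = _agg([r.nu for r in axis_results])
    _, K_sd = _agg([r.K for r in axis_results])
    rates = {getattr(r, "rate", None) for r in axis_results}
    rate = rates.pop() if len(rates) == 1 else None
    return ElasticConstants(E=E, E_sd=E_sd, nu=nu, nu_sd=nu_sd,
                            K=bulk_modulus(E, nu), K_sd=K_sd,
                            n_directions=len(axis_results), rate=rate)


class ElasticityModel:
    """Elastic-constant extraction from one or more deformation records.

    Records for different pulling directions of the same system are passed
    together and aggregated as triplicates by ``fit``.
    """

    def __init__(self, records):
        if isinstance(records, DeformationRecord):
            records = [records]
        self.records = list(records)
        if not self.records:
            raise DomainError("need at least one deformation record")

    def fit(self, interval=DEFAULT_E_INTERVAL,
            poisson_interval=DEFAULT_NU_INTERVAL,
            smooth_window: float | None = 0.01,
            mode: str = "regression") -> "ElasticConstantsResults":
        per_axis = []
        for record in self.records:
            work = (smooth_stress(record, smooth_window)
                    if smooth_window else record)
            E, E_err = youngs_modulus(work, interval=interval, mode=mode)
            if record.box_transverse is not None:
                nu, nu_err = poisson_ratio(work, interval=poisson_interval)
            else:
                nu, nu_err = 0.0, 0.0
            res = AxisElasticity(axis=record.axis, E=E, E_stderr=E_err,
                                 nu=nu, nu_stderr=nu_err,
                                 K=bulk_modulus(E, nu))
            res.rate = record.rate  # carried for aggregation
            per_axis.append(res)
        constants = aggregate_triplicate(per_axis)
        return ElasticConstantsResults(model=self, per_axis=per_axis,
                                       constants=constants,
                                       interval=tuple(interval),
                                       poisson_interval=tuple(poisson_interval),
                                       smooth_window=smooth_window)


@dataclass
class ElasticConstantsResults:
    model: ElasticityModel
    per_axis: list
    constants: ElasticConstants
    interval: tuple
    poisson_interval: tuple
    smooth_window: float | None

    @property
    def E(self) -> float:
        return self.constants.E

    @property
    def nu(self) -> float:
        return self.constants.nu

    @property
    def K(self) -> float:
        return self.constants.K

    def summary(self) -> str:
        lines = ["Elastic constants", "=" * 40,
                 f"E interval: {self.interval[0]:.3f}-{self.interval[1]:.3f} "
                 f"strain   nu interval: {self.poisson_interval[0]:.3f}-"
                 f"{self.poisson_interval[1]:.3f}   smoothing window: "
                 f"{self.smooth_window}"]
        for r in self.per_axis:
            lines.append(f"  axis {r.axis}: E = {r.E:.3f} GPa  "
                         f"nu = {r.nu:.3f}  K = {r.K:.3f} GPa")
        lines.append(self.constants.summary())
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for record in self.model.records:
            ax.plot(record.strain, record.stress, ".", ms=2,
                    label=f"axis {record.axis}")
        grid = np.linspace(*self.interval, 50)
        ax.plot(grid, self.E * grid, "k-", lw=2,
                label=f"E = {self.E:.2f} GPa")
        ax.set_xlabel("strain")
        ax.set_ylabel("stress (GPa)")
        ax.legend()
        return ax
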