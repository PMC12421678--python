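"""Tensile-index analysis of hot-pressed paper sheets.

The tensile index (N m/g) is the tensile strength (N/m) of a sheet divided
by its grammage (g/m^2): a specific-strength measure.  Hot-pressing CTMP
sheets raises both the dry and (especially) the wet index with pressing
temperature; an apparent activation energy for wet-strength development is
obtained from an Arrhenius-style fit of ln(wet index) against reciprocal
absolute pressing temperature, Ea = -R * slope.  Records with zero wet index
(below the measurable threshold) are excluded from that fit with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_GAS, celsius_to_kelvin
from .exceptions import DomainError, FitFailureError

__all__ = [
    "SheetTensileRecord",
    "StrengthArrheniusFit",
    "StrengthArrheniusModel",
    "StrengthArrheniusResults",
    "tensile_index",
    "percent_increase",
    "strength_activation_energy",
    "load_reference_sheets",
]


@dataclass(frozen=True)
class SheetTensileRecord:
    """One tensile measurement of a (possibly hot-pressed) sheet."""

    pressing_T_C: float | None
    moisture_wt_pct: float
    press_time_s: float | None
    pressure_MPa: float | None
    state: str  # dry_test | wet_test
    tensile_strength: float  # N/m
    grammage: float  # g/m^2

    def __post_init__(self):
        if self.state not in ("dry_test", "wet_test"):
            raise DomainError("state must be 'dry_test' or 'wet_test'")
        for name in ("tensile_strength", "grammage"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")

    @property
    def tensile_index(self) -> float:
        return tensile_index(self.tensile_strength, self.grammage)


def tensile_index(strength: float, grammage: float) -> float:
    """Tensile index (N m/g) = tensile strength (N/m) / grammage (g/m^2)."""
    if grammage <= 0:
        raise DomainError("grammage must be strictly positive")
    return strength / grammage


def percent_increase(reference: float, value: float) -> float:
    """Relative change in percent: 100 * (value - reference) / reference."""
    if reference <= 0:
        raise DomainError("reference must be strictly positive")
    return 100.0 * (value - reference) / reference


@dataclass
class StrengthArrheniusFit:
    """Apparent activation energy of strength development (kJ/mol)."""

    Ea: float
    stderr: float
    T_range_C: tuple[float, float]
    condition: str
    n_points: int
    prefactor: float

    def summary(self) -> str:
        return (f"Ea ({self.condition}) = {self.Ea:.1f} +/- {self.stderr:.1f} "
                f"kJ/mol over {self.T_range_C[0]:.0f}-"
                f"{self.T_range_C[1]:.0f} C ({self.n_points} points)")


def strength_activation_energy(pressing_T_C, index,
                               condition: str = "unspecified"
                               ) -> StrengthArrheniusFit:
    """OLS of ln(index) vs 1/T_K; Ea = -R * slope, in kJ/mol.

    Temperatures are pressing temperatures in Celsius (converted internally
    with T_K = T_C + 273.15).  Zero or negative indices are excluded.
    """
    T_C = np.asarray(pressing_T_C, dtype=float)
    idx = np.asarray(index, dtype=float)
    if T_C.size != idx.size:
        raise DomainError("temperature and index arrays must match")
    usable = idx > 0
    if not np.all(usable):
        warnings.warn(f"excluding {int((~usable).sum())} record(s) with "
                      "non-positive index (below measurable threshold)",
                      UserWarning, stacklevel=2)
    T_C, idx = T_C[usable], idx[usable]
    if T_C.size < 2:
        raise FitFailureError("need at least two usable records")
    T_K = celsius_to_kelvin(T_C)
    res = stats.linregress(1.0 / T_K, np.log(idx))
    Ea = -R_GAS * res.slope / 1000.0
    stderr = R_GAS * res.stderr / 1000.0 if np.isfinite(res.stderr) else 0.0
    return StrengthArrheniusFit(Ea=float(Ea), stderr=float(stderr),
                                T_range_C=(float(T_C.min()), float(T_C.max())),
                                condition=condition, n_points=int(T_C.size),
                                prefactor=float(np.exp(res.intercept)))


class StrengthArrheniusModel:
    """Activation-energy analysis of a sheet tensile table.

    Expects a DataFrame with columns ``T_C``, ``state``, and either
    ``tensile_index`` or ``strength_Npm`` + ``grammage_gm2``, plus an
    optional ``condition`` column (e.g. dry_pressed / moist_pressed).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "tensile_index" not in frame:
            frame["tensile_index"] = [
                tensile_index(s, g) for s, g in
                zip(frame["strength_Npm"], frame["grammage_gm2"])]
        self.frame = frame

    def fit(self, condition: str | None = None,
            state: str = "wet_test") -> "StrengthArrheniusResults":
        sub = self.frame[self.frame["state"] == state]
        fits = {}
        conditions = ([condition] if condition is not None
                      else sorted(sub.get("condition", pd.Series(["all"] *
                                  len(sub))).unique()))
        for cond in conditions:
            rows = (sub if cond == "all"
                    else sub[sub["condition"] == cond])
            rows = rows.dropna(subset=["T_C"])
            try:
                fits[cond] = strength_activation_energy(
                    rows["T_C"], rows["tensile_index"], condition=cond)
            except FitFailureError as exc:
                fits[cond] = exc
        return StrengthArrheniusResults(model=self, fits=fits, state=state)


@dataclass
class StrengthArrheniusResults:
    model: StrengthArrheniusModel
    fits: dict
    state: str

    def __getitem__(self, condition: str) -> StrengthArrheniusFit:
        fit = self.fits[condition]
        if isinstance(fit, Exception):
            raise fit
        return fit

    def summary(self) -> str:
        lines = [f"Sheet strength Arrhenius analysis ({self.state})",
                 "=" * 40]
        for cond, fit in self.fits.items():
            if isinstance(fit, Exception):
                lines.append(f"Ea ({cond}): failed ({fit})")
            else:
                lines.append(fit.summary())
        return "\n".join(lines)

    def compare_with_diffusion(self, arrhenius_fit) -> str:
        """Juxtapose sheet-strength Ea with a lignin-diffusion Ed fit.

        Purely a side-by-side report: no statistical test is implied by the
        comparison.
        """
        lines = [self.summary(), "-" * 40,
                 "Simulated lignin-diffusion activation energy:",
                 arrhenius_fit.summary()]
        return "\n".join(lines)


def load_reference_sheets() -> pd.DataFrame:
    """Bundled table of published reference tensile indices.

    Encodes the headline measurements of hot-pressed spruce CTMP sheets
    (100 g/m^2): the unpressed dry index 27.7 N m/g, maxima of 49.7 (dry
    sheets, 280 C) and 62.9 N m/g (moist sheets, 240 C), wet indices 21.2 /
    25.7 N m/g at 300 C, and the unmeasurable (zero) unpressed wet index.
    """
    with resources.files("lignotherm").joinpath(
            "data/sheet_reference.csv").open() as fh:
        frame = pd.read_csv(fh, comment="#")
    return frame
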