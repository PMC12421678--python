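"""Seeded synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here, emulating the
statistical structure of condensed-phase MD observables of moist amorphous
lignin:

* stepwise-cooling dilatometry curves (two asymptotic expansivity lines
  blended by a smooth crossover at the true Tg, Gaussian noise per replica);
* 3-D Brownian walkers with known diffusivity, including bimodal mixtures
  (fast water in clusters vs slow matrix-bound water);
* linear-elastic uniaxial deformation records with known Young's modulus
  and Poisson ratio plus pressure-tensor-like stress noise;
* Arrhenius diffusivity-versus-temperature series with known activation
  energy and multiplicative log-normal noise.

Generator defaults encode the study conditions the analyses were designed
for: densities near 1.25 g/cm^3 at room temperature, Tg near 418 K, a 150 to
550 K cooling ladder in 25 K steps averaged over five replicas, 200 ns
diffusion records, E near 2.2 GPa pulled to 20% strain at 0.1 m/s, and the
isothermal temperature set {300, 400, 450, 475, 500, 525, 550} K.

Determinism contract: one named seeded stream per generator call; replicas
and walkers use spawned substreams, never a shared stream, so equal seeds
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import NM2_PER_NS_TO_M2_PER_S, R_GAS
from .exceptions import DomainError
from .mechanics import DeformationRecord
from .thermal import DilatometryCurve, hyperbolic_density
from .transport import TrajectorySet

__all__ = [
    "DilatometryParams",
    "WalkerParams",
    "DeformationParams",
    "ArrheniusParams",
    "gen_dilatometry",
    "gen_random_walks",
    "gen_deformation",
    "gen_arrhenius_series",
]

_DEFAULT_T_GRID = tuple(np.arange(150.0, 551.0, 25.0))


def _hyperbolic_mapping(slope_glass, slope_melt, Tg_true, breadth):
    """Map generator parameters onto the hyperbolic density model.

    The model's asymptotic slopes are -(a+b) below and -a above the
    transition, so a = -slope_melt and b = slope_melt - slope_glass (negative
    for a physically increasing expansivity); c = 2 ln(breadth) makes e^(c/2)
    the crossover half-width in kelvin.
    """
    a = -slope_melt
    b = slope_melt - slope_glass
    c = 2.0 * np.log(breadth)
    return a, b, Tg_true, c


# ---------------------------------------------------------------------------
# dilatometry
# ---------------------------------------------------------------------------

@dataclass
class DilatometryParams:
    """Ground-truth parameters of a synthetic dilatometry experiment.

    ``rho_ref`` is the noise-free density at ``T_ref``; ``slope_glass`` and
    ``slope_melt`` are the asymptotic d(rho)/dT below and above the
    transition (both negative, the melt slope steeper); ``breadth`` is the
    crossover half-width in kelvin.  ``model`` selects the blend: the
    hyperbolic family (for which the hyperbolic estimator is exactly
    well-specified) or a tanh blend of the two crossing lines (to probe
    mis-specification).
    """

    rho_ref: float = 1.25  # g/cm^3 at T_ref
    T_ref: float = 300.0  # K
    slope_glass: float = -2e-4  # g/cm^3 per K
    slope_melt: float = -6e-4  # g/cm^3 per K
    Tg_true: float = 418.0  # K
    breadth: float = 40.0  # K
    noise_sd: float = 0.002  # g/cm^3
    T_grid: tuple = _DEFAULT_T_GRID
    n_replicas: int = 5
    seed: int = 0
    moisture_wt_pct: float | None = None
    model: str = "hyperbolic"  # or "tanh"

    def validate(self) -> None:
        if len(self.T_grid) == 0:
            raise DomainError("T_grid must not be empty")
        if self.breadth <= 0:
            raise DomainError("breadth must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if abs(self.slope_melt) <= abs(self.slope_glass):
            raise DomainError(
                "expansivity must increase above Tg: |slope_melt| > |slope_glass|")
        if self.model not in ("hyperbolic", "tanh"):
            raise DomainError("model must be 'hyperbolic' or 'tanh'")


def _dilatometry_truth(p: DilatometryParams, T: np.ndarray) -> np.ndarray:
    if p.model == "hyperbolic":
        a, b, T0, c = _hyperbolic_mapping(p.slope_glass, p.slope_melt,
                                          p.Tg_true, p.breadth)
        base = hyperbolic_density(T, 0.0, a, b, T0, c)
        ref = hyperbolic_density(np.array([p.T_ref]), 0.0, a, b, T0, c)[0]
        return base + (p.rho_ref - ref)
    # tanh blend of the two crossing lines (both pass through the corner)
    w = 0.5 * (1.0 - np.tanh((T - p.Tg_true) / p.breadth))
    line_glass = p.slope_glass * (T - p.Tg_true)
    line_melt = p.slope_melt * (T - p.Tg_true)
    base = w * line_glass + (1.0 - w) * line_melt
    w_ref = 0.5 * (1.0 - np.tanh((p.T_ref - p.Tg_true) / p.breadth))
    ref = (w_ref * p.slope_glass + (1.0 - w_ref) * p.slope_melt) \
        * (p.T_ref - p.Tg_true)
    return base + (p.rho_ref - ref)


def gen_dilatometry(p: DilatometryParams) -> DilatometryCurve:
    """Generate a replica-averaged dilatometry curve with ground truth.

    Each replica adds i.i.d. Gaussian noise to the noise-free blend model;
    the returned curve holds the replica mean, per-point sd, and the full
    ground-truth record in ``meta``.
    """
    p.validate()
    T = np.asarray(p.T_grid, dtype=float)
    truth = _dilatometry_truth(p, T)
    streams = np.random.SeedSequence(p.seed).spawn(p.n_replicas)
    replicas = np.empty((p.n_replicas, T.size))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        replicas[i] = truth + rng.normal(0.0, p.noise_sd, T.size)
    rho = replicas.mean(axis=0)
    rho_sd = (replicas.std(axis=0, ddof=1) if p.n_replicas > 1
              else np.zeros(T.size))
    meta = {
        "generator": "gen_dilatometry",
        "model": p.model,
        "Tg_true_K": p.Tg_true,
        "breadth_K": p.breadth,
        "slope_glass": p.slope_glass,
        "slope_melt": p.slope_melt,
        "rho_ref": p.rho_ref,
        "T_ref_K": p.T_ref,
        "noise_sd": p.noise_sd,
        "seed": p.seed,
    }
    return DilatometryCurve(T=T, rho=rho, rho_sd=rho_sd,
                            n_replicas=p.n_replicas,
                            moisture_wt_pct=p.moisture_wt_pct, meta=meta)


# ---------------------------------------------------------------------------
# Brownian walkers
# ---------------------------------------------------------------------------

@dataclass
class WalkerParams:
    """Parameters of a Brownian-walker ensemble.

    ``components`` lists (D m^2/s, fraction) pairs; a single pure component
    is the common case.  Increments per axis are N(0, 2 D dt) so the
    ensemble MSD slope is 6 D.
    """

    components: tuple = ((5e-12, 1.0),)
    n_walkers: int = 500
    dt: float = 0.1  # ns
    n_steps: int = 2000
    box: float = 10.0  # nm (cubic edge)
    seed: int = 0
    species: str = "water"
    temperature: float | None = None
    moisture_wt_pct: float | None = None

    @classmethod
    def single(cls, D: float, **kwargs) -> "WalkerParams":
        return cls(components=((D, 1.0),), **kwargs)

    def validate(self) -> None:
        fracs = [f for _, f in self.components]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise DomainError("component fractions must sum to 1")
        if any(d < 0 for d, _ in self.components):
            raise DomainError("diffusivities must be non-negative")
        if self.n_walkers < 1 or self.n_steps < 1:
            raise DomainError("need at least one walker and one step")
        if self.dt <= 0 or self.box <= 0:
            raise DomainError("dt and box must be positive")


def gen_random_walks(p: WalkerParams) -> TrajectorySet:
    """Generate unwrapped Brownian trajectories with labelled components."""
    p.validate()
    root = np.random.SeedSequence(p.seed)
    assign_rng = np.random.default_rng(root.spawn(1)[0])
    fracs = np.array([f for _, f in p.components])
    labels = assign_rng.choice(len(p.components), size=p.n_walkers, p=fracs)
    d_values = np.array([d for d, _ in p.components])
    # nm^2/ns for step variance
    d_nm = d_values / NM2_PER_NS_TO_M2_PER_S
    streams = root.spawn(p.n_walkers + 1)[1:]
    positions = np.empty((p.n_walkers, p.n_steps + 1, 3))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        start = rng.uniform(0.0, p.box, 3)
        sd = np.sqrt(2.0 * d_nm[labels[i]] * p.dt)
        steps = (rng.normal(0.0, sd, (p.n_steps, 3)) if sd > 0
                 else np.zeros((p.n_steps, 3)))
        positions[i] = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    times = np.arange(p.n_steps + 1) * p.dt
    truth = {
        "generator": "gen_random_walks",
        "components": [{"D_m2_s": float(d), "fraction": float(f)}
                       for d, f in p.components],
        "labels": labels.tolist(),
        "seed": p.seed,
    }
    return TrajectorySet(times=times, positions=positions,
                         species=p.species, box=np.array([p.box] * 3),
                         temperature=p.temperature,
                         moisture_wt_pct=p.moisture_wt_pct,
                         ground_truth=truth)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

@dataclass
class DeformationParams:
    """Parameters of a linear-elastic uniaxial deformation record."""

    E_true: float = 2.2  # GPa
    nu_true: float = 0.35
    rate: float = 0.1  # m/s (= nm/ns)
    box_edge: float = 10.0  # nm
    max_strain: float = 0.20
    stress_noise_sd: float = 0.05  # GPa
    n_points: int = 2000
    axis: str = "x"
    seed: int = 0
    temperature: float | None = None
    moisture_wt_pct: float | None = None

    def validate(self) -> None:
        if self.max_strain < 0.20:
            raise DomainError("max_strain must reach at least 20%")
        if not 0.0 <= self.nu_true < 0.5:
            raise DomainError("nu_true must lie in [0, 0.5)")
        if self.E_true < 0 or self.stress_noise_sd < 0:
            raise DomainError("E_true and stress_noise_sd must be non-negative")
        if self.n_points < 2:
            raise DomainError("need at least two samples")


def gen_deformation(p: DeformationParams) -> DeformationRecord:
    """Generate one pulling direction: stress = E*strain + noise.

    The axial box edge elongates with the strain; the two transverse edges
    contract by nu * strain (noise-free: the pressure-tensor fluctuations
    the analysis must cope with live in the stress series).
    """
    p.validate()
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    strain = np.linspace(0.0, p.max_strain, p.n_points)
    stress = p.E_true * strain + rng.normal(0.0, p.stress_noise_sd,
                                            p.n_points)
    box_axial = p.box_edge * (1.0 + strain)
    box_trans = np.vstack([p.box_edge * (1.0 - p.nu_true * strain)] * 2)
    meta = {
        "generator": "gen_deformation",
        "E_true_GPa": p.E_true,
        "nu_true": p.nu_true,
        "stress_noise_sd_GPa": p.stress_noise_sd,
        "box_edge_nm": p.box_edge,
        "seed": p.seed,
    }
    return DeformationRecord(axis=p.axis, strain=strain, stress=stress,
                             box_axial=box_axial, box_transverse=box_trans,
                             rate=p.rate, temperature=p.temperature,
                             moisture_wt_pct=p.moisture_wt_pct, meta=meta)


# ---------------------------------------------------------------------------
# Arrhenius series
# ---------------------------------------------------------------------------

@dataclass
class ArrheniusParams:
    """Parameters of a synthetic D(T) = D0 exp(-Ed/(R T)) series."""

    D0: float = 1e-7  # m^2/s
    Ed_true: float = 50.0  # kJ/mol
    T_list: tuple = (300.0, 400.0, 450.0, 475.0, 500.0, 525.0, 550.0)
    lognoise_sd: float = 0.1  # sd of additive noise on ln D
    seed: int = 0

    def validate(self) -> None:
        if self.D0 <= 0:
            raise DomainError("D0 must be positive")
        if any(t <= 0 for t in self.T_list):
            raise DomainError("temperatures must be positive")
        if self.lognoise_sd < 0:
            raise DomainError("lognoise_sd must be non-negative")


def gen_arrhenius_series(p: ArrheniusParams) -> pd.DataFrame:
    """Generate a (T_K, D_m2_s) table with multiplicative log-normal noise.

    Ground truth is attached as ``frame.attrs["ground_truth"]``.
    """
    p.validate()
    rng = np.random.default_rng(np.random.SeedSequence(p.seed))
    T = np.asarray(p.T_list, dtype=float)
    D = p.D0 * np.exp(-1000.0 * p.Ed_true / (R_GAS * T))
    if p.lognoise_sd > 0:
        D = D * np.exp(rng.normal(0.0, p.lognoise_sd, T.size))
    frame = pd.DataFrame({"T_K": T, "D_m2_s": D})
    frame.attrs["ground_truth"] = {
        "generator": "gen_arrhenius_series",
        "D0_m2_s": p.D0,
        "Ed_true_kJ_mol": p.Ed_true,
        "lognoise_sd": p.lognoise_sd,
        "seed": p.seed,
    }
    return frame
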