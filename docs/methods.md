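# Methods

This note documents the models and estimators implemented in lignotherm,
the synthetic-data generators that stand in for molecular-dynamics output,
the numerical choices made where the design was open, and the limits of
what the tests demonstrate.

## Physical setting

Amorphous softwood lignin plasticised by water softens over a broad
temperature range. The analyses here extract, from trajectory-derived
tabular observables, the quantities that characterise that softening:
the glass-transition temperature from density–temperature (dilatometry)
curves, diffusivities of water and lignin units with their Arrhenius
activation energies, and elastic constants from uniaxial deformation.
A companion module analyses tensile measurements of hot-pressed paper
sheets, where lignin softening manifests as wet-strength development.

## Glass-transition estimation

A dilatometry curve holds replica-averaged density ρ(T) on a temperature
ladder (default 150–550 K in 25 K steps, five replicas, matching a
stepwise quench of 25 K per 10 ns, i.e. an effective 2.5 K/ns).

**Bilinear.** Ordinary least-squares lines on the glassy window
(150–225 K) and melt window (500–550 K); T_g is the crossover
(q₂−q₁)/(m₁−m₂). Uncertainty propagates the two line-coefficient
covariances through the intersection formula to first order; a 200-resample
bootstrap is available. Slopes equal within a relative tolerance of 1e-8
raise a no-crossover error. The windows are configurable; a validation
warning fires when the estimate lands within 100 K of either window edge,
because then the windows likely overlap the transition and the estimate is
biased (the fitted "asymptote" still carries curvature). That bias is
visible in the calibration below: the bilinear method is systematically a
few–fifteen kelvin low for broad transitions even without noise.

**Hyperbolic.** The model

    rho(T) = rho0 - a (T - T0) - b H0(T, T0, c)
    H0 = (T - T0)/2 - sqrt((T - T0)^2/4 + e^c)

has straight asymptotes of slope −(a+b) (glass) and −a (melt) meeting at
T0, with crossover half-width e^(c/2). b is signed and negative when
expansivity increases above the transition; no positivity constraint is
imposed. Fitting is weighted nonlinear least squares
(`scipy.optimize.least_squares`) with multi-start over five T0 quantiles
of the span crossed with two crossover-width seeds; slope seeds come from
line fits to the outer thirds of the curve. Weight schemes: uniform
(default), inverse-variance, or inverse-variance times a linear taper from
2 (coldest point) to 1 (hottest) — the latter mimics assigning greater
statistical weight to the low-temperature end, where the glassy asymptote
is cleanest. |b| < 1e-6 g/cm^3/K flags the fit degenerate (pure line; T_g
undefined). The analytic second derivative is
ρ″ = b·e^c/(4u^{3/2}), u = (T−T0)²/4 + e^c, extremal in magnitude exactly
at T0; the estimator nevertheless locates the extremum by a numeric scan of
the fitted curve at 0.1 K resolution, so the contract (extremum of the
scanned |ρ″|) is model-agnostic. Whether one reads "minimum of ρ″" with
either sign convention, the extremum of the magnitude sits at T0 for this
family, which is the contract adopted.

**Onset.** Scanning upward from the cold end at 0.1 K on the interpolated
model curve (not raw points), T_g-onset is the first temperature where
|ρ_hyp − ρ_line|/ρ_line exceeds the threshold (default 2 %), with ρ_line
the glassy line from the bilinear diagnostics. Onset is monotone
non-decreasing in the threshold. Because the threshold is relative to the
full density (~1.25 g/cm^3), a 2 % deviation is a large absolute density
gap (~0.025 g/cm^3): whether onset reads below or above the bilinear
crossover depends on the expansivity contrast |b| and the breadth. With a
strong contrast and a broad transition the onset reads low (the transition
begins long before it completes); with a narrow transition it reads high.
Both regimes are exercised in the tests.

**WLF.** log10 a_T = C1 (T−T_g)/(C2 + (T−T_g)), with the closed-form
inverse ΔT = C2·L/(C1 − L). The coefficients are user inputs (they come
from a separate constant-rate cooling study not reproduced here); the
package only guarantees the algebra, the pole handling, and the sign
convention: a target cooling rate slower than the reference gives L < 0
and a negative temperature shift.

## Diffusivity

**MSD.** MSD(τ) averages squared displacements over molecules and sliding
time origins taken every 10th frame (origins closer than that are strongly
correlated and add little information). MSD(0) = 0 exactly. Positions must
be unwrapped; a single-step jump exceeding half a box edge raises a data
error.

**Einstein relation.** D = slope/6 with the slope from OLS on MSD vs lag
over a fit window, by default 10–50 % of the lag span: short lags carry
ballistic/caging transients, and long lags have few independent pairs. A
slope negative beyond two standard errors clamps D to zero with a flag.
Units: positions nm, times ns, 1 nm²/ns = 1e-9 m²/s, recorded in output
headers.

**Arrhenius.** OLS of ln D on 1/T; E_d = −R·slope (R = 8.314 J/(mol·K)),
reported in kJ/mol with the slope's standard error and a t-based
confidence interval. Non-positive D values are excluded with a warning. A
branch split (typically a T_g estimate for the matching moisture content)
yields independent glassy/rubbery fits.

**Per-molecule distributions.** D_eff = <|r(t0+τ)−r(t0)|²>/(6τ) per
molecule, averaged over sliding origins. Short sampling times resolve
mobility heterogeneity (fast water in clusters vs slow matrix-bound
water); the ensemble mean tends to the Einstein estimate as τ grows.
Summaries per τ report quartiles, Sarle's bimodality coefficient of
log10 D_eff, and a histogram valley ratio between the two tallest modes.
Bimodality is reported, not asserted: real mobility contrasts are a
qualitative phenomenon. One property of the ideal-walker limit deserves
note: for *identical* Brownian walkers on a fixed-length record, the
per-molecule estimate at sampling time τ averages ~span/τ independent
windows, so its spread *grows* with τ; the narrowing of real distributions
at long τ reflects molecules exchanging fast and slow environments, a
mechanism the ideal generator deliberately lacks. The tests therefore
assert the estimator's true behaviour (centered on the common D at every
τ, tighter at shorter τ), and bimodal mixtures are detected through the
component medians and the inter-mode valley.

**Density maps.** Per-frame positions are wrapped into the box, binned on
a grid over the two in-plane axes, mass-weighted (18.015 g/mol for water)
and averaged over frames. The map conserves total species mass to
round-off by construction; the 1e-6 relative tolerance in the tests covers
accumulation error.

## Elastic constants

Stress is derived from pressure-tensor diagonals as
σ = −(P_axial − mean(P_transverse)), tensile positive (the source data's
convention is unstated; this one makes uniaxial tension positive).
Because pressure tensors fluctuate strongly, the stress is smoothed by a
centered moving average over a 1 % strain width (endpoint windows shrink;
the operation is the identity for a single-sample window and idempotent on
constants). E is the OLS slope of stress on strain over 0.3–9.9 % strain —
regression rather than an endpoint secant, as it is far more robust to the
fluctuations the smoothing addresses; the secant mode is provided. ν
averages (transverse contraction)/(axial elongation) over both transverse
axes and over 2–10 % strain, excluding the sub-2 % zone where the ratio
0/0-fluctuates. K = −E/(6(ν−½)); ν within 1e-6 of ½ raises an
incompressible-limit error. Triplicates over x/y/z report mean and sample
standard deviation; the aggregate K is recomputed from the aggregated
(E, ν) so the Lamé identity K·3(1−2ν) = E holds exactly for the reported
triple, while K_sd reflects the per-axis spread. Engineering strain
(Δx/x₀) is used throughout.

## Chain topology and composition

The reference macromolecule has 26 guaiacyl repeat units joined by a
β-O-4 backbone, two aliphatic α-O-γ ether linkages as branch points
(between units 2–9 and 12–13; the second placement is configurable to the
alternative 12–3 reading of an ambiguous tabulation), and terminal-group
modifications γ-carboxyl (unit 1), γ-aldehyde (7), a truncated α-aldehyde
(11), α-ketones (21, 26) and a β-ketone (22). The graph is undirected and
annotated; 3-D geometry and force-field topology are out of scope. The
per-linkage enumeration of the backbone is a package convention — the
source enumerates only the modifications — so the census validates the
modification placements strictly and treats the backbone as β-O-4.

Molar mass sums per-residue masses from element-count formulas (guaiacyl
in-chain residue C10H12O3 = 180.2 g/mol; modification deltas such as
CH2OH→COOH = −2H+O) minus a configurable condensation loss per linkage,
default zero (table entries are read as in-chain residue masses). These
formulas are the package's own convention; no mass data exist in the
source, and the independent check is a per-atom element tally over the
same formulas. System composition inverts the moisture weight fraction:
n_water = round(mc/(100−mc) · n_chains · M_chain / 18.015); recomputing
the weight fraction from the rounded count agrees within 0.5 points for
systems of ≥ 10 chains.

## Sheet tensile analysis

Tensile index = strength/grammage (N·m/g). Percent changes are plain
relative differences; display rounding to integer percent mirrors how such
values are quoted. The activation energy of wet-strength development is
an Arrhenius-style OLS of ln(index) on 1/T_K with T_K = T_C + 273.15,
Ea = −R·slope. Records with zero index (below the measurable threshold)
are excluded rather than treated as censored — a documented limitation
that biases Ea if the zeros carry information. The bundled reference
table holds only the headline indices (27.7, 49.7, 62.9, 21.2, 25.7
N·m/g with their pressing conditions); one point per condition cannot
support a fit, so the published 55/42 kJ/mol energies serve as reference
context, and the recovery tests use noise-free exponential generators at
those scales, which the estimator inverts exactly.

## Synthetic generators

The generators define the conditions every recovery statistic is measured
under; they are deliberately simple, and their defaults are fixed once:

* **Dilatometry** — blend of two expansivity lines, default the
  hyperbolic family itself (mapping a = −slope_melt,
  b = slope_melt − slope_glass, T0 = Tg_true, c = 2 ln breadth), so the
  hyperbolic estimator is exactly well-specified; a tanh blend probes
  mis-specification. Defaults: ρ(300 K) = 1.25 g/cm³, glassy slope
  −2e-4 and melt slope −6e-4 g/cm³/K (typical amorphous-polymer
  expansivities), Tg 418 K (≈145 °C), breadth 40 K (broad transition),
  noise 0.002 g/cm³, five replicas on the 150–550 K ladder.
* **Walkers** — Gaussian increments of variance 2·D·dt per axis;
  mixtures carry labelled components. Defaults: D = 5e-12 m²/s
  (water-in-polymer scale), 500 walkers, 0.1 ns frames to 200 ns,
  10 nm box.
* **Deformation** — σ = E·ε plus Gaussian stress noise (0.05 GPa,
  emulating pressure-tensor fluctuation after averaging); transverse
  edges contract noise-free by ν·ε. Defaults E = 2.2 GPa, ν = 0.35,
  0.1 m/s, 20 % strain, 2000 samples.
* **Arrhenius** — D0·exp(−Ed/RT) with multiplicative log-normal noise;
  defaults Ed = 50 kJ/mol over {300, 400, 450, 475, 500, 525, 550} K,
  log-noise 0.1.

Determinism: each generator call consumes one `numpy.random.SeedSequence`;
replicas and walkers use spawned substreams, so equal seeds give identical
output and no stream is shared.

What the generators do *not* emulate — and hence what passing tests do not
show about real data: correlated density fluctuations along a cooling
ladder, subdiffusive caging and environment exchange of confined water,
anelastic/plastic stress response and rate-dependent stiffening, phase
separation at high moisture, and any chemistry (degradation,
condensation). Recovery within the stated tolerances demonstrates the
estimators, not the simulations.

## Problem sizes and tolerances

Test and acceptance runs use deliberately modest sizes chosen so the full
suite completes in minutes on one CPU while leaving comfortable Monte
Carlo margins: 100 curves for the T_g calibration (median |error| ≤
breadth/2 = 20 K; observed ≈ 15 K bilinear, ≈ 8 K hyperbolic), 50 walker
ensembles of 100 × 500 steps across D = 1e-15–1e-10 m²/s (mean signed
relative error ≲ 1 %, bound 2 %), 500 Arrhenius draws for interval
coverage (observed ≈ 0.95–0.97 against the 0.925–0.975 band), and 50
deformation records (median E error ≈ 3 %, bound 10 %; ν exact to the
noise-free transverse channel, bound 0.03). Scalar tolerances: bilinear
intersection and Lamé identity at machine precision; hyperbolic-T_g scan
at its 0.1 K resolution; onset at its 0.1 K grid; density-map mass at
1e-6 relative.

## Known limitations

* The WLF coefficients and hence any absolute rate-shift magnitude are
  user-supplied; only the algebra and the sign are guaranteed.
* The bilinear estimator's window-curvature bias is reported, not
  corrected; the hyperbolic method is the preferred estimator for broad
  transitions.
* Per-molecule bimodality detection is descriptive (coefficients and
  valley ratios), not a hypothesis test.
* The chain model is topological; nothing downstream consumes geometry.
* Zero-index sheet records are excluded from Arrhenius fits rather than
  modelled as censored observations.
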