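# Methods

This note documents the models behind each analysis module, the defaults
that matter, and the numerical choices made where the underlying
procedures are conventionally under-specified.

## Mass photometry

**Calibration.** Landing-event contrast is linearly related to mass.
`MassCalibration` fits mass = a·contrast + b by ordinary least squares
over ≥2 standards (three recommended; the default synthetic panel is the
66/146/480 kDa regular-field-of-view triplet of an unstained protein
standard). The intercept is free by default — instrument offsets are
real — with `force_origin` available. The fit records per-standard
relative errors; it is flagged invalid when the maximum exceeds 5 %, the
conventional acceptance bound for a three-point run. Applying a
calibration to events already in mass units is a hard error: silent
double calibration is worse than a crash.

**Histogram.** Uniform bins over a half-open window, default 10 kDa bins
on [0, 2000) kDa. Negative (unbinding) events fall outside any
non-negative window and are excluded but counted; they still enter the
event-count QC (binding:unbinding ratio, recommended maximum of 3000
events for a regular field of view, configurable floor of 100).

**Truncated multi-Gaussian fit.** The instrument records no events below
a detection limit *t* (default 30 kDa; the synthetic reference runs use
40 kDa). Each component is a Gaussian restricted to [t, ∞); the expected
count of bin [l, u) integrates the component CDF exactly (no
density×width approximation) and is identically zero for bins entirely
below *t*. By default each component is renormalized on [t, ∞) so its
amplitude Nₖ is the expected number of *observable* events and fractions
Nₖ/ΣN are well-defined; `renormalize=False` instead zeroes the model
below *t* without renormalizing — both conventions exist in the wild and
the choice is explicit. Optimization is bounded trust-region least
squares (σ > 0, N ≥ 0, ftol/xtol/gtol 1e-10), deterministic for
identical inputs. Components converging within one bin width of each
other carry no separate information and are merged (count-weighted) with
a warning; non-convergence is flagged on the result, never silent.

**Peak detection.** Initial guesses come from a moving-average-smoothed
histogram (window 5 bins, overlap-normalized so edges are not diluted),
local maxima above 5 events separated by ≥4 bin widths, with
σ⁰ = max(15 kDa, 0.08·μ⁰) and N⁰ from the local ±2σ⁰ area. These values
resolve the closest peak pair in the reference runs (106/274 kDa, gap
≈ 7σ of the lower peak) while ignoring shot noise; they are starting
points only.

**Stoichiometry.** n = round(peak/monomer), minimum 1; the relative
deviation is measured against the ideal n-mer and accepted within 10 %
by default. Rounding is exactly the nearest-n-mer assignment (verified
against exhaustive search in the tests).

## nanoDSF

**Model.** The synthetic ramp follows a two-state van't Hoff unfolding:
f(T) = K/(1+K), K = exp[−(ΔH/R)(1/T − 1/Tm)] (kelvin), with linear
native/unfolded ratio baselines and default ΔH = 400 kJ/mol — a
realistic enthalpy for a mid-size membrane protein, giving a transition
a few degrees wide. Scattering is a logistic sigmoid.

**Transition detection.** The ratio curve is smoothed
(Savitzky–Golay, window 11 points, order 3), differentiated on the grid,
and the derivative smoothed once more with a wider window (2·11−1 = 21,
order 2). Extrema of both signs are reported (a rising ratio gives a
derivative maximum; the classical "minimum of the first derivative"
convention corresponds to falling ratios) with their prominences.
Two guards keep grid-level noise out: extrema must reach 25 % of the
global derivative magnitude as well as 25 % of the derivative range in
prominence — prominence alone is inflated on the opposite-sign series by
the true transition's dip — and the reported temperature is the
derivative-weighted centroid of the half-prominence region rather than
the argmax sample. With 0.1 % relative channel noise on a 0.1 °C grid
this locates an 84 °C midpoint with worst-case error 0.26 °C over 30
seeds; the noiseless bias (from the 1/T² factor in df/dT and the
smoothing) is under 0.07 °C, within one grid step. A flat or purely
linear curve yields no transitions.

**Aggregation onset.** Baseline = median of the first 10 % of points;
plateau = maximum of the smoothed curve (window 31, order 2 — the onset
sits on the shallow foot of the sigmoid, where first-crossing detection
is far more noise-sensitive than an extremum, hence the wider window);
onset = first linear-interpolated crossing of 1 % of the
baseline-to-plateau rise on the smoothed curve. Normalization makes the
result invariant under affine scaling of the signal. No onset is
reported when the total rise is below 5 standard deviations of the
baseline segment. An order-2 polynomial filter reproduces the locally
cubic logistic foot, so the smoothing adds negligible bias (<0.01 °C
noiseless).

**Ranking and checks.** Conditions are ranked by the
highest-prominence Tm, ties broken alphabetically; initial fluorescence
must sit in [2000, 15000] counts in both channels. Buffer-control
subtraction is a plain per-temperature subtraction of a labeled blank.

## DLS

**Constants and defaults.** k_B = 1.380649e-23 J/K; λ = 658 nm, θ = 90°,
n = 1.330, T = 298.15 K, η = 8.872e-4 Pa·s (water at 25 °C) — all
overridable per measurement. q = (4πn/λ)·sin(θ/2).

**Cumulants.** g₂(τ) = B + β·exp(−2Γτ)(1 + (μ₂/2)τ²)², fitted by
bounded least squares seeded from the tail baseline and a log-linear
early-decay slope. D = Γ/q², R_h by Stokes–Einstein, PDI = μ₂/Γ²; a
negative fitted μ₂ (common for nearly monodisperse samples) is clipped
to zero for the PDI with a warning.

**Distribution inversion.** Weights over a log-spaced radius grid
(default 100 points, 0.1–1000 nm) minimize
‖g₂_model(w) − g₂‖² + α²‖Lw‖² with w ≥ 0, where L is the
second-difference operator with zero (Dirichlet) boundaries — the
boundary rows also damp spurious weight piling up at the grid edges.
B and β are refined by alternating a non-negative least-squares solve in
g₁ space with a linear fit of g₂ against the squared model. The problem
is solved on a normalized scale (g₁ ∈ [0,1], Σw = 1), so α is
dimensionless; the default α = 0.05 is the largest value at which two
equal-intensity species three-fold apart in radius remain resolved both
noiselessly and at σ = 1e-3 additive noise on g₂. No automatic L-curve
or GCV selection in this version — a documented limitation. A species
carrying only a few percent of the scattered intensity (e.g. a small
protein next to a large aggregate: intensity ∝ mass·R³) needs
substantially lower noise or weaker regularization to appear; this is
intrinsic to Laplace inversion, not a tuning artifact.

**Reweighting.** Compact-sphere Rayleigh convention: intensity ∝
mass·R³ and mass ∝ number·R³, so mass weights = intensity/R³ and number
weights = intensity/R⁶, renormalized. The maps are exact algebraic
bijections on positive-weight grids; vendor software may use a different
(undocumented) transform, which is why the radius→mass conversion below
is kept as a separate, explicit step.

**Radius↔mass power law.** log₁₀M regressed on log₁₀R_h; stored as
R_h = c·M^b so both directions are closed-form. The built-in default is
fitted to five reference (R_h, M) pairs of detergent/amphipol-solubilized
species and corresponds to M ≈ 3.56·R_h^2.32 (kDa, nm) — a much
shallower mass-radius scaling than the compact-globular b = 1/3, as
expected when micelle mass rides along.

**Aggregate detection.** Distribution route: flag when >5 % of scattered
intensity sits above 100 nm (both configurable). Correlogram route: a
two-exponential Siegert fit is accepted as evidence of a slow component
when it cuts the residual sum of squares by ≥20 % and the slow decay
maps above the cutoff radius — the numeric criterion is a heuristic and
documented as such.

## Synthetic data

Generators are deterministic per seed and write the same formats the
readers parse. Mass-photometry components are sampled from exact
truncated normals (rejection-with-redraw semantics: component counts are
exact, no positive event below the detection limit), plus optional
uniform background and sign-flipped unbinding draws. Ramps add relative
Gaussian noise per fluorescence channel and absolute noise on
scattering; correlograms add τ-independent Gaussian noise on g₂. None of
this models shot noise, drift, focus error, or detergent-micelle
kinetics — passing recovery tests on these inputs demonstrates the
correctness of the estimators under their stated models, not instrument
realism.

## Decision report

Verdicts are evaluated in pipeline order (nanoDSF, DLS, MP). Default
thresholds — all overridable and deliberately conservative package
defaults, not instrument constants: min Tm 45 °C, max PDI 0.3, max 5 %
intensity above 100 nm, mass tolerance 10 %, min target-species fraction
50 %, event counts in [100, 3000]. The first failing stage fixes the
recommendation (buffer/detergent optimization for nanoDSF,
re-purification/reconstitution for DLS and MP). A component heavier than
the expected mass beyond tolerance is a warning, not a failure, because
protein–micelle complexes always read heavy; among out-of-tolerance
components the heavier near-miss is preferred over a lighter one when
attributing the target species, for the same reason. When nothing fails
the recommendation is negative-stain microscopy first; cryo-EM grid
preparation is recommended only when the caller asserts negative stain
has already been screened (`negative_stain_ok`) — the pipeline's stage
order is part of its logic, and the tool does not skip a stage on its
own. Tightening any threshold can only demote verdicts (a property
tested explicitly), and a "proceed" recommendation never coexists with a
failing verdict.

## Problem sizes

Reference recoveries use 8000–9000 events per mass-photometry run
(2–3 components), 701-point thermal ramps (20–90 °C at 0.1 °C), and
200-point correlograms on 100-point radius grids — sizes representative
of real acquisitions at which each analysis completes in well under a
second.
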