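"""Seeded synthetic-data generators with known ground truth.

Every analysis module in the pipeline has a matching generator here:
mass-photometry event sets (truncated Gaussian populations + background
+ unbinding events), nanoDSF two-state thermal ramps with linear
baselines and a logistic scattering transition, and DLS multi-exponential
correlograms.  Outputs are deterministic per seed and written in the
exact formats the readers accept, so the full pipeline is testable
without instrument data.

Noise models are deliberately simple stand-ins: sampling noise only for
mass photometry, additive Gaussian noise relative to signal for nanoDSF,
tau-independent additive Gaussian noise on g2 for DLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .dls import Correlogram, Environment, Optics, scattering_vector, stokes_einstein_diffusion
from .nanodsf import ThermalRamp
from .photomol import CalibrationStandard, MPEventSet

__all__ = [
    "MPComponentSpec",
    "DSFRampSpec",
    "DLSComponentSpec",
    "gen_mp_events",
    "gen_calibration_events",
    "gen_dsf_ramp",
    "gen_correlogram",
    "NATIVEMARK_REGULAR_FOV",
]

GAS_CONSTANT = 8.31446261815324e-3  # kJ/(mol*K)

# regular-FOV species of the NativeMark unstained protein standard
NATIVEMARK_REGULAR_FOV: tuple[CalibrationStandard, ...] = (
    CalibrationStandard("NM1", 66.0, -66.0 / 20000.0),
    CalibrationStandard("NM2", 146.0, -146.0 / 20000.0),
    CalibrationStandard("NM3", 480.0, -480.0 / 20000.0),
)


@dataclass
class MPComponentSpec:
    """One Gaussian mass population of a synthetic event set."""

    mu: float  # kDa
    sigma: float  # kDa
    count: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.count < 0:
            raise ValueError("count must be non-negative")


def gen_mp_events(
    specs: list[MPComponentSpec],
    detection_limit: float = 30.0,
    background_count: int = 0,
    background_window: tuple[float, float] = (30.0, 2000.0),
    unbinding_fraction: float = 0.0,
    seed: int = 0,
) -> MPEventSet:
    """Draw mass-photometry events from truncated Gaussian populations.

    Each component contributes exactly ``count`` events from
    Normal(mu, sigma) conditioned on value >= detection_limit (rejection
    with redraw, so component counts are exact).  ``background_count``
    uniform events over ``background_window`` model unspecific landings;
    ``unbinding_fraction`` of the total is appended as negated draws from
    the same mixture.
    """
    if detection_limit < 0:
        raise ValueError("detection_limit must be non-negative")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    for spec in specs:
        if spec.count == 0:
            continue
        a = (detection_limit - spec.mu) / spec.sigma
        parts.append(
            truncnorm.rvs(a, np.inf, loc=spec.mu, scale=spec.sigma,
                          size=spec.count, random_state=rng)
        )
    if background_count > 0:
        lo = max(background_window[0], detection_limit)
        parts.append(rng.uniform(lo, background_window[1], size=background_count))
    values = np.concatenate(parts) if parts else np.empty(0)
    if unbinding_fraction > 0 and values.size > 0:
        n_unbind = int(round(unbinding_fraction * values.size))
        if n_unbind > 0:
            parts.append(-rng.choice(values, size=n_unbind, replace=True))
            values = np.concatenate(parts)
    truth = {
        "components": [(s.mu, s.sigma, s.count) for s in specs],
        "detection_limit": detection_limit,
        "background_count": background_count,
        "unbinding_fraction": unbinding_fraction,
        "seed": seed,
    }
    return MPEventSet(values=values, kind="mass", source="synthetic", meta=truth)


def gen_calibration_events(
    slope: float,
    intercept: float = 0.0,
    standards: list[CalibrationStandard] | None = None,
    contrast_noise: float = 0.0,
    seed: int = 0,
) -> list[CalibrationStandard]:
    """Per-standard mean contrasts on the line mass = slope*c + intercept.

    Contrasts c = (m - intercept)/slope get multiplicative Gaussian noise
    of relative width ``contrast_noise``; with zero noise a refit recovers
    the generating line exactly.
    """
    if slope == 0:
        raise ValueError("slope must be nonzero")
    if standards is None:
        standards = list(NATIVEMARK_REGULAR_FOV)
    rng = np.random.default_rng(seed)
    out = []
    for s in standards:
        c = (s.known_mass - intercept) / slope
        c *= 1.0 + contrast_noise * rng.standard_normal()
        out.append(CalibrationStandard(s.label, s.known_mass, c))
    return out


@dataclass
class DSFRampSpec:
    """Two-state unfolding ramp with linear ratio baselines.

    The fraction unfolded follows the van't Hoff relation
    f(T) = K/(1+K), K = exp[-(dH/R)(1/T - 1/Tm)] with temperatures in
    kelvin; the F350/F330 ratio interpolates between the native and
    unfolded baselines (each linear in T), and the backscattering channel
    is a logistic sigmoid.  Relative Gaussian noise applies per channel.
    """

    tm: float = 60.0  # °C
    vant_hoff_dh: float = 400.0  # kJ/mol
    ratio_native: tuple[float, float] = (0.8, 0.0)  # (value at t_start, slope per °C)
    ratio_unfolded: tuple[float, float] = (1.0, 0.0)
    scattering_midpoint: float = 70.0  # °C
    scattering_steepness: float = 0.5  # 1/°C
    scattering_baseline: float = 0.0
    scattering_amplitude: float = 1.0
    noise: float = 0.0  # relative, per fluorescence channel
    scattering_noise: float = 0.0  # absolute, on the scattering channel
    t_start: float = 20.0
    t_end: float = 90.0
    t_step: float = 0.1
    f330_level: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("ramp start must precede end")
        if self.t_step <= 0:
            raise ValueError("step must be positive")
        if self.vant_hoff_dh <= 0:
            raise ValueError("van't Hoff enthalpy must be positive")

    def temperatures(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)

    def fraction_unfolded(self, t_celsius: np.ndarray) -> np.ndarray:
        t_k = np.asarray(t_celsius, dtype=float) + 273.15
        tm_k = self.tm + 273.15
        k_eq = np.exp(-(self.vant_hoff_dh / GAS_CONSTANT) * (1.0 / t_k - 1.0 / tm_k))
        return k_eq / (1.0 + k_eq)

    def ratio(self, t_celsius: np.ndarray) -> np.ndarray:
        """Noiseless analytic F350/F330 ratio."""
        t = np.asarray(t_celsius, dtype=float)
        f = self.fraction_unfolded(t)
        rn = self.ratio_native[0] + self.ratio_native[1] * (t - self.t_start)
        ru = self.ratio_unfolded[0] + self.ratio_unfolded[1] * (t - self.t_start)
        return rn * (1.0 - f) + ru * f

    def scattering(self, t_celsius: np.ndarray) -> np.ndarray:
        """Noiseless logistic scattering curve."""
        t = np.asarray(t_celsius, dtype=float)
        return self.scattering_baseline + self.scattering_amplitude / (
            1.0 + np.exp(-self.scattering_steepness * (t - self.scattering_midpoint))
        )


def gen_dsf_ramp(spec: DSFRampSpec, label: str = "synthetic") -> ThermalRamp:
    """Realize a :class:`DSFRampSpec` as a per-capillary thermal ramp."""
    rng = np.random.default_rng(spec.seed)
    t = spec.temperatures()
    ratio = spec.ratio(t)
    f330 = np.full_like(t, spec.f330_level)
    f350 = f330 * ratio
    if spec.noise > 0:
        f330 = f330 * (1.0 + spec.noise * rng.standard_normal(t.size))
        f350 = f350 * (1.0 + spec.noise * rng.standard_normal(t.size))
    scat = spec.scattering(t)
    if spec.scattering_noise > 0:
        scat = scat + spec.scattering_noise * rng.standard_normal(t.size)
    return ThermalRamp(
        temperature=t,
        f330=np.maximum(f330, 0.0),
        f350=np.maximum(f350, 0.0),
        scattering=scat,
        label=label,
    )


@dataclass
class DLSComponentSpec:
    """One diffusing species of a synthetic correlogram."""

    rh: float  # nm
    mass_fraction: float

    def __post_init__(self) -> None:
        if self.rh <= 0:
            raise ValueError("radius must be positive")
        if self.mass_fraction < 0:
            raise ValueError("mass fraction must be non-negative")


def intensity_weights(specs: list[DLSComponentSpec]) -> np.ndarray:
    """Rayleigh compact-sphere weights: intensity ~ mass_fraction * R^3."""
    w = np.array([s.mass_fraction * s.rh**3 for s in specs], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total mass fraction must be positive")
    return w / total


def gen_correlogram(
    specs: list[DLSComponentSpec],
    optics: Optics | None = None,
    environment: Environment | None = None,
    beta: float = 0.9,
    baseline: float = 1.0,
    tau_range: tuple[float, float] = (1e-7, 1.0),
    n_tau: int = 200,
    noise: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> Correlogram:
    """Multi-exponential intensity autocorrelation with known ground truth.

    g1(tau) = sum_i w_i exp(-q^2 D(rh_i) tau) with intensity weights
    w_i ~ mass_fraction_i * rh_i^3; g2 = baseline + beta*g1^2 plus
    additive tau-independent Gaussian noise.
    """
    optics = optics or Optics()
    environment = environment or Environment()
    w = intensity_weights(specs)
    q = scattering_vector(optics)
    gammas = np.array(
        [
            q**2 * stokes_einstein_diffusion(
                s.rh * 1e-9, environment.temperature, environment.viscosity
            )
            for s in specs
        ]
    )
    tau = np.geomspace(tau_range[0], tau_range[1], n_tau)
    g1 = np.sum(w[:, None] * np.exp(-np.outer(gammas, tau)), axis=0)
    g2 = baseline + beta * g1**2
    if noise > 0:
        rng = np.random.default_rng(seed)
        g2 = g2 + noise * rng.standard_normal(tau.size)
    return Correlogram(
        tau=tau, g2=g2, optics=optics, environment=environment, label=label
    )
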