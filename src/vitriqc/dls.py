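"""Dynamic light scattering analysis.

DLS measures the intensity autocorrelation g2(tau) of laser light
scattered by particles in suspension.  For a mixture of diffusing
species the field correlation is g1(tau) = sum_i w_i exp(-q^2 D_i tau)
with intensity weights w_i, and the Siegert relation gives
g2 = B + beta * g1^2.  Two standard inversions are implemented:

* the method of cumulants — a low-order expansion yielding the mean
  decay rate Gamma, the second cumulant mu2 and the polydispersity
  index PDI = mu2/Gamma^2;
* a regularized non-negative inversion onto a log-spaced grid of
  hydrodynamic radii (smooth size distribution).

Diffusion coefficients map to hydrodynamic radii via Stokes-Einstein,
Rh = kB*T / (6*pi*eta*D).  Only populations whose radii differ by a
factor of about 3 are resolvable by the inversion — an intrinsic limit
of the Laplace inversion, not of this implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, nnls
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BOLTZMANN_CONSTANT",
    "Optics",
    "Environment",
    "Correlogram",
    "CumulantResult",
    "CumulantFit",
    "SizeDistribution",
    "SizeDistributionInverter",
    "DLSPeak",
    "RadiusMassModel",
    "scattering_vector",
    "fit_cumulants",
    "stokes_einstein_radius",
    "stokes_einstein_diffusion",
    "fit_size_distribution",
    "reweight_distribution",
    "extract_peaks",
    "radius_mass_model_fit",
    "radius_mass_convert",
    "default_radius_mass_model",
    "detect_aggregation",
    "REFERENCE_RADIUS_MASS_PAIRS",
]

BOLTZMANN_CONSTANT = 1.380649e-23  # J/K


@dataclass
class Optics:
    """Laser/detector geometry; defaults match a 658 nm, 90° instrument."""

    wavelength: float = 658e-9  # m
    angle_deg: float = 90.0
    refractive_index: float = 1.330

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.angle_deg < 180:
            raise ValueError("scattering angle must lie in (0, 180) degrees")


@dataclass
class Environment:
    """Solvent conditions; defaults are water at 25 °C."""

    temperature: float = 298.15  # K
    viscosity: float = 8.872e-4  # Pa*s

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.viscosity <= 0:
            raise ValueError("temperature and viscosity must be positive")


@dataclass
class Correlogram:
    """Measured intensity autocorrelation g2 vs lag time."""

    tau: np.ndarray  # s, strictly increasing, > 0
    g2: np.ndarray
    optics: Optics = field(default_factory=Optics)
    environment: Environment = field(default_factory=Environment)
    label: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.size != self.g2.size:
            raise ValueError("tau and g2 must have equal length")
        if self.tau.size < 20:
            raise ValueError("correlogram needs at least 20 points")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise ValueError("lag times must be positive and strictly increasing")


@dataclass
class CumulantResult:
    baseline: float  # B
    intercept: float  # beta
    gamma: float  # mean decay rate, 1/s
    mu2: float  # second cumulant, 1/s^2
    pdi: float  # mu2 / gamma^2
    diffusion: float  # m^2/s
    rh: float  # hydrodynamic radius, m
    converged: bool = True


def scattering_vector(optics: Optics) -> float:
    """Magnitude of the scattering vector q = (4*pi*n/lambda)*sin(theta/2)."""
    theta = np.deg2rad(optics.angle_deg)
    return 4.0 * np.pi * optics.refractive_index / optics.wavelength * np.sin(theta / 2)


def stokes_einstein_radius(diffusion: float, temperature: float, viscosity: float) -> float:
    """Hydrodynamic radius (m) of a sphere with diffusion coefficient D (m^2/s)."""
    if diffusion <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("D, T and eta must all be positive")
    return BOLTZMANN_CONSTANT * temperature / (6.0 * np.pi * viscosity * diffusion)


def stokes_einstein_diffusion(rh: float, temperature: float, viscosity: float) -> float:
    """Inverse map: diffusion coefficient (m^2/s) of a sphere of radius rh (m)."""
    if rh <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("Rh, T and eta must all be positive")
    return BOLTZMANN_CONSTANT * temperature / (6.0 * np.pi * viscosity * rh)


# ---------------------------------------------------------------------------
# cumulant analysis


class CumulantFit(BaseEstimator):
    """Second-order cumulant fit of an intensity autocorrelation.

    Model: g2(tau) = B + beta * exp(-2*Gamma*tau) * (1 + (mu2/2)*tau^2)^2.
    A negative fitted mu2 (possible for nearly monodisperse samples) is
    clipped to zero for the PDI with a warning.
    """

    def __init__(self, order: int = 2, tol: float = 1e-12):
        self.order = order
        self.tol = tol

    def fit(self, X, y=None):
        corr: Correlogram = X
        tau, g2 = corr.tau, corr.g2
        if np.ptp(g2) <= 0:
            raise ValueError("no dynamic range in g2: nothing to fit")
        b0 = float(g2[-max(3, tau.size // 10):].mean())
        beta0 = max(float(g2[0] - b0), 1e-6)
        # log-linear seed for Gamma from the early decay
        top = g2 - b0
        pos = top > 0.05 * beta0
        if pos.sum() >= 2:
            slope = np.polyfit(tau[pos], np.log(top[pos]), 1)[0]
            gamma0 = max(-slope / 2.0, 1.0 / tau[-1])
        else:
            gamma0 = 1.0 / tau[tau.size // 2]

        def resid(p):
            b, beta, gamma, mu2 = p
            return b + beta * np.exp(-2 * gamma * tau) * (1 + 0.5 * mu2 * tau**2) ** 2 - g2

        sol = least_squares(
            resid,
            x0=[b0, beta0, gamma0, 0.0],
            bounds=([-np.inf, 1e-12, 1e-12, -np.inf], np.inf),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
        )
        self.converged_ = bool(sol.success)
        if not self.converged_:
            warnings.warn("cumulant fit did not converge", stacklevel=2)
        self.baseline_, self.intercept_, self.gamma_, self.mu2_ = map(float, sol.x)
        if self.mu2_ < 0:
            warnings.warn("negative second cumulant clipped to 0 for PDI", stacklevel=2)
        self.pdi_ = max(self.mu2_, 0.0) / self.gamma_**2
        q = scattering_vector(corr.optics)
        self.diffusion_ = self.gamma_ / q**2
        self.rh_ = stokes_einstein_radius(
            self.diffusion_, corr.environment.temperature, corr.environment.viscosity
        )
        return self

    def predict(self, tau):
        check_is_fitted(self, "gamma_")
        tau = np.asarray(tau, dtype=float)
        return self.baseline_ + self.intercept_ * np.exp(-2 * self.gamma_ * tau) * (
            1 + 0.5 * self.mu2_ * tau**2
        ) ** 2

    def result_(self) -> CumulantResult:
        check_is_fitted(self, "gamma_")
        return CumulantResult(
            baseline=self.baseline_,
            intercept=self.intercept_,
            gamma=self.gamma_,
            mu2=self.mu2_,
            pdi=self.pdi_,
            diffusion=self.diffusion_,
            rh=self.rh_,
            converged=self.converged_,
        )


def fit_cumulants(corr: Correlogram, order: int = 2) -> CumulantResult:
    """Cumulant analysis of a correlogram (see :class:`CumulantFit`)."""
    return CumulantFit(order=order).fit(corr).result_()


# ---------------------------------------------------------------------------
# size-distribution inversion


@dataclass
class SizeDistribution:
    """Weights over a log-spaced grid of hydrodynamic radii (nm)."""

    rh_grid: np.ndarray  # nm
    weights: np.ndarray  # non-negative, sum 1
    weighting: str = "intensity"  # intensity | mass | number

    def __post_init__(self) -> None:
        self.rh_grid = np.asarray(self.rh_grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.rh_grid.size != self.weights.size:
            raise ValueError("grid and weights must have equal length")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        if self.weighting not in ("intensity", "mass", "number"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        total = self.weights.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    def mean_rh(self) -> float:
        return float(np.dot(self.rh_grid, self.weights))


class SizeDistributionInverter(BaseEstimator):
    """Regularized non-negative inversion of g2 onto a radius grid.

    Solves  min_{w >= 0} ||g2_model(w) - g2||^2 + alpha^2 ||L w||^2  with
    g2_model = B + beta*(sum_i w_i exp(-Gamma_i tau))^2, Gamma_i = q^2 D(rh_i)
    and L the second-difference operator with zero (Dirichlet) boundary
    conditions, which also damps spurious weight at the grid edges.  B and
    beta are refined by alternating linear fits against the current g1
    model.  The problem is solved on a normalized scale (g1 in [0, 1],
    weights summing to 1), so ``alpha`` is dimensionless and the default
    transfers across instruments.
    """

    def __init__(
        self,
        grid_min_nm: float = 0.1,
        grid_max_nm: float = 1000.0,
        n_grid: int = 100,
        alpha: float = 0.05,
        n_outer: int = 8,
    ):
        self.grid_min_nm = grid_min_nm
        self.grid_max_nm = grid_max_nm
        self.n_grid = n_grid
        self.alpha = alpha
        self.n_outer = n_outer

    def fit(self, X, y=None):
        corr: Correlogram = X
        tau, g2 = corr.tau, corr.g2
        q = scattering_vector(corr.optics)
        rh = np.geomspace(self.grid_min_nm, self.grid_max_nm, self.n_grid)  # nm
        gammas = q**2 * np.array(
            [
                stokes_einstein_diffusion(
                    r * 1e-9, corr.environment.temperature, corr.environment.viscosity
                )
                for r in rh
            ]
        )
        A = np.exp(-np.outer(tau, gammas))  # decay kernel
        # second-difference smoothness operator, zero outside the grid
        L = np.zeros((self.n_grid, self.n_grid))
        for i in range(self.n_grid):
            L[i, i] = -2.0
            if i > 0:
                L[i, i - 1] = 1.0
            if i < self.n_grid - 1:
                L[i, i + 1] = 1.0
        alpha_eff = float(self.alpha)

        b = float(g2[-max(3, tau.size // 10):].mean())
        beta = max(float(g2[0] - b), 1e-6)
        w = np.full(self.n_grid, 1.0 / self.n_grid)
        for _ in range(self.n_outer):
            g1_data = np.sqrt(np.clip((g2 - b) / beta, 0.0, None))
            stacked_A = np.vstack([A, alpha_eff * L])
            stacked_b = np.concatenate([g1_data, np.zeros(L.shape[0])])
            w, _ = nnls(stacked_A, stacked_b)
            total = w.sum()
            if total <= 0:
                break
            w = w / total
            g1_model = A @ w
            # refine Siegert parameters: g2 ~ b + beta * g1_model^2 (linear)
            X_lin = np.column_stack([np.ones_like(tau), g1_model**2])
            coef, *_ = np.linalg.lstsq(X_lin, g2, rcond=None)
            b, beta = float(coef[0]), float(max(coef[1], 1e-6))
        self.no_decay_ = bool(w.sum() <= 0)
        if self.no_decay_:
            warnings.warn("no decay detected: all-zero solution", stacklevel=2)
            w = np.zeros(self.n_grid)
        self.rh_grid_ = rh
        self.weights_ = w
        self.baseline_ = b
        self.intercept_ = beta
        self.model_g2_ = b + beta * (A @ w) ** 2
        resid = self.model_g2_ - g2
        dof = max(tau.size - 3, 1)
        self.residual_rms_ = float(np.sqrt(np.sum(resid**2) / dof))
        return self

    def result_(self) -> SizeDistribution:
        check_is_fitted(self, "weights_")
        return SizeDistribution(
            rh_grid=self.rh_grid_.copy(), weights=self.weights_.copy(),
            weighting="intensity",
        )


def fit_size_distribution(
    corr: Correlogram,
    grid: tuple[float, float, int] = (0.1, 1000.0, 100),
    alpha: float = 0.05,
) -> SizeDistribution:
    """Smooth intensity-weighted distribution of hydrodynamic radii."""
    inv = SizeDistributionInverter(
        grid_min_nm=grid[0], grid_max_nm=grid[1], n_grid=int(grid[2]), alpha=alpha
    ).fit(corr)
    return inv.result_()


_WEIGHT_EXPONENT = {"intensity": 0, "mass": 3, "number": 6}


def reweight_distribution(dist: SizeDistribution, target: str) -> SizeDistribution:
    """Convert between intensity-, mass- and number-weighted distributions.

    Compact-sphere Rayleigh convention: scattered intensity is
    proportional to mass * R^3 and mass to number * R^3, so
    mass_w ~ intensity_w / R^3 and number_w ~ intensity_w / R^6.
    """
    if target not in _WEIGHT_EXPONENT:
        raise ValueError(f"unknown weighting {target!r}")
    power = _WEIGHT_EXPONENT[target] - _WEIGHT_EXPONENT[dist.weighting]
    if power == 0:
        return replace(dist)
    w = dist.weights / dist.rh_grid**power
    total = w.sum()
    if total > 0:
        w = w / total
    return SizeDistribution(rh_grid=dist.rh_grid.copy(), weights=w, weighting=target)


@dataclass
class DLSPeak:
    index_range: tuple[int, int]  # half-open [i0, i1) into the grid
    rh_mean: float  # weight-averaged radius, nm
    percent: float  # % of the current weighting


def extract_peaks(dist: SizeDistribution, min_percent: float = 1.0) -> list[DLSPeak]:
    """Contiguous weight regions split at interior local minima.

    Each region reports its weight-averaged radius and its percent of the
    total weighting; regions below ``min_percent`` are dropped.  Peaks
    are returned sorted by radius.
    """
    w = dist.weights
    if w.sum() <= 0:
        return []
    # contiguous runs of positive support ...
    runs: list[tuple[int, int]] = []
    i = 0
    while i < w.size:
        if w[i] > 0:
            j = i
            while j < w.size and w[j] > 0:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # ... each split further at interior local minima
    segments: list[tuple[int, int]] = []
    for r0, r1 in runs:
        start = r0
        for i in range(r0 + 1, r1 - 1):
            if w[i] < w[i - 1] and w[i] <= w[i + 1]:
                segments.append((start, i))
                start = i
        segments.append((start, r1))
    peaks: list[DLSPeak] = []
    for b0, b1 in segments:
        seg = slice(b0, b1)
        total = w[seg].sum()
        percent = 100.0 * total / w.sum()
        if total <= 0 or percent < min_percent:
            continue
        rh_mean = float(np.dot(dist.rh_grid[seg], w[seg]) / total)
        peaks.append(DLSPeak(index_range=(b0, b1), rh_mean=rh_mean,
                             percent=float(percent)))
    peaks.sort(key=lambda p: p.rh_mean)
    return peaks


# ---------------------------------------------------------------------------
# empirical radius <-> mass power law


# (Rh nm, mass kDa) pairs for detergent/amphipol-solubilized species used
# to anchor the default empirical power law
REFERENCE_RADIUS_MASS_PAIRS: tuple[tuple[float, float], ...] = (
    (11.0, 921.0),  # DDM
    (5.0, 147.6),  # LMNG, small species
    (21.5, 4394.2),  # LMNG, large species
    (0.9, 2.8),  # A8-35, small species
    (9.7, 683.1),  # A8-35, large species
)


class RadiusMassModel(BaseEstimator):
    """Empirical power law Rh = c * M^b between hydrodynamic radius and mass.

    Fitted as ordinary least squares of log10(M) on log10(Rh); stored as
    prefactor ``c`` (nm per kDa^b) and exponent ``b`` so that
    M = (Rh/c)^(1/b).  For globular proteins b is ~1/3; detergent-bound
    membrane-protein species run shallower.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        """X: radii (nm); y: masses (kDa)."""
        rh = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if rh.size != m.size:
            raise ValueError("radius and mass arrays must have equal length")
        if rh.size < 2:
            raise ValueError("need at least 2 (radius, mass) pairs")
        if np.any(rh <= 0) or np.any(m <= 0):
            raise ValueError("radii and masses must be positive")
        slope, inter = np.polyfit(np.log10(rh), np.log10(m), 1)
        self.exponent_ = float(1.0 / slope)  # b
        self.prefactor_ = float(10 ** (-inter * self.exponent_))  # c
        if not 0 < self.exponent_ < 1:
            warnings.warn(
                f"fitted exponent b={self.exponent_:.3f} outside (0,1): "
                "pairs may not follow a compact-particle scaling",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        """Mass (kDa) from radius (nm)."""
        check_is_fitted(self, "exponent_")
        rh = np.asarray(X, dtype=float)
        return (rh / self.prefactor_) ** (1.0 / self.exponent_)

    def predict_radius(self, masses):
        """Radius (nm) from mass (kDa)."""
        check_is_fitted(self, "exponent_")
        m = np.asarray(masses, dtype=float)
        return self.prefactor_ * m**self.exponent_


def radius_mass_model_fit(pairs) -> RadiusMassModel:
    """Fit the power law to (Rh nm, M kDa) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    return RadiusMassModel().fit(arr[:, 0], arr[:, 1])


def default_radius_mass_model() -> RadiusMassModel:
    """Built-in model fitted to the five anchor pairs."""
    return radius_mass_model_fit(REFERENCE_RADIUS_MASS_PAIRS)


def radius_mass_convert(
    value: float, direction: str, model: RadiusMassModel | None = None
) -> float:
    """Convert radius (nm) to mass (kDa) or back; direction 'to_mass'|'to_radius'."""
    if model is None:
        model = default_radius_mass_model()
    if direction == "to_mass":
        return float(model.predict([value])[0])
    if direction == "to_radius":
        return float(model.predict_radius([value])[0])
    raise ValueError("direction must be 'to_mass' or 'to_radius'")


# ---------------------------------------------------------------------------
# aggregate detection


@dataclass
class AggregationFlag:
    flagged: bool
    message: str
    percent_above_cutoff: float | None = None


def detect_aggregation(
    data: Correlogram | SizeDistribution,
    cutoff_radius: float = 100.0,
    max_percent: float = 5.0,
    ssr_improvement: float = 0.20,
) -> AggregationFlag:
    """Flag large aggregates.

    Distribution route: flag when the intensity-weighted percent above
    ``cutoff_radius`` (nm) exceeds ``max_percent``.  Correlogram route:
    a correlogram is inverted first; additionally a two-exponential fit
    is compared against the single cumulant fit — a secondary slow decay
    mapping above the cutoff that reduces the residual sum of squares by
    at least ``ssr_improvement`` also flags the sample (the classic
    "bump towards higher correlation times").
    """
    if isinstance(data, SizeDistribution):
        dist = data if data.weighting == "intensity" else reweight_distribution(data, "intensity")
        pct = 100.0 * dist.weights[dist.rh_grid > cutoff_radius].sum()
        flagged = pct > max_percent
        msg = (
            f"{pct:.1f}% of scattered intensity above {cutoff_radius:.0f} nm"
            + (" — large aggregates present" if flagged else "")
        )
        return AggregationFlag(flagged=flagged, message=msg, percent_above_cutoff=pct)

    corr: Correlogram = data
    dist = fit_size_distribution(corr)
    dist_flag = detect_aggregation(dist, cutoff_radius, max_percent)
    if dist_flag.flagged:
        return dist_flag
    # correlogram route: does a slow second decay materially improve the fit?
    single = CumulantFit().fit(corr)
    ssr1 = float(np.sum((single.predict(corr.tau) - corr.g2) ** 2))
    q = scattering_vector(corr.optics)
    gamma_cut = q**2 * stokes_einstein_diffusion(
        cutoff_radius * 1e-9, corr.environment.temperature, corr.environment.viscosity
    )

    def resid(p):
        b, beta, g1r, gslow, frac = p
        g1 = (1 - frac) * np.exp(-g1r * corr.tau) + frac * np.exp(-gslow * corr.tau)
        return b + beta * g1**2 - corr.g2

    sol = least_squares(
        resid,
        x0=[single.baseline_, single.intercept_, single.gamma_, gamma_cut / 10, 0.05],
        bounds=([-np.inf, 1e-12, 1e-12, 1e-12, 0.0], [np.inf, np.inf, np.inf, gamma_cut, 1.0]),
        method="trf",
    )
    ssr2 = float(np.sum(sol.fun**2))
    frac_slow = float(sol.x[4])
    improved = ssr1 > 0 and (ssr1 - ssr2) / ssr1 >= ssr_improvement
    flagged = bool(improved and frac_slow * 100.0 > max_percent)
    msg = (
        f"secondary slow decay ({frac_slow*100:.1f}% intensity) improves fit by "
        f"{100*(ssr1-ssr2)/ssr1 if ssr1>0 else 0:.0f}%"
        if flagged
        else dist_flag.message
    )
    return AggregationFlag(
        flagged=flagged, message=msg,
        percent_above_cutoff=dist_flag.percent_above_cutoff,
    )
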