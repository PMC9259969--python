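"""Mass-photometry analysis.

Mass photometry records the interferometric contrast of single
macromolecules landing on a coverslip; contrast is linearly related to
molecular mass.  This module covers the full analysis chain: contrast→mass
calibration against a protein standard, histogramming of landing events,
peak detection, fitting of a left-truncated multi-Gaussian mixture (the
instrument detects no events below a mass cutoff, ~30 kDa), oligomeric
state assignment, and acquisition quality checks.

The two regression-shaped steps are exposed as scikit-learn style
estimators (:class:`MassCalibration`, :class:`TruncatedGaussianMixture`);
the module-level functions are thin wrappers that operate on the domain
dataclasses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks as signal_find_peaks
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MPEventSet",
    "MassHistogram",
    "CalibrationStandard",
    "CalibrationModel",
    "MassCalibration",
    "TruncatedGaussianComponent",
    "MPFitResult",
    "TruncatedGaussianMixture",
    "StoichiometryAssignment",
    "EventCountQC",
    "fit_calibration",
    "apply_calibration",
    "build_histogram",
    "detect_peaks",
    "fit_truncated_mixture",
    "assign_stoichiometry",
    "qc_event_count",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MPEventSet:
    """Single-particle landing (and unbinding) events.

    ``values`` are per-event magnitudes: kDa when ``kind == "mass"``,
    dimensionless ratiometric contrast when ``kind == "contrast"``.
    Negative values are unbinding events (particle leaving the surface).
    """

    values: np.ndarray
    kind: str  # "mass" | "contrast"
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("event values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event values must be finite")
        if self.kind not in ("mass", "contrast"):
            raise ValueError(f"kind must be 'mass' or 'contrast', got {self.kind!r}")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class MassHistogram:
    """Uniform-bin histogram of event masses over a half-open window [lo, hi)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    window: tuple[float, float]
    bin_width: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        # last bin may be clipped to hi; all others must match bin_width
        if len(widths) > 1 and not np.allclose(widths[:-1], self.bin_width, rtol=1e-9):
            raise ValueError("non-uniform bin widths")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_events(self) -> int:
        return int(self.counts.sum())


@dataclass
class CalibrationStandard:
    """One species of a calibration standard (e.g. NativeMark NM1, 66 kDa)."""

    label: str
    known_mass: float  # kDa
    mean_contrast: float  # dimensionless

    def __post_init__(self) -> None:
        if not self.known_mass > 0:
            raise ValueError("known_mass must be positive")
        if not np.isfinite(self.mean_contrast) or self.mean_contrast == 0:
            raise ValueError("mean_contrast must be finite and nonzero")


@dataclass
class CalibrationModel:
    """Linear contrast→mass map: mass = slope * contrast + intercept."""

    slope: float  # kDa per contrast unit
    intercept: float  # kDa
    standards: list[CalibrationStandard] = field(default_factory=list)
    predicted_masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    rel_errors_percent: np.ndarray = field(default_factory=lambda: np.empty(0))
    max_rel_error: float = 0.0
    is_valid: bool = True

    def predict(self, contrasts) -> np.ndarray:
        return self.slope * np.asarray(contrasts, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# calibration


class MassCalibration(BaseEstimator, RegressorMixin):
    """Ordinary least-squares contrast→mass calibration line.

    Parameters
    ----------
    force_origin : bool
        Fix the intercept to zero (line through the origin).  Default is a
        free intercept.
    validity_bound : float
        Maximum tolerated per-standard relative error in percent; the
        fitted model is flagged invalid above it.  The conventional
        acceptance bound for a three-point standard run is 5 %.
    """

    def __init__(self, force_origin: bool = False, validity_bound: float = 5.0):
        self.force_origin = force_origin
        self.validity_bound = validity_bound

    def fit(self, X, y):
        """Fit mass = a*contrast + b.  X: contrasts (n,) or (n,1); y: kDa."""
        c = np.asarray(X, dtype=float).reshape(-1)
        m = np.asarray(y, dtype=float).reshape(-1)
        if c.size != m.size:
            raise ValueError("contrasts and masses must have equal length")
        if c.size < 2:
            raise ValueError("need at least 2 calibration standards")
        if np.ptp(c) == 0:
            raise ValueError("identical contrasts: calibration line is singular")
        if self.force_origin:
            self.slope_ = float(np.dot(c, m) / np.dot(c, c))
            self.intercept_ = 0.0
        else:
            self.slope_, self.intercept_ = (float(v) for v in np.polyfit(c, m, 1))
        pred = self.slope_ * c + self.intercept_
        self.predicted_masses_ = pred
        self.rel_errors_percent_ = 100.0 * np.abs(pred - m) / m
        self.max_rel_error_ = float(self.rel_errors_percent_.max())
        self.is_valid_ = bool(self.max_rel_error_ < self.validity_bound)
        if not self.is_valid_:
            warnings.warn(
                f"calibration max relative error {self.max_rel_error_:.2f}% "
                f">= {self.validity_bound}% bound",
                stacklevel=2,
            )
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.slope_ * np.asarray(X, dtype=float) + self.intercept_


def fit_calibration(
    standards: Sequence[CalibrationStandard], force_origin: bool = False
) -> CalibrationModel:
    """Fit the calibration line through a set of standards."""
    standards = list(standards)
    est = MassCalibration(force_origin=force_origin).fit(
        [s.mean_contrast for s in standards], [s.known_mass for s in standards]
    )
    return CalibrationModel(
        slope=est.slope_,
        intercept=est.intercept_,
        standards=standards,
        predicted_masses=est.predicted_masses_,
        rel_errors_percent=est.rel_errors_percent_,
        max_rel_error=est.max_rel_error_,
        is_valid=est.is_valid_,
    )


def apply_calibration(events: MPEventSet, model: CalibrationModel) -> MPEventSet:
    """Map contrast events to masses.  Refuses mass-kind input (no silent
    double calibration)."""
    if events.kind != "contrast":
        raise ValueError(
            "events are already in mass units; refusing to calibrate twice"
        )
    if not (np.isfinite(model.slope) and np.isfinite(model.intercept)):
        raise ValueError("calibration model is not finite")
    return MPEventSet(
        values=model.predict(events.values),
        kind="mass",
        source=events.source,
        meta={**events.meta, "calibration": (model.slope, model.intercept)},
    )


# ---------------------------------------------------------------------------
# histogram + peak detection


def build_histogram(
    events: MPEventSet,
    bin_width: float = 10.0,
    window: tuple[float, float] = (0.0, 2000.0),
) -> MassHistogram:
    """Histogram mass events on a uniform grid over [lo, hi).

    Events outside the window (including negative unbinding events when
    lo >= 0) are excluded and counted in ``n_excluded``.
    """
    if events.kind != "mass":
        raise ValueError("histogram requires mass-kind events (calibrate first)")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("empty window: hi must exceed lo")
    n_bins = int(np.ceil((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = min(edges[-1], hi)  # clip the last bin to the window
    v = events.values
    in_window = (v >= lo) & (v < hi)
    counts, _ = np.histogram(v[in_window], bins=edges)
    n_excluded = int(v.size - in_window.sum())
    if in_window.sum() == 0:
        warnings.warn("0 events in window", stacklevel=2)
    return MassHistogram(
        bin_edges=edges,
        counts=counts.astype(int),
        window=(lo, hi),
        bin_width=bin_width,
        n_excluded=n_excluded,
    )


def detect_peaks(
    hist: MassHistogram,
    min_count: float = 5.0,
    min_separation: float | None = None,
    smooth_window: int = 5,
    sigma_floor: float = 15.0,
    sigma_rel: float = 0.08,
) -> list[tuple[float, float, float]]:
    """Initial mixture guesses (mu0, sigma0, n0) from smoothed local maxima.

    The histogram counts are smoothed with a centered moving average of
    ``smooth_window`` bins; local maxima above ``min_count`` and separated
    by at least ``min_separation`` kDa (default 4 bin widths) become
    starting guesses.  sigma0 = max(sigma_floor, sigma_rel * mu0); n0 is
    the summed count within +-2 sigma0 of the peak.  Guesses are starting
    points only — the mixture fit refines all of them.
    """
    counts = hist.counts.astype(float)
    if counts.size == 0 or counts.sum() == 0:
        return []
    if min_separation is None:
        min_separation = 4.0 * hist.bin_width
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    # normalize by the kernel overlap so edge bins are not diluted
    smoothed = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts), kernel, mode="same"
    )
    if np.ptp(smoothed) <= 1e-9 * max(smoothed.max(), 1.0):
        return []  # flat histogram: no structure
    centers = hist.centers
    # plateau-aware local maxima; a flat histogram has none
    idx, _ = signal_find_peaks(smoothed, height=min_count, plateau_size=(1, None))
    candidates = list(idx)
    # enforce separation, keeping the taller peak
    candidates.sort(key=lambda i: -smoothed[i])
    kept: list[int] = []
    for i in candidates:
        if all(abs(centers[i] - centers[j]) >= min_separation for j in kept):
            kept.append(i)
    kept.sort()
    guesses = []
    for i in kept:
        mu0 = float(centers[i])
        sigma0 = max(sigma_floor, sigma_rel * mu0)
        sel = np.abs(centers - mu0) <= 2.0 * sigma0
        n0 = float(counts[sel].sum())
        guesses.append((mu0, sigma0, max(n0, 1.0)))
    return guesses


# ---------------------------------------------------------------------------
# truncated multi-Gaussian fit


@dataclass
class TruncatedGaussianComponent:
    """One left-truncated Gaussian population of the mass histogram."""

    mu: float  # kDa
    sigma: float  # kDa
    n_counts: float  # expected observable events of this component
    fraction: float = 0.0


@dataclass
class MPFitResult:
    """Result of the truncated multi-Gaussian histogram fit."""

    components: list[TruncatedGaussianComponent]
    truncation_limit: float
    histogram: MassHistogram
    residual_norm: float
    r_squared: float
    converged: bool
    model_counts: np.ndarray = field(default_factory=lambda: np.empty(0))


def _bin_expectations(
    params: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    t: float,
    renormalize: bool,
) -> np.ndarray:
    """Expected counts per bin for a truncated Gaussian mixture.

    Each component contributes N_k * [Phi((u-mu)/s) - Phi((l'-mu)/s)] with
    l' = max(l, t); bins entirely below the truncation limit get exactly
    zero.  With ``renormalize`` the component is renormalized on [t, inf)
    so N_k counts observable events.
    """
    k = params.size // 3
    mus, sigmas, ns = params[:k], params[k : 2 * k], params[2 * k :]
    expect = np.zeros_like(lower)
    observable = upper > t
    lo_eff = np.maximum(lower, t)
    for mu, sigma, n in zip(mus, sigmas, ns):
        cell = norm.cdf((upper - mu) / sigma) - norm.cdf((lo_eff - mu) / sigma)
        if renormalize:
            denom = norm.sf((t - mu) / sigma)
            cell = cell / max(denom, 1e-300)
        expect += n * np.where(observable, np.maximum(cell, 0.0), 0.0)
    return expect


class TruncatedGaussianMixture(BaseEstimator):
    """Least-squares fit of left-truncated Gaussians to histogram counts.

    Minimizes sum_i (counts_i - E_i)^2 over component means, widths and
    counts, where E_i integrates each truncated Gaussian over bin i (exact
    CDF integral, not density*width).  Bins entirely below the truncation
    limit have E_i = 0.

    Parameters
    ----------
    truncation_limit : float
        Detection cutoff t in kDa; the instrument records no events below
        it (typically ~30 kDa, instrument-dependent).
    renormalize : bool
        If True (default) each component is renormalized on [t, inf) so
        its fitted count N_k is the expected number of *observable*
        events; if False the model is simply zeroed below t.
    tol : float
        Convergence tolerance on the cost (ftol of the trust-region
        optimizer).
    """

    def __init__(
        self,
        truncation_limit: float = 30.0,
        renormalize: bool = True,
        tol: float = 1e-10,
        max_nfev: int | None = None,
    ):
        self.truncation_limit = truncation_limit
        self.renormalize = renormalize
        self.tol = tol
        self.max_nfev = max_nfev

    def fit(self, X, y=None, guesses=None):
        """Fit the mixture.  X is a :class:`MassHistogram` (y unused)."""
        hist: MassHistogram = X
        if guesses is None:
            guesses = detect_peaks(hist)
        if len(guesses) == 0:
            raise ValueError("no initial guesses: provide at least one component")
        t = float(self.truncation_limit)
        lower, upper = hist.bin_edges[:-1], hist.bin_edges[1:]
        counts = hist.counts.astype(float)

        mus0 = np.array([g[0] for g in guesses], dtype=float)
        sig0 = np.array([g[1] for g in guesses], dtype=float)
        n0 = np.array([max(g[2], 1.0) for g in guesses], dtype=float)
        x0 = np.concatenate([mus0, sig0, n0])
        k = len(guesses)
        lo_b = np.concatenate(
            [np.full(k, -np.inf), np.full(k, 1e-6), np.zeros(k)]
        )
        hi_b = np.full(3 * k, np.inf)

        def residuals(p):
            return _bin_expectations(p, lower, upper, t, self.renormalize) - counts

        sol = least_squares(
            residuals,
            x0,
            bounds=(lo_b, hi_b),
            method="trf",
            ftol=self.tol,
            xtol=self.tol,
            gtol=self.tol,
            max_nfev=self.max_nfev,
        )
        p = sol.x
        order = np.argsort(p[:k])
        self.means_ = p[:k][order]
        self.sigmas_ = p[k : 2 * k][order]
        self.counts_ = p[2 * k :][order]
        self.converged_ = bool(sol.success)
        if not self.converged_:
            warnings.warn("truncated-mixture fit did not converge", stacklevel=2)
        if np.any(np.isclose(self.sigmas_, 1e-6)):
            warnings.warn("a component width hit its lower bound", stacklevel=2)
        self._merge_degenerate(hist.bin_width)
        model = _bin_expectations(
            np.concatenate([self.means_, self.sigmas_, self.counts_]),
            lower,
            upper,
            t,
            self.renormalize,
        )
        self.model_counts_ = model
        self.residual_norm_ = float(np.sum((model - counts) ** 2))
        ss_tot = float(np.sum((counts - counts.mean()) ** 2))
        self.r_squared_ = 1.0 - self.residual_norm_ / ss_tot if ss_tot > 0 else 1.0
        total = self.counts_.sum()
        self.fractions_ = self.counts_ / total if total > 0 else self.counts_
        self._histogram = hist
        return self

    def _merge_degenerate(self, bin_width: float) -> None:
        # two components collapsing onto the same mean carry no separate
        # information: merge them (count-weighted) and warn
        while True:
            d = np.diff(self.means_)
            close = np.where(d < bin_width)[0]
            if close.size == 0:
                return
            i = int(close[0])
            w = self.counts_[i : i + 2]
            wsum = w.sum() if w.sum() > 0 else 1.0
            mu = float(np.dot(w, self.means_[i : i + 2]) / wsum)
            sig = float(np.dot(w, self.sigmas_[i : i + 2]) / wsum)
            warnings.warn(
                f"merged two components converging to the same mean (~{mu:.1f} kDa)",
                stacklevel=3,
            )
            self.means_ = np.delete(self.means_, i + 1)
            self.sigmas_ = np.delete(self.sigmas_, i + 1)
            self.counts_ = np.delete(self.counts_, i + 1)
            self.means_[i], self.sigmas_[i], self.counts_[i] = mu, sig, w.sum()

    def predict(self, X):
        """Expected counts per bin of histogram X under the fitted model."""
        check_is_fitted(self, "means_")
        hist: MassHistogram = X
        return _bin_expectations(
            np.concatenate([self.means_, self.sigmas_, self.counts_]),
            hist.bin_edges[:-1],
            hist.bin_edges[1:],
            float(self.truncation_limit),
            self.renormalize,
        )

    def result_(self) -> MPFitResult:
        check_is_fitted(self, "means_")
        comps = [
            TruncatedGaussianComponent(mu=m, sigma=s, n_counts=n, fraction=f)
            for m, s, n, f in zip(
                self.means_, self.sigmas_, self.counts_, self.fractions_
            )
        ]
        return MPFitResult(
            components=comps,
            truncation_limit=float(self.truncation_limit),
            histogram=self._histogram,
            residual_norm=self.residual_norm_,
            r_squared=self.r_squared_,
            converged=self.converged_,
            model_counts=self.model_counts_,
        )


def fit_truncated_mixture(
    hist: MassHistogram,
    guesses: Sequence[tuple[float, float, float]] | None = None,
    truncation_limit: float = 30.0,
    renormalize: bool = True,
) -> MPFitResult:
    """Fit a left-truncated Gaussian mixture to a mass histogram."""
    est = TruncatedGaussianMixture(
        truncation_limit=truncation_limit, renormalize=renormalize
    )
    est.fit(hist, guesses=list(guesses) if guesses is not None else None)
    return est.result_()


# ---------------------------------------------------------------------------
# stoichiometry + QC


@dataclass
class StoichiometryAssignment:
    n: int
    rel_deviation: float
    accepted: bool


def assign_stoichiometry(
    peak_mass: float, monomer_mass: float, tolerance: float = 0.10
) -> StoichiometryAssignment:
    """Nearest oligomeric state of a fitted peak given the monomer mass.

    n = round(peak/monomer), at least 1; the relative deviation is taken
    against the ideal n-mer mass and accepted when within ``tolerance``.
    """
    if peak_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    n = max(1, int(round(peak_mass / monomer_mass)))
    ideal = n * monomer_mass
    rel = abs(peak_mass - ideal) / ideal
    return StoichiometryAssignment(n=n, rel_deviation=rel, accepted=rel <= tolerance)


@dataclass
class EventCountQC:
    n_events: int
    too_many: bool
    too_few: bool
    n_binding: int
    n_unbinding: int
    binding_unbinding_ratio: float
    messages: list[str] = field(default_factory=list)


def export_fit_tables(result: MPFitResult, components_path, curve_path=None) -> None:
    """Write the component table and optionally the histogram + fit curve
    as CSV (component masses in kDa, fractions as % of total)."""
    import pandas as pd

    rows = [
        {
            "mu_kDa": c.mu,
            "sigma_kDa": c.sigma,
            "counts": c.n_counts,
            "fraction": c.fraction,
            "percent_of_total": 100.0 * c.fraction,
        }
        for c in result.components
    ]
    pd.DataFrame(rows).to_csv(components_path, index=False)
    if curve_path is not None:
        hist = result.histogram
        pd.DataFrame(
            {
                "bin_center_kDa": hist.centers,
                "counts": hist.counts,
                "model_counts": result.model_counts,
            }
        ).to_csv(curve_path, index=False)


def plot_fit(result: MPFitResult, path) -> None:
    """Render histogram bars with the fitted mixture overlay (PNG/SVG by
    file extension; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist = result.histogram
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist.centers, hist.counts, width=hist.bin_width, alpha=0.5,
           color="steelblue", label="events")
    ax.plot(hist.centers, result.model_counts, color="crimson", lw=1.5,
            label="truncated-Gaussian fit")
    for c in result.components:
        ax.axvline(c.mu, color="gray", ls=":", lw=0.8)
        ax.annotate(f"{c.mu:.0f} kDa\n{100*c.fraction:.0f}%",
                    (c.mu, float(np.max(hist.counts)) * 0.9), fontsize=8,
                    ha="center")
    ax.set_xlabel("mass (kDa)")
    ax.set_ylabel("counts")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


_FOV_MAX_COUNTS = {"regular": 3000, "medium": 3000, "large": 3000}


def qc_event_count(
    events: MPEventSet,
    fov: str = "regular",
    min_counts: int = 100,
    max_counts: int | None = None,
) -> EventCountQC:
    """Acquisition sanity checks on the raw event list.

    The recommended maximum count for a regular field of view is 3000
    events; below ``min_counts`` the histogram is too sparse to fit.
    Positive values are binding (landing) events, negative are unbinding.
    """
    if fov not in _FOV_MAX_COUNTS:
        raise ValueError(f"unknown field of view {fov!r}")
    limit = max_counts if max_counts is not None else _FOV_MAX_COUNTS[fov]
    n = events.n
    n_bind = int(np.sum(events.values > 0))
    n_unbind = int(np.sum(events.values < 0))
    ratio = n_bind / n_unbind if n_unbind > 0 else np.inf
    msgs = []
    too_many = n > limit
    too_few = n < min_counts
    if too_many:
        msgs.append(f"{n} events exceed the recommended maximum of {limit} ({fov} FOV)")
    if too_few:
        msgs.append(f"only {n} events (floor {min_counts}); acquire more")
    if n_unbind > n_bind:
        msgs.append("more unbinding than binding events: check buffer/surface")
    return EventCountQC(
        n_events=n,
        too_many=too_many,
        too_few=too_few,
        n_binding=n_bind,
        n_unbinding=n_unbind,
        binding_unbinding_ratio=ratio,
        messages=msgs,
    )
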