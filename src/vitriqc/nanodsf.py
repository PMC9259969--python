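"""nanoDSF thermal-stability analysis.

Label-free differential scanning fluorimetry follows the intrinsic
tryptophan/tyrosine fluorescence (F350/F330 ratio) of a protein during a
thermal ramp, typically 20-90 °C at 1 °C/min.  Unfolding shifts the
ratio; the melting temperature Tm is read off the extremum of the ratio
curve's first derivative.  Instruments with a backscattering channel also
report the aggregation onset — here the temperature where the scattering
signal first rises past a small fraction (default 1 %) of its transition
amplitude, interpreted as 1 % of the protein aggregated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "ThermalRamp",
    "RatioCurve",
    "Transition",
    "DSFResult",
    "compute_ratio",
    "find_transitions",
    "find_aggregation_onset",
    "analyze_ramp",
    "rank_conditions",
    "check_initial_fluorescence",
    "subtract_blank",
]

FLUORESCENCE_RANGE = (2000.0, 15000.0)  # recommended initial counts


@dataclass
class ThermalRamp:
    """Per-capillary fluorescence (and optional backscattering) vs temperature."""

    temperature: np.ndarray  # °C, strictly increasing
    f330: np.ndarray
    f350: np.ndarray
    scattering: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        if self.scattering is not None:
            self.scattering = np.asarray(self.scattering, dtype=float)
        n = self.temperature.size
        if n < 10:
            raise ValueError("thermal ramp needs at least 10 points")
        for arr, name in ((self.f330, "f330"), (self.f350, "f350")):
            if arr.size != n:
                raise ValueError(f"{name} length does not match temperature")
        if self.scattering is not None and self.scattering.size != n:
            raise ValueError("scattering length does not match temperature")
        if np.any(np.diff(self.temperature) <= 0):
            order = np.argsort(self.temperature, kind="stable")
            warnings.warn(
                "temperature grid not strictly increasing: rows sorted", stacklevel=2
            )
            self.temperature = self.temperature[order]
            self.f330 = self.f330[order]
            self.f350 = self.f350[order]
            if self.scattering is not None:
                self.scattering = self.scattering[order]
            if np.any(np.diff(self.temperature) <= 0):
                raise ValueError("duplicate temperatures in ramp")
        if np.any(self.f330 < 0) or np.any(self.f350 < 0):
            raise ValueError("fluorescence counts must be non-negative")


@dataclass
class RatioCurve:
    """F350/F330 vs temperature; points with zero F330 are masked out."""

    temperature: np.ndarray
    ratio: np.ndarray
    n_masked: int = 0


@dataclass
class Transition:
    tm: float  # °C
    prominence: float  # |dy/dT| prominence at the extremum
    sign: int  # +1 rising signal, -1 falling


@dataclass
class DSFResult:
    label: str
    transitions: list[Transition] = field(default_factory=list)
    t_onset_agg: float | None = None
    t_agg_mid: float | None = None
    initial_fluorescence_ok: bool = True
    ratio_curve: RatioCurve | None = None
    derivative: np.ndarray | None = None

    @property
    def tm_values(self) -> list[float]:
        return [t.tm for t in self.transitions]

    @property
    def dominant_tm(self) -> float | None:
        if not self.transitions:
            return None
        return max(self.transitions, key=lambda t: t.prominence).tm


def compute_ratio(ramp: ThermalRamp) -> RatioCurve:
    """Pointwise F350/F330; zero-F330 points are dropped and counted."""
    valid = ramp.f330 > 0
    if not valid.any():
        raise ValueError("all F330 values are zero: no ratio can be formed")
    n_masked = int((~valid).sum())
    if n_masked:
        warnings.warn(f"{n_masked} points with F330 = 0 masked", stacklevel=2)
    return RatioCurve(
        temperature=ramp.temperature[valid],
        ratio=ramp.f350[valid] / ramp.f330[valid],
        n_masked=n_masked,
    )


def _smooth(y: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    window = min(window, y.size if y.size % 2 == 1 else y.size - 1)
    if window <= polyorder:
        return y
    return savgol_filter(y, window, polyorder)


def find_transitions(
    temperature: np.ndarray,
    signal: np.ndarray,
    smooth_window: int = 11,
    polyorder: int = 3,
    min_prominence: float | None = None,
) -> list[Transition]:
    """Transition temperatures from first-derivative extrema.

    The signal is smoothed with a Savitzky-Golay filter, differentiated on
    the grid, and the extrema of dy/dT (both signs: ratio transitions can
    rise or fall; the classic convention of the derivative "minimum"
    corresponds to falling ratios) are reported with their prominence.
    Extremum positions are refined to the derivative-weighted centroid of
    the half-prominence region, so Tm is not quantized to the grid.

    ``min_prominence`` defaults to a quarter of the derivative's full
    range — a flat or purely linear curve therefore yields no transitions.
    """
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 points to locate transitions")
    ys = _smooth(y, smooth_window, polyorder)
    # second, wider smoothing pass on the derivative keeps grid-level
    # noise from fragmenting or displacing the extremum
    dy = _smooth(np.gradient(ys, t), 2 * smooth_window - 1, min(polyorder, 2))
    scale = float(np.abs(dy).max())
    if scale == 0:
        return []
    if min_prominence is None:
        min_prominence = max(0.25 * float(np.ptp(dy)), 1e-6 * scale)
    out: list[Transition] = []
    for sign, series in ((1, dy), (-1, -dy)):
        # extrema must also reach a quarter of the global derivative
        # magnitude: prominence alone is inflated on the opposite-sign
        # series by the true transition's dip
        idx, props = find_peaks(series, prominence=min_prominence, height=0.25 * scale)
        for i, prom in zip(idx, props["prominences"]):
            tm = _centroid_refine(t, series, int(i), float(prom))
            # transitions must lie strictly inside the ramp
            if t[0] < tm < t[-1]:
                out.append(Transition(tm=tm, prominence=float(prom), sign=sign))
    out.sort(key=lambda tr: tr.tm)
    return out


def _centroid_refine(t: np.ndarray, y: np.ndarray, i: int, prominence: float) -> float:
    """Weighted centroid of the half-prominence region around peak i.

    Averaging over the region is far more noise-stable than the argmax
    sample and is exact for any symmetric extremum."""
    floor = y[i] - 0.5 * prominence
    lo = i
    while lo > 0 and y[lo - 1] >= floor:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] >= floor:
        hi += 1
    seg = slice(lo, hi + 1)
    w = y[seg] - floor
    total = w.sum()
    if total <= 0:
        return float(t[i])
    return float(np.dot(t[seg], w) / total)


def find_aggregation_onset(
    temperature: np.ndarray,
    scattering: np.ndarray,
    fraction: float = 0.01,
    baseline_fraction: float = 0.10,
    noise_multiple: float = 5.0,
    smooth_window: int = 31,
    polyorder: int = 2,
) -> float | None:
    """Aggregation onset: first crossing of ``fraction`` of the rise.

    The baseline is the median of the first ``baseline_fraction`` of
    points, the plateau the maximum of the smoothed curve; the onset is
    the temperature where the smoothed, normalized signal first reaches
    ``fraction``, linearly interpolated between grid points.  Returns
    ``None`` when the total rise is below ``noise_multiple`` standard
    deviations of the baseline segment (no aggregation detected).  The
    normalization makes the result invariant under affine scaling of the
    signal.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(scattering, dtype=float)
    if t.size < 20:
        raise ValueError("need at least 20 points")
    n_base = max(3, int(np.ceil(baseline_fraction * t.size)))
    baseline = float(np.median(s[:n_base]))
    noise = float(np.std(s[:n_base]))
    ss = _smooth(s, smooth_window, polyorder)
    plateau = float(ss.max())
    rise = plateau - baseline
    if rise <= 0 or rise < noise_multiple * noise:
        return None
    norm = (ss - baseline) / rise
    above = np.nonzero(norm >= fraction)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(t[0])
    # linear interpolation between the straddling grid points
    f0, f1 = norm[i - 1], norm[i]
    w = (fraction - f0) / (f1 - f0) if f1 != f0 else 0.0
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


def analyze_ramp(
    ramp: ThermalRamp,
    min_prominence: float | None = None,
    onset_fraction: float = 0.01,
) -> DSFResult:
    """Full per-capillary analysis: ratio, Tm, aggregation onset/midpoint."""
    curve = compute_ratio(ramp)
    transitions = find_transitions(
        curve.temperature, curve.ratio, min_prominence=min_prominence
    )
    t_onset = t_mid = None
    if ramp.scattering is not None:
        t_onset = find_aggregation_onset(
            ramp.temperature, ramp.scattering, fraction=onset_fraction
        )
        scat_tr = find_transitions(ramp.temperature, ramp.scattering)
        if scat_tr:
            t_mid = max(scat_tr, key=lambda tr: tr.prominence).tm
        if t_onset is not None and t_mid is not None and t_onset > t_mid:
            t_mid = None  # midpoint estimate inconsistent with onset; drop it
    ys = _smooth(curve.ratio, 11, 3)
    return DSFResult(
        label=ramp.label,
        transitions=transitions,
        t_onset_agg=t_onset,
        t_agg_mid=t_mid,
        initial_fluorescence_ok=check_initial_fluorescence(ramp)[0],
        ratio_curve=curve,
        derivative=np.gradient(ys, curve.temperature),
    )


def rank_conditions(
    results: list[tuple[str, DSFResult]], reference_label: str
) -> list[dict]:
    """Rank buffer/detergent conditions by dominant Tm.

    Returns rows sorted by descending dominant (highest-prominence) Tm
    with the Tm difference against the reference condition; ties break
    alphabetically by label.
    """
    labels = [lab for lab, _ in results]
    if reference_label not in labels:
        raise ValueError(f"reference label {reference_label!r} not among results")
    for lab, res in results:
        if not res.transitions:
            raise ValueError(f"condition {lab!r} has no detected transition")
    ref_tm = dict(results)[reference_label].dominant_tm
    rows = [
        {
            "label": lab,
            "tm": res.dominant_tm,
            "delta_tm_vs_reference": res.dominant_tm - ref_tm,
            "t_onset_agg": res.t_onset_agg,
        }
        for lab, res in results
    ]
    rows.sort(key=lambda r: (-r["tm"], r["label"]))
    return rows


def check_initial_fluorescence(ramp: ThermalRamp) -> tuple[bool, str]:
    """Both channels' first-point counts must sit in the recommended
    [2000, 15000] window for a reliable ratio."""
    lo, hi = FLUORESCENCE_RANGE
    f0_330, f0_350 = float(ramp.f330[0]), float(ramp.f350[0])
    ok = lo <= f0_330 <= hi and lo <= f0_350 <= hi
    if ok:
        msg = f"initial fluorescence OK (F330={f0_330:.0f}, F350={f0_350:.0f})"
    else:
        msg = (
            f"initial fluorescence outside [{lo:.0f}, {hi:.0f}] "
            f"(F330={f0_330:.0f}, F350={f0_350:.0f}): adjust concentration"
        )
    return ok, msg


def subtract_blank(ramp: ThermalRamp, blank: ThermalRamp) -> ThermalRamp:
    """Per-temperature subtraction of a buffer-only control ramp."""
    if ramp.temperature.size != blank.temperature.size or not np.allclose(
        ramp.temperature, blank.temperature
    ):
        raise ValueError("sample and blank ramps must share the temperature grid")
    return ThermalRamp(
        temperature=ramp.temperature,
        f330=np.maximum(ramp.f330 - blank.f330, 0.0),
        f350=np.maximum(ramp.f350 - blank.f350, 0.0),
        scattering=None
        if ramp.scattering is None
        else ramp.scattering - (blank.scattering if blank.scattering is not None else 0),
        label=ramp.label,
    )
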