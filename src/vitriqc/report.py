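"""Go/no-go decision report combining the three techniques.

The pipeline runs nanoDSF first (buffer/detergent stability), then DLS
(polydispersity and aggregates), then mass photometry (oligomeric state
and sample integrity); electron microscopy only follows when none of the
three fails.  This module evaluates per-technique verdicts against
configurable thresholds and renders a machine- plus human-readable
report.  All numeric thresholds are this package's defaults, not
instrument constants — override them per project.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .dls import SizeDistribution, detect_aggregation, extract_peaks
from .nanodsf import DSFResult
from .photomol import MPFitResult

__all__ = [
    "QCThresholds",
    "TechniqueVerdict",
    "QCReport",
    "evaluate_decision_tree",
    "render_report",
]

RECOMMENDATIONS = (
    "optimize-buffer/detergent",
    "re-purify/reconstitute",
    "proceed-to-negative-stain",
    "proceed-to-cryoEM-grids",
)

TECHNIQUE_ORDER = ("dsf", "dls", "mp")  # pipeline order

_REMEDY = {
    "dsf": "optimize-buffer/detergent",
    "dls": "re-purify/reconstitute",
    "mp": "re-purify/reconstitute",
}


@dataclass
class QCThresholds:
    """Decision thresholds; every field is overridable."""

    min_tm: float = 45.0  # °C
    min_delta_tm: float = 0.0  # °C vs reference (0 = no improvement required)
    max_pdi: float = 0.3
    max_aggregate_percent: float = 5.0  # intensity above the cutoff radius
    aggregate_cutoff_radius: float = 100.0  # nm
    mass_tolerance: float = 0.10  # relative
    min_target_species_fraction: float = 0.50
    max_event_count: int = 3000
    min_event_count: int = 100

    def __post_init__(self) -> None:
        for name in ("mass_tolerance", "min_target_species_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class TechniqueVerdict:
    technique: str
    verdict: str  # pass | warn | fail
    evidence: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    verdicts: list[TechniqueVerdict]
    recommendation: str
    thresholds: QCThresholds
    provenance: dict = field(default_factory=dict)

    def verdict_for(self, technique: str) -> TechniqueVerdict | None:
        return next((v for v in self.verdicts if v.technique == technique), None)


def _dsf_verdict(result: DSFResult, th: QCThresholds) -> TechniqueVerdict:
    ev: list[str] = []
    verdict = "pass"
    tm = result.dominant_tm
    if tm is None:
        return TechniqueVerdict("dsf", "fail", ["no thermal transition detected"])
    ev.append(f"dominant Tm = {tm:.1f} °C (threshold {th.min_tm:.1f} °C)")
    if tm < th.min_tm:
        verdict = "fail"
        ev.append("melting temperature below threshold: protein marginally stable")
    if result.t_onset_agg is not None:
        ev.append(f"aggregation onset = {result.t_onset_agg:.1f} °C")
        if result.t_onset_agg < th.min_tm:
            verdict = "warn" if verdict == "pass" else verdict
            ev.append("aggregation sets in below the Tm threshold")
    if not result.initial_fluorescence_ok:
        verdict = "warn" if verdict == "pass" else verdict
        ev.append("initial fluorescence outside the recommended window")
    return TechniqueVerdict("dsf", verdict, ev)


def _dls_verdict(
    dist: SizeDistribution, pdi: float | None, th: QCThresholds
) -> TechniqueVerdict:
    ev: list[str] = []
    verdict = "pass"
    agg = detect_aggregation(
        dist, cutoff_radius=th.aggregate_cutoff_radius,
        max_percent=th.max_aggregate_percent,
    )
    ev.append(agg.message)
    if agg.flagged:
        verdict = "fail"
    peaks = extract_peaks(dist)
    if len(peaks) > 1:
        dominant = max(p.percent for p in peaks)
        ev.append(
            f"{len(peaks)} size populations; dominant carries {dominant:.0f}% "
            "of the intensity"
        )
        if dominant < 80.0 and verdict == "pass":
            verdict = "warn"
    if pdi is not None:
        ev.append(f"PDI = {pdi:.3f} (max {th.max_pdi})")
        if pdi > th.max_pdi and verdict == "pass":
            verdict = "warn"
    return TechniqueVerdict("dls", verdict, ev)


def _mp_verdict(
    fit: MPFitResult, expected_mass: float | None, th: QCThresholds
) -> TechniqueVerdict:
    ev: list[str] = []
    verdict = "pass"
    if not fit.components:
        return TechniqueVerdict("mp", "fail", ["no mass population fitted"])
    if expected_mass is None:
        ev.append("no expected mass supplied; reporting populations only")
        for c in fit.components:
            ev.append(f"component at {c.mu:.0f} kDa ({100*c.fraction:.0f}%)")
        return TechniqueVerdict("mp", "pass", ev)
    # best-matching component: in-tolerance first; otherwise prefer the
    # smallest deviation among components *heavier* than expected, since a
    # protein-micelle complex always adds mass (a lighter near-miss is
    # more likely a bare micelle or a degradation product)
    def deviation(c):
        return (c.mu - expected_mass) / expected_mass

    within = [c for c in fit.components if abs(deviation(c)) <= th.mass_tolerance]
    heavier = [c for c in fit.components if deviation(c) > th.mass_tolerance]
    if within:
        best = min(within, key=lambda c: abs(deviation(c)))
    elif heavier:
        best = min(heavier, key=deviation)
    else:
        best = min(fit.components, key=lambda c: abs(deviation(c)))
    dev = deviation(best)
    ev.append(
        f"closest component at {best.mu:.0f} kDa vs expected {expected_mass:.0f} kDa "
        f"({100*abs(dev):.0f}% deviation, fraction {100*best.fraction:.0f}%)"
    )
    if abs(dev) <= th.mass_tolerance:
        if best.fraction < th.min_target_species_fraction:
            verdict = "warn"
            ev.append(
                f"target species fraction {100*best.fraction:.0f}% below "
                f"{100*th.min_target_species_fraction:.0f}%"
            )
    elif dev > 0:
        # heavier than expected: typical of a detergent-micelle-shifted
        # protein complex — downgrade to warn, not fail
        verdict = "warn"
        ev.append(
            "fitted mass exceeds the expected mass beyond tolerance; a bound "
            "detergent micelle can account for the extra mass"
        )
    else:
        verdict = "fail"
        ev.append("no component compatible with the expected mass (possible degradation)")
    return TechniqueVerdict("mp", verdict, ev)


def evaluate_decision_tree(
    dsf: DSFResult | None = None,
    dls: SizeDistribution | None = None,
    mp: MPFitResult | None = None,
    expected_mass: float | None = None,
    dls_pdi: float | None = None,
    thresholds: QCThresholds | None = None,
    negative_stain_ok: bool = False,
) -> QCReport:
    """Evaluate the per-technique verdicts and the overall recommendation.

    Precedence follows the pipeline order (nanoDSF, DLS, mass
    photometry): the first failing stage determines the remedy.  A
    proceed recommendation is only ever issued when no technique fails;
    ``negative_stain_ok`` upgrades it from negative stain to cryo-EM
    grid preparation when the caller has already screened stained grids.
    """
    if dsf is None and dls is None and mp is None:
        raise ValueError("at least one technique result is required")
    th = thresholds or QCThresholds()
    verdicts: list[TechniqueVerdict] = []
    if dsf is not None:
        verdicts.append(_dsf_verdict(dsf, th))
    if dls is not None:
        verdicts.append(_dls_verdict(dls, dls_pdi, th))
    if mp is not None:
        verdicts.append(_mp_verdict(mp, expected_mass, th))

    recommendation = (
        "proceed-to-cryoEM-grids" if negative_stain_ok else "proceed-to-negative-stain"
    )
    for tech in TECHNIQUE_ORDER:
        v = next((x for x in verdicts if x.technique == tech), None)
        if v is not None and v.verdict == "fail":
            recommendation = _REMEDY[tech]
            break

    config = json.dumps(asdict(th), sort_keys=True)
    provenance = {
        "tool": "vitriqc",
        "config_hash": hashlib.sha256(config.encode()).hexdigest()[:16],
        "techniques": [v.technique for v in verdicts],
    }
    return QCReport(
        verdicts=verdicts,
        recommendation=recommendation,
        thresholds=th,
        provenance=provenance,
    )


def render_report(report: QCReport, format: str = "json") -> str:
    """Serialize a report as canonical JSON or human-readable markdown."""
    if format == "json":
        payload = {
            "verdicts": [asdict(v) for v in report.verdicts],
            "recommendation": report.recommendation,
            "thresholds": asdict(report.thresholds),
            "provenance": report.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "markdown":
        lines = ["# Sample quality-control report", ""]
        for tech in TECHNIQUE_ORDER:
            v = report.verdict_for(tech)
            if v is None:
                continue  # omit absent techniques entirely
            title = {"dsf": "nanoDSF", "dls": "DLS", "mp": "Mass photometry"}[tech]
            lines.append(f"## {title}: {v.verdict.upper()}")
            lines.extend(f"- {e}" for e in v.evidence)
            lines.append("")
        lines.append(f"**Recommendation:** {report.recommendation}")
        lines.append("")
        lines.append(f"_config {report.provenance.get('config_hash', '')}_")
        return "\n".join(lines)
    raise ValueError("format must be 'json' or 'markdown'")
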