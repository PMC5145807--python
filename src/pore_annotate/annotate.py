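"""Functional-state annotation: conductive versus non-conductive.

Combines pore geometry (candidate gates from the radius profile) with
hydration evidence (water free-energy barriers, dewetted fraction, flux)
into a per-gate and overall verdict.  A gate is called CLOSED when the water
barrier reaches the closed threshold (default 10 kJ/mol ≈ 4 kT at 310 K, a
calibration sitting between barriers observed for non-conductive pores,
9–25 kJ/mol, and conductive ones, ≲4 kJ/mol) or when the gate dewets for
half the trajectory; OPEN requires all barriers at or below the open
threshold (default 5 kJ/mol ≈ 2 kT) with a continuously wetted pore.
Anything in between is INDETERMINATE.  The verdict deliberately does not
distinguish closed from desensitized/inactivated conformations — both are
non-conductive and look alike to this analysis.  Flux is reported as
evidence but never vetoes a barrier-based call.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .pore_profile import GateRegion, PoreProfile, min_radius

OPEN = "OPEN"
CLOSED = "CLOSED"
INDETERMINATE = "INDETERMINATE"

_SEVERITY = {OPEN: 0, INDETERMINATE: 1, CLOSED: 2}


@dataclass
class Thresholds:
    closed_barrier: float = 10.0  # kJ/mol; barrier at/above this → CLOSED
    open_barrier: float = 5.0  # kJ/mol; all barriers at/below this → OPEN
    dewetted_fraction: float = 0.5  # gate empty this often → CLOSED
    gate_radius: float = 4.5  # Å; sub-threshold constriction = candidate gate


@dataclass
class GateEvidence:
    """Hydration evidence attached to one gate region."""

    water_barrier: float | None = None  # kJ/mol
    barrier_is_lower_bound: bool = False
    dewetted_fraction: float | None = None


@dataclass
class AnnotationReport:
    structure_id: str
    verdict: str
    gate_verdicts: list  # one label per gate
    gates: list  # GateRegion
    evidence: list  # GateEvidence, aligned with gates
    min_radius: float
    min_radius_z: float
    flux: float | None
    thresholds: Thresholds
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "verdict": self.verdict,
            "gate_verdicts": list(self.gate_verdicts),
            "gates": [asdict(g) for g in self.gates],
            "evidence": [asdict(e) for e in self.evidence],
            "min_radius_A": self.min_radius,
            "min_radius_z_A": self.min_radius_z,
            "flux_per_ns": self.flux,
            "thresholds": asdict(self.thresholds),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnnotationReport":
        return cls(
            structure_id=data["structure_id"],
            verdict=data["verdict"],
            gate_verdicts=list(data["gate_verdicts"]),
            gates=[GateRegion(**g) for g in data["gates"]],
            evidence=[GateEvidence(**e) for e in data["evidence"]],
            min_radius=data["min_radius_A"],
            min_radius_z=data["min_radius_z_A"],
            flux=data["flux_per_ns"],
            thresholds=Thresholds(**data["thresholds"]),
            provenance=dict(data["provenance"]),
        )


def _gate_label(ev: GateEvidence, thr: Thresholds) -> str:
    dewetted = ev.dewetted_fraction is not None and ev.dewetted_fraction >= thr.dewetted_fraction
    if ev.water_barrier is not None and ev.water_barrier >= thr.closed_barrier:
        return CLOSED
    if dewetted:
        return CLOSED
    if ev.water_barrier is None:
        return INDETERMINATE  # geometry-only: narrow, but hydration unknown
    wetted = ev.dewetted_fraction is None or ev.dewetted_fraction == 0.0
    if ev.water_barrier <= thr.open_barrier and wetted and not ev.barrier_is_lower_bound:
        return OPEN
    return INDETERMINATE


def classify_state(
    profile: PoreProfile,
    gates: list | None = None,
    evidence: list | None = None,
    flux: float | None = None,
    thresholds: Thresholds | None = None,
    structure_id: str = "structure",
    provenance: dict | None = None,
) -> AnnotationReport:
    """Produce a functional-state verdict from geometry + hydration evidence.

    ``gates`` are :class:`GateRegion` candidates (narrow constrictions);
    ``evidence`` aligns with them (missing or ``None`` entries degrade that
    gate to a geometry-only INDETERMINATE call).  With no candidate gate the
    pore has no sub-threshold constriction and the verdict is OPEN.  The
    overall verdict is the worst gate (CLOSED > INDETERMINATE > OPEN).
    """
    if profile is None:
        raise ValueError("a pore-radius profile is required")
    thr = thresholds or Thresholds()
    gates = list(gates or [])
    evidence = list(evidence or [])
    evidence += [GateEvidence()] * (len(gates) - len(evidence))
    evidence = [e if e is not None else GateEvidence() for e in evidence]
    z_min, r_min = min_radius(profile)
    if not gates:
        verdict = OPEN
        gate_verdicts: list = []
    else:
        gate_verdicts = [_gate_label(e, thr) for e in evidence]
        verdict = max(gate_verdicts, key=lambda v: _SEVERITY[v])
    return AnnotationReport(
        structure_id=structure_id,
        verdict=verdict,
        gate_verdicts=gate_verdicts,
        gates=gates,
        evidence=evidence,
        min_radius=r_min,
        min_radius_z=z_min,
        flux=flux,
        thresholds=thr,
        provenance=provenance or {},
    )


def render_report(report: AnnotationReport, format: str = "json") -> str:
    """Deterministic serialisation of a report as JSON or readable text."""
    data = report.to_dict()
    if format == "json":
        return json.dumps(data, indent=2, sort_keys=True)
    if format != "text":
        raise ValueError(f"unknown format {format!r}")
    lines = [
        f"Structure: {report.structure_id}",
        f"Verdict:   {report.verdict}"
        + (" (non-conductive; closed and desensitized states are not distinguished)"
           if report.verdict == CLOSED else ""),
        f"Minimum pore radius: {report.min_radius:.2f} Å at z = {report.min_radius_z:.2f} Å",
    ]
    if report.flux is not None:
        lines.append(f"Water flux: {report.flux:.3g} ns⁻¹ (total bidirectional)")
    if not report.gates:
        lines.append(
            f"No sub-threshold constriction (all radii ≥ {report.thresholds.gate_radius} Å); "
            "geometry favors a conductive pore."
        )
    for g, e, v in zip(report.gates, report.evidence, report.gate_verdicts):
        lines.append(
            f"Gate {g.z_min:+.1f}..{g.z_max:+.1f} Å: min radius {g.min_radius:.2f} Å, "
            f"hydrophobic fraction {g.hydrophobic_fraction:.2f} -> {v}"
        )
        if e.water_barrier is not None:
            bound = " (lower bound)" if e.barrier_is_lower_bound else ""
            lines.append(f"  water barrier: {e.water_barrier:.1f} kJ/mol{bound}")
        if e.dewetted_fraction is not None:
            lines.append(f"  dewetted fraction: {e.dewetted_fraction:.2f}")
    lines.append(
        "Thresholds: closed >= %.1f kJ/mol or dewetted >= %.2f; open <= %.1f kJ/mol"
        % (report.thresholds.closed_barrier, report.thresholds.dewetted_fraction,
           report.thresholds.open_barrier)
    )
    return "\n".join(lines)
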