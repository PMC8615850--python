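"""End-to-end orientation detection and the machine-readable report.

Pipeline: load CT -> build trajectory from two points -> refine it from the
metal artifact -> gate on the polar angle -> auto-select the marker slice ->
sample the angular profile -> derive the two inverse candidates -> resolve
the 180-degree ambiguity with four methods -> report.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from . import __version__
from .ambiguity import Resolution, resolve
from .config import DetectionConfig
from .errors import UnresolvedAmbiguityError
from .lead_model import (
    CARTESIA,
    LeadSpec,
    RefineConfig,
    Trajectory,
    check_polar,
    level_center,
    make_trajectory,
    refine_trajectory,
)
from .orientation_core import (
    CandidatePair,
    anchor_axis,
    candidate_orientations,
    mean_angular_profile,
    select_marker_slice,
)
from .volume_io import CTVolume


def _to_signed(theta_deg: float) -> float:
    """Map [0, 360) to the reporting convention (-180, 180]."""
    t = theta_deg % 360.0
    return t - 360.0 if t > 180.0 else t


@dataclass(frozen=True)
class DetectionReport:
    """Result of one detection run.

    ``final_orientation_deg`` uses the convention 0 = anterior, positive
    counterclockwise viewed from superior (toward the patient's left),
    range (-180, 180]; it is absent (None) when the polar gate refuses or
    the ambiguity stays unresolved.
    """

    gate: str  # "ok" | "warn" | "refuse"
    polar_deg: float
    refined_tip: tuple[float, float, float] | None = None
    refined_dir: tuple[float, float, float] | None = None
    candidate_pair: tuple[float, float] | None = None
    final_orientation_deg: float | None = None
    methods: tuple[dict, ...] = ()
    mismatch: bool | None = None
    confidence: str | None = None
    lead_profile: str = "cartesia"
    config: dict | None = None
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "final_orientation_deg": self.final_orientation_deg,
            "orientation_convention": (
                "0 deg = anterior, positive counterclockwise viewed from "
                "superior, range (-180, 180]"
            ),
            "candidate_pair_deg": (
                list(self.candidate_pair) if self.candidate_pair else None
            ),
            "methods": [dict(m) for m in self.methods],
            "polar_deg": self.polar_deg,
            "gate": self.gate,
            "mismatch": self.mismatch,
            "confidence": self.confidence,
            "refined_tip_mm": list(self.refined_tip) if self.refined_tip else None,
            "refined_dir": list(self.refined_dir) if self.refined_dir else None,
            "lead_profile": self.lead_profile,
            "config": self.config,
            "version": self.version,
            "timestamp": self.timestamp,
        }


#: Minimal structural schema of the report JSON (shipped for consumers;
#: checked by :func:`validate_report_dict`).
REPORT_SCHEMA: dict = {
    "final_orientation_deg": (float, int, type(None)),
    "orientation_convention": (str,),
    "candidate_pair_deg": (list, type(None)),
    "methods": (list,),
    "polar_deg": (float, int),
    "gate": (str,),
    "mismatch": (bool, type(None)),
    "confidence": (str, type(None)),
    "refined_tip_mm": (list, type(None)),
    "refined_dir": (list, type(None)),
    "lead_profile": (str,),
    "config": (dict, type(None)),
    "version": (str,),
    "timestamp": (str,),
}


def validate_report_dict(d: dict) -> None:
    """Raise ValueError when a report dict violates the shipped schema."""
    for key, types in REPORT_SCHEMA.items():
        if key not in d:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(d[key], types):
            raise ValueError(
                f"report key {key!r} has type {type(d[key]).__name__}, "
                f"expected one of {[t.__name__ for t in types]}"
            )
    if d["gate"] == "refuse" and d["final_orientation_deg"] is not None:
        raise ValueError("a refused run must not carry a final orientation")


def _timestamp() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def detect_orientation(
    ct: CTVolume,
    tip,
    proximal,
    lead: LeadSpec = CARTESIA,
    cfg: DetectionConfig = DetectionConfig(),
    refine_cfg: RefineConfig = RefineConfig(),
) -> DetectionReport:
    """Run the full detection pipeline on a loaded CT volume.

    ``tip`` and ``proximal`` are two world-coordinate points on the lead
    trajectory (the tip and any more proximal point). A polar angle above
    the refusal threshold stops the pipeline with ``gate="refuse"``; an
    unresolved ambiguity (all methods degenerate) is reported with both
    candidates and no final orientation.
    """
    init = make_trajectory(tip, proximal)
    traj = refine_trajectory(ct, init, lead, refine_cfg)
    traj = anchor_axis(ct, traj, lead, threshold_hu=cfg.threshold_hu)
    gate = check_polar(traj, cfg.polar_warn_deg, cfg.polar_refuse_deg)
    base = dict(
        gate=gate,
        polar_deg=traj.polar_deg,
        refined_tip=tuple(traj.tip_world),
        refined_dir=tuple(traj.unit_dir),
        lead_profile=lead.name,
        config=cfg.to_dict(),
        timestamp=_timestamp(),
    )
    if gate == "refuse":
        return DetectionReport(**base)

    nominal = level_center(traj, lead, "marker")
    marker_center = select_marker_slice(
        ct,
        traj,
        lead,
        nominal,
        search_mm=cfg.slice_search_mm,
        step_mm=cfg.slice_search_step_mm,
        radius_mm=cfg.profile_radius_mm,
        n_angles=cfg.n_angles,
        min_amplitude_hu=cfg.min_amplitude_hu,
        radii_mm=cfg.profile_radii_mm,
        axial_offsets_mm=cfg.marker_axial_offsets_mm,
    )
    profile = mean_angular_profile(
        ct, traj, marker_center, cfg.profile_radii_mm, cfg.n_angles,
        cfg.marker_axial_offsets_mm,
    )
    pair = candidate_orientations(profile, lead, cfg.min_amplitude_hu)
    base["candidate_pair"] = (pair.theta_deg, pair.partner_deg)

    try:
        res: Resolution = resolve(
            ct, traj, lead, marker_center, pair, cfg, marker_profile=profile
        )
    except UnresolvedAmbiguityError:
        return DetectionReport(**base, confidence="reduced")

    methods = tuple(
        {
            "method": m.method,
            "chosen_theta_deg": _to_signed(m.chosen_theta_deg),
            "margin": m.margin,
            "degenerate": m.degenerate,
        }
        for m in res.methods
    )
    confidence = res.confidence
    if gate == "warn":
        confidence = "reduced"
    return DetectionReport(
        **base,
        final_orientation_deg=_to_signed(res.final_theta_deg),
        methods=methods,
        mismatch=res.mismatch,
        confidence=confidence,
    )
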