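"""Tunable detection parameters and lead-geometry profiles."""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the orientation-detection pipeline.

    Distances are millimetres, intensities Hounsfield units, angles degrees.
    """

    # angular-profile sampling; profiles are averaged over a thin
    # cylindrical shell (several radii x small axial offsets) because the
    # harmonic phase is noise-limited on a single circle
    profile_radius_mm: float = 3.0  # outside the hyperdense marker core
    profile_radii_mm: tuple[float, ...] = (2.5, 3.0, 3.5, 4.0, 4.5)
    marker_axial_offsets_mm: tuple[float, ...] = (
        -1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5
    )
    star_axial_offsets_mm: tuple[float, ...] = (-0.5, -0.25, 0.0, 0.25, 0.5)
    n_angles: int = 360  # 1-degree grid
    min_amplitude_hu: float = 10.0  # below: no usable marker artifact

    # artifact-slice auto-selection along the lead axis
    slice_search_mm: float = 1.5
    slice_search_step_mm: float = 0.25

    # perpendicular / in-line marker-slice resampling
    resample_resolution_mm: float = 0.1
    com_extent_mm: float = 10.0  # covers the marker artifact core
    sag_half_length_mm: float = 1.5  # marker center +/- 1.5 mm along the lead
    sag_half_width_mm: float = 5.0
    # COM is taken over the marker's hyperdense *volume*: a stack of
    # perpendicular slices covering the whole marker band
    com_slab_half_mm: float = 1.5
    com_slab_step_mm: float = 0.25
    threshold_hu: float = 2000.0  # metal binarization
    fill_hu: float = -1024.0

    # decision normalization / degeneracy
    deviation_scale_mm: float = 0.1  # typical meaningful COM shift
    min_deviation_mm: float = 0.02
    peak_window_deg: float = 30.0  # ASM peak search half-width
    star_window_deg: float = 15.0  # STARS streak window half-width
    margin_floor: float = 0.05
    # The marker's missing angular window sits opposite the facing direction,
    # so metal mass (and its COM) shifts toward the true orientation. Flip
    # this flag if real-lead calibration shows the opposite sign.
    com_points_toward_face: bool = True

    # polar-angle gate
    polar_warn_deg: float = 40.0
    polar_refuse_deg: float = 55.0

    def to_dict(self) -> dict:
        return asdict(self)


def _profiles_path() -> Path:
    return Path(importlib.resources.files("leadorient") / "data" / "leads.yaml")


def load_lead_profile(name_or_path: str):
    """Load a LeadSpec by profile name or from a YAML/JSON file.

    Named profiles come from the packaged ``data/leads.yaml``; a path to a
    user file (mapping of field name to value) is also accepted.
    """
    from .lead_model import LeadSpec

    path = Path(name_or_path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"} and path.exists():
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping of LeadSpec fields")
        return LeadSpec(**raw)
    with open(_profiles_path()) as fh:
        profiles = yaml.safe_load(fh)
    if name_or_path not in profiles:
        raise ConfigurationError(
            f"unknown lead profile {name_or_path!r}; "
            f"available: {', '.join(sorted(profiles))}"
        )
    return LeadSpec(**profiles[name_or_path])
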