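"""Structured run configuration: YAML key-value files with unit-suffixed keys.

Every quantity carries its unit in the key name (``gap_um``, ``sigma_mN_m``,
``stability_threshold_pF`` ...) and is converted to the package's internal
units at the boundary.  Unknown keys are rejected with the offending key
path.  Omitted keys take the calibrated device defaults (190 um gap, 6 um
parylene at eps_r 3.1, 15-sample window, 2 pF threshold, ...).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .capacitance_control import ControllerConfig
from .device_physics import DeviceGeometry, DielectricStack, FluidState
from .digital_assay import AssaySample
from .errors import InvalidInputError
from .loading_sim import AbsorberSpec, BeadPopulation, TraceCalibration

# section -> {config key: (target field, scale to internal units)}
_GEOMETRY_KEYS = {
    "gap_um": ("gap", 1e-6),
    "drive_width_mm": ("drive_width", 1e-3),
    "densify_shape": ("densify_shape", None),
    "densify_minor_mm": ("densify_minor", 1e-3),
    "densify_major_mm": ("densify_major", 1e-3),
    "contact_angle_deg": ("contact_angle", math.pi / 180.0),
    "neck_scale": ("neck_scale", 1.0),
    "parylene_thickness_um": ("_thickness", 1e-6),
    "rel_permittivity": ("_permittivity", 1.0),
}
_FLUID_KEYS = {
    "sigma_mN_m": ("sigma", 1e-3),
    "viscosity_mPa_s": ("viscosity", 1e-3),
    "k_factor": ("k_factor", 1.0),
    "label": ("label", None),
}
_CONTROLLER_KEYS = {
    "window": ("window", 1),
    "stability_threshold_pF": ("stability_threshold", 1.0),
    "rise_delta_pF": ("rise_delta", 1.0),
}
_ABSORBER_KEYS = {
    "kind": ("kind", None),
    "whatman_grade": ("whatman_grade", None),
    "thickness_um": ("thickness", 1e-6),
    "pore_size_um": ("pore_size", 1e-6),
    "layers": ("layers", 1),
    "sap_mass_mg": ("sap_mass_mg", 1.0),
    "strip_width_mm": ("strip_width", 1e-3),
    "entry_length_mm": ("entry_length", 1e-3),
    "porosity": ("porosity", 1.0),
}
_BEAD_KEYS = {
    "count": ("count", 1),
    "diameter_um": ("diameter", 1e-6),
    "magnetic_force_median_pN": ("magnetic_force_median", 1e-12),
    "magnetic_force_sigma": ("magnetic_force_sigma", 1.0),
}
_ASSAY_KEYS = {
    "concentration_mol_L": ("concentration", 1.0),
    "volume_ul": ("volume", 1e-6),
}
_TRACE_KEYS = {
    "baseline_pF": ("baseline_pF", 1.0),
    "slope_pF_per_ul": ("slope_pF_per_ul", 1.0),
    "split_plateau_pF": ("split_plateau_pF", 1.0),
    "sample_rate_hz": ("sample_rate_hz", 1.0),
    "ramp_step_pF": ("ramp_step_pF", 1.0),
    "hold_s": ("hold_s", 1.0),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration for a simulation run."""

    geometry: DeviceGeometry
    fluid: FluidState
    controller: ControllerConfig
    absorber: AbsorberSpec
    beads: BeadPopulation
    assay: AssaySample
    trace: TraceCalibration
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self):
        if not isinstance(self.seed, int) or self.seed < 0:
            raise InvalidInputError("seed must be a non-negative integer")


def _convert_section(name: str, raw: dict, keymap: dict) -> dict:
    if not isinstance(raw, dict):
        raise InvalidInputError(f"section {name!r} must be a mapping")
    out = {}
    for key, value in raw.items():
        if key not in keymap:
            raise InvalidInputError(f"unknown configuration key: {name}.{key}")
        target, scale = keymap[key]
        out[target] = value if scale is None or scale == 1 else value * scale
    return out


def _build_absorber(kw: dict) -> AbsorberSpec:
    grade = kw.pop("whatman_grade", None)
    if grade is not None:
        layers = int(kw.pop("layers", 1))
        kw.pop("kind", None)
        return AbsorberSpec.whatman(str(grade), layers=layers, **kw)
    kw.setdefault("kind", "SAP" if kw.get("sap_mass_mg", 0) else "paper")
    return AbsorberSpec(**kw)


def load_config(source) -> RunConfig:
    """Load and validate a RunConfig from a YAML file path or file object.

    Sections (all optional): ``geometry``, ``fluid``, ``controller``,
    ``absorber``, ``beads``, ``assay``, ``trace``; top-level scalars
    ``seed`` and ``out_dir``.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InvalidInputError("configuration root must be a mapping")

    known_sections = {
        "geometry", "fluid", "controller", "absorber", "beads", "assay", "trace",
    }
    for key in raw:
        if key not in known_sections | {"seed", "out_dir"}:
            raise InvalidInputError(f"unknown configuration key: {key}")

    geo_kw = _convert_section("geometry", raw.get("geometry", {}), _GEOMETRY_KEYS)
    thickness = geo_kw.pop("_thickness", 6e-6)
    permittivity = geo_kw.pop("_permittivity", 3.1)
    geo_kw.setdefault("gap", 190e-6)
    geo_kw.setdefault("drive_width", 2.2e-3)
    geometry = DeviceGeometry(
        stack=DielectricStack(thickness=thickness, rel_permittivity=permittivity),
        **geo_kw,
    )

    fluid_kw = _convert_section("fluid", raw.get("fluid", {}), _FLUID_KEYS)
    fluid_kw.setdefault("sigma", 42e-3)
    fluid = FluidState(**fluid_kw)

    ctl_kw = _convert_section("controller", raw.get("controller", {}), _CONTROLLER_KEYS)
    controller = ControllerConfig(**ctl_kw)

    abs_kw = _convert_section("absorber", raw.get("absorber", {}), _ABSORBER_KEYS)
    absorber = _build_absorber(abs_kw)

    bead_kw = _convert_section("beads", raw.get("beads", {}), _BEAD_KEYS)
    bead_kw.setdefault("count", 5000)
    beads = BeadPopulation(**bead_kw)

    assay_kw = _convert_section("assay", raw.get("assay", {}), _ASSAY_KEYS)
    assay_kw.setdefault("concentration", 1e-18)
    assay_kw.setdefault("volume", 100e-6)
    assay = AssaySample(**assay_kw)

    trace_kw = _convert_section("trace", raw.get("trace", {}), _TRACE_KEYS)
    trace = TraceCalibration(**trace_kw)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        raise InvalidInputError("seed must be a non-negative integer")
    return RunConfig(
        geometry=geometry,
        fluid=fluid,
        controller=controller,
        absorber=absorber,
        beads=beads,
        assay=assay,
        trace=trace,
        seed=seed,
        out_dir=str(raw.get("out_dir", ".")),
    )


def default_config() -> RunConfig:
    """The all-defaults configuration (no file needed)."""
    import io

    return load_config(io.StringIO("{}"))
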