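"""Reference parameter set for the explosive-dispersal models.

A single record holds every geometric, material and environmental
parameter used across the valve-energetics, coiling-dynamics,
ballistics, cell-mechanics and organ-scale modules, together with a
provenance tag per field:

``PAPER``
    printed in the source study (e.g. the 20% exocarp rest contraction,
    0.7 MPa turgor, the three cell geometries);
``DERIVED``
    produced by a calibration operation of this package (e.g. the
    tissue-level exocarp modulus, obtained from the cross-scale
    cell-file pulling force; the calibrated wall moduli);
``ASSUMED``
    not printed anywhere and chosen once as a realistic value, always
    overridable through a config file.

Units are fixed per field and documented in ``FIELD_UNITS``; they are
the natural units of each scale (μm/mm/MPa/mN/mg/ms).  Conversion to SI
for computation is done by the consuming modules via
:mod:`podburst.units`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["ReferenceParameterSet", "load_reference", "ValidationError"]


class ValidationError(ValueError):
    """A parameter value violates a physical invariant."""


@dataclass
class ReferenceParameterSet:
    # -- valve geometry -------------------------------------------------
    valve_length: float = 16.0          # mm; fruit length 17 mm minus beak
    valve_width: float = 2.0            # mm
    exocarp_thickness: float = 20.0     # μm
    middle_thickness: float = 125.0     # μm; ~9 cell layers mid-valve
    endocarpb_rod_thickness: float = 2.0  # μm, lignified rod band
    boxed_cell_depth: float = 30.0      # μm, endocarp-b cell depth (boxed geometry)
    transverse_curvature: float = 2.0   # 1/mm, initial cross-section bowing
    lignified_area_fraction: float = 0.5   # fraction of width covered by rods
    hinge_stiffness: float = 1e-6       # N·mm per rad² per mm length (thin hinges)
    tissue_density: float = 1.0         # mg/mm³

    # -- materials ------------------------------------------------------
    exocarp_rest_contraction: float = 0.20  # γ, dimensionless
    E_exocarp: float = 7.6              # MPa, tissue-level (calibrated)
    E_middle: float = 0.5               # MPa
    E_lignin: float = 5000.0            # MPa

    # -- cell scale -----------------------------------------------------
    turgor_pressure: float = 0.7        # MPa
    cell_dims_mature: tuple = (50.0, 50.0, 20.0)     # μm (L × W × D)
    cell_dims_immature: tuple = (30.0, 20.0, 14.0)   # μm
    cell_dims_athaliana: tuple = (100.0, 20.0, 20.0)  # μm
    wall_thickness: float = 1.0         # μm
    wall_poisson: float = 0.3           # dimensionless
    E_wall_length: float = 789.2        # MPa, calibrated longitudinal wall modulus
    E_wall_transverse: float = 7.86     # MPa, calibrated width-direction modulus
    E_wall_depth: float = 101.3         # MPa, calibrated depth-direction modulus

    # -- seeds, tether, environment ------------------------------------
    n_seeds: int = 10
    seed_mass: float = 0.5              # mg
    seed_radius: float = 0.6            # mm
    tether_k: float = 150.0             # N/m
    tether_c: float = 0.02              # N·s/m
    tether_delta_c: float = 40.0        # μm, critical extension
    release_height: float = 0.2         # m
    air_density: float = 1.2            # kg/m³
    gravity: float = 9.81               # m/s²
    drag_model: str = "constant_cd"     # or "sphere_correlation"
    drag_coefficient: float = 0.5       # used by the constant model

    provenance: dict = field(default_factory=lambda: dict(DEFAULT_PROVENANCE))

    # ------------------------------------------------------------------
    def validate(self) -> "ReferenceParameterSet":
        """Check all physical invariants; raise :class:`ValidationError`."""
        positive = [
            "valve_length", "valve_width", "exocarp_thickness",
            "middle_thickness", "endocarpb_rod_thickness", "boxed_cell_depth",
            "tissue_density", "E_exocarp", "E_middle", "E_lignin",
            "turgor_pressure", "wall_thickness", "E_wall_length",
            "E_wall_transverse", "E_wall_depth", "seed_mass",
            "seed_radius", "tether_k",
            "tether_delta_c", "air_density", "gravity", "drag_coefficient",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive, got "
                                      f"{getattr(self, name)!r}")
        g = self.exocarp_rest_contraction
        if not 0.0 < g < 1.0:
            raise ValidationError(
                f"exocarp_rest_contraction must lie in (0, 1), got {g!r}")
        phi = self.lignified_area_fraction
        if not 0.0 < phi <= 1.0:
            raise ValidationError(
                f"lignified_area_fraction must lie in (0, 1], got {phi!r}")
        if not 0.0 <= self.wall_poisson < 0.5:
            raise ValidationError(
                f"wall_poisson must lie in [0, 0.5), got {self.wall_poisson!r}")
        if self.hinge_stiffness < 0 or self.transverse_curvature < 0:
            raise ValidationError("hinge_stiffness and transverse_curvature "
                                  "must be non-negative")
        if self.release_height < 0:
            raise ValidationError("release_height must be non-negative")
        if self.tether_c < 0:
            raise ValidationError("tether_c must be non-negative")
        if self.drag_model not in ("constant_cd", "sphere_correlation"):
            raise ValidationError(
                f"drag_model must be 'constant_cd' or 'sphere_correlation', "
                f"got {self.drag_model!r}")
        if self.n_seeds < 0:
            raise ValidationError("n_seeds must be non-negative")
        for name in ("cell_dims_mature", "cell_dims_immature",
                     "cell_dims_athaliana"):
            dims = getattr(self, name)
            if len(dims) != 3 or any(not d > 0 for d in dims):
                raise ValidationError(f"{name} must be three positive lengths")
        missing = {f.name for f in dataclasses.fields(self)
                   if f.name != "provenance"} - set(self.provenance)
        if missing:
            raise ValidationError(f"missing provenance tags for {sorted(missing)}")
        bad = {k: v for k, v in self.provenance.items()
               if v not in ("PAPER", "DERIVED", "ASSUMED")}
        if bad:
            raise ValidationError(f"invalid provenance tags: {bad}")
        return self


FIELD_UNITS: dict[str, str] = {
    "valve_length": "mm", "valve_width": "mm",
    "exocarp_thickness": "um", "middle_thickness": "um",
    "endocarpb_rod_thickness": "um", "boxed_cell_depth": "um",
    "transverse_curvature": "1/mm", "lignified_area_fraction": "-",
    "hinge_stiffness": "N·mm/rad²/mm", "tissue_density": "mg/mm³",
    "exocarp_rest_contraction": "-",
    "E_exocarp": "MPa", "E_middle": "MPa", "E_lignin": "MPa",
    "turgor_pressure": "MPa",
    "cell_dims_mature": "um", "cell_dims_immature": "um",
    "cell_dims_athaliana": "um",
    "wall_thickness": "um", "wall_poisson": "-",
    "E_wall_length": "MPa", "E_wall_transverse": "MPa",
    "E_wall_depth": "MPa",
    "n_seeds": "-", "seed_mass": "mg", "seed_radius": "mm",
    "tether_k": "N/m", "tether_c": "N·s/m", "tether_delta_c": "um",
    "release_height": "m", "air_density": "kg/m³", "gravity": "m/s²",
    "drag_model": "-", "drag_coefficient": "-",
}

DEFAULT_PROVENANCE: dict[str, str] = {
    "valve_length": "DERIVED",            # 17 mm fruit length is printed
    "valve_width": "ASSUMED",
    "exocarp_thickness": "ASSUMED",
    "middle_thickness": "ASSUMED",        # anchored to printed 9.2 cell layers
    "endocarpb_rod_thickness": "ASSUMED",
    "boxed_cell_depth": "ASSUMED",
    "transverse_curvature": "ASSUMED",
    "lignified_area_fraction": "ASSUMED",
    "hinge_stiffness": "ASSUMED",
    "tissue_density": "ASSUMED",
    "exocarp_rest_contraction": "PAPER",  # 20% reduction in cell length
    "E_exocarp": "DERIVED",               # from 61 mN cross-scale force
    "E_middle": "ASSUMED",
    "E_lignin": "ASSUMED",                # literature scale for lignified walls
    "turgor_pressure": "PAPER",           # 0.65–0.7 MPa
    "cell_dims_mature": "PAPER",
    "cell_dims_immature": "PAPER",
    "cell_dims_athaliana": "PAPER",
    "wall_thickness": "ASSUMED",
    "wall_poisson": "ASSUMED",
    "E_wall_length": "DERIVED",           # osmotic-response calibration
    "E_wall_transverse": "DERIVED",
    "E_wall_depth": "DERIVED",
    "n_seeds": "ASSUMED",
    "seed_mass": "DERIVED",               # force/weight comparison in source
    "seed_radius": "ASSUMED",
    "tether_k": "DERIVED",                # launch-statistics calibration
    "tether_c": "DERIVED",
    "tether_delta_c": "DERIVED",
    "release_height": "ASSUMED",
    "air_density": "ASSUMED",
    "gravity": "ASSUMED",
    "drag_model": "ASSUMED",
    "drag_coefficient": "ASSUMED",
}


def load_reference(config_path: str | Path | None = None) -> ReferenceParameterSet:
    """Return the reference set, optionally overridden by a YAML config.

    The config is a flat key → value mapping whose keys must exactly match
    field names of :class:`ReferenceParameterSet` (fixed units, see
    ``FIELD_UNITS``).  Unknown keys are rejected; every override is logged;
    overridden fields are re-tagged ``ASSUMED`` unless the config also
    carries a ``provenance`` mapping.
    """
    ref = ReferenceParameterSet()
    if config_path is None:
        return ref.validate()

    path = Path(config_path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message formatting
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed config {path}{line}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")

    known = {f.name for f in dataclasses.fields(ReferenceParameterSet)}
    prov_override = raw.pop("provenance", {})
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        logger.info("override %s: %r -> %r (%s)", key, getattr(ref, key),
                    value, FIELD_UNITS.get(key, ""))
        setattr(ref, key, value)
        ref.provenance[key] = "ASSUMED"
    ref.provenance.update(prov_override)
    return ref.validate()
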