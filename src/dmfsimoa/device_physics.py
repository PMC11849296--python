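"""Electrowetting and droplet-pressure models for two-plate DMF devices.

The module collects the small set of closed-form results that govern droplet
splitting on a bead-densifying electrode:

* areal capacitance of the dielectric stack, the prerequisite quantity of the
  Young-Lippmann relation;
* the Young-Lippmann electrowetting driving force on a contact line;
* the pressure imbalance ``dp`` between the necking region and the droplet
  retained on the densifying electrode, which decides whether splitting (and
  hence bead recovery in a small residual volume) succeeds;
* the Laplace pressure of the sample reservoir, which rises as the reservoir
  drains and makes the final splitting cycles harder.

All quantities are SI internally (m, N, Pa, F).  Configuration-file
interfaces convert from the mixed laboratory units (um, mm, mN/m) at the
boundary; see :mod:`dmfsimoa.config`.

Model notes
-----------
A droplet squeezed between the plates is treated as a pancake: its internal
pressure exceeds ambient by ``sigma * (C_inplane + C_gap)`` where
``C_inplane`` is the in-plane footprint curvature and
``C_gap = -(cos(theta_top) + cos(theta_bottom)) / h`` is the gap curvature
(positive for hydrophobic plates).  Electrowetting on an actuated electrode
lowers the apparent bottom contact angle; the dimensionless factor
``k in (0, 1)`` parameterizes the fractional progression of ``cos(theta)``
from its resting value toward complete wetting,

    cos(theta_act) = cos(theta0) + k * (1 - cos(theta0)),

so ``k`` grows with applied voltage and falls with surfactant concentration.
The neck connecting the retained droplet to the departing liquid is a saddle:
concave in plane (radius proportional to the clearance between the densifying
footprint and the destination-electrode edge) and gap-curved over an
*unactuated* region.  ``dp = p_neck - p_retained`` is then linear in sigma,
strictly increasing in ``k``, and increases with destination width ``w`` with
diminishing returns -- the trends observed for reliable droplet breakup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DegenerateGeometryError, InvalidGeometryError, InvalidInputError

#: vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12

#: default resting contact angle on fluorinated hydrophobic coatings, radians
DEFAULT_CONTACT_ANGLE_RAD = math.radians(115.0)


@dataclass(frozen=True)
class DielectricStack:
    """The insulating stack on the actuated plate.

    Parameters
    ----------
    thickness : float
        Dielectric (parylene) layer thickness in metres.
    rel_permittivity : float
        Relative permittivity (dimensionless, >= 1).
    """

    thickness: float
    rel_permittivity: float

    def __post_init__(self):
        if not self.thickness > 0:
            raise InvalidGeometryError(
                f"dielectric thickness must be > 0, got {self.thickness}"
            )
        if not self.rel_permittivity >= 1:
            raise InvalidGeometryError(
                f"relative permittivity must be >= 1, got {self.rel_permittivity}"
            )


@dataclass(frozen=True)
class DeviceGeometry:
    """Two-plate DMF geometry around one densifying electrode.

    Parameters
    ----------
    gap : float
        Inter-plate spacing ``h`` in metres.
    drive_width : float
        Width ``w`` of the destination (driving) electrode in metres.
    densify_shape : {"round", "oval"}
    densify_minor : float
        Minor axis (= diameter for round electrodes) ``d`` in metres.
    densify_major : float, optional
        Major axis; defaults to ``densify_minor`` (round).
    stack : DielectricStack
    contact_angle : float
        Resting contact angle of the hydrophobic coating, radians.
    neck_scale : float
        Proportionality constant between the neck in-plane radius and the
        clearance ``(w - d) / 2``; model parameter, default 1.
    """

    gap: float
    drive_width: float
    densify_shape: str = "round"
    densify_minor: float = 1.0e-3
    densify_major: float | None = None
    stack: DielectricStack = field(
        default_factory=lambda: DielectricStack(thickness=6e-6, rel_permittivity=3.1)
    )
    contact_angle: float = DEFAULT_CONTACT_ANGLE_RAD
    neck_scale: float = 1.0

    def __post_init__(self):
        if self.densify_major is None:
            object.__setattr__(self, "densify_major", self.densify_minor)
        if self.densify_shape not in ("round", "oval"):
            raise InvalidGeometryError(
                f"densify_shape must be 'round' or 'oval', got {self.densify_shape!r}"
            )
        for name in ("gap", "drive_width", "densify_minor", "densify_major"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.densify_minor > self.densify_major:
            raise InvalidGeometryError("densify_minor must be <= densify_major")
        if not self.neck_scale > 0:
            raise InvalidGeometryError("neck_scale must be > 0")

    @property
    def densify_footprint_area(self) -> float:
        """Footprint area of the densifying electrode, m^2."""
        return math.pi / 4.0 * self.densify_minor * self.densify_major


@dataclass(frozen=True)
class FluidState:
    """Working-liquid properties.

    ``k_factor`` is the dimensionless electrowetting contact-angle-difference
    parameter in (0, 1); see the module docstring.
    """

    sigma: float
    viscosity: float = 1.0e-3
    k_factor: float = 0.6
    label: str = ""

    def __post_init__(self):
        if not self.sigma > 0:
            raise InvalidInputError(f"interfacial tension must be > 0, got {self.sigma}")
        if not self.viscosity > 0:
            raise InvalidInputError(f"viscosity must be > 0, got {self.viscosity}")
        if not 0 < self.k_factor < 1:
            raise InvalidInputError(
                f"k_factor must lie strictly in (0, 1), got {self.k_factor}"
            )


@dataclass(frozen=True)
class ActuationState:
    """RMS driving potential and on/off state of an electrode."""

    voltage: float
    active: bool = True

    def __post_init__(self):
        if self.voltage < 0:
            raise InvalidInputError(f"voltage must be >= 0, got {self.voltage}")


def capacitance_per_area(stack: DielectricStack) -> float:
    """Areal capacitance ``c = eps0 * eps_r / t`` of the dielectric, F/m^2."""
    return EPSILON_0 * stack.rel_permittivity / stack.thickness


def young_lippmann_force(
    actuation: ActuationState,
    contact_line_length: float,
    stack: DielectricStack,
) -> float:
    """Electrowetting driving force ``F = 1/2 c V^2 L`` in newtons.

    ``L`` is the length of contact line overlapping the energised electrode
    edge.  Quadratic in voltage; zero at V = 0.
    """
    if not contact_line_length > 0:
        raise InvalidGeometryError(
            f"contact_line_length must be > 0, got {contact_line_length}"
        )
    c = capacitance_per_area(stack)
    return 0.5 * c * actuation.voltage**2 * contact_line_length


def _gap_curvature(geom: DeviceGeometry, cos_bottom: float) -> float:
    """Gap-curvature contribution (1/m) with the given bottom-plate cosine."""
    return -(math.cos(geom.contact_angle) + cos_bottom) / geom.gap


def retention_pressure_imbalance(geom: DeviceGeometry, fluid: FluidState) -> float:
    """Pressure imbalance ``dp = p_neck - p_retained`` in pascals.

    Positive ``dp`` drains the neck and favours breakup of the retained
    droplet from the departing liquid (reliable bead recovery); negative
    ``dp`` feeds the neck and the retained droplet is swept away.

    The retained droplet sits on the *actuated* densifying electrode
    (electrowetted bottom contact angle); the neck spans the unactuated
    clearance between the densifying footprint and the destination-electrode
    edge and is concave in plane.  For oval electrodes the effective in-plane
    curvature is taken at the minor axis.
    """
    d = geom.densify_minor
    w = geom.drive_width
    if d >= w:
        raise DegenerateGeometryError(
            f"densifying dimension ({d} m) must be smaller than the "
            f"destination electrode width ({w} m): no necking region exists"
        )
    cos0 = math.cos(geom.contact_angle)
    cos_act = cos0 + fluid.k_factor * (1.0 - cos0)

    # retained pancake droplet: convex in plane (radius d/2), actuated gap
    p_retained = fluid.sigma * (2.0 / d + _gap_curvature(geom, cos_act))
    # neck: concave in plane (radius neck_scale*(w-d)/2), resting gap
    r_neck = geom.neck_scale * (w - d) / 2.0
    p_neck = fluid.sigma * (-1.0 / r_neck + _gap_curvature(geom, cos0))
    return p_neck - p_retained


def reservoir_laplace_pressure(
    volume: float, geom: DeviceGeometry, fluid: FluidState
) -> float:
    """Laplace pressure (Pa) of the sample reservoir holding ``volume`` m^3.

    The reservoir is a pancake of footprint radius ``r = sqrt(V / (pi h))``;
    the pressure ``sigma * (1/r + C_gap)`` rises as the reservoir drains,
    which is what makes the final splitting cycles of stepwise loading the
    hard ones.  Strictly decreasing in volume.
    """
    if not volume > 0:
        raise InvalidInputError(f"reservoir volume must be > 0, got {volume}")
    r = math.sqrt(volume / (math.pi * geom.gap))
    return fluid.sigma * (1.0 / r + _gap_curvature(geom, math.cos(geom.contact_angle)))
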