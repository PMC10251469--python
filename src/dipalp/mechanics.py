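"""Forward viscoelastic contact mechanics for dynamic instrumented palpation (DIP).

DIP measures the dynamic stiffness of soft tissue by pressing an oscillating
indenter against it: a sinusoidal force modulation about a fixed mean is
applied, and the resulting indentation response is recorded.  Three raw
observables follow for each actuation frequency -- the quasi-static stiffness
(mean force over mean displacement), the dynamic stiffness magnitude
(force amplitude over displacement amplitude) and the phase by which the
displacement lags the force.

This module supplies the forward model behind those observables:

* a linear viscoelastic constitutive law (Kelvin--Voigt by default, standard
  linear solid optionally) giving the complex modulus
  ``E*(omega) = E' + i E''`` at any actuation frequency;
* the conversion between phase lag and time lag, ``dt = delta / (2 pi f)``;
* Hertzian contact between a rigid sphere and an elastic half-space, used to
  map stiffness measurements (N/mm) to material moduli (kPa) and back.

Units follow soft-tissue indentation practice: moduli in kPa, probe radius
and indentation depth in mm, force in N, viscosity in kPa*s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

_TWO_PI = 2.0 * math.pi

#: Ratio of the Hertzian tangent stiffness dF/dd to the secant stiffness F/d
#: at the same depth.  For F proportional to d**(3/2) the tangent slope is
#: exactly 1.5 times the secant slope; feature extraction uses this factor to
#: convert a mean-ratio (secant) measurement into the tangent stiffness that
#: the modulus inversion expects.
SECANT_TO_TANGENT = 1.5


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


@dataclass(frozen=True)
class ViscoParams:
    """Linear viscoelastic tissue parameters.

    Parameters
    ----------
    e_static:
        Quasi-static (relaxed) elastic modulus in kPa.  For the Kelvin--Voigt
        model this is the storage modulus at every frequency.
    eta:
        Viscosity coefficient in kPa*s; ``eta = 0`` gives a purely elastic
        material.
    model_kind:
        ``"kelvin_voigt"`` (spring and dashpot in parallel) or ``"sls"``
        (standard linear solid / Zener: a Maxwell arm of stiffness ``e2`` and
        viscosity ``eta`` in parallel with the relaxed spring).
    e2:
        Maxwell-arm stiffness in kPa, required for ``model_kind="sls"``.
    """

    e_static: float
    eta: float = 0.0
    model_kind: str = "kelvin_voigt"
    e2: float | None = None

    def __post_init__(self) -> None:
        _require(self.e_static > 0, f"e_static must be positive, got {self.e_static}")
        _require(self.eta >= 0, f"eta must be non-negative, got {self.eta}")
        _require(
            self.model_kind in ("kelvin_voigt", "sls"),
            f"model_kind must be 'kelvin_voigt' or 'sls', got {self.model_kind!r}",
        )
        if self.model_kind == "sls":
            _require(
                self.e2 is not None and self.e2 > 0,
                "sls model requires a positive Maxwell-arm stiffness e2",
            )


@dataclass(frozen=True)
class ComplexModulus:
    """Storage/loss decomposition of the dynamic modulus at one frequency.

    ``magnitude = sqrt(storage**2 + loss**2)`` and
    ``phase = arctan(loss / storage)`` hold by construction; for a passive
    material with positive storage modulus the phase lies in [0, pi/2).
    """

    storage: float
    loss: float
    magnitude: float
    phase: float
    frequency: float


@dataclass(frozen=True)
class ProbeGeometry:
    """Indenter geometry and the calibration factor of the probe.

    Parameters
    ----------
    radius_mm:
        Effective radius of the (spherical) contact surface, mm.
    poisson:
        Poisson ratio of the tissue; 0.5 treats soft tissue as incompressible.
    k_f:
        Calibration factor relating the membrane strain reading to the
        indentation depth: ``depth_mm = |strain| / k_f``.  It also scales the
        raw force/strain ratios so that the mean ratio and amplitude ratio
        come out as stiffnesses in N/mm.  Units: 1/mm.
    """

    radius_mm: float = 5.0
    poisson: float = 0.5
    k_f: float = 0.1

    def __post_init__(self) -> None:
        _require(self.radius_mm > 0, f"radius_mm must be positive, got {self.radius_mm}")
        _require(
            0.0 <= self.poisson <= 0.5,
            f"poisson must lie in [0, 0.5], got {self.poisson}",
        )
        _require(self.k_f > 0, f"k_f must be positive, got {self.k_f}")

    @property
    def contact_factor(self) -> float:
        """1 / (1 - nu**2), the plane-strain correction of the modulus."""
        return 1.0 / (1.0 - self.poisson**2)


def complex_modulus(params: ViscoParams, frequency: float) -> ComplexModulus:
    """Evaluate the complex modulus E*(omega) at an actuation frequency.

    Kelvin--Voigt: ``E' = e_static`` and ``E'' = 2 pi f eta``.  Standard
    linear solid: the relaxed spring plus a Maxwell arm with relaxation time
    ``tau = eta / e2`` gives
    ``E' = e_static + e2 (w tau)^2 / (1 + (w tau)^2)`` and
    ``E'' = e2 w tau / (1 + (w tau)^2)``.
    """
    _require(frequency > 0, f"frequency must be positive, got {frequency}")
    omega = _TWO_PI * frequency
    if params.model_kind == "kelvin_voigt":
        storage = params.e_static
        loss = omega * params.eta
    else:  # sls
        assert params.e2 is not None
        if params.eta == 0.0:
            storage, loss = params.e_static, 0.0
        else:
            wt = omega * params.eta / params.e2
            storage = params.e_static + params.e2 * wt**2 / (1.0 + wt**2)
            loss = params.e2 * wt / (1.0 + wt**2)
    magnitude = math.hypot(storage, loss)
    phase = math.atan2(loss, storage)
    return ComplexModulus(storage=storage, loss=loss, magnitude=magnitude,
                          phase=phase, frequency=frequency)


def phase_to_timelag(phase: float, frequency: float) -> float:
    """Convert a phase lag (rad) at a known frequency into a time lag (s)."""
    _require(frequency > 0, f"frequency must be positive, got {frequency}")
    _require(phase >= 0, f"phase must be non-negative, got {phase}")
    return phase / (_TWO_PI * frequency)


def timelag(params: ViscoParams, frequency: float) -> float:
    """Time lag of displacement behind force predicted by the tissue model."""
    return phase_to_timelag(complex_modulus(params, frequency).phase, frequency)


def hertz_force(e_kpa: float, geom: ProbeGeometry, depth_mm: float) -> float:
    """Hertzian indentation force (N) of a rigid sphere at a given depth.

    ``F = (4/3) [E / (1 - nu^2)] sqrt(R) d^(3/2)`` with E in kPa and R, d in
    mm, evaluated in SI internally.  Zero depth gives zero force; the curve is
    strictly increasing and convex in depth.
    """
    _require(e_kpa > 0, f"modulus must be positive, got {e_kpa}")
    _require(depth_mm >= 0, f"depth_mm must be non-negative, got {depth_mm}")
    e_star = e_kpa * 1e3 * geom.contact_factor          # Pa
    r = geom.radius_mm * 1e-3                           # m
    d = depth_mm * 1e-3                                 # m
    return (4.0 / 3.0) * e_star * math.sqrt(r) * d**1.5


def hertz_tangent_stiffness(e_kpa: float, geom: ProbeGeometry, depth_mm: float) -> float:
    """Local contact stiffness dF/dd (N/mm) of the Hertz curve at a depth."""
    _require(e_kpa > 0, f"modulus must be positive, got {e_kpa}")
    _require(depth_mm > 0, f"depth_mm must be positive, got {depth_mm}")
    e_star = e_kpa * 1e3 * geom.contact_factor
    r = geom.radius_mm * 1e-3
    d = depth_mm * 1e-3
    return 2.0 * e_star * math.sqrt(r * d) * 1e-3       # N/m -> N/mm


def stiffness_to_modulus(stiffness_n_per_mm: float, geom: ProbeGeometry,
                         operating_depth_mm: float) -> float:
    """Invert the linearised Hertz slope to recover a modulus in kPa.

    Inverts ``dF/dd = 2 [E / (1 - nu^2)] sqrt(R d)`` at the operating depth;
    exact round trip with :func:`hertz_tangent_stiffness`.
    """
    _require(stiffness_n_per_mm > 0,
             f"stiffness must be positive, got {stiffness_n_per_mm}")
    _require(operating_depth_mm > 0,
             f"operating_depth_mm must be positive, got {operating_depth_mm}")
    r = geom.radius_mm * 1e-3
    d = operating_depth_mm * 1e-3
    e_star = stiffness_n_per_mm * 1e3 / (2.0 * math.sqrt(r * d))  # Pa
    return e_star / geom.contact_factor / 1e3                     # kPa


def indentation_depth(e_kpa: float, geom: ProbeGeometry, force_n: float) -> float:
    """Depth (mm) at which the Hertz curve carries a given mean force (N).

    Closed-form inverse of :func:`hertz_force`:
    ``d = [3 F (1 - nu^2) / (4 E sqrt(R))]^(2/3)``.
    """
    _require(e_kpa > 0, f"modulus must be positive, got {e_kpa}")
    _require(force_n > 0, f"force_n must be positive, got {force_n}")
    e_star = e_kpa * 1e3 * geom.contact_factor
    r = geom.radius_mm * 1e-3
    d = (3.0 * force_n / (4.0 * e_star * math.sqrt(r))) ** (2.0 / 3.0)
    return d * 1e3
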