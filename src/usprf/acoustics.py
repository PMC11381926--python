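"""Acoustic intensity utilities.

Plane-wave intensity estimates from hydrophone pressure measurements:
the spatial-peak pulse-average intensity is ``I_SPPA = p^2 / (2 Z)`` with
``p`` the spatial-peak pressure amplitude (Pa) and ``Z`` the acoustic
impedance of the medium (Rayl, i.e. Pa s/m); the spatial-peak temporal-
average intensity is ``I_SPTA = I_SPPA * duty_cycle``.
"""

from __future__ import annotations

WATER_IMPEDANCE_RAYL = 1.5e6
"""Acoustic impedance of water (Rayl), the standard free-field reference."""


def isppa(pressure_pa: float, impedance_rayl: float = WATER_IMPEDANCE_RAYL) -> float:
    """Spatial-peak pulse-average intensity in W/cm^2.

    Parameters
    ----------
    pressure_pa
        Spatial-peak pressure amplitude (Pa), non-negative.
    impedance_rayl
        Acoustic impedance of the medium (Rayl), positive.
    """
    if pressure_pa < 0:
        raise ValueError("pressure must be non-negative")
    if impedance_rayl <= 0:
        raise ValueError("impedance must be positive")
    w_per_m2 = pressure_pa**2 / (2.0 * impedance_rayl)
    return w_per_m2 / 1e4


def ispta(isppa_w_cm2: float, duty_cycle: float) -> float:
    """Spatial-peak temporal-average intensity, ``I_SPPA`` times duty cycle."""
    if not 0.0 <= duty_cycle <= 1.0:
        raise ValueError("duty cycle must lie in [0, 1]")
    if isppa_w_cm2 < 0:
        raise ValueError("isppa must be non-negative")
    return isppa_w_cm2 * duty_cycle
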