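"""Centralized degree/radian handling for circular colour-wheel data.

Colour is represented as a hue angle in degrees in [0, 360) everywhere data
is stored or serialized; likelihood code works in radians. Signed angular
errors live in (-180, 180] degrees (equivalently (-pi, pi] radians), with the
boundary assigned to +180 by convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_signed_deg", "wrap_deg", "deg2rad", "rad2deg", "angular_error"]


def wrap_deg(angle_deg):
    """Wrap an angle (degrees) into [0, 360)."""
    return np.asarray(angle_deg, dtype=float) % 360.0


def wrap_signed_deg(angle_deg):
    """Wrap an angle (degrees) into (-180, 180]; exactly 180 maps to +180."""
    a = np.asarray(angle_deg, dtype=float) % 360.0
    out = np.where(a > 180.0, a - 360.0, a)
    return out if out.ndim else float(out)


def angular_error(target_colour_deg, response_colour_deg):
    """Signed angular error (response - target) in degrees, in (-180, 180].

    Invariant under a common rotation of both angles on the wheel.
    """
    return wrap_signed_deg(
        np.asarray(response_colour_deg, dtype=float)
        - np.asarray(target_colour_deg, dtype=float)
    )


def deg2rad(x):
    return np.asarray(x, dtype=float) * (np.pi / 180.0)


def rad2deg(x):
    return np.asarray(x, dtype=float) * (180.0 / np.pi)
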