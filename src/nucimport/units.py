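"""Centralized unit conversions.

Internal convention: volumes in liters, concentrations in molar, amounts in
mol, embryo time in hours, droplet time in minutes, lengths in micrometers.
"""

import numpy as np

#: 1 cubic micrometer in liters.
UM3_TO_L = 1e-15

#: Molar to micromolar.
M_TO_UM = 1e6


def sphere_volume(diameter):
    """Volume of a sphere from its diameter (same cubed length units).

    Parameters
    ----------
    diameter : float or array-like
        Sphere diameter, must be non-negative.

    Returns
    -------
    float or ndarray
        pi * d**3 / 6.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        from ._exceptions import InvalidInput

        raise InvalidInput("sphere diameter must be non-negative")
    out = np.pi * d**3 / 6.0
    return float(out) if np.isscalar(diameter) else out


def um3_to_liters(volume_um3):
    """Convert a volume from cubic micrometers to liters."""
    return np.asarray(volume_um3, dtype=float) * UM3_TO_L
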