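"""Nuclear/cell geometry to NCV-ratio timecourse and import flux.

The embryo's developmental progression is tracked through the
nucleocytoplasmic volume ratio (NCV-ratio): total nuclear volume divided by
cell volume.  Nuclei are treated as spheres; the per-stage cell volume is the
embryo volume divided by the cell count.  A shape-preserving monotone spline
(PCHIP) of the aggregated observations provides the forward map time -> NCV,
its exact functional inverse NCV -> time (by cubic root solving on the same
spline, so the round trip is machine-precise), and the time derivative of the
total nuclear volume that drives the import flux

    F_total(t) = dV_nuc/dt * sum_i [P_i]

with negative local derivatives (measurement noise) clamped to zero: the
model describes net import during nuclear growth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._exceptions import FitFailure, InvalidInput
from .units import UM3_TO_L, sphere_volume

#: Reference embryo (fertilized frog egg) diameter in micrometers.
DEFAULT_EMBRYO_DIAMETER_UM = 1200.0

#: Fraction of the cytoplasmic volume accessible to protein; the remainder
#: is excluded by yolk and lipids.
DEFAULT_ACCESSIBLE_FRACTION = 0.30


@dataclass
class GeometryObservation:
    """One microscopy measurement of nuclear/cell geometry.

    Parameters
    ----------
    time_h : float
        Hours post fertilization (>= 0).
    nucleus_diameters : sequence of float
        Measured nucleus diameters in micrometers (> 0); typically a sample
        of nuclei from a representative sector.
    cell_count : int
        Number of cells (and nuclei) in the embryo at this time (>= 1).
    embryo_diameter : float
        Embryo diameter in micrometers; defaults to the reference egg size.
    replicate_id : str
    """

    time_h: float
    nucleus_diameters: list = field(default_factory=list)
    cell_count: int = 1
    embryo_diameter: float = DEFAULT_EMBRYO_DIAMETER_UM
    replicate_id: str = "r1"

    def __post_init__(self):
        if self.time_h < 0:
            raise InvalidInput(f"time must be >= 0, got {self.time_h}")
        if self.cell_count < 1:
            raise InvalidInput(f"cell_count must be >= 1, got {self.cell_count}")
        if len(self.nucleus_diameters) == 0:
            raise InvalidInput("at least one nucleus diameter is required")
        if any(d <= 0 for d in self.nucleus_diameters):
            raise InvalidInput("nucleus diameters must be positive")
        if self.embryo_diameter <= 0:
            raise InvalidInput("embryo diameter must be positive")

    @property
    def total_nuclear_volume_um3(self) -> float:
        """Cell count times the mean measured single-nucleus volume."""
        vols = sphere_volume(np.asarray(self.nucleus_diameters, dtype=float))
        return float(np.mean(vols) * self.cell_count)


def compute_ncv(observation: GeometryObservation, accessible_fraction: float = 1.0) -> float:
    """Nucleocytoplasmic volume ratio for one observation.

    Total nuclear volume over the embryo volume, the latter optionally scaled
    by the accessible cytoplasm fraction.  Scale-invariant: multiplying all
    lengths by a common factor leaves the ratio unchanged.
    """
    if not (0 < accessible_fraction <= 1):
        raise InvalidInput("accessible_fraction must be in (0, 1]")
    v_embryo = sphere_volume(observation.embryo_diameter) * accessible_fraction
    if v_embryo == 0:
        raise InvalidInput("embryo volume is zero")
    return observation.total_nuclear_volume_um3 / v_embryo


class MonotoneTimeMap:
    """Invertible monotone map between time and NCV-ratio plus nuclear volume.

    Built on shape-preserving piecewise-cubic Hermite interpolants through
    per-time aggregated observations.  ``inverse`` solves the forward cubic
    exactly, so ``inverse(forward(t)) == t`` to machine precision on the
    support.  Evaluation outside the observed time range clamps to the
    boundary values (no extrapolation).
    """

    def __init__(self, times_h, ncv_values, vnuc_liters):
        t = np.asarray(times_h, dtype=float)
        v = np.asarray(ncv_values, dtype=float)
        w = np.asarray(vnuc_liters, dtype=float)
        if t.size < 4:
            raise InvalidInput("need at least 4 distinct times")
        if np.any(np.diff(t) <= 0):
            raise InvalidInput("times must be strictly increasing")
        bad = t[np.where(np.diff(v) <= 0)[0] + 1]
        if bad.size:
            raise FitFailure(
                "aggregate NCV trend is not strictly increasing at the "
                f"observations at t = {bad.tolist()} h"
            )
        self.times = t
        self.ncv_values = v
        self.vnuc_liters = w
        self._ncv = PchipInterpolator(t, v, extrapolate=False)
        self._vnuc = PchipInterpolator(t, w, extrapolate=False)
        self._dvnuc = self._vnuc.derivative()

    @property
    def support(self):
        """(t_min, t_max) in hours."""
        return float(self.times[0]), float(self.times[-1])

    def _clamp_t(self, t):
        return np.clip(np.asarray(t, dtype=float), self.times[0], self.times[-1])

    def forward(self, t):
        """NCV-ratio at time ``t`` (hours); clamped outside the support."""
        out = self._ncv(self._clamp_t(t))
        return float(out) if np.isscalar(t) else out

    def vnuc(self, t):
        """Total nuclear volume in liters at time ``t``; clamped."""
        out = self._vnuc(self._clamp_t(t))
        return float(out) if np.isscalar(t) else out

    def dvnuc_dt(self, t):
        """d(V_nuc)/dt in liters/hour; zero outside the support."""
        tt = np.asarray(t, dtype=float)
        inside = (tt >= self.times[0]) & (tt <= self.times[-1])
        out = np.where(inside, self._dvnuc(self._clamp_t(tt)), 0.0)
        return float(out) if np.isscalar(t) else out

    def inverse(self, ncv):
        """Time (hours) at which the NCV-ratio equals ``ncv``.

        Values outside the fitted NCV range clamp to the boundary times.
        """
        scalar = np.isscalar(ncv)
        vals = np.atleast_1d(np.asarray(ncv, dtype=float))
        lo, hi = self.ncv_values[0], self.ncv_values[-1]
        out = np.empty_like(vals)
        for i, v in enumerate(vals):
            if v <= lo:
                out[i] = self.times[0]
            elif v >= hi:
                out[i] = self.times[-1]
            else:
                roots = self._ncv.solve(v, extrapolate=False)
                roots = roots[(roots >= self.times[0]) & (roots <= self.times[-1])]
                out[i] = roots[0]
        return float(out[0]) if scalar else out

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "times_h": self.times.tolist(),
            "ncv_ratio": self.ncv_values.tolist(),
            "total_nuclear_volume_l": self.vnuc_liters.tolist(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d) -> "MonotoneTimeMap":
        return cls(d["times_h"], d["ncv_ratio"], d["total_nuclear_volume_l"])

    @classmethod
    def from_json(cls, path) -> "MonotoneTimeMap":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_volume_map(
    observations,
    accessible_fraction: float = 1.0,
) -> MonotoneTimeMap:
    """Fit the monotone time <-> NCV map from geometry observations.

    Observations sharing a time (replicates) are averaged before fitting.
    Raises :class:`FitFailure` if the aggregated trend is non-monotone.
    """
    if len(observations) == 0:
        raise InvalidInput("no observations")
    by_time: dict = {}
    for obs in observations:
        by_time.setdefault(obs.time_h, []).append(obs)
    times = np.array(sorted(by_time), dtype=float)
    if times.size < 4:
        raise InvalidInput("need observations at >= 4 distinct times")
    ncv = np.array(
        [np.mean([compute_ncv(o, accessible_fraction) for o in by_time[t]]) for t in times]
    )
    vnuc = np.array(
        [np.mean([o.total_nuclear_volume_um3 for o in by_time[t]]) for t in times]
    ) * UM3_TO_L
    if np.any(ncv <= 0):
        raise InvalidInput("NCV values must be positive")
    return MonotoneTimeMap(times, ncv, vnuc)


def total_import_flux(volmap: MonotoneTimeMap, total_protein_concentration: float):
    """Total nuclear import flux F_total(t) in mol/hour.

    The rate of total nuclear volume increase times the total protein
    concentration; negative volume derivatives clamp to zero (with a
    warning the first time one is encountered).
    """
    if total_protein_concentration <= 0:
        raise InvalidInput("total protein concentration must be positive")
    warned = [False]

    def flux(t):
        dv = volmap.dvnuc_dt(t)
        neg = np.any(np.asarray(dv) < 0)
        if neg and not warned[0]:
            warned[0] = True
            warnings.warn("negative volume derivative clamped to zero in flux")
        out = np.clip(dv, 0.0, None) * total_protein_concentration
        return float(out) if np.isscalar(t) else out

    return flux
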