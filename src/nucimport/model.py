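"""Competitive nuclear-import model.

A limiting pool of importin (total concentration [I_0], constant in time)
is shared by n substrates under Langmuir competitive binding.  With
cytoplasmic concentrations [P_cyto,i] and dissociation constants K_Di, the
fraction of importin occupied by substrate i is

    theta_i = ([P_cyto,i]/K_Di) / (1 + sum_j [P_cyto,j]/K_Dj)

and the volume-driven total import flux

    F_total(t) = dV_nuc/dt * sum_k [P_k]

is partitioned among substrates by their occupancies:

    dP_nuc,i/dt = theta_i * F_total(t),      P_cyto,i = P_i - P_nuc,i.

High-affinity (small K_D) substrates monopolize importin early; as they
deplete from the cytoplasm, importin becomes available to weaker binders,
producing sequential nuclear entry.  Inert cytoplasmic species carry
K_D = inf and never import.  The same equations apply to embryos (flux from
the immunofluorescence-derived nuclear volume curve) and to encapsulated
droplets (flux from the droplet nuclear volume curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from ._exceptions import InvalidInput
from .volume import MonotoneTimeMap, total_import_flux

#: Default total importin concentration (molar).
DEFAULT_IMPORTIN_TOTAL_M = 1.5e-6

#: Default lognormal parameters of ln K_D (K_D in molar).
DEFAULT_KD_MU_LN = -18.0
DEFAULT_KD_SIGMA_LN = 2.0

#: Default embryo composition: 4,600 nuclear species at 44 nM each (~10% of
#: proteome mass) plus an inert cytoplasmic pool at 1.8 mM; ~2 mM total.
DEFAULT_N_NUCLEAR = 4600
DEFAULT_NUCLEAR_CONC_M = 44e-9
DEFAULT_CYTO_POOL_M = 1.8e-3

#: Fertilized frog egg volume (1.2 mm diameter sphere) in liters.
DEFAULT_EMBRYO_VOLUME_L = np.pi * 1200.0**3 / 6.0 * 1e-15


def sample_kd(
    n: int,
    mu_ln: float = DEFAULT_KD_MU_LN,
    sigma_ln: float = DEFAULT_KD_SIGMA_LN,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample dissociation constants: ln(K_D) ~ Normal(mu_ln, sigma_ln), molar."""
    if n < 1:
        raise InvalidInput("n must be >= 1")
    if sigma_ln < 0:
        raise InvalidInput("sigma_ln must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.exp(rng.normal(mu_ln, sigma_ln, size=n))


def importin_occupancy(cyto_concentrations, kd) -> np.ndarray:
    """Occupancy theta_i of total importin per substrate (Langmuir competition).

    Inert species (K_D = inf) get theta = 0.  Always 0 <= theta_i and
    sum(theta) <= 1.
    """
    c = np.asarray(cyto_concentrations, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(c < 0):
        raise InvalidInput("concentrations must be >= 0")
    if np.any(k <= 0):
        raise InvalidInput("K_D must be positive (inf allowed for inert species)")
    w = np.where(np.isinf(k), 0.0, c / k)
    return w / (1.0 + w.sum())


@dataclass
class ImportModelConfig:
    """Configuration of one competitive-import simulation.

    ``flux_source`` is either a :class:`~nucimport.volume.MonotoneTimeMap`
    (embryo regime) or any object with a ``dvnuc_dt(t)`` method and a
    ``support`` attribute (droplet regime; see :func:`droplet_flux_variant`).
    Concentrations are molar; the per-substrate amounts are
    [P_i] * V_embryo.
    """

    kd_m: np.ndarray
    total_concentrations_m: np.ndarray
    flux_source: object
    importin_total_m: float = DEFAULT_IMPORTIN_TOTAL_M
    embryo_volume_l: float = DEFAULT_EMBRYO_VOLUME_L
    substrate_ids: list = field(default_factory=list)
    rtol: float = 1e-6
    atol_m: float = 1e-12

    def __post_init__(self):
        self.kd_m = np.asarray(self.kd_m, dtype=float)
        self.total_concentrations_m = np.asarray(self.total_concentrations_m, dtype=float)
        if self.kd_m.shape != self.total_concentrations_m.shape:
            raise InvalidInput("kd and concentrations must have the same length")
        if np.any(self.total_concentrations_m < 0):
            raise InvalidInput("concentrations must be >= 0")
        if np.any(self.kd_m <= 0):
            raise InvalidInput("K_D must be positive or inf")
        if not self.substrate_ids:
            self.substrate_ids = [f"s{i}" for i in range(self.kd_m.size)]

    @property
    def n_substrates(self) -> int:
        return int(self.kd_m.size)

    @property
    def total_protein_concentration_m(self) -> float:
        return float(self.total_concentrations_m.sum())


def default_embryo_config(
    n_nuclear: int = DEFAULT_N_NUCLEAR,
    nuclear_conc_m: float | None = None,
    cyto_pool_m: float = DEFAULT_CYTO_POOL_M,
    volmap: MonotoneTimeMap | None = None,
    seed: int = 0,
) -> ImportModelConfig:
    """The default embryo configuration.

    ``n_nuclear`` nuclear species with lognormal K_D plus one inert
    cytoplasmic pool.  When ``n_nuclear`` differs from 4,600 the
    per-species concentration is scaled to preserve the nuclear proteome
    mass (10% of ~2 mM total), keeping the competition regime comparable.
    """
    if volmap is None:
        from .synth import default_embryo_volmap

        volmap = default_embryo_volmap()
    if nuclear_conc_m is None:
        nuclear_conc_m = DEFAULT_NUCLEAR_CONC_M * DEFAULT_N_NUCLEAR / n_nuclear
    kd = np.concatenate([sample_kd(n_nuclear, seed=seed), [np.inf]])
    conc = np.concatenate([np.full(n_nuclear, nuclear_conc_m), [cyto_pool_m]])
    ids = [f"nuc{i}" for i in range(n_nuclear)] + ["cyto_pool"]
    return ImportModelConfig(kd, conc, volmap, substrate_ids=ids)


@dataclass
class SimulationState:
    """Snapshot of the simulation at one time point."""

    time: float
    nuclear_amounts_mol: np.ndarray
    cytoplasmic_amounts_mol: np.ndarray
    occupancy: np.ndarray
    importin_total_m: float

    @property
    def bound_importin_m(self) -> np.ndarray:
        """[IP_cyto,i] = theta_i * [I_0] per substrate (molar)."""
        return self.occupancy * self.importin_total_m

    @property
    def free_importin_m(self) -> float:
        """[I] = [I_0] * (1 - sum theta_i) (molar)."""
        return float(self.importin_total_m * (1.0 - self.occupancy.sum()))


@dataclass
class SimulationResult:
    """Trajectories of a competitive-import simulation."""

    config: ImportModelConfig
    times: np.ndarray
    nuclear_amounts_mol: np.ndarray  # (n_times, n_substrates)

    @property
    def total_amounts_mol(self) -> np.ndarray:
        return self.config.total_concentrations_m * self.config.embryo_volume_l

    @property
    def nuclear_fraction(self) -> np.ndarray:
        """(n_times, n_substrates); NaN for zero-abundance species."""
        tot = self.total_amounts_mol
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(tot > 0, self.nuclear_amounts_mol / tot, np.nan)

    def state_at(self, index: int) -> SimulationState:
        p_nuc = self.nuclear_amounts_mol[index]
        p_cyto = np.clip(self.total_amounts_mol - p_nuc, 0.0, None)
        theta = importin_occupancy(p_cyto / self.config.embryo_volume_l, self.config.kd_m)
        return SimulationState(
            time=float(self.times[index]),
            nuclear_amounts_mol=p_nuc,
            cytoplasmic_amounts_mol=p_cyto,
            occupancy=theta,
            importin_total_m=self.config.importin_total_m,
        )


def simulate_import(
    config: ImportModelConfig,
    t_span: tuple | None = None,
    output_grid: np.ndarray | None = None,
    method: str = "RK45",
) -> SimulationResult:
    """Integrate dP_nuc,i/dt = theta_i * F_total(t).

    Adaptive explicit Runge-Kutta with the configured tolerances;
    deterministic given the config.  Cytoplasmic amounts are floored at
    zero inside the right-hand side (the occupancy vanishing as a substrate
    depletes makes this self-limiting).
    """
    lo, hi = config.flux_source.support
    if t_span is None:
        t_span = (lo, hi)
    if not (lo <= t_span[0] <= hi and lo <= t_span[1] <= hi):
        raise InvalidInput(f"t_span {t_span} outside the flux support [{lo}, {hi}]")
    if output_grid is None:
        output_grid = np.linspace(t_span[0], t_span[1], 200)
    flux = total_import_flux(config.flux_source, config.total_protein_concentration_m)
    tot_mol = config.total_concentrations_m * config.embryo_volume_l
    vol = config.embryo_volume_l
    kd = config.kd_m

    def rhs(t, p_nuc):
        c_cyto = np.clip(tot_mol - p_nuc, 0.0, None) / vol
        theta = importin_occupancy(c_cyto, kd)
        return theta * flux(t)

    sol = solve_ivp(
        rhs,
        t_span,
        y0=np.zeros(config.n_substrates),
        t_eval=output_grid,
        method=method,
        rtol=config.rtol,
        atol=config.atol_m * vol,
    )
    if not sol.success:  # pragma: no cover - solver diagnostics path
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    p = np.clip(sol.y.T, 0.0, None)
    p = np.minimum(p, tot_mol[None, :])
    return SimulationResult(config=config, times=sol.t, nuclear_amounts_mol=p)


def entry_half_time(result: SimulationResult) -> np.ndarray:
    """First time each substrate's nuclear fraction crosses 0.5 (hours).

    Linear interpolation between grid points; NaN when the fraction never
    crosses 0.5 within the simulated window.
    """
    frac = result.nuclear_fraction
    t = result.times
    out = np.full(result.config.n_substrates, np.nan)
    for i in range(frac.shape[1]):
        f = frac[:, i]
        above = np.nonzero(f >= 0.5)[0]
        if above.size == 0 or not np.isfinite(f).all():
            continue
        j = above[0]
        if j == 0:
            out[i] = t[0]
        else:
            f0, f1 = f[j - 1], f[j]
            out[i] = t[j - 1] + (0.5 - f0) / (f1 - f0) * (t[j] - t[j - 1])
    return out


def nuclear_concentration_profiles(result: SimulationResult) -> tuple[np.ndarray, np.ndarray]:
    """Nuclear concentration [nuclear]_i(t) = P_nuc,i(t) / V_nuc(t) and peak times.

    Requires V_nuc > 0 on the whole output grid (start after the first
    nucleus forms).  Returns (concentrations (n_times, n), peak_times (n,)).
    """
    vnuc = np.asarray(result.config.flux_source.vnuc(result.times), dtype=float)
    if np.any(vnuc <= 0):
        raise InvalidInput("nuclear volume must be positive on the output grid")
    conc = result.nuclear_amounts_mol / vnuc[:, None]
    peak_times = result.times[np.argmax(conc, axis=0)]
    return conc, peak_times


class DropletVolumeCurve:
    """Nuclear volume curve of an encapsulated droplet, usable as a flux source.

    Wraps a monotone non-decreasing V_nuc(t) sampled on a grid (time in the
    droplet assay's native minutes or in hours — the flux inherits the
    unit).  Provides the same ``support`` / ``vnuc`` / ``dvnuc_dt`` surface
    as :class:`~nucimport.volume.MonotoneTimeMap`.
    """

    def __init__(self, times, vnuc_liters):
        from scipy.interpolate import PchipInterpolator

        t = np.asarray(times, dtype=float)
        v = np.asarray(vnuc_liters, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidInput("times must be strictly increasing")
        if np.any(np.diff(v) < 0):
            raise InvalidInput("droplet nuclear volume must be non-decreasing")
        self.times = t
        self._v = PchipInterpolator(t, v, extrapolate=False)
        self._dv = self._v.derivative()

    @property
    def support(self):
        return float(self.times[0]), float(self.times[-1])

    def vnuc(self, t):
        out = self._v(np.clip(t, self.times[0], self.times[-1]))
        return float(out) if np.isscalar(t) else out

    def dvnuc_dt(self, t):
        tt = np.asarray(t, dtype=float)
        inside = (tt >= self.times[0]) & (tt <= self.times[-1])
        out = np.where(inside, self._dv(np.clip(tt, self.times[0], self.times[-1])), 0.0)
        return float(out) if np.isscalar(t) else out


def droplet_flux_variant(curve: DropletVolumeCurve, total_protein_concentration_m: float):
    """Import flux from a droplet nuclear-volume curve (same construction as the embryo)."""
    return total_import_flux(curve, total_protein_concentration_m)


def euler_oracle(config: ImportModelConfig, t_span, output_grid, dt: float = 1e-3):
    """Fixed-step explicit Euler reference integration (small n only).

    Independent of :func:`simulate_import`'s adaptive solver; used to
    cross-check trajectories.
    """
    flux = total_import_flux(config.flux_source, config.total_protein_concentration_m)
    tot_mol = config.total_concentrations_m * config.embryo_volume_l
    vol = config.embryo_volume_l
    t0, t1 = t_span
    n_steps = int(np.ceil((t1 - t0) / dt))
    t = t0
    p = np.zeros(config.n_substrates)
    grid = np.asarray(output_grid, dtype=float)
    out = np.zeros((grid.size, config.n_substrates))
    gi = 0
    for _ in range(n_steps + 1):
        while gi < grid.size and grid[gi] <= t + 1e-12:
            out[gi] = p
            gi += 1
        h = min(dt, t1 - t)
        if h <= 0:
            break
        c_cyto = np.clip(tot_mol - p, 0.0, None) / vol
        theta = importin_occupancy(c_cyto, config.kd_m)
        p = np.minimum(p + h * theta * flux(t), tot_mol)
        t += h
    while gi < grid.size:
        out[gi] = p
        gi += 1
    return SimulationResult(config=config, times=grid, nuclear_amounts_mol=out)
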