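"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the study conditions of the embryo assays: an
exponentially increasing nucleocytoplasmic volume ratio during cleavage,
sigmoidal nuclear-fraction trajectories sampled over 18 timepoints in 5
replicates with multiplicative lognormal channel noise, linear RanQ69L
bound-fraction decays from 0.5, droplet frames with a disk nucleus whose
intensity follows a rising RNC sigmoid, lognormal K_D substrate sets, and
protein complexes whose members share entry times.  Each generator is a
pure function of its parameters and the seed, and returns a
:class:`GroundTruth` sidecar describing the planted values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .coherence import ComplexCatalog
from .droplet import DropletFrame, DropletTrace
from .nuclear_fraction import FractionationSignalTable
from .affinity import TitrationTable
from .units import sphere_volume
from .volume import (
    DEFAULT_EMBRYO_DIAMETER_UM,
    GeometryObservation,
    MonotoneTimeMap,
    fit_volume_map,
)

# Study conditions of the default synthetic embryo: the NCV-ratio rises
# exponentially from ~1e-5 shortly after fertilization to ~4e-2 (the oocyte
# value) over the first ~45 h at 16 C, while cell counts double roughly
# every 3.3 h and nuclei shrink from ~30 um to ~18 um diameter.
NCV_AT_FERTILIZATION = 1.2e-5
NCV_GROWTH_PER_H = 0.18
GEOMETRY_T_START_H = 2.0
GEOMETRY_T_END_H = 45.0
CELL_DOUBLING_H = 3.3
MAX_CELL_COUNT = 16384


@dataclass
class GroundTruth:
    """Planted parameter values serialized alongside every generated dataset."""

    seed: int
    params: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def save(self, path):
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "params": _clean(self.params), "values": _clean(self.values)},
                fh,
                indent=1,
            )


def generate_geometry(
    n_timepoints: int = 18,
    t_start_h: float = GEOMETRY_T_START_H,
    t_end_h: float = GEOMETRY_T_END_H,
    ncv0: float = NCV_AT_FERTILIZATION,
    growth_per_h: float = NCV_GROWTH_PER_H,
    replicates: int = 1,
    diameter_noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[list[GeometryObservation], GroundTruth]:
    """Geometry observations following an exponential NCV-ratio trajectory.

    Cell counts double every ``CELL_DOUBLING_H`` (capped), and nucleus
    diameters are back-computed so the total nuclear volume matches the
    target NCV(t) = ncv0 * exp(growth * t) of the whole embryo volume.
    Optional multiplicative noise on the measured diameters per replicate.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(t_start_h, t_end_h, n_timepoints)
    v_embryo = sphere_volume(DEFAULT_EMBRYO_DIAMETER_UM)
    obs = []
    truth_d = {}
    for t in times:
        count = int(min(2 ** np.floor(t / CELL_DOUBLING_H), MAX_CELL_COUNT))
        v_total = ncv0 * np.exp(growth_per_h * t) * v_embryo
        d_true = (6.0 * v_total / count / np.pi) ** (1.0 / 3.0)
        truth_d[float(t)] = {"cell_count": count, "nucleus_diameter_um": d_true}
        for r in range(replicates):
            n_measured = min(count, 10)
            noise = (
                rng.normal(0.0, diameter_noise_cv, size=n_measured)
                if diameter_noise_cv > 0
                else np.zeros(n_measured)
            )
            obs.append(
                GeometryObservation(
                    time_h=float(t),
                    nucleus_diameters=list(d_true * (1.0 + noise)),
                    cell_count=count,
                    replicate_id=f"r{r + 1}",
                )
            )
    truth = GroundTruth(
        seed=seed,
        params={
            "ncv0": ncv0,
            "growth_per_h": growth_per_h,
            "t_start_h": t_start_h,
            "t_end_h": t_end_h,
            "diameter_noise_cv": diameter_noise_cv,
        },
        values={"per_time": truth_d},
    )
    return obs, truth


@lru_cache(maxsize=1)
def default_embryo_volmap() -> MonotoneTimeMap:
    """The default noiseless synthetic embryo volume map (cached)."""
    obs, _ = generate_geometry(n_timepoints=40, diameter_noise_cv=0.0, seed=0)
    return fit_volume_map(obs)


def generate_embryo_proteomics(
    n_proteins: int = 200,
    n_timepoints: int = 18,
    replicates: int = 5,
    noise_cv: float = 0.05,
    background_fraction: float = 0.02,
    t_half_range_h: tuple = (10.0, 40.0),
    volmap: MonotoneTimeMap | None = None,
    true_t_half_h: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[FractionationSignalTable, dict, GroundTruth]:
    """Fractionation signal table with planted sigmoidal NF trajectories.

    True T_embryo1/2 values are drawn uniformly over ``t_half_range_h``
    (or supplied), converted to midpoint NCVs through the volume map, and
    the resulting NF sigmoids are turned into supernatant / flow-through
    signals with a planted cytoplasmic-retention background (a constant
    fraction of each protein's signal retained in every supernatant,
    emulating what the 2-cell-stage subtraction removes) and multiplicative
    lognormal noise.

    Returns (table, oocyte_nf dict, ground truth).  The earliest stage is
    the background-reference (2-cell analog) stage, labeled "s01".
    """
    if volmap is None:
        volmap = default_embryo_volmap()
    rng = np.random.default_rng(seed)
    if true_t_half_h is None:
        true_t_half_h = rng.uniform(*t_half_range_h, size=n_proteins)
    else:
        true_t_half_h = np.asarray(true_t_half_h, dtype=float)
        n_proteins = true_t_half_h.size
    v_half = np.asarray(volmap.forward(true_t_half_h))
    kappa = rng.uniform(3.0, 8.0, size=n_proteins)
    k = kappa / v_half
    oocyte_nf = rng.uniform(0.6, 0.95, size=n_proteins)
    total_signal = np.exp(rng.normal(0.0, 0.3, size=n_proteins))
    pids = [f"p{i:04d}" for i in range(n_proteins)]

    times = np.linspace(GEOMETRY_T_START_H, GEOMETRY_T_END_H, n_timepoints)
    stages = [f"s{i + 1:02d}" for i in range(n_timepoints)]
    stage_times = dict(zip(stages, times.tolist()))
    ncv = np.asarray(volmap.forward(times))
    # NF(v) = oocyte_nf / (1 + exp(-k (v - v_half))) per protein x stage
    nf = oocyte_nf[:, None] / (1.0 + np.exp(-k[:, None] * (ncv[None, :] - v_half[:, None])))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    cols, data = [], []
    for j, stage in enumerate(stages):
        for rep in range(replicates):
            rlab = f"r{rep + 1}"
            noise_sup = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_proteins))
            noise_flo = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_proteins))
            sup = (nf[:, j] + background_fraction) * total_signal * noise_sup
            flo = (1.0 - nf[:, j]) * total_signal * noise_flo
            cols += [(stage, "supernatant", rlab), (stage, "flow_through", rlab)]
            data += [sup, flo]
    df = pd.DataFrame(
        np.column_stack(data),
        index=pd.Index(pids, name="protein_id"),
        columns=pd.MultiIndex.from_tuples(cols, names=["stage", "compartment", "replicate"]),
    )
    table = FractionationSignalTable(df, stage_times)
    oo = dict(zip(pids, oocyte_nf.tolist()))
    truth = GroundTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "n_timepoints": n_timepoints,
            "replicates": replicates,
            "noise_cv": noise_cv,
            "background_fraction": background_fraction,
        },
        values={
            "protein_id": pids,
            "t_half_h": true_t_half_h,
            "midpoint_ncv": v_half,
            "steepness": k,
            "oocyte_nf": oocyte_nf,
        },
    )
    return table, oo, truth


def generate_titration(
    n_proteins: int = 300,
    n_background: int = 30,
    ran_levels: tuple = (0.0, 1.0, 2.0, 4.0, 7.0, 10.0),
    replicates: int = 3,
    fraction_noise_sd: float = 0.03,
    max_slope: float = 0.05,
    kd_mu_ln: float = -18.0,
    kd_sigma_ln: float = 2.0,
    t_half_noise_sd_h: float = 5.0,
    seed: int = 0,
) -> tuple[TitrationTable, GroundTruth]:
    """RanQ69L titration table with slopes coupled to a planted ln K_D.

    Each substrate's affinity slope is a monotone (logistic) map of its
    ln K_D into (-max_slope, 0); background proteins have slope 0.  Bound
    fractions 0.5 + m*x + noise (clipped to [0, 1]) are converted back to
    pulldown signals with the level-0 signal drawn lognormally.  The
    planted T_embryo1/2 shares the ln K_D latent (plus noise), so the
    generative affinity <-> entry-time coupling is known.
    """
    if 0.0 not in ran_levels:
        raise ValueError("ran_levels must include 0")
    rng = np.random.default_rng(seed)
    ln_kd = rng.normal(kd_mu_ln, kd_sigma_ln, size=n_proteins)
    z = (ln_kd - kd_mu_ln) / kd_sigma_ln
    slopes = -max_slope / (1.0 + np.exp(z))  # high affinity (low K_D) -> steep decay
    t_half = 25.0 + 5.0 * z + rng.normal(0.0, t_half_noise_sd_h, size=n_proteins)
    pids = [f"p{i:04d}" for i in range(n_proteins)]
    bids = [f"bg{i:03d}" for i in range(n_background)]
    all_ids = pids + bids
    all_slopes = np.concatenate([slopes, np.zeros(n_background)])
    rows = []
    for i, pid in enumerate(all_ids):
        for rep in range(replicates):
            s0 = float(np.exp(rng.normal(0.0, 0.3)))
            for x in ran_levels:
                if x == 0:
                    rows.append((pid, f"r{rep + 1}", x, s0))
                    continue
                f = np.clip(
                    0.5 + all_slopes[i] * x + rng.normal(0.0, fraction_noise_sd),
                    1e-3,
                    1.0 - 1e-3,
                )
                rows.append((pid, f"r{rep + 1}", x, s0 * f / (1.0 - f)))
    df = pd.DataFrame(rows, columns=["protein_id", "replicate", "ran_level", "signal"])
    table = TitrationTable(df, background_ids=set(bids))
    truth = GroundTruth(
        seed=seed,
        params={
            "n_proteins": n_proteins,
            "n_background": n_background,
            "ran_levels": list(ran_levels),
            "replicates": replicates,
            "fraction_noise_sd": fraction_noise_sd,
            "max_slope": max_slope,
        },
        values={
            "protein_id": pids,
            "ln_kd": ln_kd,
            "slope": slopes,
            "t_half_h": t_half[: len(pids)],
        },
    )
    return table, truth


def _rnc_sigmoid(t, t_half, plateau, rate):
    return 0.5 + (plateau - 0.5) / (1.0 + np.exp(-rate * (t - t_half)))


def generate_droplet_traces(
    probe_delta_t_min: dict | None = None,
    n_droplets: int = 6,
    t_end_min: float = 120.0,
    frame_interval_min: float = 2.0,
    reference_t_half_min: float = 30.0,
    droplet_offset_range_min: float = 10.0,
    plateau: float = 0.9,
    rate_per_min: float = 0.2,
    rnc_noise_sd: float = 0.01,
    seed: int = 0,
) -> tuple[dict, GroundTruth]:
    """Pre-extracted RNC traces for a cohort of probes with planted delays.

    For each probe (name -> planted dT in minutes) and droplet, both
    channels share a droplet-level timing offset (uniform within
    +/- ``droplet_offset_range_min``) that cancels in the per-droplet dT.
    Frames every 2 minutes.  Returns {probe: [DropletTrace, ...]} and the
    ground truth.
    """
    if probe_delta_t_min is None:
        probe_delta_t_min = {f"probe{i}": 4.0 * i for i in range(9)}
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_end_min + frame_interval_min / 2, frame_interval_min)
    out = {}
    truth_v = {}
    for probe, dt in probe_delta_t_min.items():
        traces = []
        for d in range(n_droplets):
            offset = rng.uniform(-droplet_offset_range_min, droplet_offset_range_min)
            th_ref = reference_t_half_min + offset
            th_pro = th_ref + dt
            rnc_ref = _rnc_sigmoid(times, th_ref, plateau, rate_per_min)
            rnc_pro = _rnc_sigmoid(times, th_pro, plateau, rate_per_min)
            if rnc_noise_sd > 0:
                rnc_ref = np.clip(rnc_ref + rng.normal(0, rnc_noise_sd, times.size), 0, 1)
                rnc_pro = np.clip(rnc_pro + rng.normal(0, rnc_noise_sd, times.size), 0, 1)
            traces.append(
                DropletTrace(
                    droplet_id=f"{probe}_d{d}",
                    time_min=times.copy(),
                    rnc={"reference": rnc_ref, "probe": rnc_pro},
                )
            )
        out[probe] = traces
        truth_v[probe] = {"delta_t_half_min": dt}
    truth = GroundTruth(
        seed=seed,
        params={
            "n_droplets": n_droplets,
            "frame_interval_min": frame_interval_min,
            "reference_t_half_min": reference_t_half_min,
            "plateau": plateau,
            "rate_per_min": rate_per_min,
            "rnc_noise_sd": rnc_noise_sd,
        },
        values=truth_v,
    )
    return out, truth


def generate_droplet_frames(
    times_min: np.ndarray | None = None,
    reference_t_half_min: float = 24.0,
    probe_delta_t_min: float = 12.0,
    plateau: float = 0.9,
    rate_per_min: float = 0.2,
    image_size_px: int = 96,
    nucleus_radius_px: tuple = (6.0, 14.0),
    cyto_intensity: float = 100.0,
    noise_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[DropletFrame], GroundTruth]:
    """Two-channel droplet frames with a disk nucleus and planted RNC sigmoids.

    The whole frame is cytoplasm at constant intensity; a centered disk
    nucleus grows linearly in radius while its intensity follows the
    planted per-channel RNC trajectory (nuclear mean = c * RNC/(1 - RNC)).
    Gaussian read noise with standard deviation ``noise_fraction`` times
    the nucleus/cytoplasm contrast (floored at 1% of the cytoplasm level).
    """
    if times_min is None:
        times_min = np.arange(0.0, 61.0, 2.0)
    rng = np.random.default_rng(seed)
    h = image_size_px
    yy, xx = np.mgrid[0:h, 0:h]
    c0 = (h - 1) / 2.0
    r_lo, r_hi = nucleus_radius_px
    frames = []
    rnc_truth = {"reference": [], "probe": []}
    for i, t in enumerate(times_min):
        frac = i / max(len(times_min) - 1, 1)
        radius = r_lo + (r_hi - r_lo) * frac
        mask = (yy - c0) ** 2 + (xx - c0) ** 2 <= radius**2
        chans = {}
        for name, th in (
            ("reference", reference_t_half_min),
            ("probe", reference_t_half_min + probe_delta_t_min),
        ):
            rnc = float(np.clip(_rnc_sigmoid(t, th, plateau, rate_per_min), 0.0, 0.95))
            rnc_truth[name].append(rnc)
            nuc = cyto_intensity * rnc / (1.0 - rnc)
            img = np.full((h, h), cyto_intensity)
            img[mask] = nuc
            if noise_fraction > 0:
                sd = max(noise_fraction * abs(nuc - cyto_intensity), 0.01 * cyto_intensity)
                img = np.clip(img + rng.normal(0.0, sd, img.shape), 0.0, None)
            chans[name] = img
        frames.append(DropletFrame(time_min=float(t), reference=chans["reference"], probe=chans["probe"]))
    truth = GroundTruth(
        seed=seed,
        params={
            "reference_t_half_min": reference_t_half_min,
            "probe_delta_t_min": probe_delta_t_min,
            "plateau": plateau,
            "rate_per_min": rate_per_min,
            "image_size_px": image_size_px,
            "nucleus_radius_px": list(nucleus_radius_px),
            "noise_fraction": noise_fraction,
        },
        values={
            "times_min": np.asarray(times_min),
            "rnc_reference": np.asarray(rnc_truth["reference"]),
            "rnc_probe": np.asarray(rnc_truth["probe"]),
        },
    )
    return frames, truth


def generate_complex_catalog(
    n_complexes: int = 50,
    size_range: tuple = (5, 10),
    coherence: float = 0.9,
    pool_mean_h: float = 25.0,
    pool_sd_h: float = 7.0,
    n_extra_pool: int = 200,
    seed: int = 0,
) -> tuple[ComplexCatalog, pd.Series, GroundTruth]:
    """Complex catalog whose members share entry times to a tunable degree.

    Within-complex SD equals (1 - coherence) * pool SD; complex centers are
    dispersed so that every member's marginal entry-time distribution
    matches the pool (coherence 0 therefore reproduces the null exactly).
    Returns (catalog, t_half series over members plus extra pool proteins,
    ground truth).
    """
    if not (0.0 <= coherence <= 1.0):
        raise ValueError("coherence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    within_sd = (1.0 - coherence) * pool_sd_h
    center_sd = np.sqrt(max(pool_sd_h**2 - within_sd**2, 0.0))
    members = {}
    t_half = {}
    centers = {}
    pid = 0
    for c in range(n_complexes):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        center = pool_mean_h + center_sd * rng.standard_normal()
        ids = []
        for _ in range(size):
            name = f"m{pid:04d}"
            t_half[name] = center + within_sd * rng.standard_normal()
            ids.append(name)
            pid += 1
        members[f"cplx{c:03d}"] = ids
        centers[f"cplx{c:03d}"] = center
    for i in range(n_extra_pool):
        t_half[f"x{i:04d}"] = pool_mean_h + pool_sd_h * rng.standard_normal()
    catalog = ComplexCatalog(members)
    truth = GroundTruth(
        seed=seed,
        params={
            "n_complexes": n_complexes,
            "size_range": list(size_range),
            "coherence": coherence,
            "pool_mean_h": pool_mean_h,
            "pool_sd_h": pool_sd_h,
            "within_sd_h": within_sd,
        },
        values={"complex_centers_h": centers},
    )
    return catalog, pd.Series(t_half, name="t_half_h"), truth
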