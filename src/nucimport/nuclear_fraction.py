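"""Per-protein nuclear fractions and entry-time sigmoid fits.

The nuclear filtration assay splits embryonic lysate into a nuclei-enriched
supernatant and a nuclear-depleted flow-through; multiplexed proteomics
yields a relative signal for every protein in both compartments at every
developmental stage.  The nuclear fraction is

    NF = S_sup / (S_sup + S_flow)

after subtracting the 2-cell-stage supernatant signal (negligible nuclear
amounts, so it measures cytoplasmic retention on the filter) from all other
supernatant measurements.  NF is fitted as a bounded logistic of the
NCV-ratio, with the upper asymptote pinned to the oocyte nuclear fraction
and the midpoint constrained to [0, 1]; the fitted midpoint, mapped back
through the time <-> NCV spline, gives T_embryo1/2 — the time post
fertilization (16 C) at which half of the protein has entered embryonic
nuclei.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._exceptions import ConfigurationError, InvalidInput
from .volume import MonotoneTimeMap

#: Midpoint seeds for the deterministic multi-start of the sigmoid fit.
MIDPOINT_SEEDS = (0.001, 0.01, 0.1, 0.5, 0.9)

#: NF range below which no transition is observable and the fit is degenerate.
DEGENERATE_NF_RANGE = 0.05


@dataclass
class FractionationSignalTable:
    """Relative MS signals of the filtration assay.

    Parameters
    ----------
    signals : pandas.DataFrame
        Index: protein_id.  Columns: MultiIndex (stage, compartment,
        replicate) with compartment in {"supernatant", "flow_through"}.
        Values are non-negative relative signals; NaN marks a missing
        measurement.
    stage_times_h : dict
        stage label -> hours post fertilization.
    """

    signals: pd.DataFrame
    stage_times_h: dict

    def __post_init__(self):
        cols = self.signals.columns
        if cols.nlevels != 3:
            raise InvalidInput("columns must be (stage, compartment, replicate)")
        comps = set(cols.get_level_values(1))
        if not comps <= {"supernatant", "flow_through"}:
            raise InvalidInput(f"unknown compartments: {comps}")
        vals = self.signals.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise InvalidInput("signals must be non-negative")
        for stage in cols.get_level_values(0).unique():
            sub = cols[cols.get_level_values(0) == stage]
            if {"supernatant", "flow_through"} - set(sub.get_level_values(1)):
                raise InvalidInput(f"stage {stage!r} lacks one compartment")
            if stage not in self.stage_times_h:
                raise InvalidInput(f"no time annotation for stage {stage!r}")

    @property
    def stages(self):
        return list(self.signals.columns.get_level_values(0).unique())


@dataclass
class NuclearFractionSeries:
    """NF observations for one protein, annotated with NCV and time."""

    protein_id: str
    ncv_ratio: np.ndarray
    time_h: np.ndarray
    nf: np.ndarray
    replicate_id: np.ndarray
    oocyte_nf: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.oocyte_nf <= 1.0):
            raise InvalidInput("oocyte_nf must lie in [0, 1]")


@dataclass
class EntrySigmoidFit:
    """Bounded logistic fit of NF against NCV-ratio.

    ``status`` is "ok", "degenerate" (no observable transition) or
    "failed"; ``t_half_embryo_h`` is defined only for "ok" fits after
    :func:`t_half_from_fit`.
    """

    protein_id: str
    midpoint_ncv: float = np.nan
    steepness: float = np.nan
    upper_asymptote: float = np.nan
    residual_rms: float = np.nan
    status: str = "failed"
    t_half_embryo_h: float = field(default=np.nan)


def background_correct(
    table: FractionationSignalTable, reference_stage: str
) -> FractionationSignalTable:
    """Subtract the reference-stage supernatant signal per protein.

    The 2-cell-stage supernatant carries essentially no nuclei, so its
    signal estimates cytoplasmic retention on the filter.  It is subtracted
    from every supernatant column (per replicate when the replicate measured
    the reference stage, otherwise the across-replicate mean), negatives
    clip to zero, and the flow-through is untouched.  The reference stage is
    retained with corrected supernatant zero.
    """
    if reference_stage not in table.stages:
        raise ConfigurationError(f"reference stage {reference_stage!r} not in table")
    df = table.signals.copy()
    sup = df.xs("supernatant", axis=1, level=1, drop_level=False)
    ref = sup.xs(reference_stage, axis=1, level=0, drop_level=False)
    ref_by_rep = {
        rep: ref[(reference_stage, "supernatant", rep)]
        for rep in ref.columns.get_level_values(2)
    }
    ref_mean = ref.mean(axis=1)
    for stage, comp, rep in sup.columns:
        baseline = ref_by_rep.get(rep, ref_mean)
        df[(stage, comp, rep)] = (df[(stage, comp, rep)] - baseline).clip(lower=0.0)
    return FractionationSignalTable(df, dict(table.stage_times_h))


def compute_nf(
    table: FractionationSignalTable,
    volmap: MonotoneTimeMap,
    oocyte_nf: dict | float = 1.0,
) -> list[NuclearFractionSeries]:
    """Nuclear fraction series per protein from a background-corrected table.

    NF = S_sup / (S_sup + S_flow) per stage and replicate; a stage where
    both signals are zero (or either is missing) yields a missing point
    rather than zero.  Stages are annotated with their NCV-ratio through the
    volume map.
    """
    out = []
    cols = table.signals.columns
    pairs = sorted(
        {(s, r) for s, c, r in cols if (s, "supernatant", r) in cols and (s, "flow_through", r) in cols}
    )
    for pid, row in table.signals.iterrows():
        ncv, t, nf, rep = [], [], [], []
        for stage, r in pairs:
            s_sup = row.get((stage, "supernatant", r), np.nan)
            s_flo = row.get((stage, "flow_through", r), np.nan)
            if np.isnan(s_sup) or np.isnan(s_flo) or (s_sup + s_flo) == 0:
                continue
            time = table.stage_times_h[stage]
            ncv.append(volmap.forward(time))
            t.append(time)
            nf.append(s_sup / (s_sup + s_flo))
            rep.append(r)
        oo = oocyte_nf.get(pid, np.nan) if isinstance(oocyte_nf, dict) else oocyte_nf
        out.append(
            NuclearFractionSeries(
                protein_id=str(pid),
                ncv_ratio=np.asarray(ncv),
                time_h=np.asarray(t),
                nf=np.asarray(nf),
                replicate_id=np.asarray(rep, dtype=object),
                oocyte_nf=float(oo) if np.isfinite(oo) else 1.0,
            )
        )
    return out


def _sigmoid(v, v_half, k, upper):
    return upper / (1.0 + np.exp(-k * (v - v_half)))


def fit_entry_sigmoid(series: NuclearFractionSeries) -> EntrySigmoidFit:
    """Fit NF(v) = oocyte_nf / (1 + exp(-k (v - v_half))) over all replicates.

    v_half is hard-bounded to [0, 1] and k > 0.  Deterministic multi-start
    bounded least squares from the midpoint seeds; replicate points are
    pooled into a single fit.  Returns status "failed" when fewer than 4
    points or fewer than 2 distinct NCV values are available, "degenerate"
    when the observed NF range is below 0.05.
    """
    fit = EntrySigmoidFit(protein_id=series.protein_id)
    v = np.asarray(series.ncv_ratio, dtype=float)
    y = np.asarray(series.nf, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    if v.size < 4 or np.unique(v).size < 2:
        return fit
    if np.ptp(y) < DEGENERATE_NF_RANGE:
        fit.status = "degenerate"
        return fit
    upper = series.oocyte_nf
    vspan = max(np.ptp(v), np.max(v) * 1e-3, 1e-12)

    def resid(p):
        return _sigmoid(v, p[0], p[1], upper) - y

    best = None
    for seed in MIDPOINT_SEEDS:
        for k0 in (4.0 / vspan, 4.0 / max(seed, 1e-6)):
            try:
                sol = least_squares(
                    resid,
                    x0=[seed, k0],
                    bounds=([0.0, 1e-3], [1.0, 1e9]),
                    method="trf",
                )
            except Exception:  # pragma: no cover - optimizer edge cases
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        return fit
    fit.midpoint_ncv = float(best.x[0])
    fit.steepness = float(best.x[1])
    fit.upper_asymptote = float(upper)
    fit.residual_rms = float(np.sqrt(np.mean(best.fun**2)))
    fit.status = "ok"
    return fit


def t_half_from_fit(fit: EntrySigmoidFit, volmap: MonotoneTimeMap) -> float:
    """Convert a fitted midpoint NCV to T_embryo1/2 in hours.

    Midpoints outside the fitted NCV support clamp to the boundary time
    with a warning.  Degenerate or failed fits yield NaN.
    """
    if fit.status != "ok":
        return np.nan
    lo, hi = volmap.ncv_values[0], volmap.ncv_values[-1]
    if not (lo <= fit.midpoint_ncv <= hi):
        warnings.warn(
            f"{fit.protein_id}: midpoint NCV {fit.midpoint_ncv:.3g} outside the "
            "volume-map support; clamped to the boundary"
        )
    t = float(volmap.inverse(fit.midpoint_ncv))
    fit.t_half_embryo_h = t
    return t


def fit_cohort(
    series_list,
    volmap: MonotoneTimeMap,
) -> pd.DataFrame:
    """Fit every series and tabulate midpoints and T_embryo1/2.

    Returns a DataFrame indexed by protein_id with columns midpoint_ncv,
    steepness, oocyte_nf, t_half_h, residual_rms, status.
    """
    rows = {}
    for s in series_list:
        f = fit_entry_sigmoid(s)
        t = t_half_from_fit(f, volmap) if f.status == "ok" else np.nan
        rows[s.protein_id] = {
            "midpoint_ncv": f.midpoint_ncv,
            "steepness": f.steepness,
            "oocyte_nf": f.upper_asymptote,
            "t_half_h": t,
            "residual_rms": f.residual_rms,
            "status": f.status,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "protein_id"
    return df
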