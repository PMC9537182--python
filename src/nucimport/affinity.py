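"""Importin-affinity proxies from RanQ69L titration pulldowns.

RanQ69L (a GTP-locked Ran mutant) releases substrates from importin beta,
so a protein's pulldown signal decays with the added RanQ69L amount in
proportion to its Ran-sensitive (genuine) importin binding.  Per condition
the bound fraction is

    f(x) = S(x) / (S(x) + S(0))

(signal with RanQ69L level x over the sum with the no-Ran condition), which
is 0.5 at x = 0 by construction; a linear fit f = 0.5 + m*x with the
intercept fixed at 0.5 yields the slope m, the per-replicate affinity
proxy (more negative = tighter importin binding).  Triplicate slopes are
integrated into a single importin-affinity proxy by 10-fold cross-validated
canonical correlation analysis against T_embryo1/2.  A robust binned
power-law regression calibrates absolute protein concentrations from
normalized log ion signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.cross_decomposition import CCA

from ._exceptions import ConfigurationError, FitFailure, InvalidInput


@dataclass
class TitrationTable:
    """Long-format pulldown signals across RanQ69L levels and replicates.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns: protein_id, replicate, ran_level (normalized added RanQ69L
        amount, >= 0, with level 0 present per replicate), signal (>= 0).
        Optional column bait_signal gives the per-condition importin/IgG
        carrier signal for loading normalization.
    background_ids : set
        Proteins known not to interact with importin (glycolytic enzymes,
        mitochondrial proteins, ...), used for renormalization.
    """

    data: pd.DataFrame
    background_ids: set = field(default_factory=set)

    def __post_init__(self):
        req = {"protein_id", "replicate", "ran_level", "signal"}
        if not req <= set(self.data.columns):
            raise InvalidInput(f"titration table needs columns {sorted(req)}")
        if (self.data["signal"].dropna() < 0).any():
            raise InvalidInput("signals must be non-negative")
        if (self.data["ran_level"] < 0).any():
            raise InvalidInput("ran levels must be non-negative")
        for rep, grp in self.data.groupby("replicate"):
            if 0 not in set(grp["ran_level"]):
                raise InvalidInput(f"replicate {rep!r} lacks the RanQ69L = 0 condition")


def bound_fraction(signal_with_ran: float, signal_without_ran: float) -> float:
    """f = S_ran / (S_ran + S_noran); NaN when both signals are zero."""
    if signal_with_ran < 0 or signal_without_ran < 0:
        raise InvalidInput("signals must be non-negative")
    tot = signal_with_ran + signal_without_ran
    if tot == 0:
        return np.nan
    return signal_with_ran / tot


def normalize_pulldown(table: TitrationTable, min_background: int = 5) -> TitrationTable:
    """Two-stage normalization of a titration table.

    First each condition's signals are divided by that condition's bait
    (carrier) signal when provided; then each condition is rescaled so that
    the median bound fraction of the background proteins is 0.5 at every
    RanQ69L level.  Idempotent on an already-normalized table.
    """
    bg = table.background_ids & set(table.data["protein_id"])
    if not bg:
        raise ConfigurationError("no background proteins available for normalization")
    if len(bg) < min_background:
        warnings.warn(
            f"only {len(bg)} background proteins (recommended >= {min_background})"
        )
    df = table.data.copy()
    if "bait_signal" in df.columns:
        df["signal"] = df["signal"] / df["bait_signal"]
        df["bait_signal"] = 1.0
    # median background ratio S(x)/S(0) per replicate and level -> rescale to 1
    for rep, grp in df.groupby("replicate"):
        s0 = (
            grp[grp["ran_level"] == 0]
            .groupby("protein_id")["signal"]
            .mean()
        )
        for level in sorted(set(grp["ran_level"])):
            if level == 0:
                continue
            mask = (df["replicate"] == rep) & (df["ran_level"] == level)
            sub = df.loc[mask].set_index("protein_id")["signal"]
            common = [p for p in bg if p in sub.index and p in s0.index and s0[p] > 0]
            if not common:
                raise ConfigurationError(
                    f"no background proteins measured at level {level} of {rep!r}"
                )
            ratio = np.median([sub[p] / s0[p] for p in common])
            if ratio > 0:
                df.loc[mask, "signal"] = df.loc[mask, "signal"] / ratio
    return TitrationTable(df, set(table.background_ids))


def bound_fraction_table(table: TitrationTable) -> pd.DataFrame:
    """Bound fractions per protein/replicate/level from a titration table.

    Returns a long DataFrame (protein_id, replicate, ran_level, fraction)
    where fraction = S(x) / (S(x) + S(0)) within each replicate.
    """
    rows = []
    for (pid, rep), grp in table.data.groupby(["protein_id", "replicate"]):
        s0 = grp.loc[grp["ran_level"] == 0, "signal"].mean()
        for _, r in grp.iterrows():
            f = bound_fraction(r["signal"], s0) if np.isfinite(r["signal"]) else np.nan
            rows.append((pid, rep, r["ran_level"], f))
    return pd.DataFrame(rows, columns=["protein_id", "replicate", "ran_level", "fraction"])


def fit_affinity_slope(fractions) -> float:
    """Least-squares slope of f = 0.5 + m*x through the fixed intercept.

    ``fractions`` is an iterable of (ran_level, fraction) pairs; pairs with
    a missing fraction are dropped.  Requires >= 2 distinct levels.
    """
    pts = [(x, f) for x, f in fractions if np.isfinite(f)]
    if len({x for x, _ in pts}) < 2:
        raise FitFailure("need >= 2 distinct RanQ69L levels")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts]) - 0.5
    denom = np.sum(x * x)
    if denom == 0:
        raise FitFailure("all RanQ69L levels are zero")
    return float(np.sum(x * y) / denom)


def replicate_slopes(table: TitrationTable) -> pd.DataFrame:
    """Per-protein, per-replicate affinity slopes (wide: one column per replicate)."""
    fr = bound_fraction_table(table)
    rows = {}
    for (pid, rep), grp in fr.groupby(["protein_id", "replicate"]):
        try:
            m = fit_affinity_slope(zip(grp["ran_level"], grp["fraction"]))
        except FitFailure:
            m = np.nan
        rows.setdefault(pid, {})[rep] = m
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    df.index.name = "protein_id"
    return df


@dataclass
class AffinityProxy:
    """Integrated importin-affinity proxy for one protein."""

    protein_id: str
    slope_per_replicate: np.ndarray
    integrated_proxy: float
    n_replicates_observed: int


def integrate_replicates_cca(
    slopes: pd.DataFrame,
    t_half: pd.Series,
    folds: int = 10,
    seed: int = 0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Cross-validated 1-D CCA projection of replicate slopes against T_embryo1/2.

    Proteins (rows of ``slopes``) with >= ``min_replicates`` observed slopes
    and a defined t_half are shuffled with the seed, split into ``folds``
    contiguous blocks, and for each fold a one-component CCA axis is trained
    on the remaining proteins (missing replicate values mean-imputed within
    the training fold) and applied to the held-out block.  Projections are
    oriented so that a higher proxy means higher affinity, i.e. earlier
    entry (negative training correlation with t_half).

    Returns a DataFrame indexed by protein_id with the replicate slopes,
    ``integrated_proxy`` and ``n_replicates_observed``.
    """
    keep = slopes.index.intersection(t_half.dropna().index)
    X = slopes.loc[keep].to_numpy(dtype=float)
    y = t_half.loc[keep].to_numpy(dtype=float)
    n_obs = np.isfinite(X).sum(axis=1)
    sel = n_obs >= min_replicates
    keep, X, y, n_obs = keep[sel], X[sel], y[sel], n_obs[sel]
    n = len(keep)
    if n < 3:
        raise InvalidInput("need >= 3 proteins with enough replicates and t_half")
    if folds > n:
        warnings.warn(f"reducing folds from {folds} to {n}")
        folds = n
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    blocks = np.array_split(order, folds)
    proxy = np.full(n, np.nan)
    for test_idx in blocks:
        train_idx = np.setdiff1d(order, test_idx)
        Xtr, Xte = X[train_idx].copy(), X[test_idx].copy()
        col_mean = np.nanmean(Xtr, axis=0)
        for j in range(X.shape[1]):
            Xtr[np.isnan(Xtr[:, j]), j] = col_mean[j]
            Xte[np.isnan(Xte[:, j]), j] = col_mean[j]
        ytr = y[train_idx]
        cca = CCA(n_components=1, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cca.fit(Xtr, ytr.reshape(-1, 1))
            ptr = cca.transform(Xtr).ravel()
            pte = cca.transform(Xte).ravel()
        # calibrate fold scores onto a common scale (training-fold linear map
        # score -> t_half), then negate: higher proxy = higher affinity =
        # earlier entry.  Folds are otherwise only defined up to an affine
        # transform, which would decorrelate the concatenation.
        if ptr.std() > 0:
            slope, intercept = np.polyfit(ptr, ytr, 1)
        else:  # degenerate axis: fall back to the training mean
            slope, intercept = 0.0, float(ytr.mean())
        proxy[test_idx] = -(intercept + slope * pte)
    out = slopes.loc[keep].copy()
    out.columns = [f"slope_{c}" for c in out.columns]
    out["integrated_proxy"] = proxy
    out["n_replicates_observed"] = n_obs
    return out


def variance_explained(proxy, t_half) -> tuple[float, float]:
    """Squared Pearson correlation of proxy vs t_half and its two-sided p."""
    x = np.asarray(proxy, dtype=float)
    y = np.asarray(t_half, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InvalidInput("need >= 3 paired points")
    if x.std() == 0 or y.std() == 0:
        raise InvalidInput("zero variance in proxy or t_half")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


BIN_WIDTH_LOG10 = 1.0 / 3.0
RAMSAY_A = 1.65


class AbundanceCalibration:
    """Power-law map from normalized log10 ion signal to molar concentration.

    Reference proteins are binned by log signal (bin width 1/3), the median
    log10 concentration per populated bin is regressed on the bin center
    with a robust M-estimator (Ramsay's E_a, a = 1.65), and the fit
    extrapolates concentration estimates to all proteins.
    """

    def __init__(self, log10_signal, log10_conc_m):
        x = np.asarray(log10_signal, dtype=float)
        y = np.asarray(log10_conc_m, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        edges = np.arange(
            np.floor(x.min() / BIN_WIDTH_LOG10) * BIN_WIDTH_LOG10,
            x.max() + BIN_WIDTH_LOG10,
            BIN_WIDTH_LOG10,
        )
        centers, medians = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (x >= lo) & (x < hi)
            if m.any():
                # within-bin median signal as the regressor: exact for a
                # noiseless power law, unlike the geometric bin center
                centers.append(np.median(x[m]))
                medians.append(np.median(y[m]))
        if len(centers) < 2:
            raise FitFailure("fewer than 2 populated bins")
        X = sm.add_constant(np.asarray(centers))
        rlm = sm.RLM(np.asarray(medians), X, M=sm.robust.norms.RamsayE(a=RAMSAY_A))
        res = rlm.fit()
        self.intercept, self.slope = float(res.params[0]), float(res.params[1])
        self.bin_centers = np.asarray(centers)
        self.bin_medians = np.asarray(medians)

    def predict_log10_conc(self, log10_signal):
        return self.intercept + self.slope * np.asarray(log10_signal, dtype=float)

    def predict_conc_m(self, log10_signal):
        """Concentration estimate in molar."""
        return 10.0 ** self.predict_log10_conc(log10_signal)


def calibrate_abundance(log10_signal, log10_conc_m) -> AbundanceCalibration:
    """Fit the binned robust power-law calibration (see AbundanceCalibration)."""
    return AbundanceCalibration(log10_signal, log10_conc_m)
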