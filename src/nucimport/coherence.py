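"""Entry-time coherence of protein complexes and rank-order statistics.

Subunits of a stable complex are expected to enter embryonic nuclei
together, so the standard deviation (SD) of member T_embryo1/2 within a
complex should be small compared to random protein sets of the same size.
The null distribution is built by drawing, for each retained complex,
random member sets (without replacement, same size) from the pool of all
proteins with a defined entry time; the observed and null SD distributions
are compared with the two-sample Wilcoxon rank-sum (Mann-Whitney) test.
Rank-order agreement between two orderings (nuclear entry vs gene
activation; embryo vs droplet import) uses Spearman correlation with an
exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import InvalidInput

#: Minimum complex size retained in the coherence analysis.
DEFAULT_MIN_SIZE = 5

#: Null draws per complex.
DEFAULT_N_DRAWS = 100

#: Largest n for which the Spearman p-value is computed by full enumeration.
EXACT_SPEARMAN_MAX_N = 10


@dataclass
class ComplexCatalog:
    """complex_id -> list of member protein ids (unique within a complex)."""

    members: dict

    def __post_init__(self):
        for cid, mm in self.members.items():
            if len(set(mm)) != len(mm):
                raise InvalidInput(f"duplicate members in complex {cid!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ComplexCatalog":
        """Build from a long table with columns complex_id, member_id."""
        return cls(
            {cid: list(grp["member_id"]) for cid, grp in df.groupby("complex_id")}
        )


def complex_entry_sd(
    catalog: ComplexCatalog,
    t_half: dict | pd.Series,
    min_size: int = DEFAULT_MIN_SIZE,
) -> pd.Series:
    """Sample SD of member entry times per complex.

    Members without a defined (finite) t_half are dropped; complexes with
    fewer than ``min_size`` measured members are excluded.
    """
    th = pd.Series(t_half, dtype=float).dropna()
    out = {}
    for cid, mm in catalog.members.items():
        vals = th.reindex(mm).dropna()
        if len(vals) >= min_size:
            out[cid] = float(np.std(vals, ddof=1))
    if not out:
        raise InvalidInput("no complex retains enough measured members")
    return pd.Series(out, name="entry_sd_h")


def null_complex_sd(
    catalog: ComplexCatalog,
    t_half: dict | pd.Series,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
) -> np.ndarray:
    """Null SD distribution under random member assignment.

    For each retained complex and each draw, a member set of the observed
    size is sampled without replacement from the pool of all proteins with
    a defined t_half.  Reproducible under the seed.
    """
    th = pd.Series(t_half, dtype=float).dropna()
    pool = th.to_numpy()
    sizes = []
    for cid, mm in catalog.members.items():
        k = th.reindex(mm).dropna().size
        if k >= min_size:
            sizes.append(k)
    if not sizes:
        raise InvalidInput("no complex retains enough measured members")
    if max(sizes) > pool.size:
        raise InvalidInput("protein pool smaller than the largest complex")
    rng = np.random.default_rng(seed)
    out = np.empty(len(sizes) * n_draws)
    i = 0
    for k in sizes:
        for _ in range(n_draws):
            out[i] = np.std(rng.choice(pool, size=k, replace=False), ddof=1)
            i += 1
    return out


def wilcoxon_compare(observed_sds, null_sds) -> tuple[float, float]:
    """Two-sided two-sample rank-sum (Mann-Whitney) test.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise (scipy's automatic policy).  Returns
    (U statistic, two-sided p); all-tied samples give p = 1.
    """
    a = np.asarray(observed_sds, dtype=float)
    b = np.asarray(null_sds, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInput("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(a.size * b.size / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CoherenceResult:
    """Outcome of the complex entry-time coherence test."""

    observed_sds: pd.Series
    null_sds: np.ndarray
    statistic: float
    p_value: float
    n_draws: int
    seed: int


def coherence_test(
    catalog: ComplexCatalog,
    t_half: dict | pd.Series,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
) -> CoherenceResult:
    """Observed vs null entry-time SDs with a rank-sum comparison."""
    obs = complex_entry_sd(catalog, t_half, min_size=min_size)
    null = null_complex_sd(catalog, t_half, n_draws=n_draws, seed=seed, min_size=min_size)
    u, p = wilcoxon_compare(obs.to_numpy(), null)
    return CoherenceResult(
        observed_sds=obs, null_sds=null, statistic=u, p_value=p, n_draws=n_draws, seed=seed
    )


def _spearman_rho(rank_a, rank_b) -> float:
    ra = rank_a - rank_a.mean()
    rb = rank_b - rank_b.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    if denom == 0:
        return np.nan
    return float((ra * rb).sum() / denom)


def rank_correlation(order_a, order_b) -> tuple[float, float]:
    """Spearman rho (average-rank ties) with an exact permutation p at small n.

    For n <= 10 the two-sided p is the fraction of all n! permutations of
    one ranking whose |rho| is at least the observed |rho|; larger samples
    use the t approximation.  Constant rankings raise
    :class:`InvalidInput`.
    """
    a = np.asarray(order_a, dtype=float)
    b = np.asarray(order_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise InvalidInput("need paired rankings with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidInput("constant ranking: rho undefined")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    rho = _spearman_rho(ra, rb)
    n = a.size
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.int64)
        rb_perm = rb[perms]  # (n!, n)
        ra_c = ra - ra.mean()
        rb_c = rb_perm - rb_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum(axis=1))
        rhos = (rb_c @ ra_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(a, b).pvalue)
    return rho, p
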