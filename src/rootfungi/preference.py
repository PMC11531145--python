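"""Host-plant specificity: d' scores, position-constrained permutation nulls,
standardized preference and two-dimensional pair preference.

The d' index is the standardized Kullback–Leibler specialization of one
node's interaction distribution against partner availability:

    d_i = sum_j p'_ij ln(p'_ij / q_j),  p'_ij = N(i,j)/A_i,  q_j = A_j/m
    d'  = (d_i - d_min) / (d_max - d_min)  in [0, 1]

with d_min/d_max the extreme values attainable by redistributing the A_i
interactions over integer cells given the fixed marginals.  Statistical
significance comes from shuffling host-plant labels among root samples
*within the same sampling position*, which preserves each position's host
multiset and therefore the availability vector q.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .community import CommunityTable, CommunityDataError, SampleMetadata, to_binary

__all__ = [
    "BipartiteCounts",
    "PreferenceResult",
    "TwoDimPreference",
    "build_bipartite",
    "dprime",
    "kl_specialization",
    "dprime_bounds",
    "shuffle_within_position",
    "standardized_preference",
    "two_dim_preference",
    "bh_fdr",
]


@dataclass(frozen=True)
class BipartiteCounts:
    """Fungal OTU x plant genus co-observation counts.

    ``n[i, j]`` is the number of root samples in which OTU i occurs on plant
    j; marginals are the row totals ``a_otu``, column totals ``a_plant`` and
    the grand total ``m``.
    """

    otu_ids: list[str]
    plants: list[str]
    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if n.ndim != 2 or n.shape != (len(self.otu_ids), len(self.plants)):
            raise CommunityDataError("bipartite matrix shape mismatch")
        if n.size and (n < 0).any():
            raise CommunityDataError("negative bipartite counts")
        object.__setattr__(self, "n", n.astype(np.int64))

    @property
    def a_otu(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def a_plant(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def m(self) -> int:
        return int(self.n.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.n, index=self.otu_ids, columns=self.plants)


def _filter_roots(
    root_binary: CommunityTable,
    metadata: SampleMetadata,
    min_host_samples: int,
) -> pd.DataFrame:
    roots = metadata.roots
    roots = roots[roots["sample_id"].isin(root_binary.sample_ids)]
    counts = roots["host_plant"].value_counts()
    keep = counts[counts >= min_host_samples].index
    return roots[roots["host_plant"].isin(keep)].reset_index(drop=True)


def build_bipartite(
    root_binary: CommunityTable,
    metadata: SampleMetadata,
    min_otu_occurrence: int = 30,
    min_host_samples: int = 30,
) -> BipartiteCounts:
    """Cross-tabulate OTU occurrences against host plants after filtering.

    Host plants with fewer than ``min_host_samples`` root samples are dropped
    first (same rule as the jSDM); OTUs occurring in fewer than
    ``min_otu_occurrence`` of the remaining samples are discarded.
    """
    roots = _filter_roots(root_binary, metadata, min_host_samples)
    if roots.empty:
        raise CommunityDataError("no root samples pass the host filter")
    b = to_binary(root_binary.subset_samples(list(roots["sample_id"])))
    occ = b.counts.sum(axis=0)
    keep = occ >= min_otu_occurrence
    if not keep.any():
        raise CommunityDataError("no OTU passes the occurrence filter")
    otus = [o for o, k in zip(b.otu_ids, keep) if k]
    plants = sorted(roots["host_plant"].unique())
    h = pd.get_dummies(roots["host_plant"])[plants].to_numpy(dtype=np.int64)
    n = b.counts[:, keep].T @ h
    return BipartiteCounts(otus, plants, n)


# ---------------------------------------------------------------------------
# d' and its integer-redistribution bounds
# ---------------------------------------------------------------------------

def kl_specialization(row: np.ndarray, q: np.ndarray) -> float:
    """Raw KL specialization d_i of one interaction row against availability q."""
    a = row.sum()
    if a <= 0:
        raise CommunityDataError("d' undefined for an empty row")
    p = row / a
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _hill_climb(x: np.ndarray, caps: np.ndarray, q: np.ndarray, sign: float) -> np.ndarray:
    """Single-unit exchange hill climbing on sign * d (sign=+1 maximizes)."""
    x = x.copy()
    k = len(x)
    improved = True
    best = sign * kl_specialization(x, q)
    while improved:
        improved = False
        for j, l in itertools.permutations(range(k), 2):
            if x[j] == 0 or x[l] >= caps[l]:
                continue
            x[j] -= 1
            x[l] += 1
            val = sign * kl_specialization(x, q)
            if val > best + 1e-12:
                best = val
                improved = True
            else:
                x[j] += 1
                x[l] -= 1
    return x


def _subset_sums(caps: np.ndarray, limit: int, skip: int | None = None) -> np.ndarray:
    """Boolean reachability of subset sums of ``caps`` up to ``limit``."""
    reach = np.zeros(limit + 1, dtype=bool)
    reach[0] = True
    for j, c in enumerate(caps):
        if j == skip or c == 0 or c > limit:
            continue
        c = int(c)
        shifted = np.concatenate([np.zeros(c, dtype=bool), reach[: limit + 1 - c]])
        reach |= shifted
    return reach


def dprime_bounds(total: int, col_totals: np.ndarray) -> tuple[float, float]:
    """d_min and d_max over integer redistributions of ``total`` interactions
    with cell caps equal to the column totals.

    d_min: largest-remainder apportionment proportional to availability,
    polished by single-unit exchanges — exact, because the objective is
    separable convex on an exchange-connected integer polytope.

    d_max: exact vertex enumeration.  A convex maximum has at most one column
    strictly between its bounds, and because availability is proportional to
    the caps (q_j = c_j / m) every fully-filled column contributes
    ln(m/A) per interaction regardless of identity, so

        d_max = ln(m/A) + max_{j*, r} (r/A) ln(r / c_j*)

    over partial columns j* and remainders r = A - (a subset sum of the other
    caps) with 0 < r <= c_j*; r = 0 (an exact subset sum) attains ln(m/A)
    itself.  Subset sums come from a boolean knapsack table.
    """
    caps = np.asarray(col_totals, dtype=np.int64)
    m = int(caps.sum())
    a = int(total)
    if a > m:
        raise CommunityDataError("row total exceeds the sum of column totals")
    q = caps / m
    # --- d_min: proportional apportionment then polish
    ideal = a * q
    base = np.minimum(np.floor(ideal).astype(np.int64), caps)
    rem = a - base.sum()
    frac = ideal - base
    for j in np.argsort(-frac):
        if rem == 0:
            break
        if base[j] < caps[j]:
            base[j] += 1
            rem -= 1
    if rem > 0:  # caps were binding; dump remainder wherever room is left
        for j in np.argsort(-(caps - base)):
            add = min(rem, caps[j] - base[j])
            base[j] += add
            rem -= add
            if rem == 0:
                break
    xmin = _hill_climb(base, caps, q, sign=-1.0)
    d_min = kl_specialization(xmin, q)
    # --- d_max: exact vertex enumeration via subset sums
    log_ma = np.log(m / a)
    best = -np.inf
    if _subset_sums(caps, a)[a]:
        best = log_ma
    for jstar in range(len(caps)):
        if caps[jstar] == 0:
            continue
        reach = _subset_sums(caps, a, skip=jstar)
        r = a - np.nonzero(reach)[0]
        r = r[(r > 0) & (r <= caps[jstar])]
        if r.size:
            best = max(best, log_ma + float(np.max((r / a) * np.log(r / caps[jstar]))))
    return d_min, float(best)


# -- vectorized per-matrix d' (marginals taken from the matrix itself) ------

def _term(x: np.ndarray, a: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Elementwise KL contribution (x/a) ln(x/(a q)), with 0 ln 0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (x / a[:, None]) * np.log(
            np.maximum(x, 1) / (a[:, None] * np.maximum(q[None, :], 1e-300))
        )
    return np.where(x > 0, val, 0.0)


def _dmin_vec(a: np.ndarray, caps: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Exact d_min for each row total in ``a`` (shared caps/availability).

    Proportional apportionment start, then vectorized single-unit exchange
    descent; exchange-local minima of the separable convex objective are
    global, so the result is exact.
    """
    a = np.asarray(a, dtype=np.int64)
    caps = np.asarray(caps, dtype=np.int64)
    ideal = np.outer(a, q)
    x = np.minimum(np.floor(ideal).astype(np.int64), caps[None, :])
    rem = a - x.sum(1)
    prio = np.where(x < caps[None, :], ideal - x, -np.inf)
    while (rem > 0).any():
        rows = np.nonzero(rem > 0)[0]
        j = np.argmax(prio[rows], axis=1)
        x[rows, j] += 1
        rem[rows] -= 1
        prio[rows, j] = np.where(x[rows, j] >= caps[j], -np.inf, prio[rows, j] - 1.0)
    safe_a = np.maximum(a, 1)
    for _ in range(10 * len(caps) + 10):  # descent terminates quickly
        g0 = _term(x, safe_a, q)
        g_rm = np.where(x > 0, _term(x - 1, safe_a, q) - g0, np.inf)
        g_ad = np.where(x < caps[None, :], _term(x + 1, safe_a, q) - g0, np.inf)
        j_rm = np.argmin(g_rm, axis=1)
        rows = np.arange(len(a))
        best_rm = g_rm[rows, j_rm]
        ad = g_ad.copy()
        ad[rows, j_rm] = np.inf  # the moved unit must land elsewhere
        l_ad = np.argmin(ad, axis=1)
        best_ad = ad[rows, l_ad]
        delta = best_rm + best_ad
        move = (delta < -1e-12) & (a > 0)
        if not move.any():
            break
        x[rows[move], j_rm[move]] -= 1
        x[rows[move], l_ad[move]] += 1
    return _term(x, safe_a, q).sum(1)


def _build_reach_tables(caps: np.ndarray, limit: int):
    reach_all = _subset_sums(caps, limit)
    excl = [
        np.nonzero(_subset_sums(caps, limit, skip=j))[0] for j in range(len(caps))
    ]
    return reach_all, excl


def _dmax_vec(a: np.ndarray, caps: np.ndarray, reach_all, excl) -> np.ndarray:
    """Exact d_max for each row total in ``a`` via vertex enumeration.

    For each candidate partial column the remainder term is convex in r, so
    only the extreme feasible remainders need evaluation; exact subset sums
    attain ln(m/a) itself.
    """
    a = np.asarray(a, dtype=np.int64)
    m = int(caps.sum())
    safe_a = np.maximum(a, 1)
    log_ma = np.log(m / safe_a)
    best = np.where(reach_all[np.minimum(a, len(reach_all) - 1)], 0.0, -np.inf)
    for j, c in enumerate(caps):
        if c == 0:
            continue
        s = excl[j]
        for idx in (
            np.searchsorted(s, a - c, side="left"),
            np.searchsorted(s, a, side="left") - 1,
        ):
            valid = (idx >= 0) & (idx < len(s))
            sv = s[np.clip(idx, 0, len(s) - 1)]
            r = a - sv
            ok = valid & (r > 0) & (r <= c)
            rr = np.maximum(r, 1)
            val = np.where(ok, (rr / safe_a) * np.log(rr / c), -np.inf)
            best = np.maximum(best, val)
    return log_ma + best


def _dprime_matrix(n: np.ndarray, cache: dict | None = None) -> np.ndarray:
    """Normalized d' per row of one bipartite matrix, with availability and
    integer-redistribution bounds taken from this matrix's own marginals.

    ``cache`` memoises the subset-sum tables on the column-total vector (the
    plant-side tables are permutation-invariant and hit one entry)."""
    n = np.asarray(n, dtype=np.int64)
    rows = n.shape[0]
    if n.shape[1] < 2:
        return np.full(rows, np.nan)
    a = n.sum(1)
    ct = n.sum(0)
    m = int(ct.sum())
    if m == 0:
        return np.full(rows, np.nan)
    q = ct / m
    d = _term(n, np.maximum(a, 1), q).sum(1)
    limit = int(a.max())
    key = (ct.tobytes(), limit)
    if cache is not None and key in cache:
        reach_all, excl = cache[key]
    else:
        reach_all, excl = _build_reach_tables(ct, limit)
        if cache is not None:
            cache[key] = (reach_all, excl)
    d_max = _dmax_vec(a, ct, reach_all, excl)
    d_min = _dmin_vec(a, ct, q)
    span = d_max - d_min
    with np.errstate(invalid="ignore"):
        out = np.where((a > 0) & (span > 1e-12), (d - d_min) / np.where(span > 0, span, 1.0), np.nan)
    return out


def dprime(matrix: np.ndarray | BipartiteCounts, axis: int = 0) -> np.ndarray:
    """Normalized d' in [0, 1] per row (axis=0) or per column (axis=1).

    Returns NaN where the bounds coincide (e.g. a single partner column).
    """
    n = matrix.n if isinstance(matrix, BipartiteCounts) else np.asarray(matrix)
    if axis == 1:
        n = n.T
    return _dprime_matrix(n)


# ---------------------------------------------------------------------------
# Position-constrained permutations
# ---------------------------------------------------------------------------

def shuffle_within_position(
    roots: pd.DataFrame, rng: np.random.Generator
) -> pd.Series:
    """One permutation of host labels constrained within sampling positions.

    ``roots`` needs columns sample_id / position_id / host_plant; the multiset
    of hosts at each position is preserved exactly.
    """
    hosts = roots["host_plant"].to_numpy().copy()
    for _, idx in roots.groupby("position_id").indices.items():
        hosts[idx] = hosts[rng.permutation(idx)]
    return pd.Series(hosts, index=roots["sample_id"].to_numpy(), name="host_plant")


def _host_index_permutations(
    roots: pd.DataFrame, plants: list[str], n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_samples) array of plant indices under constrained shuffles."""
    plant_idx = {p: j for j, p in enumerate(plants)}
    base = np.array([plant_idx[h] for h in roots["host_plant"]])
    out = np.tile(base, (n_perm, 1))
    for _, idx in roots.groupby("position_id").indices.items():
        if len(idx) < 2:
            continue
        order = np.argsort(rng.random((n_perm, len(idx))), axis=1)
        out[:, idx] = base[idx][order]
    return out


# ---------------------------------------------------------------------------
# Standardized preference and two-dimensional preference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferenceResult:
    """Per-node d' preference scores with permutation nulls and FDR."""

    otus: pd.DataFrame    # d_prime, null_mean, null_sd, z, p, q, degenerate
    plants: pd.DataFrame
    n_perm: int
    seed: int


@dataclass(frozen=True)
class TwoDimPreference:
    """Standardized per-pair preference scores (2DP) with p and q matrices."""

    score: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_perm: int
    seed: int


def _perm_counts(
    binary: np.ndarray, host_codes: np.ndarray, n_plants: int
) -> np.ndarray:
    """Bipartite counts for one host assignment: (otus, plants)."""
    h = np.zeros((host_codes.size, n_plants), dtype=np.int64)
    h[np.arange(host_codes.size), host_codes] = 1
    return binary.T @ h


def _preference_engine(
    root_binary: CommunityTable,
    metadata: SampleMetadata,
    n_perm: int,
    seed: int,
    min_otu_occurrence: int,
    min_host_samples: int,
):
    """Shared permutation stream for d' preference and 2DP (same seed =>
    identical randomized matrices)."""
    roots = _filter_roots(root_binary, metadata, min_host_samples)
    if roots.empty:
        raise CommunityDataError("no root samples pass the host filter")
    b = to_binary(root_binary.subset_samples(list(roots["sample_id"])))
    occ = b.counts.sum(axis=0)
    keep = occ >= min_otu_occurrence
    if not keep.any():
        raise CommunityDataError("no OTU passes the occurrence filter")
    otus = [o for o, k in zip(b.otu_ids, keep) if k]
    binary = b.counts[:, keep].astype(np.int64)
    plants = sorted(roots["host_plant"].unique())
    if len(plants) < 2:
        raise CommunityDataError("d' undefined with a single host plant")
    rng = np.random.default_rng(seed)
    host_codes = _host_index_permutations(roots, plants, n_perm, rng)
    obs_codes = np.array([plants.index(h) for h in roots["host_plant"]])
    n_obs = _perm_counts(binary, obs_codes, len(plants))
    perm_stack = np.empty((n_perm, len(otus), len(plants)), dtype=np.int64)
    for t in range(n_perm):
        perm_stack[t] = _perm_counts(binary, host_codes[t], len(plants))
    return roots, otus, plants, n_obs, perm_stack


def _node_scores(
    n_obs: np.ndarray, perm_stack: np.ndarray, ids: list[str]
) -> pd.DataFrame:
    """d', permutation null, z, two-tailed permutation p per node (rows).

    Every randomized matrix is scored against its own marginals (availability
    and redistribution bounds are recomputed per permutation, as in the
    original randomization procedure)."""
    cache: dict = {}
    d_obs = _dprime_matrix(n_obs, cache)
    n_perm = perm_stack.shape[0]
    d_perm = np.empty((n_perm, len(ids)))
    for t in range(n_perm):
        d_perm[t] = _dprime_matrix(perm_stack[t], cache)
    mean = np.nanmean(d_perm, axis=0)
    sd = np.nanstd(d_perm, axis=0, ddof=0)
    degenerate = (sd <= 1e-12) | ~np.isfinite(d_obs)
    z = np.where(degenerate, 0.0, (d_obs - mean) / np.where(sd > 0, sd, 1.0))
    centered = np.abs(d_perm - mean[None, :])
    p = (np.sum(centered >= np.abs(d_obs - mean)[None, :] - 1e-12, axis=0) + 1.0) / (
        n_perm + 1.0
    )
    p = np.where(degenerate, 1.0, p)
    q_fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "d_prime": d_obs,
            "null_mean": mean,
            "null_sd": sd,
            "z": z,
            "p": p,
            "q": q_fdr,
            "degenerate": degenerate,
        },
        index=ids,
    )


def standardized_preference(
    root_binary: CommunityTable,
    metadata: SampleMetadata,
    n_perm: int = 10000,
    seed: int = 0,
    min_otu_occurrence: int = 30,
    min_host_samples: int = 30,
) -> PreferenceResult:
    """Standardized d' host-preference scores for every OTU, and (transposed)
    every plant's preference for fungi.

    z = (d'_original - mean(d'_randomized)) / sd(d'_randomized); the two-tailed
    p uses permutation ranks of d' with the (+1)/(n+1) convention; q is
    Benjamini–Hochberg.  A zero permutation spread yields score 0 with the
    ``degenerate`` flag set.
    """
    _, otus, plants, n_obs, perm_stack = _preference_engine(
        root_binary, metadata, n_perm, seed, min_otu_occurrence, min_host_samples
    )
    otu_frame = _node_scores(n_obs, perm_stack, otus)
    plant_frame = _node_scores(
        n_obs.T, perm_stack.transpose(0, 2, 1), plants
    )
    return PreferenceResult(otu_frame, plant_frame, n_perm, seed)


def two_dim_preference(
    root_binary: CommunityTable,
    metadata: SampleMetadata,
    n_perm: int = 10000,
    seed: int = 0,
    min_otu_occurrence: int = 30,
    min_host_samples: int = 30,
) -> TwoDimPreference:
    """Two-dimensional (pairwise) preference: the z-score of each OTU-plant
    co-observation count against the position-constrained permutation null.

    Shares the permutation stream with :func:`standardized_preference` for
    equal seeds.  Cells with zero permutation spread are flagged with NaN.
    """
    _, otus, plants, n_obs, perm_stack = _preference_engine(
        root_binary, metadata, n_perm, seed, min_otu_occurrence, min_host_samples
    )
    mean = perm_stack.mean(axis=0)
    sd = perm_stack.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(sd > 0, (n_obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    centered = np.abs(perm_stack - mean[None])
    p = (np.sum(centered >= np.abs(n_obs - mean)[None] - 1e-12, axis=0) + 1.0) / (
        n_perm + 1.0
    )
    p = np.where(sd > 0, p, np.nan)
    flat = p.ravel()
    qv = np.full_like(flat, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        qv[ok] = bh_fdr(flat[ok])
    qm = qv.reshape(p.shape)
    idx, cols = otus, plants
    return TwoDimPreference(
        pd.DataFrame(score, index=idx, columns=cols),
        pd.DataFrame(p, index=idx, columns=cols),
        pd.DataFrame(qm, index=idx, columns=cols),
        n_perm,
        seed,
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
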