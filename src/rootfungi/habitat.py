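"""Root-vs-soil habitat preference and spatial autocorrelation.

Habitat preference contrasts each OTU's occurrence and mean relative
abundance between root-tip and bulk-soil samples, then tests the coupling of
root occurrence to soil abundance with a Poisson GLM: the per-(position x
host genus) count of root samples containing the OTU is regressed on the
log soil relative abundance at the position and host genus identity, with
log(number of root samples of that genus at that position) as offset.

Spatial autocorrelation is profiled with a Mantel correlogram: for each
geographic distance class, the Mantel correlation between position-level
Jaccard dissimilarity and membership in the class, with permutation p-values
and BH-FDR across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import CommunityTable, CommunityDataError, GuildMap, SampleMetadata, to_binary
from .ordination import geographic_distance, jaccard_binary
from .preference import bh_fdr

__all__ = [
    "HabitatPoint",
    "GLMResult",
    "CorrelogramResult",
    "habitat_surface",
    "glm_soil_coupling",
    "glm_soil_coupling_all",
    "pool_by_position",
    "mantel_correlogram",
]


@dataclass(frozen=True)
class HabitatPoint:
    otu_id: str
    n_root_samples_detected: int
    n_soil_samples_detected: int
    mean_rel_abund_root: float
    mean_rel_abund_soil: float


@dataclass(frozen=True)
class GLMResult:
    """Soil-coupling GLM summary for one OTU."""

    otu_id: str
    soil_coefficient: float          # standardized: beta * SD(log soil abundance)
    p_value: float
    plant_coefficients: pd.Series
    converged: bool
    intercept: float = np.nan


@dataclass(frozen=True)
class CorrelogramResult:
    """Mantel correlogram: per-distance-class r, permutation p and BH q."""

    classes: pd.DataFrame  # class_mid_m, r, p, q, n_pairs
    breaks: np.ndarray
    n_perm: int

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.classes
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.plot(c["class_mid_m"], c["r"], "o-", color="k", mfc="white")
        sig = c["q"] < 0.05
        ax.plot(c.loc[sig, "class_mid_m"], c.loc[sig, "r"], "*", ms=12, color="k")
        ax.set_xlabel("distance class midpoint (m)")
        ax.set_ylabel("Mantel r")
        return ax


# ---------------------------------------------------------------------------
# Habitat surface
# ---------------------------------------------------------------------------

def _mean_log_rel_abund(table: CommunityTable) -> np.ndarray:
    """Mean log10 relative abundance over the samples where each OTU occurs."""
    counts = table.counts.astype(float)
    depth = counts.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    prop = counts / depth
    out = np.full(counts.shape[1], np.nan)
    present = prop > 0
    for j in range(counts.shape[1]):
        mask = present[:, j]
        if mask.any():
            out[j] = np.log10(prop[mask, j]).mean()
    return out


def habitat_surface(
    root_table: CommunityTable,
    soil_table: CommunityTable,
    metadata: SampleMetadata,
    min_root: int = 30,
    min_soil: int = 15,
) -> pd.DataFrame:
    """Occurrence counts and mean log relative abundance per habitat for the
    OTUs detected in at least ``min_root`` root and ``min_soil`` soil samples.
    """
    shared = [o for o in root_table.otu_ids if o in set(soil_table.otu_ids)]
    root = root_table.subset_otus(shared)
    soil = soil_table.subset_otus(shared)
    n_root = (root.counts > 0).sum(axis=0)
    n_soil = (soil.counts > 0).sum(axis=0)
    keep = (n_root >= min_root) & (n_soil >= min_soil)
    frame = pd.DataFrame(
        {
            "n_root_samples_detected": n_root,
            "n_soil_samples_detected": n_soil,
            "mean_rel_abund_root": _mean_log_rel_abund(root),
            "mean_rel_abund_soil": _mean_log_rel_abund(soil),
        },
        index=shared,
    )
    return frame[keep]


# ---------------------------------------------------------------------------
# Poisson GLM with offset
# ---------------------------------------------------------------------------

def _glm_table(
    root_table: CommunityTable,
    soil_table: CommunityTable,
    metadata: SampleMetadata,
    otu: str,
) -> pd.DataFrame:
    """Per (position x host genus) response/exposure plus soil abundance."""
    meta = metadata.data.set_index("sample_id")
    roots = metadata.roots
    roots = roots[roots["sample_id"].isin(root_table.sample_ids)].copy()
    hit = pd.Series(
        (root_table.data[otu] > 0).astype(int).to_numpy(), index=root_table.sample_ids
    )
    roots["hit"] = hit.loc[roots["sample_id"]].to_numpy()
    grouped = (
        roots.groupby(["position_id", "host_plant"], observed=True)
        .agg(y=("hit", "sum"), exposure=("hit", "size"))
        .reset_index()
    )
    soil_ids = [s for s in soil_table.sample_ids if s in meta.index]
    soil_pos = meta.loc[soil_ids, "position_id"]
    depth = soil_table.subset_samples(soil_ids).row_sums().astype(float)
    prop = soil_table.data.loc[soil_ids, otu].to_numpy() / np.where(depth > 0, depth, 1.0)
    pos_prop = pd.Series(prop, index=soil_pos.to_numpy())
    grouped = grouped[grouped["position_id"].isin(pos_prop.index)].copy()
    positive = pos_prop[pos_prop > 0]
    pseudo = positive.min() / 2.0 if len(positive) else 0.5
    grouped["soil_log_abund"] = np.log10(
        pos_prop.loc[grouped["position_id"]].to_numpy() + pseudo
    )
    return grouped


def glm_soil_coupling(
    root_table: CommunityTable,
    soil_table: CommunityTable,
    metadata: SampleMetadata,
    otu: str,
) -> GLMResult:
    """Poisson GLM of root occurrences against soil relative abundance.

    The soil coefficient is standardized by the predictor's standard
    deviation; p is the Wald test of the raw coefficient.  Non-convergence or
    a degenerate design yields a flagged result rather than an exception.
    """
    tab = _glm_table(root_table, soil_table, metadata, otu)
    if tab.empty:
        return GLMResult(otu, np.nan, np.nan, pd.Series(dtype=float), False)
    x = pd.get_dummies(tab["host_plant"], drop_first=True).astype(float)
    x.columns = [f"plant:{c}" for c in x.columns]
    sd = tab["soil_log_abund"].std(ddof=0)
    if sd < 1e-10:
        sd = 0.0
    if sd > 0:  # a constant predictor is dropped (coefficient 0 by convention)
        x.insert(0, "soil_log_abund", tab["soil_log_abund"])
    x = sm.add_constant(x, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                tab["y"].to_numpy(),
                x,
                family=sm.families.Poisson(),
                offset=np.log(tab["exposure"].to_numpy(dtype=float)),
            ).fit(maxiter=100)
        converged = bool(fit.converged) and np.all(np.isfinite(fit.bse))
        beta = fit.params["soil_log_abund"] if sd > 0 else 0.0
        pval = fit.pvalues["soil_log_abund"] if sd > 0 else 1.0
    except Exception:
        return GLMResult(otu, np.nan, np.nan, pd.Series(dtype=float), False)
    plant_cols = [c for c in x.columns if c.startswith("plant:")]
    return GLMResult(
        otu,
        float(beta * sd),
        float(pval),
        fit.params[plant_cols],
        converged,
        intercept=float(fit.params["const"]),
    )


def glm_soil_coupling_all(
    root_table: CommunityTable,
    soil_table: CommunityTable,
    metadata: SampleMetadata,
    min_root: int = 30,
    min_soil: int = 15,
) -> pd.DataFrame:
    """Soil-coupling GLM for every OTU passing the habitat-surface filters."""
    surf = habitat_surface(root_table, soil_table, metadata, min_root, min_soil)
    rows = []
    for otu in surf.index:
        res = glm_soil_coupling(root_table, soil_table, metadata, otu)
        rows.append(
            {
                "otu_id": otu,
                "soil_coefficient": res.soil_coefficient,
                "p": res.p_value,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

def pool_by_position(
    table: CommunityTable, metadata: SampleMetadata, kind: str = "root"
) -> CommunityTable:
    """Pool samples to position-level presence/absence (idempotent)."""
    meta = metadata.data.set_index("sample_id")
    ids = [s for s in table.sample_ids if s in meta.index and meta.loc[s, "kind"] == kind]
    sub = table.subset_samples(ids)
    pos = meta.loc[ids, "position_id"].to_numpy()
    pooled = (
        pd.DataFrame(sub.counts > 0, index=pos, columns=sub.otu_ids)
        .groupby(level=0)
        .any()
        .astype(np.int64)
    )
    return CommunityTable(pooled)


def _sturges(n_pairs: int) -> int:
    return int(np.ceil(np.log2(n_pairs)) + 1)


def mantel_correlogram(
    community_binary: CommunityTable,
    metadata: SampleMetadata,
    n_classes: int | None = None,
    n_perm: int = 10000,
    seed: int = 0,
    guild_subset: str | None = None,
    guilds: GuildMap | None = None,
    kind: str = "root",
) -> CorrelogramResult:
    """Mantel correlogram of Jaccard dissimilarity against distance classes.

    Root communities are pooled to position-level presence/absence before the
    Jaccard matrix.  Per class c the statistic is r_c = -cor(D, 1[pair in c])
    over all position pairs, so positive r means similar communities within
    the class.  p-values come from shuffling position identities (two-tailed,
    (+1)/(n+1) convention), q from BH across retained classes.
    """
    if guild_subset is not None:
        if guilds is None:
            raise ValueError("guild_subset requires a GuildMap")
        members = guilds.members(guild_subset, community_binary.otu_ids)
        if not members:
            raise CommunityDataError(f"no OTUs in guild {guild_subset!r}")
        community_binary = community_binary.subset_otus(members)
    pooled = pool_by_position(community_binary, metadata, kind=kind)
    positions = pooled.sample_ids
    if len(positions) < 3:
        raise CommunityDataError("need at least 3 positions")
    pos_meta = metadata.data.drop_duplicates("position_id").set_index("position_id")
    geo = geographic_distance(
        SampleMetadata(
            pos_meta.loc[positions].reset_index().assign(
                sample_id=lambda d: d["position_id"]
            )[list(SampleMetadata.REQUIRED)]
        )
    )
    comm = jaccard_binary(pooled)
    n = len(positions)
    iu = np.triu_indices(n, 1)
    dvec = comm.d[iu]
    gvec = geo.d[iu]
    if n_classes is None:
        n_classes = _sturges(len(gvec))
    breaks = np.linspace(gvec.min(), gvec.max() + 1e-9, n_classes + 1)
    labels = np.digitize(gvec, breaks[1:-1])
    ind = np.zeros((len(gvec), n_classes))
    ind[np.arange(len(gvec)), labels] = 1.0
    counts = ind.sum(axis=0)
    keep = counts >= 2
    if not keep.all():
        warnings.warn("distance class(es) with < 2 pairs dropped", stacklevel=2)
    ind = ind[:, keep]
    mids = 0.5 * (breaks[:-1] + breaks[1:])[keep]

    def _corr(d: np.ndarray) -> np.ndarray:
        dc = d - d.mean()
        sd = dc.std(ddof=0)
        if sd <= 1e-15:
            return np.full(ind.shape[1], np.nan)
        ic = ind - ind.mean(axis=0, keepdims=True)
        isd = ic.std(axis=0, ddof=0)
        return -(dc @ ic) / (len(d) * sd * np.where(isd > 0, isd, 1.0))

    r_obs = _corr(dvec)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(ind.shape[1])
    valid = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dp = comm.d[np.ix_(perm, perm)][iu]
        rp = _corr(dp)
        if np.all(np.isnan(rp)):
            continue
        valid += 1
        exceed += np.abs(rp) >= np.abs(r_obs) - 1e-12
    if valid == 0 or np.all(np.isnan(r_obs)):
        p = np.full(ind.shape[1], np.nan)
    else:
        p = (exceed + 1.0) / (valid + 1.0)
    qv = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        qv[ok] = bh_fdr(p[ok])
    classes = pd.DataFrame(
        {
            "class_mid_m": mids,
            "r": r_obs,
            "p": p,
            "q": qv,
            "n_pairs": counts[keep].astype(int),
        }
    )
    return CorrelogramResult(classes, breaks, n_perm)
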