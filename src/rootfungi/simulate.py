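"""Seeded generator of root-tip / bulk-soil community datasets with known truth.

The generator emulates a forest sampling design: ~124 sampling positions at
least 4 m apart, one bulk-soil sample per position and several root-tip
samples per position, each root tip labelled with a host plant genus.  Each
fungal OTU belongs to a functional guild whose archetype controls which
assembly processes act on it:

* host-plant filtering — per-(OTU, plant) probit shifts with guild-specific
  standard deviation (strong for AMF-like fungi);
* coupling to the background soil community — the OTU's standardized latent
  soil log-abundance field enters the root occurrence probit (strong for
  ectomycorrhizal fungi);
* spatial autocorrelation — a Gaussian-process field with exponential
  covariance and guild-specific range (strong for ectomycorrhizal fungi);
* fungus–fungus covariance — shared latent factors with guild-specific
  loading scale (strong for endophyte-like fungi).

Occurrence of OTU s in root sample i at position q with host h:

    P(y_is = 1) = Phi(alpha_s + B_plant[s, h] + c_g * z_s(q)
                      + w_s(q) + lambda_s' u_i),   u_i ~ N(0, I_r)

Read counts for present OTUs are multinomial over lognormal abundances with
negative-binomial sequencing depths (root mean 2e4, soil mean 1e5, size 2 —
plausible magnitudes for MiSeq metabarcoding, configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm

from .community import CommunityTable, GuildMap, SampleMetadata

__all__ = [
    "GuildArchetype",
    "TruthParams",
    "Landscape",
    "SyntheticDataset",
    "generate_landscape",
    "simulate_soil",
    "simulate_roots",
    "generate_dataset",
    "generate_network_dataset",
    "assembly_preset",
    "null_preset",
    "network_preset",
]

#: Default host-plant genera (the woody genera typical of a cool-temperate
#: mixed forest).
DEFAULT_PLANTS = (
    "Pinus", "Betula", "Quercus", "Populus", "Castanea",
    "Corylus", "Acer", "Larix", "Juglans", "Fagus",
)


@dataclass(frozen=True)
class GuildArchetype:
    """Per-guild generative effect scales (all on the probit scale except
    ``spatial_range`` which is in metres)."""

    n_otus: int
    plant_effect_sd: float = 0.0
    soil_coupling: float = 0.0
    spatial_range: float = 8.0
    spatial_sd: float = 0.0
    factor_loading_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be > 0")
        for name in ("plant_effect_sd", "soil_coupling", "spatial_sd", "factor_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_guilds() -> dict[str, GuildArchetype]:
    # Mirrors the contrast seen between guilds in the field: EcMF strongly
    # soil-coupled and spatially structured, endophytes driven by
    # fungus-fungus covariance, AMF strongly host-filtered.
    return {
        "EcMF": GuildArchetype(60, 0.15, 1.0, 10.0, 0.8, 0.25),
        "Endophyte": GuildArchetype(30, 0.4, 0.15, 5.0, 0.15, 1.0),
        "AMF": GuildArchetype(10, 1.2, 0.2, 6.0, 0.3, 0.4),
        "Other_RAF": GuildArchetype(20, 0.8, 0.3, 6.0, 0.2, 0.5),
        "Pathogen": GuildArchetype(5, 0.5, 0.2, 6.0, 0.2, 0.4),
        "Mycoparasite": GuildArchetype(5, 0.2, 0.2, 6.0, 0.2, 0.6),
    }


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative parameters emulating the study design."""

    n_positions: int = 124
    min_spacing: float = 4.0
    arena_size: float | None = None
    plants: tuple[str, ...] = DEFAULT_PLANTS
    plant_clump_range: float = 25.0
    samples_per_position_mean: float = 13.0
    guilds: dict[str, GuildArchetype] = field(default_factory=_default_guilds)
    n_latent_factors: int = 2
    base_prevalence: tuple[float, float] = (0.05, 0.45)
    root_depth_mean: float = 2e4
    root_depth_size: float = 2.0
    soil_depth_mean: float = 1e5
    soil_depth_size: float = 2.0
    soil_field_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_positions < 2:
            raise ValueError("need at least 2 positions")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be > 0")

    @property
    def n_otus(self) -> int:
        return sum(g.n_otus for g in self.guilds.values())

    def otu_guilds(self) -> list[str]:
        out: list[str] = []
        for name, g in self.guilds.items():
            out.extend([name] * g.n_otus)
        return out

    def null(self) -> "TruthParams":
        """Copy with every generative effect switched off (global null)."""
        guilds = {
            name: replace(g, plant_effect_sd=0.0, soil_coupling=0.0,
                          spatial_sd=0.0, factor_loading_sd=0.0)
            for name, g in self.guilds.items()
        }
        return replace(self, guilds=guilds)


@dataclass(frozen=True)
class Landscape:
    """Sampling positions with coordinates and per-root-sample host plants."""

    positions: pd.DataFrame          # position_id, x, y
    root_hosts: pd.DataFrame         # sample_id, position_id, host_plant

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def n_root_samples(self) -> int:
        return len(self.root_hosts)

    def metadata(self) -> SampleMetadata:
        pos = self.positions.set_index("position_id")
        roots = self.root_hosts.copy()
        roots["kind"] = "root"
        roots["x"] = pos.loc[roots["position_id"], "x"].to_numpy()
        roots["y"] = pos.loc[roots["position_id"], "y"].to_numpy()
        soils = pd.DataFrame(
            {
                "sample_id": "soil_" + self.positions["position_id"],
                "kind": "soil",
                "position_id": self.positions["position_id"],
                "x": self.positions["x"],
                "y": self.positions["y"],
                "host_plant": pd.NA,
            }
        )
        cols = list(SampleMetadata.REQUIRED)
        return SampleMetadata(pd.concat([roots[cols], soils[cols]], ignore_index=True))


@dataclass(frozen=True)
class SyntheticDataset:
    root: CommunityTable
    soil: CommunityTable
    metadata: SampleMetadata
    guilds: GuildMap
    truth: dict
    params: TruthParams


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(params: TruthParams, rng: np.random.Generator) -> Landscape:
    """Place positions on a jittered grid guaranteeing the minimum spacing and
    assign spatially clumped host plants to root samples.

    Grid cell size is 1.5 x min_spacing with jitter 0.25 x min_spacing, so
    points in adjacent cells are always >= min_spacing apart.
    """
    s = params.min_spacing
    cell = 1.5 * s
    jit = 0.25 * s
    side = math.ceil(math.sqrt(params.n_positions))
    extent = side * cell
    if params.arena_size is not None:
        fit = int(params.arena_size // cell)
        if fit * fit < params.n_positions:
            raise ValueError(
                f"cannot place {params.n_positions} positions >= {s} m apart in a "
                f"{params.arena_size} m arena; enlarge the arena"
            )
        side = fit
    cells = rng.permutation(side * side)[: params.n_positions]
    ix, iy = cells // side, cells % side
    x = ix * cell + cell / 2 + rng.uniform(-jit, jit, params.n_positions)
    y = iy * cell + cell / 2 + rng.uniform(-jit, jit, params.n_positions)
    positions = pd.DataFrame(
        {
            "position_id": [f"pos{i:03d}" for i in range(params.n_positions)],
            "x": x,
            "y": y,
        }
    )

    # Spatially clumped plant assignment: each genus has a hotspot; the
    # probability of a genus at a position decays with distance to its hotspot.
    k = len(params.plants)
    hot = rng.uniform(0, extent, size=(k, 2))
    base = rng.dirichlet(np.full(k, 2.0))
    d2 = (x[:, None] - hot[None, :, 0]) ** 2 + (y[:, None] - hot[None, :, 1]) ** 2
    w = base[None, :] * np.exp(-d2 / (2 * params.plant_clump_range ** 2))
    w = w / w.sum(axis=1, keepdims=True)

    rows = []
    sid = 0
    for q in range(params.n_positions):
        n_root = 1 + rng.poisson(max(params.samples_per_position_mean - 1, 0.0))
        hosts = rng.choice(k, size=n_root, p=w[q])
        for h in hosts:
            rows.append((f"root{sid:05d}", positions["position_id"][q], params.plants[h]))
            sid += 1
    root_hosts = pd.DataFrame(rows, columns=["sample_id", "position_id", "host_plant"])
    return Landscape(positions, root_hosts)


# ---------------------------------------------------------------------------
# Gaussian-process helpers
# ---------------------------------------------------------------------------

def _gp_fields(coords: np.ndarray, ranges: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance GP fields (positions x OTUs) with exponential covariance,
    one field per OTU with OTU-specific range; exact via Cholesky."""
    n = coords.shape[0]
    d = np.sqrt(
        (coords[:, None, 0] - coords[None, :, 0]) ** 2
        + (coords[:, None, 1] - coords[None, :, 1]) ** 2
    )
    out = np.empty((n, len(ranges)))
    chol_cache: dict[float, np.ndarray] = {}
    for j, r in enumerate(ranges):
        r = float(r)
        if r not in chol_cache:
            cov = np.exp(-d / r) + 1e-8 * np.eye(n)
            chol_cache[r] = np.linalg.cholesky(cov)
        out[:, j] = chol_cache[r] @ rng.standard_normal(n)
    return out


def _nb_depth(mean: float, size: float, n: int, rng: np.random.Generator) -> np.ndarray:
    p = size / (size + mean)
    return np.maximum(rng.negative_binomial(size, p, size=n), 1)


# ---------------------------------------------------------------------------
# Soil and root communities
# ---------------------------------------------------------------------------

def simulate_soil(
    params: TruthParams, landscape: Landscape, rng: np.random.Generator
) -> tuple[CommunityTable, np.ndarray]:
    """Soil community counts plus the latent per-OTU log-abundance fields.

    Each OTU's latent log abundance across positions is mu_s + sd * GP(range_g)
    with the guild's spatial range; counts are multinomial over softmax
    abundances given a negative-binomial depth.
    """
    coords = landscape.positions[["x", "y"]].to_numpy(dtype=float)
    guild_names = params.otu_guilds()
    ranges = np.array([params.guilds[g].spatial_range for g in guild_names])
    fields = _gp_fields(coords, ranges, rng)
    mu = rng.normal(0.0, 1.0, size=len(guild_names))
    latent = mu[None, :] + params.soil_field_sd * fields
    n_pos = landscape.n_positions
    depths = _nb_depth(params.soil_depth_mean, params.soil_depth_size, n_pos, rng)
    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs = probs / probs.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depths[q], probs[q]) for q in range(n_pos)])
    ids = ["soil_" + p for p in landscape.positions["position_id"]]
    otus = [f"OTU{j:04d}" for j in range(len(guild_names))]
    table = CommunityTable(pd.DataFrame(counts, index=ids, columns=otus))
    return table, latent


def simulate_roots(
    params: TruthParams,
    landscape: Landscape,
    soil_latents: np.ndarray,
    rng: np.random.Generator,
) -> tuple[CommunityTable, dict]:
    """Root-tip community counts from the guild-structured probit model.

    Returns the table and a truth dict with ``alpha``, ``B_plant``,
    ``soil_coupling``, ``spatial_field``, ``loadings`` and ``latent_u``.
    """
    guild_names = params.otu_guilds()
    n_otus = len(guild_names)
    r = params.n_latent_factors
    if r > n_otus:
        raise ValueError("latent dimension exceeds the number of OTUs")
    coords = landscape.positions[["x", "y"]].to_numpy(dtype=float)
    pos_index = {p: q for q, p in enumerate(landscape.positions["position_id"])}
    plants = list(params.plants)
    plant_index = {p: j for j, p in enumerate(plants)}

    lo, hi = params.base_prevalence
    alpha = norm.ppf(rng.uniform(lo, hi, size=n_otus))
    plant_sd = np.array([params.guilds[g].plant_effect_sd for g in guild_names])
    soil_c = np.array([params.guilds[g].soil_coupling for g in guild_names])
    spatial_sd = np.array([params.guilds[g].spatial_sd for g in guild_names])
    loading_sd = np.array([params.guilds[g].factor_loading_sd for g in guild_names])
    ranges = np.array([params.guilds[g].spatial_range for g in guild_names])

    b_plant = rng.normal(0.0, 1.0, size=(n_otus, len(plants))) * plant_sd[:, None]
    spatial_field = _gp_fields(coords, ranges, rng) * spatial_sd[None, :]
    loadings = rng.normal(0.0, 1.0, size=(n_otus, r)) * loading_sd[:, None]

    # standardized soil latent fields (zero mean, unit sd across positions)
    z = soil_latents - soil_latents.mean(axis=0, keepdims=True)
    sd = z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd

    n_samples = landscape.n_root_samples
    u = rng.standard_normal((n_samples, r))
    qidx = np.array([pos_index[p] for p in landscape.root_hosts["position_id"]])
    hidx = np.array([plant_index[h] for h in landscape.root_hosts["host_plant"]])

    eta = (
        alpha[None, :]
        + b_plant.T[hidx]
        + soil_c[None, :] * z[qidx]
        + spatial_field[qidx]
        + u @ loadings.T
    )
    present = rng.uniform(size=eta.shape) < norm.cdf(eta)

    depths = _nb_depth(params.root_depth_mean, params.root_depth_size, n_samples, rng)
    abund = np.exp(rng.normal(0.0, 1.0, size=eta.shape)) * present
    counts = np.zeros_like(eta, dtype=np.int64)
    for i in range(n_samples):
        tot = abund[i].sum()
        if tot > 0:
            counts[i] = rng.multinomial(depths[i], abund[i] / tot)
    otus = [f"OTU{j:04d}" for j in range(n_otus)]
    table = CommunityTable(
        pd.DataFrame(counts, index=list(landscape.root_hosts["sample_id"]), columns=otus)
    )
    truth = {
        "alpha": alpha,
        "B_plant": b_plant,
        "plants": plants,
        "soil_coupling": soil_c,
        "spatial_field": spatial_field,
        "loadings": loadings,
        "latent_u": u,
        "guilds": guild_names,
    }
    return table, truth


def generate_dataset(params: TruthParams, seed: int) -> SyntheticDataset:
    """Full root+soil dataset with metadata, guild map and generative truth."""
    rng = np.random.default_rng(seed)
    landscape = generate_landscape(params, rng)
    soil, latent = simulate_soil(params, landscape, rng)
    root, truth = simulate_roots(params, landscape, latent, rng)
    truth["soil_latent"] = latent
    guilds = GuildMap(dict(zip(root.otu_ids, params.otu_guilds())))
    return SyntheticDataset(root, soil, landscape.metadata(), guilds, truth, params)


# ---------------------------------------------------------------------------
# Gaussian-copula dataset for network inference
# ---------------------------------------------------------------------------

def generate_network_dataset(
    p: int = 50,
    n: int = 500,
    true_sparse_edges: int = 40,
    true_rank: int = 3,
    rng: int | np.random.Generator = 0,
    edge_strength: float = 0.4,
    confounder_strength: float = 1.8,
    depth_mean: float = 2e4,
    depth_size: float = 2.0,
) -> tuple[CommunityTable, dict]:
    """Counts from a Gaussian copula with precision Theta = S_true - L_true.

    ``S_true`` is sparse symmetric with ``true_sparse_edges`` off-diagonal
    pairs; ``L_true`` is PSD with rank ``true_rank`` (a latent confounder).
    Latent Gaussians are mapped to counts by a per-OTU negative-binomial
    quantile transform.  Returns the table and ``{"S_true", "L_true",
    "Theta", "edges"}``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    max_edges = p * (p - 1) // 2
    if true_sparse_edges > max_edges:
        raise ValueError("too many edges requested")
    iu = np.triu_indices(p, 1)
    pick = rng.choice(max_edges, size=true_sparse_edges, replace=False)
    s = np.zeros((p, p))
    vals = rng.uniform(0.6, 1.0, size=true_sparse_edges) * edge_strength
    vals *= rng.choice([-1.0, 1.0], size=true_sparse_edges)
    s[iu[0][pick], iu[1][pick]] = vals
    s = s + s.T
    # diagonal dominance => S positive definite
    np.fill_diagonal(s, np.abs(s).sum(axis=1) + 1.0)

    if true_rank > 0:
        # strong latent drivers: orthonormal loadings with equal eigenvalues
        # just inside the positive-definiteness limit of S - L
        lam, _ = np.linalg.qr(rng.standard_normal((p, true_rank)))
        smin = np.linalg.eigvalsh(s).min()
        ev = min(0.5 * confounder_strength, 0.95) * smin
        low = ev * (lam @ lam.T)
    else:
        low = np.zeros((p, p))
    theta = s - low
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    zraw = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    uq = norm.cdf(zraw / d)
    means = np.exp(rng.normal(np.log(depth_mean / p), 1.0, size=p))
    nb_p = depth_size / (depth_size + means)
    counts = nbinom.ppf(np.clip(uq, 1e-12, 1 - 1e-12), depth_size, nb_p[None, :])
    otus = [f"OTU{j:04d}" for j in range(p)]
    ids = [f"s{i:04d}" for i in range(n)]
    table = CommunityTable(pd.DataFrame(counts.astype(np.int64), index=ids, columns=otus))
    edges = set(zip(iu[0][pick].tolist(), iu[1][pick].tolist()))
    return table, {"S_true": s, "L_true": low, "Theta": theta, "edges": edges}


# ---------------------------------------------------------------------------
# Presets (scaled-down study conditions used throughout the test surface)
# ---------------------------------------------------------------------------

def assembly_preset() -> TruthParams:
    """Parameter-recovery conditions: ~300 root samples, 40 OTUs in three
    guild archetypes, two latent factors."""
    guilds = {
        "EcMF": GuildArchetype(16, 0.0, 1.0, 10.0, 0.8, 0.25),
        "Endophyte": GuildArchetype(16, 0.4, 0.15, 5.0, 0.15, 1.2),
        "AMF": GuildArchetype(8, 1.4, 0.2, 6.0, 0.3, 0.4),
    }
    return TruthParams(
        n_positions=75,
        plants=DEFAULT_PLANTS[:6],
        samples_per_position_mean=4.0,
        guilds=guilds,
        n_latent_factors=2,
        base_prevalence=(0.1, 0.45),
        root_depth_mean=2e4,
        soil_depth_mean=1e5,
    )


def null_preset() -> TruthParams:
    """Global-null calibration conditions: full 124-position design, 60 OTUs,
    every generative effect zero."""
    guilds = {
        "EcMF": GuildArchetype(30, spatial_range=10.0),
        "Endophyte": GuildArchetype(20, spatial_range=5.0),
        "AMF": GuildArchetype(10, spatial_range=6.0),
    }
    return TruthParams(
        n_positions=124,
        plants=DEFAULT_PLANTS,
        samples_per_position_mean=10.0,
        guilds=guilds,
        n_latent_factors=2,
        base_prevalence=(0.1, 0.4),
    ).null()


def network_preset(seed: int = 0) -> tuple[CommunityTable, dict]:
    """Network-recovery conditions: p=50 OTUs, n=500 samples, 40 true edges,
    a rank-3 latent confounder."""
    return generate_network_dataset(p=50, n=500, true_sparse_edges=40, true_rank=3,
                                    rng=np.random.default_rng(seed))
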