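"""Direct fungus–fungus association inference (sparse + low-rank model).

Un-rarefied counts are centred-log-ratio (CLR) transformed; the inverse
covariance (precision) of the CLR data is decomposed as Theta = S - L with S
sparse (direct associations) and L positive semidefinite of low rank (shared
latent environmental drivers).  The estimator solves the latent-variable
graphical lasso

    min_{S, L}  -logdet(S - L) + tr(Sigma_hat (S - L))
                + lambda ||S||_1,offdiag + gamma tr(L)
    s.t.  S - L > 0,  L >= 0

by ADMM, with gamma tuned by bisection so that rank(L) hits a requested
target; the number of latent variables (0..20) is chosen by BIC.  Edges of
the sparse part are reported as partial correlations
rho_uv = -S_uv / sqrt(S_uu S_vv); positive and negative subnetworks are
analysed separately, with Louvain modules on the positive network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .community import CommunityTable, CommunityDataError, GuildMap

__all__ = [
    "CLRMatrix",
    "SparseLowRankModel",
    "SLRResults",
    "AssociationNetwork",
    "clr",
    "slr_fit",
    "select_lambda",
    "bic_select",
    "extract_network",
    "louvain_modules",
    "degree_vs_llr",
]

_EDGE_TOL = 1e-8


@dataclass(frozen=True)
class CLRMatrix:
    """Centred log-ratio transformed counts (each row sums to zero)."""

    data: pd.DataFrame
    pseudocount: float

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def correlation(self) -> np.ndarray:
        return np.corrcoef(self.values, rowvar=False)


def clr(counts: CommunityTable | np.ndarray, pseudocount: float = 1.0) -> CLRMatrix:
    """log(counts + pseudocount) centred within each sample."""
    if isinstance(counts, CommunityTable):
        df = counts.data
    else:
        arr = np.asarray(counts)
        df = pd.DataFrame(arr)
    logx = np.log(df.to_numpy(dtype=float) + pseudocount)
    centred = logx - logx.mean(axis=1, keepdims=True)
    return CLRMatrix(pd.DataFrame(centred, index=df.index, columns=df.columns),
                     pseudocount)


# ---------------------------------------------------------------------------
# ADMM solver for the latent-variable graphical lasso
# ---------------------------------------------------------------------------

def _soft_offdiag(a: np.ndarray, thr: float) -> np.ndarray:
    out = np.sign(a) * np.maximum(np.abs(a) - thr, 0.0)
    np.fill_diagonal(out, np.diag(a))
    return out


def _objective(sigma, s, low, lam, gamma):
    theta = s - low
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    off = np.abs(s).sum() - np.abs(np.diag(s)).sum()
    return -logdet + float(np.sum(sigma * theta)) + lam * off + gamma * np.trace(low)


def _admm_lvglasso(
    sigma: np.ndarray,
    lam: float,
    gamma: float,
    rho: float = 2.0,
    max_iter: int = 800,
    tol: float = 1e-7,
    with_latent: bool = True,
    init: tuple | None = None,
):
    """ADMM for min -logdet(R) + tr(Sigma R) + lam||S||_1,off + gamma tr(L)
    subject to R = S - L, R > 0, L >= 0.  Returns (S, L, trace, converged)."""
    p = sigma.shape[0]
    if init is None:
        s = np.diag(1.0 / (np.diag(sigma) + 1e-6))
        low = np.zeros((p, p))
        dual = np.zeros((p, p))
    else:
        s, low, dual = (m.copy() for m in init)
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        # R-update (closed form via eigendecomposition)
        m = s - low - dual - sigma / rho
        d, qm = np.linalg.eigh((m + m.T) / 2)
        r_eig = (d + np.sqrt(d ** 2 + 4.0 / rho)) / 2.0
        r = (qm * r_eig) @ qm.T
        # S-update (soft threshold off-diagonal)
        s_new = _soft_offdiag(r + low + dual, lam / rho)
        # L-update (eigenvalue shrink + PSD projection)
        if with_latent:
            a = s_new - r - dual
            da, qa = np.linalg.eigh((a + a.T) / 2)
            low_new = (qa * np.maximum(da - gamma / rho, 0.0)) @ qa.T
        else:
            low_new = low
        resid = r - s_new + low_new
        dual = dual + resid
        s_chg = np.linalg.norm(s_new - s) + np.linalg.norm(low_new - low)
        s, low = s_new, low_new
        trace.append(_objective(sigma, s, low, lam, gamma))
        if np.linalg.norm(resid) < tol * p and s_chg < tol * p:
            converged = True
            break
    return s, low, dual, np.asarray(trace), converged


def _rank(low: np.ndarray, tol: float = _EDGE_TOL) -> int:
    if not np.any(low):
        return 0
    ev = np.linalg.eigvalsh((low + low.T) / 2)
    return int(np.sum(ev > tol * max(ev.max(), 1.0)))


@dataclass
class SLRResults:
    """Fitted sparse + low-rank precision decomposition."""

    s: pd.DataFrame
    low_rank: np.ndarray
    rank: int
    lambda_: float
    gamma: float
    n: int
    objective_trace: np.ndarray
    converged: bool
    bic: float = np.nan

    @property
    def otu_ids(self) -> list[str]:
        return list(self.s.index)

    @property
    def theta(self) -> np.ndarray:
        return self.s.to_numpy() - self.low_rank

    def n_edges(self) -> int:
        sm = self.s.to_numpy()
        off = np.abs(np.triu(sm, 1))
        return int(np.sum(off > _EDGE_TOL))

    def partial_correlations(self) -> pd.DataFrame:
        sm = self.s.to_numpy()
        d = np.sqrt(np.clip(np.diag(sm), 1e-12, None))
        rho = -sm / np.outer(d, d)
        np.fill_diagonal(rho, 1.0)
        rho[np.abs(sm) <= _EDGE_TOL] = 0.0
        np.fill_diagonal(rho, 1.0)
        return pd.DataFrame(rho, index=self.s.index, columns=self.s.columns)

    def summary(self) -> str:
        lines = [
            "Sparse + low-rank inverse covariance (latent-variable graphical lasso)",
            f"  OTUs:            {self.s.shape[0]}    samples: {self.n}",
            f"  lambda:          {self.lambda_:.4g}   gamma: {self.gamma:.4g}",
            f"  latent rank:     {self.rank}",
            f"  edges (sparse):  {self.n_edges()}",
            f"  BIC:             {self.bic:.2f}" if np.isfinite(self.bic) else "  BIC:             (not evaluated)",
            f"  converged:       {self.converged}",
        ]
        return "\n".join(lines)


def _compute_bic(sigma: np.ndarray, res: "SLRResults") -> float:
    theta = res.theta
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    p = sigma.shape[0]
    fit = res.n * (-logdet + float(np.sum(sigma * theta)))
    dof = res.n_edges() + res.rank * p - res.rank * (res.rank - 1) // 2
    return fit + np.log(res.n) * dof


class SparseLowRankModel:
    """Latent-variable graphical model over CLR-transformed counts.

    The empirical *correlation* matrix of the CLR data is used as the
    covariance input (scale stability).  ``fit`` targets a given latent rank;
    ``fit_bic`` scans ranks 0..20 and keeps the smallest-BIC model.
    """

    def __init__(self, data: CLRMatrix | np.ndarray, n: int | None = None,
                 otu_ids: list[str] | None = None):
        if isinstance(data, CLRMatrix):
            self.sigma = data.correlation()
            self.n = data.n
            self.otu_ids = list(data.data.columns)
        else:
            self.sigma = np.asarray(data, dtype=float)
            if n is None:
                raise ValueError("n (sample count) required with a covariance input")
            self.n = n
            self.otu_ids = otu_ids or [f"V{i}" for i in range(self.sigma.shape[0])]
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise CommunityDataError("covariance input not symmetric")

    # -- single fit at a target rank --------------------------------------
    def fit(
        self,
        lambda_: float,
        target_rank: int,
        rho: float = 2.0,
        max_iter: int = 800,
        tol: float = 1e-7,
        gamma_bracket: tuple[float, float] | None = None,
        bisect_steps: int = 30,
    ) -> SLRResults:
        """Solve at ``lambda_`` with gamma bisected until rank(L) equals
        ``target_rank`` (rank 0 = plain graphical lasso).

        rank(L) is non-increasing in gamma; ties between gammas achieving the
        target break toward the smaller gamma.  Non-convergence of the ADMM
        within ``max_iter`` is flagged on the result, not raised.
        """
        if not 0 <= target_rank <= self.sigma.shape[0]:
            raise ValueError("target_rank out of range")
        if target_rank == 0:
            s, low, dual, trace, conv = _admm_lvglasso(
                self.sigma, lambda_, 0.0, rho, max_iter, tol, with_latent=False
            )
            return self._pack(s, np.zeros_like(s), 0, lambda_, np.inf, trace, conv)
        lo, hi = gamma_bracket if gamma_bracket else (1e-4, 2.0 * np.abs(self.sigma).max())
        init = None
        best = None
        # ensure the bracket straddles the target rank
        for _ in range(bisect_steps):
            mid = np.sqrt(lo * hi)
            s, low, dual, trace, conv = _admm_lvglasso(
                self.sigma, lambda_, mid, rho, max_iter, tol, init=init
            )
            init = (s, low, dual)
            r = _rank(low)
            if r == target_rank:
                best = (s, low, mid, trace, conv)
                hi = mid  # ties toward smaller gamma: keep searching downward
            elif r > target_rank:
                lo = mid
            else:
                hi = mid
            if hi / lo < 1.005:
                break
        if best is None:
            # closest achievable rank at the final gamma
            best = (s, low, mid, trace, conv)
        s, low, gam, trace, conv = best
        return self._pack(s, low, _rank(low), lambda_, gam, trace, conv)

    def _pack(self, s, low, rank, lam, gamma, trace, conv) -> SLRResults:
        res = SLRResults(
            pd.DataFrame(s, index=self.otu_ids, columns=self.otu_ids),
            low_rank=(low + low.T) / 2,
            rank=rank,
            lambda_=lam,
            gamma=gamma,
            n=self.n,
            objective_trace=trace,
            converged=conv,
        )
        res.bic = _compute_bic(self.sigma, res)
        return res

    # -- BIC over ranks ----------------------------------------------------
    def fit_bic(
        self,
        lambda_: float | None = None,
        ranks: range = range(0, 21),
        max_density: float = 0.05,
        **fit_kw,
    ) -> tuple[SLRResults, pd.DataFrame]:
        """Fit every rank in ``ranks`` (0..20 by default) and keep the model
        with the smallest BIC; returns (best fit, BIC table)."""
        if lambda_ is None:
            lambda_ = select_lambda(self.sigma, self.n, max_density=max_density)
        rows = []
        best: SLRResults | None = None
        for r in ranks:
            res = self.fit(lambda_, r, **fit_kw)
            rows.append(
                {"rank": r, "achieved_rank": res.rank, "bic": res.bic,
                 "n_edges": res.n_edges(), "converged": res.converged}
            )
            if best is None or res.bic < best.bic:
                best = res
        table = pd.DataFrame(rows)
        return best, table


def slr_fit(clr_cov: np.ndarray, n: int, lambda_: float, target_rank: int,
            **kw) -> SLRResults:
    """Functional wrapper: latent-variable graphical lasso at a target rank."""
    return SparseLowRankModel(clr_cov, n=n).fit(lambda_, target_rank, **kw)


def select_lambda(
    sigma: np.ndarray,
    n: int,
    max_density: float = 0.05,
    n_path: int = 25,
) -> float:
    """Densest lambda on a log path whose rank-0 graph stays at or below the
    edge-density ceiling."""
    lam_max = np.abs(sigma - np.diag(np.diag(sigma))).max()
    if lam_max <= 0:
        return 1e-3
    path = np.geomspace(lam_max, lam_max * 1e-2, n_path)
    p = sigma.shape[0]
    max_edges = p * (p - 1) / 2
    chosen = path[0]
    init = None
    for lam in path:
        s, low, dual, _, _ = _admm_lvglasso(
            sigma, lam, 0.0, max_iter=300, with_latent=False, init=init
        )
        init = (s, low, dual)
        density = np.sum(np.abs(np.triu(s, 1)) > _EDGE_TOL) / max_edges
        if density <= max_density:
            chosen = lam
        else:
            break
    return float(chosen)


def bic_select(
    clr_matrix: CLRMatrix,
    ranks: range = range(0, 21),
    lambda_: float | None = None,
    **fit_kw,
) -> tuple[SLRResults, pd.DataFrame]:
    """BIC model selection over latent ranks 0..20 for CLR data."""
    model = SparseLowRankModel(clr_matrix)
    return model.fit_bic(lambda_=lambda_, ranks=ranks, **fit_kw)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class AssociationNetwork:
    """Signed association network from the sparse component."""

    nodes: pd.DataFrame   # index otu_id, column guild
    edges: pd.DataFrame   # otu1, otu2, partial_correlation, sign, amf_pair

    def subnetwork(self, sign: int) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        sub = self.edges[self.edges["sign"] == sign]
        for _, row in sub.iterrows():
            g.add_edge(row["otu1"], row["otu2"],
                       weight=abs(row["partial_correlation"]))
        return g

    def degrees(self, sign: int) -> pd.Series:
        g = self.subnetwork(sign)
        return pd.Series(dict(g.degree()), name=f"degree_{'pos' if sign > 0 else 'neg'}")


def extract_network(fit: SLRResults, guilds: GuildMap | None = None) -> AssociationNetwork:
    """Edge list from the sparse component with signed partial correlations.

    AMF–AMF pairs are flagged (their apparent co-occurrences can reflect the
    multi-genome biology of arbuscular mycorrhizal fungi rather than
    interactions) so downstream reports can exclude them.
    """
    rho = fit.partial_correlations().to_numpy()
    ids = fit.otu_ids
    guild = (
        pd.Series(guilds.guild_of(ids), index=ids)
        if guilds is not None
        else pd.Series("Unassigned", index=ids)
    )
    iu = np.triu_indices(len(ids), 1)
    mask = np.abs(fit.s.to_numpy()[iu]) > _EDGE_TOL
    rows = []
    for a, b in zip(iu[0][mask], iu[1][mask]):
        w = rho[a, b]
        rows.append(
            {
                "otu1": ids[a],
                "otu2": ids[b],
                "partial_correlation": w,
                "sign": int(np.sign(w)),
                "amf_pair": guild[ids[a]] == "AMF" and guild[ids[b]] == "AMF",
            }
        )
    edges = pd.DataFrame(rows, columns=["otu1", "otu2", "partial_correlation",
                                        "sign", "amf_pair"])
    return AssociationNetwork(pd.DataFrame({"guild": guild}), edges)


def louvain_modules(
    network: AssociationNetwork | nx.Graph, seed: int = 0
) -> tuple[pd.Series, float]:
    """Louvain community detection on the positive association network.

    Returns module assignments (singletons allowed) and the modularity of the
    partition; deterministic for a fixed seed.
    """
    g = network.subnetwork(1) if isinstance(network, AssociationNetwork) else network
    comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    assign = {}
    for k, nodes in enumerate(comms):
        for node in nodes:
            assign[node] = k
    mod = nx.community.modularity(g, comms, weight="weight") if g.number_of_edges() else 0.0
    return pd.Series(assign, name="module"), float(mod)


def degree_vs_llr(
    network: AssociationNetwork,
    cov_llr: pd.Series,
    occurrence: pd.Series | None = None,
    log_abundance: pd.Series | None = None,
) -> pd.DataFrame:
    """Kendall tau-b concordance of network degree centrality with the jSDM
    covariance log-likelihood ratio (and optionally occurrence/abundance)."""
    rows = []
    for sign, label in ((1, "positive"), (-1, "negative")):
        deg = network.degrees(sign)
        common = deg.index.intersection(cov_llr.index)
        targets = {"cov_llr": cov_llr}
        if occurrence is not None:
            targets["occurrence"] = occurrence
        if log_abundance is not None:
            targets["log_abundance"] = log_abundance
        for tname, series in targets.items():
            idx = deg.index.intersection(series.index)
            tau, p = kendalltau(deg.loc[idx], series.loc[idx])
            rows.append(
                {"network": label, "against": tname, "kendall_tau": tau,
                 "p": p, "n": len(idx)}
            )
    return pd.DataFrame(rows)
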