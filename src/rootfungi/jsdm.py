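"""Latent-factor multivariate probit joint species distribution model (jSDM).

Occurrences of many fungal OTUs across root samples are modelled jointly:

    P(y_is = 1 | u_i) = Phi(x_i' beta_s + lambda_s' u_i),   u_i ~ N(0, I_r)

where the covariate blocks are host plant identity (P), principal coordinates
of the background soil fungal community (S), spatial eigenvectors of the
sampling positions (Sp), and the shared latent factors u_i carrying residual
fungus–fungus covariance (Cov).  The marginal likelihood integrates the
factors out; it is estimated by Monte Carlo with common random numbers and
maximised by L-BFGS.  Without the Cov term the model factorises into
independent probit regressions and the likelihood is exact.

The 16-model lattice enumerates every subset of {P, S, Sp, Cov}; per-OTU
log-likelihood ratios between specific model pairs attribute explanatory
power to each factor, and Steel–Dwass tests compare those ratios between
fungal guilds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr, logsumexp
from scipy.stats import rankdata, studentized_range

from .community import CommunityTable, CommunityDataError, GuildMap, SampleMetadata, to_binary
from .ordination import bray_curtis, pcoa, spatial_eigenvectors

__all__ = [
    "ModelSpec",
    "MODEL_LATTICE",
    "DesignMatrices",
    "JointProbitModel",
    "JSDMResults",
    "LatticeResults",
    "FactorAttribution",
    "prepare_inputs",
    "fit_lattice",
    "per_otu_llr",
    "attribute_factors",
    "steel_dwass",
    "roc_auc",
]

_LOG_CLIP = np.log(1e-12)


# ---------------------------------------------------------------------------
# Model specifications (Table-1 style lattice)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which factor blocks enter the model; all False is the null model."""

    include_p: bool = False
    include_s: bool = False
    include_sp: bool = False
    include_cov: bool = False

    @property
    def name(self) -> str:
        parts = [
            lab
            for flag, lab in (
                (self.include_p, "P"),
                (self.include_s, "S"),
                (self.include_sp, "Sp"),
                (self.include_cov, "Cov"),
            )
            if flag
        ]
        if not parts:
            return "Null"
        if len(parts) == 4:
            return "Full (P + S + Sp + Cov)"
        return " + ".join(parts)


def _lattice_specs() -> list[ModelSpec]:
    # Full first, then by decreasing factor count, P-major order, Null last.
    specs = sorted(
        (ModelSpec(*flags) for flags in itertools.product([True, False], repeat=4)),
        key=lambda s: (
            -(s.include_p + s.include_s + s.include_sp + s.include_cov),
            not s.include_p,
            not s.include_s,
            not s.include_sp,
        ),
    )
    return specs


#: The 16 models examined, Full first and Null last.
MODEL_LATTICE: tuple[ModelSpec, ...] = tuple(_lattice_specs())


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrices:
    """Covariate blocks aligned with the filtered root samples.

    ``p`` holds host-plant dummies (reference genus dropped), ``s`` the soil
    PCoA axes mapped to root samples by position, ``sp`` the spatial
    eigenvectors, ``extra`` optional continuous covariates (e.g. soil pH).
    """

    sample_ids: list[str]
    p: pd.DataFrame
    s: pd.DataFrame
    sp: pd.DataFrame
    extra: pd.DataFrame | None = None

    def matrix(self, spec: ModelSpec) -> np.ndarray:
        blocks = [np.ones((len(self.sample_ids), 1))]
        if spec.include_p:
            blocks.append(self.p.to_numpy(dtype=float))
        if spec.include_s:
            blocks.append(self.s.to_numpy(dtype=float))
        if spec.include_sp:
            blocks.append(self.sp.to_numpy(dtype=float))
        if self.extra is not None:
            blocks.append(self.extra.to_numpy(dtype=float))
        return np.hstack(blocks)

    def column_names(self, spec: ModelSpec) -> list[str]:
        names = ["intercept"]
        if spec.include_p:
            names += list(self.p.columns)
        if spec.include_s:
            names += list(self.s.columns)
        if spec.include_sp:
            names += list(self.sp.columns)
        if self.extra is not None:
            names += list(self.extra.columns)
        return names


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    return (df - df.mean(axis=0)) / sd


def prepare_inputs(
    root_table: CommunityTable,
    soil_table: CommunityTable,
    metadata: SampleMetadata,
    min_host_samples: int = 30,
    cum_threshold: float = 0.90,
    max_soil_axes: int | None = None,
    max_spatial: int | None = None,
    extra: pd.DataFrame | None = None,
    min_otu_occurrence: int = 1,
) -> tuple[pd.DataFrame, DesignMatrices]:
    """Build the binary response and covariate blocks for the jSDM.

    Root samples at positions lacking a soil sample are dropped, as are root
    samples of infrequent host plants (fewer than ``min_host_samples``).  Soil
    community structure enters as Bray–Curtis PCoA axes up to the cumulative
    contribution threshold; spatial structure as positive-eigenvalue spatial
    eigenvectors.  OTUs observed in every retained sample or in fewer than
    ``min_otu_occurrence`` samples are excluded (their probit intercepts are
    unidentifiable).
    """
    meta = metadata.data.set_index("sample_id")
    soil_pos = meta.loc[[s for s in soil_table.sample_ids if s in meta.index], "position_id"]
    covered = set(soil_pos)
    roots = metadata.roots
    roots = roots[roots["sample_id"].isin(root_table.sample_ids)]
    roots = roots[roots["position_id"].isin(covered)]
    host_counts = roots["host_plant"].value_counts()
    keep_hosts = host_counts[host_counts >= min_host_samples].index
    roots = roots[roots["host_plant"].isin(keep_hosts)]
    if roots["host_plant"].nunique() < 2:
        raise CommunityDataError("fewer than 2 host plant levels after filtering")
    roots = roots.reset_index(drop=True)
    sample_ids = list(roots["sample_id"])

    y = to_binary(root_table.subset_samples(sample_ids)).data
    prev = y.sum(axis=0)
    keep_otus = (prev >= min_otu_occurrence) & (prev < len(y))
    y = y.loc[:, keep_otus]

    # host plant dummies, most frequent genus as reference
    ref = roots["host_plant"].value_counts().idxmax()
    dummies = pd.get_dummies(roots["host_plant"]).astype(float)
    dummies = dummies.drop(columns=[ref])
    dummies.columns = [f"plant:{c}" for c in dummies.columns]
    dummies.index = sample_ids

    # soil PCoA axes at the positions retained
    pos_of_root = roots.set_index("sample_id")["position_id"]
    used_pos = sorted(set(pos_of_root))
    soil_ids = [s for s in soil_table.sample_ids if meta.loc[s, "position_id"] in used_pos]
    soil_sub = soil_table.subset_samples(soil_ids)
    ord_res = pcoa(bray_curtis(soil_sub), cum_threshold=cum_threshold)
    s_by_pos = ord_res.as_frame()
    s_by_pos.index = [meta.loc[s, "position_id"] for s in soil_ids]
    if max_soil_axes is not None:
        s_by_pos = s_by_pos.iloc[:, :max_soil_axes]
    s_block = _standardize(s_by_pos.loc[pos_of_root].set_index(pos_of_root.index))
    s_block.columns = [f"soil:{c}" for c in s_block.columns]

    # spatial eigenvectors over the retained positions
    pos_meta = metadata.data[metadata.data["position_id"].isin(used_pos)]
    sev = spatial_eigenvectors(SampleMetadata(pos_meta.reset_index(drop=True)))
    sp_by_pos = sev.as_frame()
    if max_spatial is not None:
        sp_by_pos = sp_by_pos.iloc[:, :max_spatial]
    sp_block = _standardize(sp_by_pos.loc[pos_of_root].set_index(pos_of_root.index))
    sp_block.columns = [f"space:{c}" for c in sp_block.columns]

    extra_block = None
    if extra is not None:
        extra_block = _standardize(extra.loc[sample_ids].astype(float))

    # no constant non-intercept columns
    for block in (dummies, s_block, sp_block):
        const = block.std(axis=0, ddof=0) == 0
        if const.any():
            block.drop(columns=block.columns[const], inplace=True)

    designs = DesignMatrices(sample_ids, dummies, s_block, sp_block, extra_block)
    return y, designs


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _draws(n_factors: int, mc_samples: int, seed: int) -> np.ndarray:
    """Common random numbers: fixed standard-normal draws, (M, r)."""
    if n_factors == 0:
        return np.zeros((1, 0))
    rng = np.random.default_rng(seed)
    return rng.standard_normal((mc_samples, n_factors))


def _log_bernoulli(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Clipped log Bernoulli(y | Phi(eta)); shapes broadcast."""
    lp = np.where(y, log_ndtr(eta), log_ndtr(-eta))
    return np.maximum(lp, _LOG_CLIP)


def _loglik_parts(
    b: np.ndarray,
    lam: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    want_grad: bool,
):
    """Joint MC log-likelihood and (optionally) gradients.

    Shapes: x (n,p), y (n,S) boolean, b (p,S), lam (S,r), u (M,r).
    Returns (ll, grad_b, grad_lam, weights, lp) where lp is (n,M,S).
    """
    m = u.shape[0]
    eta = x @ b  # (n, S)
    eta = eta[:, None, :] + (u @ lam.T)[None, :, :]  # (n, M, S)
    lp = _log_bernoulli(eta, y[:, None, :])
    l_im = lp.sum(axis=2)  # (n, M)
    ll_i = logsumexp(l_im, axis=1) - np.log(m)
    ll = float(ll_i.sum())
    if not want_grad:
        return ll, None, None, None, lp, l_im, ll_i
    w = np.exp(l_im - ll_i[:, None] - np.log(m))  # posterior weights, rows sum to 1
    # probit score d log Bern / d eta, zeroed where the log-prob was clipped
    log_phi = -0.5 * eta ** 2 - 0.5 * np.log(2 * np.pi)
    score = np.where(y[:, None, :], np.exp(log_phi - log_ndtr(eta)),
                     -np.exp(log_phi - log_ndtr(-eta)))
    score = np.where(lp > _LOG_CLIP + 1e-12, score, 0.0)
    g = np.einsum("im,ims->is", w, score)
    grad_b = x.T @ g
    grad_lam = np.einsum("im,ims,mk->sk", w, score, u)
    return ll, grad_b, grad_lam, w, lp, l_im, ll_i


class JointProbitModel:
    """Latent-factor multivariate probit model for one model specification.

    Parameters
    ----------
    response : pandas.DataFrame
        Binary occurrences, samples x OTUs.
    designs : DesignMatrices
        Covariate blocks; ``spec`` selects which enter.
    spec : ModelSpec
    n_factors : int
        Latent dimension r; must be >= 1 exactly when ``spec.include_cov``.
    mc_samples : int
        Monte Carlo draws used during fitting (common random numbers).
    seed : int
        Seed for the common random numbers; fits are reproducible given
        (seed, mc_samples, optimizer settings).
    """

    def __init__(
        self,
        response: pd.DataFrame,
        designs: DesignMatrices,
        spec: ModelSpec,
        n_factors: int = 8,
        mc_samples: int = 100,
        seed: int = 0,
    ):
        if spec.include_cov and n_factors < 1:
            raise ValueError("include_cov requires n_factors >= 1")
        self.response = response
        self.designs = designs
        self.spec = spec
        self.r = n_factors if spec.include_cov else 0
        if self.r > response.shape[1]:
            raise ValueError("latent dimension exceeds the number of OTUs")
        self.mc_samples = mc_samples if spec.include_cov else 1
        self.seed = seed
        self.x = designs.matrix(spec)
        self.y = response.to_numpy(dtype=bool)
        self.u = _draws(self.r, self.mc_samples, seed)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        maxiter: int = 300,
        ridge: float = 1e-6,
        init_b: np.ndarray | None = None,
        init_loadings: np.ndarray | None = None,
        gtol: float = 1e-5,
    ) -> "JSDMResults":
        """Maximise the (MC) marginal likelihood by L-BFGS.

        A small ridge penalty (excluding the intercept) keeps coefficients
        finite under perfect separation.  Non-convergence is flagged on the
        results object, not raised.
        """
        n, s = self.y.shape
        p = self.x.shape[1]
        r = self.r
        rng = np.random.default_rng(self.seed + 1)
        b0 = np.zeros((p, s)) if init_b is None else init_b.copy()
        if init_b is None:
            from scipy.stats import norm as _norm
            prev = self.y.mean(axis=0).clip(1e-3, 1 - 1e-3)
            b0[0] = _norm.ppf(prev)
        lam0 = (
            0.05 * rng.standard_normal((s, r))
            if init_loadings is None
            else init_loadings.copy()
        )
        trace: list[float] = []

        def unpack(theta):
            return theta[: p * s].reshape(p, s), theta[p * s:].reshape(s, r)

        def objective(theta):
            b, lam = unpack(theta)
            ll, gb, gl, *_ = _loglik_parts(b, lam, self.x, self.y, self.u, True)
            pen = 0.5 * ridge * (np.sum(b[1:] ** 2) + np.sum(lam ** 2))
            gb = -gb / n
            gb[1:] += ridge * b[1:] / n
            gl = -gl / n + ridge * lam / n
            trace.append(ll)
            return -(ll - pen) / n, np.concatenate([gb.ravel(), gl.ravel()])

        theta0 = np.concatenate([b0.ravel(), lam0.ravel()])
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "maxcor": 20},
        )
        b_hat, lam_hat = unpack(res.x)
        return JSDMResults(
            model=self,
            spec=self.spec,
            b=pd.DataFrame(b_hat, index=self.designs.column_names(self.spec),
                           columns=self.response.columns),
            loadings=pd.DataFrame(lam_hat, index=self.response.columns,
                                  columns=[f"factor{k + 1}" for k in range(r)]),
            converged=bool(res.success),
            n_iter=int(res.nit),
            trace=np.asarray(trace),
            mc_samples=self.mc_samples,
            seed=self.seed,
        )


@dataclass
class JSDMResults:
    """Fitted jSDM: coefficients, loadings, likelihoods and diagnostics."""

    model: JointProbitModel
    spec: ModelSpec
    b: pd.DataFrame
    loadings: pd.DataFrame
    converged: bool
    n_iter: int
    trace: np.ndarray
    mc_samples: int
    seed: int
    _ll_cache: dict = field(default_factory=dict, repr=False)

    # -- likelihood --------------------------------------------------------
    def log_likelihood(
        self, mc_samples: int = 1000, seed: int | None = None, chunk: int = 64
    ) -> tuple[float, pd.Series]:
        """Monte-Carlo joint log-likelihood and a per-OTU decomposition.

        The per-OTU vector is the posterior-weighted expected log Bernoulli
        term per OTU plus an equal share of the factor-mixing entropy, so it
        sums exactly to the total; for models without latent factors it is the
        exact Bernoulli decomposition.
        """
        seed = self.seed if seed is None else seed
        key = (mc_samples, seed)
        if key in self._ll_cache:
            return self._ll_cache[key]
        m = self.model
        u = _draws(m.r, mc_samples if m.r else 1, seed)
        bmat = self.b.to_numpy()
        lam = self.loadings.to_numpy()
        n, s = m.y.shape
        total = 0.0
        per = np.zeros(s)
        for lo in range(0, n, chunk):
            sl = slice(lo, min(lo + chunk, n))
            _, _, _, _, lp, l_im, ll_i = _loglik_parts(bmat, lam, m.x[sl], m.y[sl], u, False)
            w = np.exp(l_im - ll_i[:, None] - np.log(u.shape[0]))
            per += np.einsum("im,ims->s", w, lp)
            gap = ll_i - np.einsum("im,im->i", w, l_im)
            per += gap.sum() / s
            total += ll_i.sum()
        out = (float(total), pd.Series(per, index=self.response_columns))
        self._ll_cache[key] = out
        return out

    @property
    def response_columns(self) -> pd.Index:
        return self.model.response.columns

    @property
    def total_loglik(self) -> float:
        return self.log_likelihood()[0]

    @property
    def per_otu_loglik(self) -> pd.Series:
        return self.log_likelihood()[1]

    # -- predictions -------------------------------------------------------
    def predicted_probabilities(
        self, mc_samples: int = 1000, seed: int | None = None, kind: str = "posterior"
    ) -> pd.DataFrame:
        """Fitted occurrence probabilities.

        ``kind="marginal"`` integrates the latent factors against their prior,
        E_u[Phi(x'b + lam'u)]; ``kind="posterior"`` (default) weights the
        draws by each sample's posterior over u given its observed occurrence
        vector — the usual in-sample fitted values for a latent-factor model.
        The two coincide for models without latent factors.
        """
        seed = self.seed if seed is None else seed
        m = self.model
        u = _draws(m.r, mc_samples if m.r else 1, seed)
        bmat = self.b.to_numpy()
        lam = self.loadings.to_numpy()
        eta = (m.x @ bmat)[:, None, :] + (u @ lam.T)[None]
        if kind == "marginal" or m.r == 0:
            probs = ndtr(eta).mean(axis=1)
        elif kind == "posterior":
            lp = _log_bernoulli(eta, m.y[:, None, :])
            l_im = lp.sum(axis=2)
            w = np.exp(l_im - logsumexp(l_im, axis=1, keepdims=True))
            probs = np.einsum("im,ims->is", w, ndtr(eta))
        else:
            raise ValueError("kind must be 'posterior' or 'marginal'")
        return pd.DataFrame(probs, index=m.response.index, columns=m.response.columns)

    def roc_auc(self, mc_samples: int = 200, kind: str = "posterior") -> float:
        """Pooled rank-based AUC over every (sample, OTU) cell."""
        probs = self.predicted_probabilities(mc_samples=mc_samples, kind=kind)
        return roc_auc(probs.to_numpy().ravel(), self.model.y.ravel())

    def summary(self) -> str:
        n, s = self.model.y.shape
        total = self.total_loglik
        lines = [
            "Joint species distribution model (latent-factor probit)",
            f"  model:        {self.spec.name}",
            f"  samples:      {n}    OTUs: {s}",
            f"  covariates:   {self.b.shape[0]}   latent factors: {self.loadings.shape[1]}",
            f"  MC draws:     {self.mc_samples} (fit)",
            f"  log-lik:      {total:.2f}",
            f"  converged:    {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Lattice fitting and factor attribution
# ---------------------------------------------------------------------------

@dataclass
class LatticeResults:
    """All 16 fitted models plus an LL-sorted report table."""

    results: dict[str, JSDMResults]
    eval_mc_samples: int
    eval_seed: int

    def __getitem__(self, name: str) -> JSDMResults:
        return self.results[name]

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for name, res in self.results.items():
            ll, _ = res.log_likelihood(self.eval_mc_samples, self.eval_seed)
            rows.append(
                {
                    "model": name,
                    "log_likelihood": ll,
                    "P": res.spec.include_p,
                    "S": res.spec.include_s,
                    "Sp": res.spec.include_sp,
                    "Cov": res.spec.include_cov,
                    "converged": res.converged,
                }
            )
        return (
            pd.DataFrame(rows)
            .sort_values("log_likelihood", ascending=False)
            .reset_index(drop=True)
        )


def fit_lattice(
    response: pd.DataFrame,
    designs: DesignMatrices,
    n_factors: int = 8,
    seed: int = 0,
    mc_samples: int = 100,
    eval_mc_samples: int = 1000,
    maxiter: int = 300,
    ridge: float = 1e-6,
) -> LatticeResults:
    """Fit all 16 models of the factor lattice with a shared seed.

    Models with latent factors are initialised from the fit of the
    corresponding factor-free model (coefficients carried over, loadings
    started near zero) so training log-likelihood is non-decreasing along
    nesting edges up to Monte Carlo error.
    """
    results: dict[str, JSDMResults] = {}
    order = [s for s in MODEL_LATTICE if not s.include_cov] + [
        s for s in MODEL_LATTICE if s.include_cov
    ]
    for spec in order:
        init_b = None
        if spec.include_cov:
            base = ModelSpec(spec.include_p, spec.include_s, spec.include_sp, False)
            base_res = results[base.name]
            init_b = base_res.b.to_numpy()
        model = JointProbitModel(
            response, designs, spec,
            n_factors=n_factors if spec.include_cov else 0,
            mc_samples=mc_samples, seed=seed,
        )
        results[spec.name] = model.fit(maxiter=maxiter, ridge=ridge, init_b=init_b)
    return LatticeResults(results, eval_mc_samples, seed)


def per_otu_llr(
    fit_a: JSDMResults,
    fit_b: JSDMResults,
    mc_samples: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Per-OTU log-likelihood ratio LL_s(A) - LL_s(B) with shared MC draws."""
    _, la = fit_a.log_likelihood(mc_samples, seed)
    _, lb = fit_b.log_likelihood(mc_samples, seed)
    return la - lb


#: The four factor-attribution comparisons: each factor's contribution is the
#: LLR of the covariance-free model P + S + Sp against the model dropping that
#: factor; the Cov contribution is Full vs P + S + Sp.
COMPARISON_PAIRS: dict[str, tuple[str, str]] = {
    "P": ("P + S + Sp", "S + Sp"),
    "S": ("P + S + Sp", "P + Sp"),
    "Sp": ("P + S + Sp", "P + S"),
    "Cov": ("Full (P + S + Sp + Cov)", "P + S + Sp"),
}


@dataclass
class FactorAttribution:
    """Per-OTU LLRs for each factor plus optional guild comparisons."""

    llr: pd.DataFrame  # OTUs x {P, S, Sp, Cov}
    comparison_pairs: dict[str, tuple[str, str]]
    guild_labels: pd.Series | None = None
    guild_tests: dict[str, pd.DataFrame] = field(default_factory=dict)

    def guild_medians(self, factor: str) -> pd.Series:
        if self.guild_labels is None:
            raise ValueError("no guild labels attached")
        return self.llr[factor].groupby(self.guild_labels).median()


def attribute_factors(
    lattice: LatticeResults,
    guilds: GuildMap | None = None,
    min_guild_size: int = 5,
) -> FactorAttribution:
    """Attribute explanatory power to P, S, Sp and Cov via the four fixed
    model comparisons, optionally with Steel–Dwass guild tests."""
    cols = {}
    for factor, (a, b) in COMPARISON_PAIRS.items():
        cols[factor] = per_otu_llr(
            lattice[a], lattice[b], lattice.eval_mc_samples, lattice.eval_seed
        )
    llr = pd.DataFrame(cols)
    guild_labels = None
    tests: dict[str, pd.DataFrame] = {}
    if guilds is not None:
        guild_labels = pd.Series(guilds.guild_of(llr.index), index=llr.index)
        for factor in llr.columns:
            try:
                tests[factor] = steel_dwass(
                    llr[factor].to_numpy(), guild_labels.to_numpy(), min_guild_size
                )
            except CommunityDataError:
                continue
    return FactorAttribution(llr, dict(COMPARISON_PAIRS), guild_labels, tests)


# ---------------------------------------------------------------------------
# Steel–Dwass all-pairs rank test and AUC
# ---------------------------------------------------------------------------

def _sd_pair(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    na, nb = len(x), len(y)
    n = na + nb
    ranks = rankdata(np.concatenate([x, y]))
    ra = ranks[:na].sum()
    expect = na * (n + 1) / 2.0
    var = na * nb / (n * (n - 1.0)) * (np.sum(ranks ** 2) - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0, 1.0
    t = (ra - expect) / np.sqrt(var)
    p = float(studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
    return float(t), min(max(p, 0.0), 1.0)


def _letter_display(groups: list[str], sig: set[frozenset]) -> dict[str, str]:
    """Compact letters: groups sharing a letter are not significantly different."""
    letters: list[set[str]] = []
    for g in groups:
        placed = False
        for bucket in letters:
            if all(frozenset((g, h)) not in sig for h in bucket):
                bucket.add(g)
                placed = True
        if not placed:
            letters.append({g})
    out = {g: "" for g in groups}
    for i, bucket in enumerate(letters):
        ch = chr(ord("a") + i)
        for g in bucket:
            out[g] += ch
    return out


def steel_dwass(
    values: np.ndarray,
    group_labels: np.ndarray,
    min_group_size: int = 5,
) -> pd.DataFrame:
    """All-pairs Steel–Dwass–Critchlow–Fligner comparisons.

    Pairwise rank statistics with average-rank ties, calibrated against the
    studentized range distribution with k groups and infinite df.  Groups
    smaller than ``min_group_size`` are excluded.  Returns a tidy frame of
    pairs with ``statistic``, ``p``, and per-group ``letters`` attached in
    ``DataFrame.attrs``.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names, counts = np.unique(group_labels, return_counts=True)
    eligible = [str(g) for g, c in zip(names, counts) if c >= min_group_size]
    if len(eligible) < 2:
        raise CommunityDataError("fewer than 2 groups meet the minimum size")
    k = len(eligible)
    data = {g: values[group_labels == g] for g in eligible}
    rows = []
    sig = set()
    for a, b in itertools.combinations(eligible, 2):
        t, p = _sd_pair(data[a], data[b], k)
        rows.append({"group1": a, "group2": b, "statistic": t, "p": p})
        if p < 0.05:
            sig.add(frozenset((a, b)))
    out = pd.DataFrame(rows)
    order = sorted(eligible, key=lambda g: -np.median(data[g]))
    out.attrs["letters"] = _letter_display(order, sig)
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    n1 = labels.sum()
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))
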