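"""Seeded evaluation experiments on the synthetic study conditions.

Each function runs one calibration or parameter-recovery experiment end to
end — generate data with known truth, run the corresponding analysis stage,
measure the outcome — and returns plain dictionaries of numbers.  These are
the routines behind the package's reproducibility script and the heavier
property tests; problem sizes are the scaled-down study conditions described
in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .community import to_binary
from .habitat import glm_soil_coupling_all, mantel_correlogram
from .jsdm import (
    COMPARISON_PAIRS,
    JointProbitModel,
    ModelSpec,
    per_otu_llr,
    prepare_inputs,
    roc_auc,
)
from .network import SparseLowRankModel, clr, select_lambda
from .preference import standardized_preference
from .simulate import (
    assembly_preset,
    generate_dataset,
    generate_network_dataset,
    null_preset,
)

__all__ = [
    "preference_null_calibration",
    "mantel_null_calibration",
    "assembly_replicate",
    "assembly_recovery",
    "glm_recovery",
    "network_edge_f1",
    "bic_rank_calibration",
    "confounder_absorption",
]


def _subseed(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Global-null calibration
# ---------------------------------------------------------------------------

def preference_null_calibration(
    n_replicates: int = 50, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Standardized-preference z under the global null.

    Returns the grand mean and SD of z over all non-degenerate OTUs and the
    proportion of q < 0.05 discoveries averaged over replicates.
    """
    params = null_preset()
    zs: list[np.ndarray] = []
    disc = []
    for k in range(n_replicates):
        s = _subseed(seed, k)
        ds = generate_dataset(params, seed=s)
        res = standardized_preference(
            to_binary(ds.root), ds.metadata, n_perm=n_perm, seed=s,
            min_otu_occurrence=30, min_host_samples=30,
        )
        ok = res.otus[~res.otus["degenerate"]]
        zs.append(ok["z"].to_numpy())
        disc.append(float((ok["q"] < 0.05).mean()))
    z = np.concatenate(zs)
    return {
        "z_mean": float(z.mean()),
        "z_sd": float(z.std(ddof=0)),
        "fdr_discovery_rate": float(np.mean(disc)),
        "n_otus": int(z.size),
        "n_replicates": n_replicates,
    }


def mantel_null_calibration(
    n_replicates: int = 100, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Per-class rejection rate of the Mantel correlogram on spatially
    unstructured (global-null) communities; should sit near alpha = 0.05."""
    params = null_preset()
    rejected = 0
    total = 0
    for k in range(n_replicates):
        s = _subseed(seed, k + 10_000)
        ds = generate_dataset(params, seed=s)
        res = mantel_correlogram(
            to_binary(ds.root), ds.metadata, n_perm=n_perm, seed=s
        )
        p = res.classes["p"].to_numpy()
        p = p[np.isfinite(p)]
        rejected += int((p < 0.05).sum())
        total += p.size
    return {
        "rejection_rate": rejected / total if total else np.nan,
        "n_classes_total": total,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Assembly-preset parameter recovery
# ---------------------------------------------------------------------------

def assembly_replicate(
    seed: int,
    mc_samples: int = 40,
    maxiter: int = 150,
    eval_mc: int = 400,
    n_factors: int = 2,
) -> dict:
    """One assembly-preset replicate: fit the five attribution models and
    return guild-median LLRs, ordering indicators and the full-model AUC."""
    ds = generate_dataset(assembly_preset(), seed=seed)
    y, designs = prepare_inputs(ds.root, ds.soil, ds.metadata, min_host_samples=30)
    fits = {}
    specs = {
        "P + S + Sp": ModelSpec(True, True, True, False),
        "S + Sp": ModelSpec(False, True, True, False),
        "P + Sp": ModelSpec(True, False, True, False),
        "P + S": ModelSpec(True, True, False, False),
    }
    for name, spec in specs.items():
        fits[name] = JointProbitModel(
            y, designs, spec, n_factors=0, mc_samples=1, seed=11
        ).fit(maxiter=maxiter)
    full_spec = ModelSpec(True, True, True, True)
    fits["Full (P + S + Sp + Cov)"] = JointProbitModel(
        y, designs, full_spec, n_factors=n_factors, mc_samples=mc_samples, seed=11
    ).fit(maxiter=maxiter, init_b=fits["P + S + Sp"].b.to_numpy())
    eval_seed = 97
    llr = {
        f: per_otu_llr(fits[a], fits[b], eval_mc, eval_seed)
        for f, (a, b) in COMPARISON_PAIRS.items()
    }
    guild = pd.Series([ds.guilds[o] for o in y.columns], index=y.columns)
    med = {f: v.groupby(guild).median() for f, v in llr.items()}
    plant_truth_sd = {"EcMF": 0.0, "Endophyte": 0.4, "AMF": 1.4}
    has_effect = guild.map(plant_truth_sd).to_numpy() > 0
    return {
        "plant_llr_auc": roc_auc(llr["P"].to_numpy(), has_effect),
        "soil_order_ok": bool(med["S"]["EcMF"] > med["S"]["Endophyte"]),
        "cov_order_ok": bool(med["Cov"]["Endophyte"] > med["Cov"]["EcMF"]),
        "full_auc": fits["Full (P + S + Sp + Cov)"].roc_auc(),
        "guild_median_llr": {f: m.to_dict() for f, m in med.items()},
    }


def assembly_recovery(n_seeds: int = 20, seed: int = 0, **kw) -> dict:
    """Aggregate the assembly-preset recovery over seeded replicates."""
    reps = [assembly_replicate(_subseed(seed, k + 20_000), **kw) for k in range(n_seeds)]
    return {
        "plant_llr_auc": float(np.mean([r["plant_llr_auc"] for r in reps])),
        "soil_order_fraction": float(np.mean([r["soil_order_ok"] for r in reps])),
        "cov_order_fraction": float(np.mean([r["cov_order_ok"] for r in reps])),
        "full_model_auc": float(np.mean([r["full_auc"] for r in reps])),
        "n_seeds": n_seeds,
    }


def glm_recovery(n_replicates: int = 20, seed: int = 0) -> dict:
    """Soil-coupling GLM recovery.

    Coupled OTUs (EcMF archetype, probit soil coupling 1.0) should yield
    positive significant standardized coefficients; on global-null data the
    coefficients should centre at zero.
    """
    params = assembly_preset()
    hit = []
    for k in range(n_replicates):
        s = _subseed(seed, k + 30_000)
        ds = generate_dataset(params, seed=s)
        res = glm_soil_coupling_all(ds.root, ds.soil, ds.metadata,
                                    min_root=15, min_soil=5)
        guild = pd.Series([ds.guilds[o] for o in res.index], index=res.index)
        ecmf = res[guild == "EcMF"]
        ok = ecmf["converged"] & np.isfinite(ecmf["soil_coefficient"])
        ecmf = ecmf[ok]
        if ecmf.empty:
            continue
        frac_sig = float(((ecmf["soil_coefficient"] > 0) & (ecmf["p"] < 0.05)).mean())
        hit.append(float(np.median(ecmf["soil_coefficient"]) > 0 and frac_sig >= 0.5))
    nullco = []
    for k in range(max(n_replicates // 4, 3)):
        s = _subseed(seed, k + 40_000)
        ds = generate_dataset(null_preset(), seed=s)
        res = glm_soil_coupling_all(ds.root, ds.soil, ds.metadata,
                                    min_root=15, min_soil=5)
        res = res[res["converged"] & np.isfinite(res["soil_coefficient"])]
        nullco.append(res["soil_coefficient"].to_numpy())
    nullco = np.concatenate(nullco) if nullco else np.array([np.nan])
    return {
        "coupled_recovery_rate": float(np.mean(hit)) if hit else np.nan,
        "null_coefficient_mean": float(np.nanmean(nullco)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Network recovery
# ---------------------------------------------------------------------------

def _edge_sets(fit, p: int):
    iu = np.triu_indices(p, 1)
    mask = np.abs(fit.s.to_numpy()[iu]) > 1e-8
    return set(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


def _f1(est: set, truth: set) -> float:
    tp = len(est & truth)
    return 2 * tp / (len(est) + len(truth)) if est or truth else 1.0


def network_edge_f1(seed: int = 0, n_lambda: int = 16, n_replicates: int = 1) -> dict:
    """Edge-recovery F1 at the oracle lambda (the best on a log path, judged
    against the ground-truth edge set) with the true latent rank, averaged
    over replicate datasets."""
    f1s = []
    lams = []
    n_true = 0
    for k in range(n_replicates):
        tab, truth = generate_network_dataset(rng=_subseed(seed, k + 60_000))
        model = SparseLowRankModel(clr(tab))
        p = len(model.otu_ids)
        best, best_lam = 0.0, np.nan
        for lam in np.geomspace(0.03, 0.35, n_lambda):
            fit = model.fit(lam, 3)
            f1 = _f1(_edge_sets(fit, p), truth["edges"])
            if f1 > best:
                best, best_lam = f1, float(lam)
        f1s.append(best)
        lams.append(best_lam)
        n_true = len(truth["edges"])
    return {
        "edge_f1": float(np.mean(f1s)),
        "oracle_lambda": float(np.mean(lams)),
        "n_true_edges": n_true,
        "n_replicates": n_replicates,
    }


def bic_rank_calibration(
    n_replicates: int = 10, seed: int = 0, ranks: range = range(0, 21)
) -> dict:
    """BIC-selected latent rank across replicates of the rank-3 generator."""
    hits = []
    selected = []
    for k in range(n_replicates):
        s = _subseed(seed, k + 50_000)
        tab, _ = generate_network_dataset(rng=s)
        model = SparseLowRankModel(clr(tab))
        fit, _table = model.fit_bic(ranks=ranks)
        selected.append(fit.rank)
        hits.append(abs(fit.rank - 3) <= 2)
    return {
        "rank_within2_fraction": float(np.mean(hits)),
        "selected_ranks": selected,
        "n_replicates": n_replicates,
    }


def confounder_absorption(seed: int = 0) -> dict:
    """With no true edges and a strong rank-2 confounder, the latent model at
    the BIC rank should emit far fewer edges than the rank-0 graphical lasso
    at the same lambda."""
    tab, _ = generate_network_dataset(
        true_sparse_edges=0, true_rank=2, rng=seed
    )
    model = SparseLowRankModel(clr(tab))
    lam = select_lambda(model.sigma, model.n)
    rank0 = model.fit(lam, 0)
    best, _table = model.fit_bic(lambda_=lam, ranks=range(0, 9))
    e0, eb = rank0.n_edges(), best.n_edges()
    return {
        "rank0_edges": e0,
        "slr_edges": eb,
        "edge_ratio": eb / e0 if e0 else np.nan,
        "bic_rank": best.rank,
        "lambda": lam,
    }
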