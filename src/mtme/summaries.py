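"""Posterior genetic-parameter summaries and model comparison.

Derived quantities are computed sample-by-sample from the retained
chain, so every summary carries a full posterior distribution:

* broad-sense heritability  h2 = sigma_g^2 / (sigma_g^2 + sigma_r^2 + sigma_e^2)
  per trait and environment, where under the full model the genetic
  variance for an environment is the genotype main-effect variance plus
  that environment's interaction variance (main only under the null
  model);
* genetic correlation between two traits within an environment, from
  the corresponding genetic covariance entries;
* genotypic and residual coefficients of variation (percent of the
  trait's observed mean) and their ratio, the relative variation index;
* DIC = D(theta_bar) + 2 pD with pD = mean(D) - D(theta_bar), by default
  on the marginal deviance (random effects integrated out), with the
  conditional (given random effects) deviance available as an option;
* genotype genetic values (main + environment deviation) with HPD
  intervals and descending ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import hpd_interval, posterior_mode
from .gibbs import PosteriorChain, gaussian_deviance
from .model import AssembledModel

__all__ = [
    "ParameterSummary",
    "ModelComparison",
    "heritability_samples",
    "genetic_correlation_samples",
    "coefficient_of_variation",
    "relative_variation_index",
    "dic",
    "compare_models",
    "genotype_values",
    "summary_table",
]


@dataclass(frozen=True)
class ParameterSummary:
    parameter: str
    mean: float
    median: float
    mode: float
    hpd_lower: float
    hpd_upper: float


@dataclass(frozen=True)
class ModelComparison:
    dic_full: float
    dic_null: float
    pd_full: float
    pd_null: float

    @property
    def delta(self) -> float:
        """DIC(null) - DIC(full); positive favours the full model."""
        return self.dic_null - self.dic_full

    @property
    def preferred(self) -> str:
        if self.delta > 2:
            return "full"
        if self.delta < -2:
            return "null"
        return "indistinguishable"


def _genetic_cov_samples(chain: PosteriorChain, env_idx: int) -> np.ndarray:
    """(S, T, T) genetic covariance per iteration for one environment:
    main-effect covariance, plus the environment's interaction covariance
    under the full model."""
    g = chain.cov["genotype"]
    if "gxe" in chain.cov:
        return g + chain.cov["gxe"][:, env_idx]
    return g


def heritability_samples(chain: PosteriorChain, trait: str, environment: str) -> np.ndarray:
    """Per-iteration broad-sense heritability for one trait in one
    environment; every sample lies in [0, 1]."""
    t = chain.trait_index(trait)
    e = chain.env_index(environment)
    sg = _genetic_cov_samples(chain, e)[:, t, t]
    sr = chain.cov["block"][:, e, t, t] if "block" in chain.cov else 0.0
    se = chain.cov["residual"][:, e, t, t]
    return sg / (sg + sr + se)


def genetic_correlation_samples(
    chain: PosteriorChain, trait_a: str, trait_b: str, environment: str
) -> tuple[np.ndarray, int]:
    """Per-iteration genetic correlation between two traits in one
    environment.  Returns (samples in [-1, 1], number of zero-variance
    iterations excluded)."""
    if trait_a == trait_b:
        raise ValueError("genetic correlation requires two distinct traits")
    a = chain.trait_index(trait_a)
    b = chain.trait_index(trait_b)
    e = chain.env_index(environment)
    G = _genetic_cov_samples(chain, e)
    va, vb, cab = G[:, a, a], G[:, b, b], G[:, a, b]
    ok = (va > 0) & (vb > 0)
    rho = cab[ok] / np.sqrt(va[ok] * vb[ok])
    return rho, int((~ok).sum())


def relative_variation_index(cv_g: float, cv_e: float) -> float:
    """Ratio CVg/CVe; values above 1 indicate genetic variation dominates
    residual variation."""
    if cv_e <= 0:
        raise ValueError("CVe must be positive")
    return cv_g / cv_e


def coefficient_of_variation(
    chain: PosteriorChain, table, trait: str, environment: str
) -> tuple[float, float, float]:
    """(CVg%, CVe%, CVg/CVe) from posterior-mean variance components and
    the observed trait mean in that environment."""
    t = chain.trait_index(trait)
    e = chain.env_index(environment)
    df = table.to_frame()
    sel = (df["trait"] == trait) & (df["environment"] == environment)
    mean_pheno = float(df.loc[sel, "value"].mean())
    if not np.isfinite(mean_pheno) or mean_pheno == 0:
        raise ValueError(
            f"phenotype mean for ({trait}, {environment}) is zero or undefined"
        )
    sg = float(_genetic_cov_samples(chain, e)[:, t, t].mean())
    se = float(chain.cov["residual"][:, e, t, t].mean())
    cv_g = 100.0 * np.sqrt(sg) / abs(mean_pheno)
    cv_e = 100.0 * np.sqrt(se) / abs(mean_pheno)
    return cv_g, cv_e, relative_variation_index(cv_g, cv_e)


def _marginal_deviance_factory(chain: PosteriorChain, model: AssembledModel):
    """Return a function computing -2 log N(y; X beta, V(theta)) with the
    random effects integrated out:
    V = sum_k Z_k (I ⊗ Sigma_k) Z_k' + R."""
    n, T = model.Y.shape
    env = model.env_of_plot
    n_obs = n * T
    E = len(chain.environments)
    masks = {
        name: ti.plot_level[:, None] == ti.plot_level[None, :]
        for name, ti in model.terms.items()
    }
    env_col = env[:, None]
    eye_plot = np.eye(n, dtype=bool)
    const = n_obs * np.log(2.0 * np.pi)

    def deviance(beta: np.ndarray, covs: dict, res: np.ndarray) -> float:
        V = np.zeros((n, n, T, T))
        for name, mask in masks.items():
            arr = covs[name]
            if arr.ndim == 2:  # shared across environments
                V[mask] += arr
            else:  # per-environment (levels never cross environments)
                for e in range(E):
                    V[mask & (env_col == e)] += arr[e]
        for e in range(E):
            V[eye_plot & (env_col == e)] += res[e]
        Vm = V.transpose(0, 2, 1, 3).reshape(n_obs, n_obs)
        r = (model.Y - beta[env]).ravel()
        L = np.linalg.cholesky(Vm)
        z = np.linalg.solve(L, r)
        return float(const + 2.0 * np.sum(np.log(np.diag(L))) + z @ z)

    return deviance


def dic(
    chain: PosteriorChain,
    model: AssembledModel,
    deviance: str = "marginal",
    max_samples: int = 400,
) -> tuple[float, float]:
    """(DIC, pD) with pD = mean(D) - D(theta_bar) and DIC = mean(D) + pD.

    ``deviance="marginal"`` (default) integrates the random effects out of
    the likelihood, so theta is (beta, covariance matrices); the marginal
    deviance is evaluated on an evenly spaced subsample of at most
    ``max_samples`` retained draws.  With many random-effect levels the
    conditional deviance rewards effects that merely absorb noise, so the
    marginal version discriminates nested models far more reliably.

    ``deviance="conditional"`` uses the per-iteration conditional deviance
    track stored in the chain, with theta_bar plugging in posterior means
    of beta, all effect levels, and the residual covariances.
    """
    if deviance == "conditional":
        if chain.deviance.size == 0:
            raise ValueError("chain has no stored deviance track")
        mean_dev = float(chain.deviance.mean())
        beta_bar = chain.beta.mean(axis=0)  # (E, T)
        resid = model.Y - beta_bar[model.env_of_plot]
        for name, means in chain.effect_means.items():
            resid = resid - means[model.terms[name].plot_level]
        res_bar = chain.cov["residual"].mean(axis=0)  # (E, T, T)
        d_at_mean = gaussian_deviance(resid, res_bar, model.env_of_plot)
        p_d = mean_dev - d_at_mean
        return d_at_mean + 2.0 * p_d, p_d
    if deviance != "marginal":
        raise ValueError("deviance must be 'marginal' or 'conditional'")
    dev_fn = _marginal_deviance_factory(chain, model)
    term_names = list(model.terms)
    idx = np.unique(
        np.linspace(0, chain.n_samples - 1, min(max_samples, chain.n_samples)).astype(int)
    )
    devs = [
        dev_fn(
            chain.beta[i],
            {name: chain.cov[name][i] for name in term_names},
            chain.cov["residual"][i],
        )
        for i in idx
    ]
    mean_dev = float(np.mean(devs))
    d_at_mean = dev_fn(
        chain.beta.mean(axis=0),
        {name: chain.cov[name].mean(axis=0) for name in term_names},
        chain.cov["residual"].mean(axis=0),
    )
    p_d = mean_dev - d_at_mean
    return d_at_mean + 2.0 * p_d, p_d


def compare_models(
    fit_full: tuple[PosteriorChain, AssembledModel],
    fit_null: tuple[PosteriorChain, AssembledModel],
) -> ModelComparison:
    """DIC comparison of a full (interaction) and null fit on the same data."""
    chain_f, model_f = fit_full
    chain_n, model_n = fit_null
    if chain_f.data_fingerprint != chain_n.data_fingerprint:
        raise ValueError("model comparison requires fits on identical data")
    dic_f, pd_f = dic(chain_f, model_f)
    dic_n, pd_n = dic(chain_n, model_n)
    return ModelComparison(dic_full=dic_f, dic_null=dic_n, pd_full=pd_f, pd_null=pd_n)


def genotype_values(
    chain: PosteriorChain, environment: str, trait: str, prob: float = 0.95
) -> pd.DataFrame:
    """Posterior-mean genetic value (main + environment deviation) per
    genotype with HPD interval, ranked descending (ties broken by label)."""
    if chain.effects is None:
        raise ValueError(
            "effect samples were not stored; re-run the sampler with "
            "store_effects=True to rank genotype values"
        )
    t = chain.trait_index(trait)
    chain.env_index(environment)
    g_samples = chain.effects["genotype"][:, :, t]  # (S, G)
    genotypes = [str(lv) for lv in chain.effect_levels["genotype"]]
    total = g_samples
    if "gxe" in chain.effects:
        levels = chain.effect_levels["gxe"]
        col_of = {lv[1]: i for i, lv in enumerate(levels) if lv[0] == environment}
        dev = chain.effects["gxe"][:, [col_of[g] for g in genotypes], t]
        total = g_samples + dev
    rows = []
    for j, g in enumerate(genotypes):
        lo, hi = hpd_interval(total[:, j], prob)
        rows.append((g, float(total[:, j].mean()), lo, hi))
    df = pd.DataFrame(rows, columns=["genotype", "genetic_value", "hpd_lower", "hpd_upper"])
    df = df.sort_values(
        ["genetic_value", "genotype"], ascending=[False, True]
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df


def _summarize(name: str, samples: np.ndarray, prob: float = 0.95) -> ParameterSummary:
    lo, hi = hpd_interval(samples, prob)
    return ParameterSummary(
        parameter=name,
        mean=float(np.mean(samples)),
        median=float(np.median(samples)),
        mode=posterior_mode(samples),
        hpd_lower=lo,
        hpd_upper=hi,
    )


def summary_table(chain: PosteriorChain, prob: float = 0.95) -> pd.DataFrame:
    """One row per cell mean, variance component, heritability, and
    genetic correlation, each with posterior mean/median/mode and HPD."""
    rows: list[ParameterSummary] = []
    for ei, e in enumerate(chain.environments):
        for ti, t in enumerate(chain.traits):
            rows.append(_summarize(f"beta[{e}|{t}]", chain.beta[:, ei, ti], prob))
    for name, arr in chain.cov.items():
        if arr.ndim == 3:  # shared (S, T, T)
            for ti, t in enumerate(chain.traits):
                rows.append(_summarize(f"var_{name}[{t}]", arr[:, ti, ti], prob))
        else:
            for ei, e in enumerate(chain.environments):
                for ti, t in enumerate(chain.traits):
                    rows.append(
                        _summarize(f"var_{name}[{e}|{t}]", arr[:, ei, ti, ti], prob)
                    )
    for e in chain.environments:
        for t in chain.traits:
            rows.append(
                _summarize(f"h2[{e}|{t}]", heritability_samples(chain, t, e), prob)
            )
        for i, a in enumerate(chain.traits):
            for b in chain.traits[i + 1 :]:
                rho, _ = genetic_correlation_samples(chain, a, b, e)
                if rho.size:
                    rows.append(_summarize(f"rho[{e}|{a},{b}]", rho, prob))
    return pd.DataFrame([r.__dict__ for r in rows])
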