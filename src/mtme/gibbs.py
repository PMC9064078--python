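"""Gibbs sampler for Bayesian multi-trait multi-environment mixed models.

Every full conditional is available in closed form: fixed effects and
random-effect levels are multivariate Gaussian; each unstructured
covariance matrix (per random term, and the residual per environment)
is inverse-Wishart.  One systematic scan per iteration updates, in
order: beta, each random term's level effects (in spec order), each
term's covariance, then the per-environment residual covariances; the
conditional deviance is recorded for every retained draw.

Traits are internally standardized to unit empirical variance for
numerical conditioning (switchable); every stored quantity is
back-transformed to the original trait scale.  Two runs with the same
model, priors, and seed produce bit-identical chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ConfigError, PriorSpec, RunConfig
from .model import AssembledModel

__all__ = [
    "PosteriorChain",
    "SamplerError",
    "run_gibbs",
    "gaussian_deviance",
    "sample_inverse_wishart",
]


class SamplerError(RuntimeError):
    """Numerical failure inside the Gibbs sweep (with iteration index)."""


_TRIL_CACHE: dict[int, tuple] = {}


def _tril_idx(d: int):
    if d not in _TRIL_CACHE:
        _TRIL_CACHE[d] = (np.tril_indices(d, -1), np.diag_indices(d), np.arange(d))
    return _TRIL_CACHE[d]


def sample_inverse_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from IW(df, scale): density ∝ |S|^{-(df+d+1)/2} exp(-tr(scale S^{-1})/2).

    Bartlett decomposition; for d = 1 this reduces to scale / chi2(df).
    """
    d = scale.shape[0]
    if df <= d - 1:
        raise ConfigError(f"inverse-Wishart df must exceed d-1={d - 1}, got {df}")
    if d == 1:
        return scale / rng.chisquare(df)
    # W ~ Wishart(df, scale^{-1});  return W^{-1}
    tril, diag, rng_d = _tril_idx(d)
    C = np.linalg.cholesky(scale)
    M = np.linalg.solve(C.T, np.eye(d))  # M M' = scale^{-1}
    A = np.zeros((d, d))
    A[tril] = rng.standard_normal(len(tril[0]))
    A[diag] = np.sqrt(rng.chisquare(df - rng_d))
    L = M @ A
    W = L @ L.T
    out = np.linalg.inv(W)
    return 0.5 * (out + out.T)


def gaussian_deviance(resid: np.ndarray, cov_by_env: np.ndarray, env_of_plot: np.ndarray) -> float:
    """Conditional deviance -2 log p(y | beta, effects, residual covariances).

    ``resid`` is the (n_plots, T) matrix of plot-level trait residuals;
    each plot in environment e contributes a N_T(0, cov_by_env[e])
    log-density.
    """
    n, T = resid.shape
    dev = 0.0
    for e in range(cov_by_env.shape[0]):
        mask = env_of_plot == e
        ne = int(mask.sum())
        if ne == 0:
            continue
        try:
            L = np.linalg.cholesky(cov_by_env[e])
        except np.linalg.LinAlgError as exc:
            raise SamplerError(f"singular residual covariance in environment {e}") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        z = np.linalg.solve(L, resid[mask].T)
        quad = float(np.sum(z * z))
        dev += ne * (T * np.log(2.0 * np.pi) + logdet) + quad
    return dev


@dataclass
class PosteriorChain:
    """Retained MCMC samples, on the original trait scale.

    ``cov`` maps term name -> samples: shape (S, T, T) for the shared
    genotype term, (S, E, T, T) for per-environment terms and for
    ``"residual"``.  ``effect_means`` holds running posterior means of
    every random-effect level (always available); full effect samples
    are kept only when the run was configured with ``store_effects``.
    """

    traits: tuple[str, ...]
    environments: tuple[str, ...]
    variant: str
    beta: np.ndarray                      # (S, E, T)
    cov: dict[str, np.ndarray]
    deviance: np.ndarray                  # (S,)
    effect_means: dict[str, np.ndarray]   # term -> (q, T)
    effect_levels: dict[str, list]
    effects: dict[str, np.ndarray] | None  # term -> (S, q, T) if stored
    seed: int
    config: dict
    data_fingerprint: str

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not in chain (have {self.traits})") from None

    def env_index(self, environment: str) -> int:
        try:
            return self.environments.index(environment)
        except ValueError:
            raise KeyError(
                f"environment {environment!r} not in chain (have {self.environments})"
            ) from None

    # ---- persistence (CSV per parameter group + JSON sidecar) ----------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        S, E, T = self.beta.shape
        cols = {
            f"beta[{e}|{t}]": self.beta[:, ei, ti]
            for ei, e in enumerate(self.environments)
            for ti, t in enumerate(self.traits)
        }
        pd.DataFrame({"iteration": np.arange(S), **cols}).to_csv(
            d / "beta.csv", index=False
        )
        for name, arr in self.cov.items():
            cols = {}
            if arr.ndim == 3:  # (S, T, T)
                for i, a in enumerate(self.traits):
                    for j, b in enumerate(self.traits):
                        if i <= j:
                            cols[f"cov[{a}|{b}]"] = arr[:, i, j]
            else:  # (S, E, T, T)
                for ei, e in enumerate(self.environments):
                    for i, a in enumerate(self.traits):
                        for j, b in enumerate(self.traits):
                            if i <= j:
                                cols[f"cov[{e}|{a}|{b}]"] = arr[:, ei, i, j]
            pd.DataFrame({"iteration": np.arange(S), **cols}).to_csv(
                d / f"cov_{name}.csv", index=False
            )
        pd.DataFrame({"iteration": np.arange(S), "deviance": self.deviance}).to_csv(
            d / "deviance.csv", index=False
        )
        if self.effects is not None:
            for name, arr in self.effects.items():
                q = arr.shape[1]
                cols = {
                    f"u[{lv}|{t}]": arr[:, li, ti]
                    for li, lv in enumerate(self._level_strs(name))
                    for ti, t in enumerate(self.traits)
                }
                pd.DataFrame({"iteration": np.arange(S), **cols}).to_csv(
                    d / f"effects_{name}.csv", index=False
                )
        meta = {
            "traits": list(self.traits),
            "environments": list(self.environments),
            "variant": self.variant,
            "seed": self.seed,
            "config": self.config,
            "data_fingerprint": self.data_fingerprint,
            "effect_levels": {k: [list(map(str, lv)) if isinstance(lv, tuple) else str(lv) for lv in v] for k, v in self.effect_levels.items()},
            "effect_means": {k: v.tolist() for k, v in self.effect_means.items()},
            "has_effect_samples": self.effects is not None,
            "cov_shapes": {k: list(v.shape) for k, v in self.cov.items()},
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    def _level_strs(self, name: str) -> list[str]:
        return [
            "|".join(lv) if isinstance(lv, (tuple, list)) else str(lv)
            for lv in self.effect_levels[name]
        ]

    @classmethod
    def load(cls, directory: str | Path) -> "PosteriorChain":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        traits = tuple(meta["traits"])
        envs = tuple(meta["environments"])
        T, E = len(traits), len(envs)
        beta_df = pd.read_csv(d / "beta.csv")
        S = len(beta_df)
        beta = np.empty((S, E, T))
        for ei, e in enumerate(envs):
            for ti, t in enumerate(traits):
                beta[:, ei, ti] = beta_df[f"beta[{e}|{t}]"]
        cov: dict[str, np.ndarray] = {}
        for name, shape in meta["cov_shapes"].items():
            df = pd.read_csv(d / f"cov_{name}.csv")
            arr = np.empty([S] + shape[1:])
            if len(shape) == 3:
                for i, a in enumerate(traits):
                    for j, b in enumerate(traits):
                        key = f"cov[{a}|{b}]" if i <= j else f"cov[{b}|{a}]"
                        arr[:, i, j] = df[key]
            else:
                for ei, e in enumerate(envs):
                    for i, a in enumerate(traits):
                        for j, b in enumerate(traits):
                            key = f"cov[{e}|{a}|{b}]" if i <= j else f"cov[{e}|{b}|{a}]"
                            arr[:, ei, i, j] = df[key]
            cov[name] = arr
        deviance = pd.read_csv(d / "deviance.csv")["deviance"].to_numpy()
        effect_levels = {
            k: [tuple(lv) if isinstance(lv, list) else lv for lv in v]
            for k, v in meta["effect_levels"].items()
        }
        effect_means = {k: np.array(v) for k, v in meta["effect_means"].items()}
        effects = None
        if meta["has_effect_samples"]:
            effects = {}
            for name in effect_levels:
                df = pd.read_csv(d / f"effects_{name}.csv")
                q = len(effect_levels[name])
                arr = np.empty((S, q, T))
                level_strs = [
                    "|".join(lv) if isinstance(lv, tuple) else str(lv)
                    for lv in effect_levels[name]
                ]
                for li, lv in enumerate(level_strs):
                    for ti, t in enumerate(traits):
                        arr[:, li, ti] = df[f"u[{lv}|{t}]"]
                effects[name] = arr
        return cls(
            traits=traits,
            environments=envs,
            variant=meta["variant"],
            beta=beta,
            cov=cov,
            deviance=deviance,
            effect_means=effect_means,
            effect_levels=effect_levels,
            effects=effects,
            seed=meta["seed"],
            config=meta["config"],
            data_fingerprint=meta["data_fingerprint"],
        )


def run_gibbs(model: AssembledModel, config: RunConfig) -> PosteriorChain:
    """Run the Gibbs sampler and return the retained, thinned chain.

    Priors come from ``config.prior``; ``config.standardize`` controls the
    internal unit-variance rescaling of each trait (priors are interpreted
    on the working scale).  Retained samples number
    floor((n_iter - burn_in)/thin) and must be >= 1.
    """
    prior = config.prior
    rng = np.random.default_rng(config.seed)
    T = len(model.traits)
    E = len(model.environments)
    n = model.Y.shape[0]
    env = model.env_of_plot
    n_e = model.n_plots_per_env.astype(float)
    prior.validate(T)
    if config.n_retained < 1:
        raise ConfigError("chain plan retains no samples")

    # working scale
    if config.standardize:
        s = model.Y.std(axis=0, ddof=0)
        if np.any(s <= 0):
            raise ConfigError("cannot standardize a trait with zero variance")
    else:
        s = np.ones(T)
    Ys = model.Y / s

    nu0 = float(prior.nu0) if prior.nu0 is not None else T + 1.0
    V0 = prior.v0_scale * np.eye(T)
    v_beta = prior.v_beta

    fix_beta = None
    if prior.fix_beta is not None:
        fix_beta = np.asarray(prior.fix_beta, dtype=float) / s
        if fix_beta.shape != (E, T):
            raise ConfigError(f"fix_beta must have shape ({E}, {T})")
    fix_res = None
    if prior.fix_residual is not None:
        fix_res = np.empty((E, T, T))
        for ei, e in enumerate(model.environments):
            fix_res[ei] = np.asarray(prior.fix_residual[e], dtype=float) / np.outer(s, s)

    # term bookkeeping
    term_names = [t.name for t in model.spec.random_terms]
    terms = {name: model.terms[name] for name in term_names}
    per_env = {name: terms[name].term.per_environment for name in term_names}
    env_levels = {
        name: [np.where(terms[name].level_env == e)[0] for e in range(E)]
        for name in term_names
    }
    env_plots = [np.where(env == e)[0] for e in range(E)]
    # plots per level (balanced): per env for per-env terms; per (level, env) otherwise
    counts = {}
    for name in term_names:
        ti = terms[name]
        if per_env[name]:
            counts[name] = [
                n_e[e] / max(len(env_levels[name][e]), 1) for e in range(E)
            ]
        else:
            counts[name] = [n_e[e] / ti.n_levels for e in range(E)]

    # initial state
    beta = fix_beta.copy() if fix_beta is not None else np.array(
        [Ys[env_plots[e]].mean(axis=0) for e in range(E)]
    )
    effects = {name: np.zeros((terms[name].n_levels, T)) for name in term_names}
    cov = {}
    for name in term_names:
        init = np.eye(T) * 0.1
        cov[name] = (
            np.tile(init, (E, 1, 1)) if per_env[name] else init.copy()
        )
    res_cov = fix_res.copy() if fix_res is not None else np.tile(np.eye(T), (E, 1, 1))

    S_keep = config.n_retained
    beta_out = np.empty((S_keep, E, T))
    cov_out = {
        name: np.empty((S_keep, E, T, T)) if per_env[name] else np.empty((S_keep, T, T))
        for name in term_names
    }
    cov_out["residual"] = np.empty((S_keep, E, T, T))
    dev_out = np.empty(S_keep)
    eff_out = (
        {name: np.empty((S_keep, terms[name].n_levels, T)) for name in term_names}
        if config.store_effects
        else None
    )
    eff_mean = {name: np.zeros((terms[name].n_levels, T)) for name in term_names}

    log_jacobian = 2.0 * n * float(np.sum(np.log(s)))
    scale_outer = np.outer(s, s)

    def chol_or_fail(A: np.ndarray, it: int, what: str) -> np.ndarray:
        try:
            return np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise SamplerError(
                f"non-SPD conditional precision for {what} at iteration {it}"
            ) from exc

    kept = 0
    eye_T = np.eye(T)
    for it in range(config.n_iter):
        prec = np.empty((E, T, T))
        for e in range(E):
            Lr = chol_or_fail(res_cov[e], it, f"residual env {e}")
            inv_L = np.linalg.solve(Lr, eye_T)
            prec[e] = inv_L.T @ inv_L

        eff_sum = np.zeros((n, T))
        for name in term_names:
            eff_sum += effects[name][terms[name].plot_level]

        # -- fixed effects (cell means per environment) -----------------
        if fix_beta is None:
            R = Ys - eff_sum
            for e in range(E):
                Se = R[env_plots[e]].sum(axis=0)
                A = n_e[e] * prec[e] + eye_T / v_beta
                L = chol_or_fail(A, it, f"beta env {e}")
                mean = np.linalg.solve(A, prec[e] @ Se)
                z = rng.standard_normal(T)
                beta[e] = mean + np.linalg.solve(L.T, z)

        resid = Ys - beta[env] - eff_sum

        # -- random-effect levels ---------------------------------------
        for name in term_names:
            ti = terms[name]
            own = effects[name][ti.plot_level]
            Rk = resid + own
            q = ti.n_levels
            Ssum = np.zeros((q, T))
            np.add.at(Ssum, ti.plot_level, Rk)
            new_eff = np.empty_like(effects[name])
            if per_env[name]:
                for e in range(E):
                    idx = env_levels[name][e]
                    if len(idx) == 0:
                        continue
                    Sig_inv = np.linalg.inv(cov[name][e])
                    A = counts[name][e] * prec[e] + Sig_inv
                    L = chol_or_fail(A, it, f"{name} env {e}")
                    rhs = Ssum[idx] @ prec[e].T
                    means = np.linalg.solve(A, rhs.T).T
                    z = rng.standard_normal((T, len(idx)))
                    new_eff[idx] = means + np.linalg.solve(L.T, z).T
            else:
                comb = ti.plot_level * E + env
                S2 = np.zeros((q * E, T))
                np.add.at(S2, comb, Rk)
                S2 = S2.reshape(q, E, T)
                Sig_inv = np.linalg.inv(cov[name])
                A = Sig_inv + sum(counts[name][e] * prec[e] for e in range(E))
                L = chol_or_fail(A, it, name)
                rhs = sum(S2[:, e, :] @ prec[e].T for e in range(E))
                means = np.linalg.solve(A, rhs.T).T
                z = rng.standard_normal((T, q))
                new_eff = means + np.linalg.solve(L.T, z).T
            resid += own - new_eff[ti.plot_level]
            effects[name] = new_eff

        # -- term covariances -------------------------------------------
        for name in term_names:
            U = effects[name]
            if per_env[name]:
                for e in range(E):
                    idx = env_levels[name][e]
                    Ue = U[idx]
                    cov[name][e] = sample_inverse_wishart(
                        rng, nu0 + len(idx), V0 + Ue.T @ Ue
                    )
            else:
                cov[name] = sample_inverse_wishart(
                    rng, nu0 + U.shape[0], V0 + U.T @ U
                )

        # -- residual covariance per environment ------------------------
        if fix_res is None:
            for e in range(E):
                Ee = resid[env_plots[e]]
                res_cov[e] = sample_inverse_wishart(
                    rng, nu0 + len(Ee), V0 + Ee.T @ Ee
                )

        # -- bookkeeping -------------------------------------------------
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            if kept < S_keep:
                beta_out[kept] = beta * s
                for name in term_names:
                    if per_env[name]:
                        cov_out[name][kept] = cov[name] * scale_outer
                    else:
                        cov_out[name][kept] = cov[name] * scale_outer
                cov_out["residual"][kept] = res_cov * scale_outer
                dev_out[kept] = (
                    gaussian_deviance(resid, res_cov, env) + log_jacobian
                )
                for name in term_names:
                    scaled = effects[name] * s
                    eff_mean[name] += scaled
                    if eff_out is not None:
                        eff_out[name][kept] = scaled
                kept += 1

    for name in eff_mean:
        eff_mean[name] /= max(kept, 1)

    return PosteriorChain(
        traits=model.traits,
        environments=model.environments,
        variant=model.spec.variant,
        beta=beta_out,
        cov=cov_out,
        deviance=dev_out,
        effect_means=eff_mean,
        effect_levels={name: list(terms[name].levels) for name in term_names},
        effects=eff_out,
        seed=config.seed,
        config={
            "n_iter": config.n_iter,
            "burn_in": config.burn_in,
            "thin": config.thin,
            "store_effects": config.store_effects,
            "standardize": config.standardize,
            "nu0": nu0,
            "v0_scale": prior.v0_scale,
            "v_beta": prior.v_beta,
        },
        data_fingerprint=model.data_fingerprint(),
    )
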