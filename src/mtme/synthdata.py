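"""Synthetic phenotype generation for multi-environment RCBD trials.

Generates plot x trait observations from the additive Gaussian model

    y_{iekt} = beta[e, t] + g_{it} + ge_{iet} + r_{ekt} + eps_{iekt}

with genotype main effects g_i ~ N_T(0, Sigma_g) shared across
environments, per-environment genotype deviations (the G x E
interaction) ge_{ie} ~ N_T(0, Sigma_int_e), block effects
r_{ek} ~ N_T(0, Sigma_r_e) and plot residuals eps ~ N_T(0, Sigma_e_e).
The true parameters are kept alongside the generated table so that
parameter-recovery checks can compare posterior intervals against them.

The bundled ``rice`` scenario emulates a flood-irrigated rice trial:
25 genotypes, 2 environments, 3 complete blocks per environment, and two
traits — grain yield (GY, kg/ha) and days to flowering (FL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import PhenotypeRecord, PhenotypeTable, ValidationError

__all__ = [
    "TrialDesign",
    "GenerativeTruth",
    "correlation_to_covariance",
    "simulate_phenotypes",
    "default_rice_scenario",
    "RICE_SCENARIO",
]


@dataclass(frozen=True)
class TrialDesign:
    """Dimensions and labels of a balanced multi-environment RCBD trial."""

    n_genotypes: int
    environments: tuple[str, ...]
    blocks_per_environment: int
    traits: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValidationError("need at least 2 genotypes")
        if len(self.environments) < 1:
            raise ValidationError("need at least 1 environment")
        if self.blocks_per_environment < 2:
            raise ValidationError("need at least 2 blocks per environment")
        if len(self.traits) < 1:
            raise ValidationError("need at least 1 trait")

    @property
    def genotype_labels(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    @property
    def block_labels(self) -> list[str]:
        return [str(k + 1) for k in range(self.blocks_per_environment)]

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * len(self.environments) * self.blocks_per_environment


def _check_spd(name: str, m: np.ndarray, dim: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (dim, dim):
        raise ValidationError(f"{name} must be {dim}x{dim}, got shape {m.shape}")
    if not np.allclose(m, m.T):
        raise ValidationError(f"{name} is not symmetric")
    w = np.linalg.eigvalsh(m)
    if w[0] <= 0:
        raise ValidationError(
            f"{name} is not positive-definite (smallest eigenvalue {w[0]:.3g})"
        )
    return m


@dataclass
class GenerativeTruth:
    """True parameters of the simulation, on the trait's own scale.

    beta: (E, T) environment x trait cell means.
    sigma_g: (T, T) genotype main-effect covariance.
    sigma_int: env -> (T, T) G x E deviation covariance.
    sigma_r: env -> (T, T) block-effect covariance.
    sigma_e: env -> (T, T) plot residual covariance.
    """

    beta: np.ndarray
    sigma_g: np.ndarray
    sigma_int: dict[str, np.ndarray]
    sigma_r: dict[str, np.ndarray]
    sigma_e: dict[str, np.ndarray]

    def validate(self, design: TrialDesign) -> None:
        E, T = len(design.environments), len(design.traits)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (E, T):
            raise ValidationError(
                f"beta must be (n_env={E}, n_traits={T}), got {self.beta.shape}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("beta must be finite")
        self.sigma_g = _check_spd("sigma_g", self.sigma_g, T)
        for name, d in (
            ("sigma_int", self.sigma_int),
            ("sigma_r", self.sigma_r),
            ("sigma_e", self.sigma_e),
        ):
            if set(d) != set(design.environments):
                raise ValidationError(
                    f"{name} keys {sorted(d)} do not match environments "
                    f"{sorted(design.environments)}"
                )
            for e in design.environments:
                d[e] = _check_spd(f"{name}[{e}]", d[e], T)


def correlation_to_covariance(sds, corr) -> np.ndarray:
    """Build a covariance matrix from standard deviations and a correlation
    matrix: Sigma[i, j] = sds[i] * sds[j] * corr[i, j]."""
    sds = np.asarray(sds, dtype=float)
    corr = np.asarray(corr, dtype=float)
    if np.any(sds <= 0):
        raise ValidationError("standard deviations must be positive")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValidationError("corr must be symmetric with unit diagonal")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise ValidationError("correlation entries must lie in [-1, 1]")
    w = np.linalg.eigvalsh(corr)
    if w[0] <= 1e-12:
        raise ValidationError(
            f"correlation matrix is not positive-definite "
            f"(smallest eigenvalue {w[0]:.3g})"
        )
    return np.outer(sds, sds) * corr


def simulate_phenotypes(
    design: TrialDesign,
    truth: GenerativeTruth,
    seed: int,
    degenerate: bool = False,
) -> PhenotypeTable:
    """Draw one complete balanced trial from the generative model.

    With ``degenerate=True`` all random effects and residuals are forced to
    exactly zero, so every plot value equals its cell mean — the noiseless
    limit used to validate plumbing.

    The same (design, truth, seed) always yields an identical table.
    """
    truth.validate(design)
    rng = np.random.default_rng(seed)
    T = len(design.traits)
    genos = design.genotype_labels
    zeros = np.zeros(T)

    def draw(cov: np.ndarray, n: int) -> np.ndarray:
        if degenerate:
            return np.zeros((n, T))
        return rng.multivariate_normal(zeros, cov, size=n, method="cholesky")

    g_eff = draw(truth.sigma_g, design.n_genotypes)  # (G, T)
    records: list[PhenotypeRecord] = []
    for e_idx, env in enumerate(design.environments):
        ge_eff = draw(truth.sigma_int[env], design.n_genotypes)
        r_eff = draw(truth.sigma_r[env], design.blocks_per_environment)
        for k, block in enumerate(design.block_labels):
            eps = draw(truth.sigma_e[env], design.n_genotypes)
            for i, geno in enumerate(genos):
                vals = truth.beta[e_idx] + g_eff[i] + ge_eff[i] + r_eff[k] + eps[i]
                for t, trait in enumerate(design.traits):
                    records.append(
                        PhenotypeRecord(geno, env, block, trait, float(vals[t]))
                    )
    return PhenotypeTable(records)


# --------------------------------------------------------------------------
# Bundled scenario: flood-irrigated rice trial
# --------------------------------------------------------------------------

#: Versioned preset for the rice trial scenario.  Cell means are the
#: posterior means reported for the trial being emulated; the (co)variance
#: magnitudes are this package's choices, sized to give mid-range
#: broad-sense heritability (~0.6 for both traits) and a moderate positive
#: GY-FL genetic correlation (~0.46), with trait-appropriate units
#: (kg/ha for GY, days for FL).
RICE_SCENARIO: dict = {
    "design": {
        "n_genotypes": 25,
        "environments": ("1", "2"),
        "blocks_per_environment": 3,
        "traits": ("FL", "GY"),
    },
    # rows = environments 1, 2; columns = traits in sorted order (FL, GY)
    "beta": [[99.40, 4210.91], [76.43, 3901.56]],
    "sigma_g": {"sds": (3.0, 180.0), "corr_offdiag": 0.5},
    "sigma_int": {"sds": (1.5, 90.0), "corr_offdiag": 0.3},
    "sigma_r": {"sds": (1.0, 60.0), "corr_offdiag": 0.0},
    "sigma_e": {"sds": (2.5, 150.0), "corr_offdiag": 0.2},
}


def _corr2(offdiag: float) -> np.ndarray:
    return np.array([[1.0, offdiag], [offdiag, 1.0]])


def default_rice_scenario(seed: int = 0) -> tuple[TrialDesign, GenerativeTruth]:
    """The bundled rice-trial scenario: 25 genotypes x 2 environments x
    3 blocks, traits FL (days) and GY (kg/ha).

    The seed argument is accepted for interface symmetry with
    :func:`simulate_phenotypes`; the scenario itself is deterministic.
    """
    p = RICE_SCENARIO
    design = TrialDesign(**p["design"])
    envs = design.environments

    def cov(block: dict) -> np.ndarray:
        return correlation_to_covariance(block["sds"], _corr2(block["corr_offdiag"]))

    truth = GenerativeTruth(
        beta=np.array(p["beta"], dtype=float),
        sigma_g=cov(p["sigma_g"]),
        sigma_int={e: cov(p["sigma_int"]) for e in envs},
        sigma_r={e: cov(p["sigma_r"]) for e in envs},
        sigma_e={e: cov(p["sigma_e"]) for e in envs},
    )
    truth.validate(design)
    return design, truth
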