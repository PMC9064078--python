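"""Model variants and design-matrix assembly for MTME mixed models.

A model is the Gaussian linear mixed model

    y = X beta + Z_block r + Z_geno g [+ Z_gxe u] + eps

with cell-mean fixed effects beta_{e,t} (one mean per environment x
trait), multivariate random effects over the trait axis, and a
per-environment unstructured residual covariance.  The *full* variant
carries the genotype-by-environment interaction term ``gxe``; the *null*
variant omits it, so a genotype's effect is forced to be identical
across environments.

Assembly produces both a compact plot-major representation used by the
sampler (an (n_plots, T) response matrix plus integer level-index
arrays) and, on demand, the stacked ``y``/``X``/``Z_k`` matrices of the
textbook formulation (rows ordered plot-major, trait-minor; plots sorted
by environment, block, genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ConfigError, PhenotypeTable, ValidationError

__all__ = ["RandomTerm", "ModelSpec", "AssembledModel", "build_model_spec", "assemble"]

VARIANTS = ("full", "null")

GROUPINGS = ("block", "genotype", "gxe")


@dataclass(frozen=True)
class RandomTerm:
    """One random term of the model.

    ``grouping`` names the factor whose levels receive effects; the
    effect axis is always the ordered trait list.  ``per_environment``
    marks a block-diagonal-by-environment covariance (one unstructured
    T x T matrix per environment) versus a single shared T x T matrix.
    """

    name: str
    grouping: str
    per_environment: bool

    def __post_init__(self) -> None:
        if self.grouping not in GROUPINGS:
            raise ConfigError(f"unknown grouping {self.grouping!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model variant."""

    variant: str
    traits: tuple[str, ...]
    random_terms: tuple[RandomTerm, ...]

    @property
    def has_interaction(self) -> bool:
        return any(t.grouping == "gxe" for t in self.random_terms)


def build_model_spec(variant: str, traits) -> ModelSpec:
    """Standard model variants.

    ``full``: block-within-environment + genotype main + genotype x
    environment deviation.  ``null``: the same without the interaction
    term.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    traits = tuple(traits)
    if not traits:
        raise ConfigError("traits must be non-empty")
    terms = [
        RandomTerm("block", "block", per_environment=True),
        RandomTerm("genotype", "genotype", per_environment=False),
    ]
    if variant == "full":
        terms.append(RandomTerm("gxe", "gxe", per_environment=True))
    return ModelSpec(variant=variant, traits=traits, random_terms=tuple(terms))


@dataclass
class TermIndex:
    """Level bookkeeping for one random term.

    ``levels``: ordered level labels; ``level_env``: index of the
    environment each level belongs to (-1 for shared terms);
    ``plot_level``: (n_plots,) index of each plot's level.
    """

    term: RandomTerm
    levels: list
    level_env: np.ndarray
    plot_level: np.ndarray

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class AssembledModel:
    """Response and incidence structure of a model on a concrete table."""

    def __init__(self, table: PhenotypeTable, spec: ModelSpec):
        missing = [t for t in spec.traits if t not in table.traits]
        if missing:
            raise ValidationError(f"traits {missing} absent from table")
        if len(table.genotypes) < 2:
            raise ValidationError("genotype variance requires at least 2 genotypes")
        self.table = table
        self.spec = spec
        self.traits = tuple(sorted(spec.traits))
        self.environments = tuple(table.environments)
        self.genotypes = tuple(table.genotypes)
        env_i = {e: i for i, e in enumerate(self.environments)}
        trait_i = {t: i for i, t in enumerate(self.traits)}

        # plots sorted by (environment, block, genotype); table order matches
        plots = sorted(
            {(r.environment, r.block, r.genotype) for r in table.records}
        )
        self.plots = plots
        n = len(plots)
        T = len(self.traits)
        self.Y = np.empty((n, T))
        for p, (e, b, g) in enumerate(plots):
            for t, trait in enumerate(self.traits):
                self.Y[p, t] = table.value(g, e, b, trait)
        self.env_of_plot = np.array([env_i[e] for e, _, _ in plots], dtype=np.intp)
        self.n_plots_per_env = np.bincount(
            self.env_of_plot, minlength=len(self.environments)
        )

        self.terms: dict[str, TermIndex] = {}
        for term in spec.random_terms:
            self.terms[term.name] = self._index_term(term, plots, env_i)

        self._trait_i = trait_i

    def _index_term(self, term: RandomTerm, plots, env_i) -> TermIndex:
        if term.grouping == "block":
            levels = sorted({(e, b) for e, b, _ in plots})
        elif term.grouping == "genotype":
            levels = list(self.genotypes)
        else:  # gxe
            levels = sorted({(e, g) for e, _, g in plots})
        lev_i = {lv: i for i, lv in enumerate(levels)}
        if term.grouping == "block":
            plot_level = np.array([lev_i[(e, b)] for e, b, _ in plots], dtype=np.intp)
            level_env = np.array([env_i[e] for e, _ in levels], dtype=np.intp)
        elif term.grouping == "genotype":
            plot_level = np.array([lev_i[g] for _, _, g in plots], dtype=np.intp)
            level_env = np.full(len(levels), -1, dtype=np.intp)
        else:
            plot_level = np.array([lev_i[(e, g)] for e, _, g in plots], dtype=np.intp)
            level_env = np.array([env_i[e] for e, _ in levels], dtype=np.intp)
        return TermIndex(term, levels, level_env, plot_level)

    # -- stacked textbook form ------------------------------------------

    @property
    def n_obs(self) -> int:
        return self.Y.size

    @property
    def y(self) -> np.ndarray:
        """Stacked response, plot-major / trait-minor."""
        return self.Y.ravel()

    @property
    def row_index(self) -> list[tuple[str, str, str, str]]:
        """(genotype, environment, block, trait) for each row of ``y``."""
        out = []
        for e, b, g in self.plots:
            for t in self.traits:
                out.append((g, e, b, t))
        return out

    @property
    def X(self) -> np.ndarray:
        """Cell-means fixed-effect incidence: one column per
        (environment, trait), exactly one 1 per row."""
        E, T = len(self.environments), len(self.traits)
        X = np.zeros((self.n_obs, E * T))
        for p in range(len(self.plots)):
            e = self.env_of_plot[p]
            for t in range(T):
                X[p * T + t, e * T + t] = 1.0
        return X

    @property
    def beta_index(self) -> list[tuple[str, str]]:
        """(environment, trait) label for each column of X."""
        return [(e, t) for e in self.environments for t in self.traits]

    def Z(self, term_name: str) -> np.ndarray:
        """Incidence matrix of one random term over (level, trait) columns."""
        ti = self.terms[term_name]
        T = len(self.traits)
        Z = np.zeros((self.n_obs, ti.n_levels * T))
        for p in range(len(self.plots)):
            lv = ti.plot_level[p]
            for t in range(T):
                Z[p * T + t, lv * T + t] = 1.0
        return Z

    def data_fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.Y).tobytes())
        h.update(",".join(self.traits).encode())
        h.update(",".join(self.environments).encode())
        return h.hexdigest()


def assemble(table: PhenotypeTable, spec: ModelSpec) -> AssembledModel:
    """Assemble a model spec on a phenotype table."""
    return AssembledModel(table, spec)
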