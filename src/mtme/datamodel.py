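"""Domain types and I/O for multi-environment trial phenotypes.

The on-disk phenotype format is a long (tidy) CSV with one row per
plot x trait observation::

    genotype,environment,block,trait,value

Block labels are interpreted as nested within environment: block "1" in
environment "E1" and block "1" in "E2" are physically distinct
replications.  Version 1 requires a complete balanced design — every
(genotype, environment, block) plot carries a value for every trait —
which matches randomized-complete-block trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "PhenotypeRecord",
    "PhenotypeTable",
    "PriorSpec",
    "RunConfig",
    "read_phenotypes",
    "write_phenotypes",
    "load_config",
]

REQUIRED_COLUMNS = ("genotype", "environment", "block", "trait", "value")


class SchemaError(ValueError):
    """A required column is missing or unresolvable."""


class ValidationError(ValueError):
    """Table contents violate a structural invariant."""


class ConfigError(ValueError):
    """Run configuration violates an invariant."""


@dataclass(frozen=True)
class PhenotypeRecord:
    """One plot x trait observation.

    ``block`` identifies a replication *within* its environment; the same
    textual label in two environments denotes two distinct blocks.
    """

    genotype: str
    environment: str
    block: str
    trait: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(
                f"non-finite value {self.value!r} for "
                f"({self.genotype}, {self.environment}, {self.block}, {self.trait})"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.genotype, self.environment, self.block, self.trait)


class PhenotypeTable:
    """A validated, complete-balanced collection of phenotype records.

    Index sets (sorted label lists) are derived on construction:
    ``genotypes``, ``environments``, ``traits`` and ``blocks`` (per
    environment).  Validation enforces uniqueness of
    (genotype, environment, block, trait) and complete balance.
    """

    def __init__(self, records: Sequence[PhenotypeRecord]):
        if not records:
            raise ValidationError("a phenotype table must contain at least one record")
        seen: set[tuple[str, str, str, str]] = set()
        for rec in records:
            if rec.key in seen:
                raise ValidationError(f"duplicate observation key {rec.key}")
            seen.add(rec.key)
        self.records: tuple[PhenotypeRecord, ...] = tuple(
            sorted(records, key=lambda r: (r.environment, r.block, r.genotype, r.trait))
        )
        self.genotypes = sorted({r.genotype for r in records})
        self.environments = sorted({r.environment for r in records})
        self.traits = sorted({r.trait for r in records})
        self.blocks: dict[str, list[str]] = {
            e: sorted({r.block for r in records if r.environment == e})
            for e in self.environments
        }
        self._validate_shape()
        self._values = {r.key: r.value for r in self.records}

    def _validate_shape(self) -> None:
        if len(self.genotypes) < 2:
            raise ValidationError("need at least 2 genotypes")
        if len(self.traits) < 1:
            raise ValidationError("need at least 1 trait")
        for e, blocks in self.blocks.items():
            if len(blocks) < 2:
                raise ValidationError(f"environment {e!r} has fewer than 2 blocks")
        keys = {r.key for r in self.records}
        missing = []
        for e in self.environments:
            for b in self.blocks[e]:
                for g in self.genotypes:
                    for t in self.traits:
                        if (g, e, b, t) not in keys:
                            missing.append((g, e, b, t))
        if missing:
            shown = ", ".join(map(str, missing[:5]))
            raise ValidationError(
                f"design is not complete/balanced: {len(missing)} missing cell(s), "
                f"e.g. {shown}"
            )
        expected = len(self.traits) * sum(
            len(self.genotypes) * len(self.blocks[e]) for e in self.environments
        )
        if len(self.records) != expected:
            raise ValidationError(
                f"record count {len(self.records)} != expected {expected} for a "
                "complete balanced design"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.records == other.records

    @property
    def n_plots(self) -> int:
        return len(self.records) // len(self.traits)

    def value(self, genotype: str, environment: str, block: str, trait: str) -> float:
        return self._values[(genotype, environment, block, trait)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": [r.genotype for r in self.records],
                "environment": [r.environment for r in self.records],
                "block": [r.block for r in self.records],
                "trait": [r.trait for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        records = [
            PhenotypeRecord(
                genotype=str(row.genotype),
                environment=str(row.environment),
                block=str(row.block),
                trait=str(row.trait),
                value=float(row.value),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    def counts(self) -> pd.DataFrame:
        """Observation counts per trait x environment."""
        df = self.to_frame()
        return df.groupby(["trait", "environment"], sort=True).size().rename("n").reset_index()


def read_phenotypes(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> PhenotypeTable:
    """Read a long-format phenotype CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Optional mapping from the canonical column names
        (``genotype, environment, block, trait, value``) to the names used
        in the file.
    """
    df = pd.read_csv(path, dtype=str)
    dialect = dict(dialect or {})
    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = dialect.get(canonical, canonical)
        if source not in df.columns:
            raise SchemaError(
                f"missing required column {source!r} (for {canonical!r}) in {path}"
            )
        rename[source] = canonical
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)]
    df["value"] = df["value"].astype(float)
    return PhenotypeTable.from_frame(df)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    """Write a table as long-format CSV; round-trips exactly through
    :func:`read_phenotypes` (values serialized with :func:`repr` precision)."""
    df = table.to_frame()
    df["value"] = [repr(v) for v in df["value"]]
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration and priors
# --------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Priors for the Gibbs sampler.

    Covariance matrices of every random term and of the residual get
    inverse-Wishart priors IW(nu0, V0) with defaults nu0 = d + 1 (uniform
    marginal prior on correlations) and V0 = v0_scale * I, where d is the
    trait dimension.  v0_scale is interpreted on the working scale: with
    internal per-trait standardization to unit variance, the default 0.05
    puts the prior scale at 5% of the phenotypic variance of each trait —
    weak enough not to swamp terms with few levels (e.g. a block term with
    3 replicates) yet proper.  Fixed effects get independent N(0, v_beta)
    priors on the working scale.

    ``fix_beta`` / ``fix_residual`` pin the fixed effects or the
    per-environment residual covariances at known values instead of
    sampling them; these exist for degenerate-case checks against
    closed-form posteriors.
    """

    nu0: float | None = None
    v0_scale: float = 0.05
    v_beta: float = 1e8
    fix_beta: object | None = None          # array (E, T) on the data scale
    fix_residual: object | None = None      # dict env -> (T, T) on the data scale

    def validate(self, dim: int) -> None:
        if self.nu0 is not None and self.nu0 <= dim - 1:
            raise ConfigError(f"nu0 must exceed d-1 = {dim - 1}, got {self.nu0}")
        if self.v0_scale <= 0:
            raise ConfigError("v0_scale must be positive")
        if self.v_beta <= 0:
            raise ConfigError("v_beta must be positive")


@dataclass
class RunConfig:
    """MCMC chain plan: iterations, burn-in, thinning, seed."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    store_effects: bool = False
    standardize: bool = True
    prior: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.n_iter <= 0:
            raise ConfigError("n_iter must be positive")
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ConfigError(
                f"burn_in must satisfy 0 <= burn_in < n_iter "
                f"(got burn_in={self.burn_in}, n_iter={self.n_iter})"
            )
        if self.thin <= 0:
            raise ConfigError("thin must be positive")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML or JSON.

    Recognized keys: ``n_iter, burn_in, thin, seed, store_effects,
    standardize`` and a nested ``prior`` block with ``nu0, v0_scale,
    v_beta``.  Missing keys take the defaults.
    """
    text = Path(path).read_text()
    try:
        data = json.loads(text)
    except json.JSONDecodeError:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    prior_kwargs = data.pop("prior", {}) or {}
    unknown = set(prior_kwargs) - {"nu0", "v0_scale", "v_beta"}
    if unknown:
        raise ConfigError(f"unknown prior keys: {sorted(unknown)}")
    allowed = {"n_iter", "burn_in", "thin", "seed", "store_effects", "standardize"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(prior=PriorSpec(**prior_kwargs), **data)
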