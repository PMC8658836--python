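"""Discrete hyperparameter spaces for multitask network architectures.

A space is an ordered collection of named factors, each with a short list
of admissible levels.  The space is simultaneously the source of the
exhaustive grid, of uniform random draws, and of the fixed-length binary
chromosomes used by the genetic algorithm (two bits per factor).
"""

from __future__ import annotations

import json
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from typing import Any

import numpy as np
import yaml

__all__ = [
    "Factor",
    "HyperparameterSpace",
    "ArchitectureConfig",
    "Chromosome",
    "default_space",
    "enumerate_grid",
    "sample_random",
    "encode",
    "decode",
]

BITS_PER_FACTOR = 2


@dataclass(frozen=True)
class Factor:
    """One tunable hyperparameter: a name, a kind, and 2-4 ordered levels.

    ``kind`` is ``"quantitative"`` (numeric levels, strictly monotone in
    either direction) or ``"qualitative"`` (categorical levels such as the
    activation function).
    """

    name: str
    kind: str
    levels: tuple[Any, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "qualitative"):
            raise ValueError(f"unknown factor kind {self.kind!r}")
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValueError(f"factor {self.name!r} needs at least 2 levels")
        if len(self.levels) > 2**BITS_PER_FACTOR:
            raise ValueError(
                f"factor {self.name!r} has {len(self.levels)} levels; "
                f"at most {2**BITS_PER_FACTOR} are encodable"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"factor {self.name!r} has duplicate levels")
        if self.kind == "quantitative":
            diffs = np.diff([float(v) for v in self.levels])
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError(
                    f"quantitative factor {self.name!r} levels must be "
                    "strictly monotone"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, value: Any) -> int:
        try:
            return self.levels.index(value)
        except ValueError:
            raise ValueError(
                f"{value!r} is not a level of factor {self.name!r}"
            ) from None


@dataclass(frozen=True)
class HyperparameterSpace:
    """An ordered list of factors; the grid is their Cartesian product."""

    factors: tuple[Factor, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    @property
    def cardinality(self) -> int:
        out = 1
        for f in self.factors:
            out *= f.n_levels
        return out

    @property
    def n_bits(self) -> int:
        return BITS_PER_FACTOR * len(self.factors)

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def config_from_indices(self, indices: tuple[int, ...]) -> "ArchitectureConfig":
        if len(indices) != len(self.factors):
            raise ValueError("one level index per factor required")
        return ArchitectureConfig(
            tuple(
                (f.name, f.levels[i]) for f, i in zip(self.factors, indices)
            )
        )

    def indices_of(self, config: "ArchitectureConfig") -> tuple[int, ...]:
        return tuple(
            f.level_index(config[f.name]) for f in self.factors
        )

    def unrank(self, rank: int) -> "ArchitectureConfig":
        """Mixed-radix decoding of a grid rank (lexicographic, last factor
        fastest) into a configuration."""
        if not 0 <= rank < self.cardinality:
            raise ValueError("rank out of range")
        idx = []
        for f in reversed(self.factors):
            rank, r = divmod(rank, f.n_levels)
            idx.append(r)
        return self.config_from_indices(tuple(reversed(idx)))

    # -- serialization -------------------------------------------------

    def to_dict(self) -> list[dict[str, Any]]:
        return [
            {"name": f.name, "kind": f.kind, "levels": list(f.levels)}
            for f in self.factors
        ]

    @classmethod
    def from_dict(cls, items: list[dict[str, Any]]) -> "HyperparameterSpace":
        return cls(
            tuple(
                Factor(d["name"], d["kind"], tuple(d["levels"])) for d in items
            )
        )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "HyperparameterSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ArchitectureConfig(Mapping):
    """One hyperparameter combination, stored as ordered (name, value) pairs.

    Behaves as an immutable mapping keyed by factor name.  For the default
    space the keys are ``neurons_layer1..3``, ``dropout``, ``learning_rate``,
    ``epochs``, ``activation``, ``optimizer`` and ``penalty``.  A combination
    with ``neurons_layer2 == 0`` but ``neurons_layer3 > 0`` is a legal grid
    point (the grid keeps the full Cartesian product) but describes a network
    with a gap; :meth:`effective_hidden_layers` drops layers after the first
    empty one so that the realised network is always well-formed.
    """

    items: tuple[tuple[str, Any], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(tuple(p) for p in self.items))

    def __getitem__(self, key: str) -> Any:
        for k, v in self.items:
            if k == key:
                return v
        raise KeyError(key)

    def __iter__(self) -> Iterator[str]:
        return (k for k, _ in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __hash__(self) -> int:
        return hash(self.items)

    def as_dict(self) -> dict[str, Any]:
        return dict(self.items)

    def to_json(self) -> str:
        return json.dumps(self.as_dict())

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ArchitectureConfig":
        return cls(tuple(mapping.items()))

    def effective_hidden_layers(self) -> tuple[int, ...]:
        """Hidden-layer widths with the no-gap rule applied.

        Truncates at the first zero-width layer, so e.g. (100, 0, 500)
        realises a single hidden layer of 100 neurons.
        """
        widths = []
        for key in ("neurons_layer1", "neurons_layer2", "neurons_layer3"):
            w = int(self.get(key, 0))
            if w <= 0:
                break
            widths.append(w)
        return tuple(widths)


@dataclass(frozen=True)
class Chromosome:
    """Fixed-length binary encoding of a configuration: 2 bits per factor."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("chromosome bits must be 0 or 1")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)


_DEFAULT_FACTORS = (
    Factor("neurons_layer1", "quantitative", (10, 100, 500, 1000)),
    Factor("neurons_layer2", "quantitative", (0, 100, 500, 1000)),
    Factor("neurons_layer3", "quantitative", (0, 100, 500, 1000)),
    Factor("dropout", "quantitative", (0.0, 0.1, 0.25, 0.5)),
    Factor("learning_rate", "quantitative", (1e-2, 1e-3, 1e-4, 1e-5)),
    Factor("epochs", "quantitative", (5, 50, 200, 500)),
    Factor("activation", "qualitative", ("sigmoid", "relu", "tanh", "elu")),
    Factor("optimizer", "qualitative", ("sgd", "adam", "rmsprop", "adagrad")),
    Factor("penalty", "qualitative", ("none", "L1", "L2")),
)


def default_space() -> HyperparameterSpace:
    """The full tuning space: eight 4-level factors plus the 3-level
    regularisation penalty, 4^8 x 3 = 196,608 architectures in total."""
    return HyperparameterSpace(_DEFAULT_FACTORS)


def enumerate_grid(space: HyperparameterSpace) -> Iterator[ArchitectureConfig]:
    """Yield every grid point exactly once, lexicographically over factor
    order with the last factor varying fastest."""
    for rank in range(space.cardinality):
        yield space.unrank(rank)


def sample_random(
    space: HyperparameterSpace, n: int, seed: int | np.random.Generator
) -> list[ArchitectureConfig]:
    """Draw ``n`` distinct configurations uniformly from the grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > space.cardinality:
        raise ValueError(
            f"cannot draw {n} distinct configs from a grid of "
            f"{space.cardinality}"
        )
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    ranks = rng.choice(space.cardinality, size=n, replace=False)
    return [space.unrank(int(r)) for r in ranks]


def random_chromosome(
    space: HyperparameterSpace, rng: np.random.Generator
) -> Chromosome:
    return Chromosome(tuple(int(b) for b in rng.integers(0, 2, space.n_bits)))


def encode(config: ArchitectureConfig, space: HyperparameterSpace) -> Chromosome:
    """Binary-encode a configuration: each factor's level index as a 2-bit
    big-endian code."""
    bits: list[int] = []
    for f in space.factors:
        idx = f.level_index(config[f.name])
        bits.extend(((idx >> 1) & 1, idx & 1))
    return Chromosome(tuple(bits))


def decode(
    chrom: Chromosome,
    space: HyperparameterSpace,
    repair_gaps: bool = False,
) -> ArchitectureConfig:
    """Decode any bit pattern into a valid configuration.

    The 2-bit code is taken modulo the factor's level count, so every
    pattern is decodable even for the 3-level penalty factor (code 3 wraps
    to level 0).  Decoding is the exact inverse of :func:`encode` on the
    grid, so gap combinations (``neurons_layer2 == 0`` with
    ``neurons_layer3 > 0``) survive as distinct grid points; the gap is
    resolved when a network is realised (``effective_hidden_layers``).
    With ``repair_gaps=True`` the third layer is instead zeroed here.
    """
    if len(chrom) != space.n_bits:
        raise ValueError(
            f"chromosome length {len(chrom)} != expected {space.n_bits}"
        )
    indices = []
    for i, f in enumerate(space.factors):
        hi, lo = chrom.bits[2 * i], chrom.bits[2 * i + 1]
        indices.append(((hi << 1) | lo) % f.n_levels)
    cfg = space.config_from_indices(tuple(indices))
    if (
        repair_gaps
        and cfg.get("neurons_layer2") == 0
        and cfg.get("neurons_layer3", 0) != 0
    ):
        f3 = space.factor("neurons_layer3")
        if 0 in f3.levels:
            fixed = dict(cfg.items)
            fixed["neurons_layer3"] = 0
            cfg = ArchitectureConfig.from_mapping(fixed)
    return cfg
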