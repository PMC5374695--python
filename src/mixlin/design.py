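"""Titration (mixture) experiment designs.

A :class:`MixtureDesign` declares which sample types are pure RNA samples and
how each mixture type is composed of them, e.g. the SEQC-style design where
C = 0.75 A + 0.25 B and D = 0.25 A + 0.75 B, with four replicates of each
sample type. The design carries the ground-truth coefficients the mixture
regression is expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import DesignError

WEIGHT_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MixtureDesign:
    """Pure sample types, mixture compositions, and replicate counts.

    Attributes
    ----------
    pure_types
        Ordered pure sample-type labels (at least two).
    mixtures
        mixture type -> {pure type: weight}; weights are in [0, 1] and sum
        to 1 within 1e-12.
    replicates
        sample type -> replicate count (>= 1) for every pure and mixture type.
    """

    pure_types: tuple[str, ...]
    mixtures: Mapping[str, Mapping[str, float]]
    replicates: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pure_types", tuple(self.pure_types))
        object.__setattr__(self, "mixtures",
                           {m: dict(w) for m, w in self.mixtures.items()})
        object.__setattr__(self, "replicates", dict(self.replicates))
        self.validate()

    def validate(self) -> None:
        if len(self.pure_types) < 2:
            raise DesignError("a mixture design needs at least 2 pure sample types")
        if len(set(self.pure_types)) != len(self.pure_types):
            raise DesignError("duplicate pure sample types")
        for mix, weights in self.mixtures.items():
            if mix in self.pure_types:
                raise DesignError(f"mixture type {mix!r} collides with a pure type")
            unknown = set(weights) - set(self.pure_types)
            if unknown:
                raise DesignError(f"mixture {mix!r} references undeclared pure types {sorted(unknown)}")
            vals = list(weights.values())
            if any((not math.isfinite(w)) or w < 0 or w > 1 for w in vals):
                raise DesignError(f"mixture {mix!r} weights must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > WEIGHT_SUM_TOL:
                raise DesignError(
                    f"mixture {mix!r} weights sum to {sum(vals)!r}, expected 1 within {WEIGHT_SUM_TOL}")
        for t in self.sample_types:
            n = self.replicates.get(t)
            if n is None:
                raise DesignError(f"no replicate count declared for sample type {t!r}")
            if int(n) != n or n < 1:
                raise DesignError(f"replicate count for {t!r} must be a positive integer, got {n!r}")

    # -- accessors --------------------------------------------------------
    @property
    def mixture_types(self) -> tuple[str, ...]:
        return tuple(self.mixtures)

    @property
    def sample_types(self) -> tuple[str, ...]:
        return self.pure_types + self.mixture_types

    def weights(self, mixture_type: str) -> dict[str, float]:
        """Component weights of a mixture type over all pure types (0 if absent)."""
        if mixture_type not in self.mixtures:
            raise DesignError(f"unknown mixture type {mixture_type!r}")
        w = self.mixtures[mixture_type]
        return {t: float(w.get(t, 0.0)) for t in self.pure_types}

    def n_combinations(self, mixture_type: str) -> int:
        """Number of replicate combinations for one mixture regression."""
        if mixture_type not in self.mixtures:
            raise DesignError(f"unknown mixture type {mixture_type!r}")
        n = self.replicates[mixture_type]
        for t in self.pure_types:
            n *= self.replicates[t]
        return n

    # -- constructors / serialization ------------------------------------
    @classmethod
    def seqc(cls, n_replicates: int = 4) -> "MixtureDesign":
        """The SEQC-style titration design: A, B pure; C = 3:1, D = 1:3 mixes."""
        return cls(
            pure_types=("A", "B"),
            mixtures={"C": {"A": 0.75, "B": 0.25}, "D": {"A": 0.25, "B": 0.75}},
            replicates={t: n_replicates for t in ("A", "B", "C", "D")},
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "MixtureDesign":
        try:
            return cls(pure_types=tuple(d["pure_types"]),
                       mixtures=d["mixtures"],
                       replicates=d["replicates"])
        except KeyError as e:
            raise DesignError(f"design file missing key {e.args[0]!r}") from e

    @classmethod
    def from_yaml(cls, path) -> "MixtureDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, Mapping):
            raise DesignError(f"design file {path} does not contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "pure_types": list(self.pure_types),
            "mixtures": {m: dict(w) for m, w in self.mixtures.items()},
            "replicates": dict(self.replicates),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
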