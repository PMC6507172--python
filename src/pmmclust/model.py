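"""Core domain types for gene-set clustering.

A *gene-set* is a named collection of gene identifiers, optionally carrying a
significance score (e.g. an FDR q-value from gene-set analysis) and a
regulation direction.  A *collection* groups gene-sets over a common gene
universe.  A :class:`PPINetwork` is a symmetric, weighted, self-loop-free
graph of functional associations between genes; pairs absent from the network
implicitly score zero.

Gene identifiers are treated as opaque, case-sensitive strings (whitespace is
trimmed by the readers); no symbol aliasing is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Direction",
    "GeneSet",
    "GeneSetCollection",
    "PPINetwork",
    "DistanceSpec",
    "DistanceMatrix",
    "DistanceTrace",
    "Measure",
    "InvalidInputError",
    "DegenerateInputError",
]


class InvalidInputError(ValueError):
    """An input violates a structural precondition (empty set, bad universe...)."""


class DegenerateInputError(ValueError):
    """A mathematically degenerate configuration (e.g. kappa with E = 1)."""


class Direction(str, Enum):
    """Regulation direction of a gene-set in the underlying experiment."""

    UP = "up"
    DOWN = "down"
    NONE = "none"

    @classmethod
    def parse(cls, token: str | None) -> "Direction":
        if token is None:
            return cls.NONE
        t = str(token).strip().lower()
        mapping = {
            "up": cls.UP, "+": cls.UP, "1": cls.UP,
            "down": cls.DOWN, "dn": cls.DOWN, "-": cls.DOWN, "-1": cls.DOWN,
            "none": cls.NONE, "": cls.NONE, "0": cls.NONE, "na": cls.NONE,
        }
        if t not in mapping:
            raise InvalidInputError(f"unknown direction token: {token!r}")
        return mapping[t]


class Measure(str, Enum):
    """Gene-set distance measure."""

    MM = "MM"
    PMM = "pMM"
    KAPPA = "KAPPA"

    @classmethod
    def parse(cls, token: "str | Measure") -> "Measure":
        if isinstance(token, Measure):
            return token
        for m in cls:
            if m.value.lower() == str(token).strip().lower():
                return m
        raise InvalidInputError(f"unknown distance measure: {token!r}")


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers.

    Parameters
    ----------
    name : str
        Identifier, unique within a collection.
    genes : frozenset of str
        Member genes; must be non-empty.
    score : float, optional
        Gene-set significance score, e.g. an FDR q-value.
    direction : Direction
        Regulation direction (up / down / none).
    description : str
        Free-text annotation (retained from GMT files).
    """

    name: str
    genes: frozenset[str]
    score: float | None = None
    direction: Direction = Direction.NONE
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise InvalidInputError("gene-set name must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise InvalidInputError(f"gene-set {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered list of gene-sets over a common gene universe.

    The universe defaults to the union of all member genes; a larger explicit
    universe (e.g. all assayed genes) changes only the kappa distance, which
    counts co-absences.
    """

    sets: list[GeneSet]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise InvalidInputError(f"duplicate gene-set names: {sorted(dupes)}")
        union = frozenset().union(*(s.genes for s in self.sets)) if self.sets else frozenset()
        if self.universe is None:
            self.universe = union
        else:
            self.universe = frozenset(self.universe)
            missing = union - self.universe
            if missing:
                raise InvalidInputError(
                    f"{len(missing)} member genes are outside the universe "
                    f"(e.g. {sorted(missing)[:3]})"
                )

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def all_genes(self) -> frozenset[str]:
        return frozenset().union(*(s.genes for s in self.sets)) if self.sets else frozenset()

    def filter_by_size(self, min_size: int = 10, max_size: int = 200) -> "GeneSetCollection":
        """Keep only gene-sets whose size lies in [min_size, max_size]."""
        kept = [s for s in self.sets if min_size <= len(s) <= max_size]
        return GeneSetCollection(kept, universe=self.universe)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class PPINetwork:
    """Symmetric weighted gene graph with zero-score absent pairs.

    Edge scores must be positive; the maximum stored score ``max_score``
    normalises the PPI term of the weighted Meet/Min distance.  For inputs
    already normalised to the unit interval, pass ``max_score_override=1.0``.
    """

    def __init__(
        self,
        edges: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = (),
        max_score_override: float | None = None,
    ) -> None:
        items: Iterable[tuple[str, str, float]]
        if isinstance(edges, Mapping):
            items = ((x, y, s) for (x, y), s in edges.items())
        else:
            items = edges
        self._edges: dict[tuple[str, str], float] = {}
        for x, y, s in items:
            if x == y:
                raise InvalidInputError(f"self-edge on gene {x!r}")
            s = float(s)
            if s <= 0:
                raise InvalidInputError(f"non-positive edge score {s} for pair ({x}, {y})")
            key = _pair_key(x, y)
            # duplicate pairs keep the maximum score
            if key not in self._edges or s > self._edges[key]:
                self._edges[key] = s
        if max_score_override is not None and max_score_override <= 0:
            raise InvalidInputError("max_score_override must be positive")
        self._max_override = max_score_override

    @property
    def max_score(self) -> float:
        if self._max_override is not None:
            return self._max_override
        if not self._edges:
            return 1.0  # irrelevant: every score is zero
        return max(self._edges.values())

    def score(self, x: str, y: str) -> float:
        if x == y:
            return 0.0
        return self._edges.get(_pair_key(x, y), 0.0)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        return dict(self._edges)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for x, y in self._edges:
            out.add(x)
            out.add(y)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self._edges)

    def scaled(self, factor: float) -> "PPINetwork":
        """Return a copy with every edge score multiplied by ``factor`` > 0."""
        if factor <= 0:
            raise InvalidInputError("scale factor must be positive")
        return PPINetwork({k: v * factor for k, v in self._edges.items()})


@dataclass(frozen=True)
class DistanceSpec:
    """Which distance to compute and how.

    ``alpha`` balances the PPI term of the weighted Meet/Min distance
    (0 disables it, 1 gives full weight).  ``clamp`` truncates the final
    weighted distance to [0, 1]; kappa is never clamped.
    """

    measure: Measure = Measure.MM
    alpha: float = 1.0
    clamp: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "measure", Measure.parse(self.measure))
        if not (0.0 <= self.alpha <= 1.0):
            raise InvalidInputError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise gene-set distance matrix under one measure."""

    set_names: list[str]
    values: np.ndarray
    spec: DistanceSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.set_names)
        if self.values.shape != (n, n):
            raise InvalidInputError(
                f"matrix shape {self.values.shape} does not match {n} set names"
            )

    def pair(self, a: str, b: str) -> float:
        i, j = self.set_names.index(a), self.set_names.index(b)
        return float(self.values[i, j])

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle distances as a flat array."""
        iu = np.triu_indices(len(self.set_names), k=1)
        return self.values[iu]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.set_names, columns=self.set_names)


@dataclass(frozen=True)
class DistanceTrace:
    """Intermediate quantities of a pairwise distance computation.

    ``w`` is the ambiguity down-weight min(|A|,|B|)/(|A|+|B|) applied to PPIs
    landing in the overlap; ``observed``/``expected`` are the kappa agreement
    rates; the two directed weighted Meet/Min values are reported before the
    min/clamp step.
    """

    w: float
    observed: float
    expected: float
    directed_ab: float
    directed_ba: float
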