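"""Combinatorial mutant landscapes: genotypes, mutational paths, additivity.

A study of n candidate historical amino-acid replacements defines a 2**n
genotype space (each site either ancestral, 0, or derived, 1).  This module
enumerates that space, enumerates the n! orderings in which the replacements
can accumulate, computes additive (no-epistasis) expectations for multi-site
mutants from single-mutant effects, and classifies mutational paths as
accessible or not given a per-step tolerance for loss of function.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MutationSite",
    "Genotype",
    "MutationalPath",
    "AccessibilityConfig",
    "enumerate_genotypes",
    "enumerate_paths",
    "additive_expectation",
    "accessible_paths",
]

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MutationSite:
    """A candidate historical replacement, e.g. ``Y267Q``.

    ``position`` is 1-based in a named reference numbering (for SABATH
    methyltransferases, conventionally the C. breweri SAMT numbering).
    """

    label: str
    ancestral_residue: str
    position: int
    derived_residue: str

    def __post_init__(self) -> None:
        if self.ancestral_residue == self.derived_residue:
            raise ValueError(
                f"site {self.label!r}: ancestral and derived residue are identical"
            )
        if self.position < 1:
            raise ValueError(f"site {self.label!r}: position must be >= 1")
        for res in (self.ancestral_residue, self.derived_residue):
            if res not in _AA_CODES:
                raise ValueError(f"site {self.label!r}: invalid residue code {res!r}")

    @classmethod
    def from_label(cls, label: str) -> "MutationSite":
        """Parse a compact label such as ``"Y267Q"``."""
        anc, derived = label[0], label[-1]
        return cls(label, anc, int(label[1:-1]), derived)


@dataclass(frozen=True)
class Genotype:
    """A point in the combinatorial landscape: 0 = ancestral, 1 = derived."""

    bits: tuple[int, ...]
    site_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != len(self.site_order):
            raise ValueError("bits and site_order must have equal length")
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("genotype bits must be 0 or 1")

    @property
    def name(self) -> str:
        """Canonical bit-string form, e.g. ``"0101"``."""
        return "".join(str(b) for b in self.bits)

    @property
    def n_mutations(self) -> int:
        return sum(self.bits)

    @property
    def mutated_sites(self) -> tuple[str, ...]:
        return tuple(s for s, b in zip(self.site_order, self.bits) if b)

    @classmethod
    def from_string(cls, bitstring: str, site_order: Sequence[str]) -> "Genotype":
        return cls(tuple(int(c) for c in bitstring), tuple(site_order))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class MutationalPath:
    """An order in which the full set of replacements accumulates."""

    steps: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.steps)) != len(self.steps):
            raise ValueError("a path must visit each site exactly once")

    def genotypes(self, site_order: Sequence[str]) -> list[Genotype]:
        """Genotypes visited along the path, wild type first."""
        order = tuple(site_order)
        acquired: set[str] = set()
        out = [Genotype(tuple(0 for _ in order), order)]
        for step in self.steps:
            acquired.add(step)
            out.append(Genotype(tuple(int(s in acquired) for s in order), order))
        return out


@dataclass(frozen=True)
class AccessibilityConfig:
    """Tolerance for per-step decline when classifying paths.

    ``epsilon`` is the decrease in preference tolerated at any single step,
    on ``scale`` (raw preference ratio or its natural log).  ``epsilon = 0``
    demands monotone non-decreasing preference along the path.
    """

    epsilon: float = 0.0
    scale: str = "ratio"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.scale not in ("ratio", "log_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")


def _validate_sites(sites: Sequence[MutationSite]) -> tuple[str, ...]:
    if not sites:
        raise ValueError("at least one mutation site is required")
    labels = tuple(s.label for s in sites)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate site labels: {dupes}")
    return labels


def enumerate_genotypes(sites: Sequence[MutationSite]) -> list[Genotype]:
    """All 2**n genotypes, lexicographic by bit string; wild type first."""
    labels = _validate_sites(sites)
    return [
        Genotype(bits, labels)
        for bits in itertools.product((0, 1), repeat=len(labels))
    ]


def enumerate_paths(sites: Sequence[MutationSite]) -> list[MutationalPath]:
    """All n! accumulation orders, lexicographic in the given site order."""
    labels = _validate_sites(sites)
    return [MutationalPath(p) for p in itertools.permutations(labels)]


def additive_expectation(
    wt_value: float,
    single_effects: Mapping[str, float],
    target: Genotype,
    scale: str = "ratio",
) -> float:
    """No-epistasis expectation for ``target`` from single-mutant effects.

    Each effect is the single mutant's value minus the wild-type value on
    ``scale``; the expectation is the wild-type value plus the sum of effects
    of the sites mutated in ``target``.  Comparing this against the observed
    multi-mutant value is the direct test for epistasis (an observed value
    above the additive expectation indicates positive-magnitude epistasis).
    """
    if scale not in ("ratio", "log_ratio"):
        raise ValueError(f"unknown scale {scale!r}")
    total = wt_value
    for site in target.mutated_sites:
        if site not in single_effects:
            raise KeyError(f"no single-mutant effect supplied for site {site!r}")
        total += single_effects[site]
    return total


def accessible_paths(
    values: Mapping[str, float],
    sites: Sequence[MutationSite],
    cfg: AccessibilityConfig | None = None,
) -> list[tuple[MutationalPath, bool]]:
    """Classify every mutational path as accessible or not.

    ``values`` maps canonical genotype bit strings to preference values.  A
    path is accessible iff at every step the next genotype's value is at
    least the current value minus ``cfg.epsilon`` (on ``cfg.scale``).
    """
    cfg = cfg or AccessibilityConfig()
    labels = _validate_sites(sites)

    def value_of(g: Genotype) -> float:
        try:
            v = values[g.name]
        except KeyError:
            raise KeyError(f"no value supplied for genotype {g.name!r}") from None
        if cfg.scale == "log_ratio":
            if v <= 0:
                raise ValueError(
                    f"genotype {g.name!r}: value {v} not positive; log scale undefined"
                )
            return math.log(v)
        return float(v)

    # fail fast on incomplete landscapes
    for g in enumerate_genotypes(sites):
        value_of(g)

    out: list[tuple[MutationalPath, bool]] = []
    for path in enumerate_paths(sites):
        chain = [value_of(g) for g in path.genotypes(labels)]
        ok = all(b >= a - cfg.epsilon for a, b in zip(chain, chain[1:]))
        out.append((path, ok))
    return out
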