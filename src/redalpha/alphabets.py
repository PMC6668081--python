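"""Reduced alphabets and substitution rules.

A reduced alphabet is an n-member subset of the 20 genetically coded amino
acids; a substitution rule is a total map sending every letter to an alphabet
member (identity on members).  "Virtual mutagenesis" is the letterwise
application of a rule to sequences.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .constants import AA_INDEX, AA_ORDER, N_LETTERS, PREBIOTIC_LETTERS
from .errors import ConfigurationError


@dataclass(frozen=True)
class ReducedAlphabet:
    """An n-letter subset of the 20-letter amino-acid code."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError("alphabet must have at least one member")
        bad = set(self.members) - set(AA_ORDER)
        if bad:
            raise ConfigurationError(f"letters outside the 20-letter code: {sorted(bad)}")

    @classmethod
    def from_string(cls, letters: str) -> "ReducedAlphabet":
        return cls(frozenset(letters))

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def canonical(self) -> str:
        """Sorted member string; the canonical form used for seeding and ranking."""
        return "".join(sorted(self.members))

    @property
    def member_indices(self) -> tuple[int, ...]:
        return tuple(AA_INDEX[a] for a in sorted(self.members))

    @property
    def excluded_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(AA_ORDER) if a not in self.members)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


PREBIOTIC = ReducedAlphabet(PREBIOTIC_LETTERS)


@dataclass(frozen=True)
class SubstitutionRule:
    """Total map 20 letters -> alphabet members, identity on members."""

    mapping: Mapping[str, str]
    _table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        members = {v for v in self.mapping.values()}
        if set(self.mapping) != set(AA_ORDER):
            raise ConfigurationError("rule must map all 20 letters")
        for m in members:
            if self.mapping.get(m) != m:
                raise ConfigurationError(f"rule is not a fixed point on member {m!r}")
        table = np.array([AA_INDEX[self.mapping[a]] for a in AA_ORDER], dtype=np.int64)
        object.__setattr__(self, "_table", table)
        trans = str.maketrans(
            AA_ORDER + "X", "".join(self.mapping[a] for a in AA_ORDER) + "X"
        )
        object.__setattr__(self, "_trans", trans)

    @classmethod
    def identity(cls) -> "SubstitutionRule":
        return cls({a: a for a in AA_ORDER})

    @classmethod
    def from_assignment(
        cls, alphabet: ReducedAlphabet, assignment: Mapping[str, str]
    ) -> "SubstitutionRule":
        """Build a rule from the images of the excluded letters only."""
        mapping = {a: a for a in alphabet.members}
        for a in AA_ORDER:
            if a not in alphabet.members:
                img = assignment[a]
                if img not in alphabet.members:
                    raise ConfigurationError(f"{a!r} mapped outside the alphabet")
                mapping[a] = img
        return cls(mapping)

    @classmethod
    def from_string(cls, images: str) -> "SubstitutionRule":
        """Parse the 20-character image string in ACDEFGHIKLMNPQRSTVWY order."""
        if len(images) != N_LETTERS:
            raise ConfigurationError("rule string must have 20 characters")
        return cls(dict(zip(AA_ORDER, images.upper())))

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.mapping.values())

    @property
    def table(self) -> np.ndarray:
        """Letter-index image array of length 20 (int64)."""
        return self._table

    def as_string(self) -> str:
        return "".join(self.mapping[a] for a in AA_ORDER)

    def apply(self, sequence: str) -> str:
        """Letterwise image of a sequence ('X' passes through)."""
        unknown = set(sequence) - set(AA_ORDER) - {"X"}
        if unknown:
            raise ConfigurationError(f"letters with no mapping: {sorted(unknown)}")
        return sequence.translate(self._trans)


def apply_rule(sequence: str, rule: SubstitutionRule) -> str:
    """Rewrite a sequence under a substitution rule (virtual mutagenesis)."""
    return rule.apply(sequence)


def count_reduced_alphabets(n: int) -> int:
    """Number of n-member alphabets: C(20, n)."""
    if not 0 <= n <= N_LETTERS:
        raise ConfigurationError("alphabet size must be in 0..20")
    return math.comb(N_LETTERS, n)


def count_substitution_rules(n: int) -> int:
    """Number of total substitution rules for an n-member alphabet: n^(20-n)."""
    if not 1 <= n <= N_LETTERS:
        raise ConfigurationError("alphabet size must be in 1..20")
    return n ** (N_LETTERS - n)


def enumerate_alphabets(n: int) -> Iterator[ReducedAlphabet]:
    """All n-member alphabets in lexicographic order of their sorted strings."""
    if not 1 <= n <= N_LETTERS:
        raise ConfigurationError("alphabet size must be in 1..20")
    for combo in itertools.combinations(AA_ORDER, n):
        yield ReducedAlphabet(frozenset(combo))
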