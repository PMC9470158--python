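"""Fragmentation patterns (clonal life cycles) and their combinatorics.

A clonal life cycle is identified with a *fragmentation pattern*: groups of
cells grow by cell division and, on reaching ``m + 1`` cells, immediately
split into offspring groups whose sizes form a partition of ``m + 1`` with at
least two parts (no cells are lost during fragmentation).  The pattern
``2+1``, for example, is the life cycle in which a tricellular group sheds a
solitary cell and keeps growing as a bicellular group.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "FragmentationPattern",
    "enumerate_life_cycles",
    "constrained_triplet_roles",
    "is_constrained_triplet",
]


@dataclass(frozen=True, order=True)
class FragmentationPattern:
    """A partition of ``m + 1`` with at least two parts.

    Parameters
    ----------
    parts : tuple of int
        Offspring group sizes.  Stored canonically in non-increasing order;
        two patterns are equal iff their part multisets are equal.
    """

    parts: tuple[int, ...]

    def __init__(self, parts) -> None:
        parts = tuple(sorted((int(p) for p in parts), reverse=True))
        if len(parts) < 2:
            raise ValueError(
                f"a fragmentation pattern needs at least two parts, got {parts!r}"
            )
        if any(p < 1 for p in parts):
            raise ValueError(f"offspring sizes must be positive, got {parts!r}")
        object.__setattr__(self, "parts", parts)

    @classmethod
    def from_string(cls, text: str) -> "FragmentationPattern":
        """Parse the field notation ``"a+b+c"`` (whitespace tolerated)."""
        try:
            parts = [int(tok) for tok in text.replace(" ", "").split("+")]
        except ValueError as exc:
            raise ValueError(f"cannot parse fragmentation pattern {text!r}") from exc
        return cls(parts)

    def __str__(self) -> str:
        return "+".join(str(p) for p in self.parts)

    def __repr__(self) -> str:
        return f"FragmentationPattern({self})"

    @property
    def maturity(self) -> int:
        """Maturity size ``m``: groups fragment on reaching ``m + 1`` cells."""
        return sum(self.parts) - 1

    @property
    def n_offspring(self) -> int:
        return len(self.parts)

    @cached_property
    def smallest_offspring(self) -> int:
        return self.parts[-1]

    def offspring_vector(self, n: int) -> np.ndarray:
        """Offspring counts by size: component ``i`` (1-based) is the number
        of groups of size ``i`` produced by one fragmentation event.
        """
        n = int(n)
        if n < self.parts[0]:
            raise ValueError(
                f"need n >= largest offspring ({self.parts[0]}), got n={n}"
            )
        pi = np.zeros(n, dtype=float)
        for p in self.parts:
            pi[p - 1] += 1
        return pi

    def constraining_pairs(self) -> set[frozenset["FragmentationPattern"]]:
        """All unordered pairs of life cycles that *constrain* this one.

        The pattern is constrained by ``(merged, sub)`` when its fragmentation
        can be realised as the merged pattern's fragmentation immediately
        followed by the sub-pattern's fragmentation of one offspring group:
        for every proper sub-multiset ``S`` of the parts with at least two
        parts and sum ``s``, the merged pattern is ``(parts \\ S) + {s}`` and
        the sub-pattern is ``S`` itself.  Binary fragmentation patterns have
        no such pair, which is why only they can be evolutionarily stable.
        """
        pairs: set[frozenset[FragmentationPattern]] = set()
        counts = Counter(self.parts)
        distinct = sorted(counts)
        # enumerate sub-multisets by count vectors (deduplicates by value)
        ranges = [range(counts[p] + 1) for p in distinct]
        for combo in itertools.product(*ranges):
            sub = []
            for p, c in zip(distinct, combo):
                sub.extend([p] * c)
            if len(sub) < 2 or len(sub) == len(self.parts):
                continue
            remainder = list((counts - Counter(sub)).elements())
            merged = FragmentationPattern(remainder + [sum(sub)])
            pairs.add(frozenset({merged, FragmentationPattern(sub)}))
        return pairs


def enumerate_life_cycles(max_group_size: int) -> set[FragmentationPattern]:
    """All life cycles whose groups never exceed ``max_group_size`` cells,
    i.e. every partition with >= 2 parts of every total in
    ``2 .. max_group_size + 1``.
    """
    max_group_size = int(max_group_size)
    if max_group_size < 1:
        raise ValueError("max_group_size must be a positive integer")
    out: set[FragmentationPattern] = set()
    for total in range(2, max_group_size + 2):
        for parts in _partitions(total):
            if len(parts) >= 2:
                out.add(FragmentationPattern(parts))
    return out


def _partitions(total: int, largest: int | None = None):
    """Integer partitions of ``total`` in non-increasing order."""
    if largest is None:
        largest = total
    if total == 0:
        yield ()
        return
    for first in range(min(total, largest), 0, -1):
        for rest in _partitions(total - first, first):
            yield (first,) + rest


def constrained_triplet_roles(
    k1: FragmentationPattern,
    k2: FragmentationPattern,
    k3: FragmentationPattern,
) -> FragmentationPattern | None:
    """If the three patterns form a constrained triplet, return the
    constrained pattern ``kappa(M)``; otherwise return ``None``.

    A triplet is constrained when one pattern's fragmentation rule is a
    combination of the other two's (the pair appears in its
    :meth:`FragmentationPattern.constraining_pairs`).
    """
    trio = (k1, k2, k3)
    if len(set(trio)) != 3:
        raise ValueError("a triplet needs three distinct patterns")
    for middle in trio:
        others = frozenset(p for p in trio if p != middle)
        if others in middle.constraining_pairs():
            return middle
    return None


def is_constrained_triplet(
    k1: FragmentationPattern,
    k2: FragmentationPattern,
    k3: FragmentationPattern,
) -> bool:
    return constrained_triplet_roles(k1, k2, k3) is not None
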