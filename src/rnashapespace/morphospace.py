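"""Sizing the morphospace of RNA structures and shapes.

The morphospace is the set of all phenotypic forms realizable at a given
length: here, all nested secondary structures (with a minimum hairpin
length of 3 and helices down to length 1), or all abstract shapes they map
to.  This module provides

* the exact sequence-space size ``4^L``;
* published asymptotic counts of level-3 and level-5 shapes,
  ``s3(L) = 1.85 * 1.46^L * L^(-3/2)`` and
  ``s5(L) = 2.44 * 1.32^L * L^(-3/2)``,
  together with a nearest-power-of-ten helper (counts of this kind are
  usually only meaningful to an order of magnitude);
* exact brute-force counterparts for small L — enumeration of all valid
  structures, a dynamic-programming structure count, a distinct-shape
  count — which serve as oracles for the sampling machinery;
* a uniform random-structure sampler (DP-weighted), used for property
  testing of the parser and abstraction code;
* occupancy fractions (observed shapes / possible shapes).
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Iterator, Optional

import numpy as np

from .shape_abstraction import shape_of

#: brute-force enumeration is intended for oracle-scale lengths only
ENUMERATION_CAP = 18

_ASYMPTOTIC = {3: (1.85, 1.46), 5: (2.44, 1.32)}


def sequence_space_size(L: int) -> int:
    """Exact number of RNA sequences of length L: 4**L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return 4 ** L


def asymptotic_shape_count(L: int, level: int) -> float:
    """Asymptotic number of shapes of length L at level 3 or 5.

    Constants correspond to minimum hairpin length 3 and minimum helix
    (ladder) length 1.  The formula is asymptotic in L; at small L it can
    disagree with exact enumeration, and both are reported side by side
    rather than reconciled.
    """
    if level not in _ASYMPTOTIC:
        raise ValueError(f"asymptotic counts exist for levels 3 and 5, got {level}")
    if L < 1:
        raise ValueError("L must be >= 1")
    a, b = _ASYMPTOTIC[level]
    return a * b ** L * L ** -1.5


def nearest_power_of_ten(x: float) -> int:
    """Exponent of the power of ten nearest to x (log10 rounded, ties up)."""
    if x <= 0:
        raise ValueError("x must be positive")
    return math.floor(math.log10(x) + 0.5)


@lru_cache(maxsize=None)
def count_structures(L: int, min_hairpin: int = 3) -> int:
    """Exact number of nested structures of length L (hairpin >= min_hairpin).

    Standard first-position recursion: position 1 is unpaired, or pairs with
    position j enclosing at least ``min_hairpin`` residues,
    ``S(n) = S(n-1) + sum_{j=m+2}^{n} S(j-2) * S(n-j)`` with S(n)=1 for
    n <= m+1.  Includes the empty (open-chain) structure.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    m = min_hairpin
    if L <= m + 1:
        return 1
    total = count_structures(L - 1, m)
    for j in range(m + 2, L + 1):
        total += count_structures(j - 2, m) * count_structures(L - j, m)
    return total


def enumerate_structures(L: int, min_hairpin: int = 3,
                         cap: int = ENUMERATION_CAP) -> Iterator[str]:
    """Yield every valid structure of length L exactly once.

    Uses the same first-position decomposition as :func:`count_structures`,
    so each structure is produced by a unique derivation.  Guarded by
    ``cap`` because the count grows exponentially.
    """
    if L > cap:
        raise ValueError(f"L={L} exceeds enumeration cap {cap}")

    @lru_cache(maxsize=None)
    def enum(n: int) -> tuple[str, ...]:
        if n == 0:
            return ("",)
        if n <= min_hairpin + 1:
            return ("." * n,)
        out = ["." + s for s in enum(n - 1)]
        for j in range(min_hairpin + 2, n + 1):
            for inner in enum(j - 2):
                for rest in enum(n - j):
                    out.append("(" + inner + ")" + rest)
        return tuple(out)

    yield from enum(L)


def count_shapes_exact(L: int, level: int, min_hairpin: int = 3,
                       cap: int = ENUMERATION_CAP) -> int:
    """Number of distinct abstract shapes over all structures of length L."""
    return len({shape_of(db, level)
                for db in enumerate_structures(L, min_hairpin, cap)})


def sample_structures(L: int, n: int, seed: int,
                      min_hairpin: int = 3) -> list[str]:
    """Draw n structures of length L uniformly at random.

    Exact uniform sampling over all valid structures via the counting
    recursion: each derivation step is chosen with probability proportional
    to the number of structures it leads to.  Intended for property tests;
    lengths well beyond the enumeration cap are fine (counts are exact
    integers).
    """
    rng = np.random.default_rng(seed)
    m = min_hairpin

    def randbelow(total: int) -> int:
        # exact uniform integer in [0, total) even beyond int64
        if total.bit_length() < 63:
            return int(rng.integers(total))
        k = total.bit_length()
        while True:
            u = 0
            for _ in range((k + 62) // 63):
                u = (u << 63) | int(rng.integers(1 << 63))
            u &= (1 << k) - 1
            if u < total:
                return u

    def draw(length: int) -> str:
        if length <= m + 1:
            return "." * length
        total = count_structures(length, m)
        # choose the first-position derivation
        u = randbelow(total)
        acc = count_structures(length - 1, m)
        if u < acc:
            return "." + draw(length - 1)
        for j in range(m + 2, length + 1):
            block = count_structures(j - 2, m) * count_structures(length - j, m)
            if u < acc + block:
                return "(" + draw(j - 2) + ")" + draw(length - j)
            acc += block
        raise AssertionError("unreachable: counts inconsistent")

    return [draw(L) for _ in range(n)]


def occupancy_fraction(n_observed_shapes: int,
                       morphospace_size: float) -> float:
    """Fraction of the morphospace occupied by the observed shapes."""
    if n_observed_shapes < 0:
        raise ValueError("observed shape count must be >= 0")
    if morphospace_size < 1:
        raise ValueError("morphospace size must be >= 1")
    return n_observed_shapes / morphospace_size


def morphospace_table(L: int, level: Optional[int] = None,
                      min_hairpin: int = 3) -> dict:
    """Summary row used by the CLI: asymptotic size, its order of magnitude,
    and exact counts when L is within the enumeration cap."""
    from .gsampling import default_level

    lvl = default_level(L) if level is None else level
    asym = asymptotic_shape_count(L, lvl) if lvl in _ASYMPTOTIC else None
    row = {
        "L": L,
        "level": lvl,
        "sequence_space": sequence_space_size(L),
        "asymptotic_shapes": asym,
        "power_of_ten": nearest_power_of_ten(asym) if asym else None,
        "exact_structures": None,
        "exact_shapes": None,
    }
    if L <= ENUMERATION_CAP:
        row["exact_structures"] = count_structures(L, min_hairpin)
        row["exact_shapes"] = count_shapes_exact(L, lvl, min_hairpin)
    return row
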