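"""G-sampling: shape-frequency spectra from uniform random sequences.

"G-sampling" estimates the frequency ``f_pG`` of each coarse-grained shape
``p`` by drawing genotypes (sequences) uniformly at random, folding each
one, and abstracting the resulting structure.  Because the genotype–
phenotype map is strongly biased, the resulting rank–frequency spectrum
spans many orders of magnitude, and ``f_pG * 4^L`` estimates the neutral
set size (the number of sequences folding to shapes in class ``p``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .folding import Folder
from .secondary_structure import SequenceError
from .shape_abstraction import abstract_shape, parse_dot_bracket

_BASES = np.array(list("ACGU"))


def default_level(L: int) -> int:
    """Default abstraction level per length: 3 up to L=55, 5 beyond.

    Shorter strands need the finer level-3 description to resolve enough
    distinct shapes; longer strands produce too many level-3 shapes for
    reliable frequencies, so the helix-nesting level 5 is used.
    """
    return 3 if L <= 55 else 5


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration of a uniform (or base-biased) sequence sampler.

    ``gc``, when given, overrides ``base_probs`` with
    ``((1-gc)/2, gc/2, gc/2, (1-gc)/2)`` for A, C, G, U.
    """

    L: int
    n: int
    seed: int
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        probs = self.probs
        if any(p < 0 for p in probs):
            raise ValueError("base probabilities must be nonnegative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError("base probabilities must sum to 1")

    @property
    def probs(self) -> tuple[float, float, float, float]:
        if self.gc is not None:
            if not 0.0 <= self.gc <= 1.0:
                raise ValueError("gc must be in [0, 1]")
            at = (1.0 - self.gc) / 2.0
            cg = self.gc / 2.0
            return (at, cg, cg, at)
        return self.base_probs


def sample_sequences(config: SamplerConfig,
                     chunk: int = 4096) -> Iterator[str]:
    """Yield ``config.n`` i.i.d. sequences; identical stream per seed."""
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.probs, dtype=float)
    probs = probs / probs.sum()
    remaining = config.n
    while remaining > 0:
        m = min(chunk, remaining)
        codes = rng.choice(4, size=(m, config.L), p=probs)
        for row in codes:
            yield "".join(_BASES[row])
        remaining -= m


@dataclass
class ShapeSpectrum:
    """Shape -> count table from a sample of sequences.

    Frequencies are ``count / n_samples``; 95% Wilson score intervals are
    attached on demand, and ``f * 4^L`` gives the neutral-set-size
    estimate for each shape.  Shapes never observed are simply absent.
    """

    L: int
    level: int
    n_samples: int
    counts: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total != self.n_samples:
            raise ValueError(
                f"counts sum to {total}, expected n_samples={self.n_samples}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative shape count")

    @property
    def n_shapes(self) -> int:
        return len(self.counts)

    def frequency(self, shape: str) -> float:
        return self.counts.get(shape, 0) / self.n_samples

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n_samples
        return {s: c / n for s, c in self.counts.items()}

    def wilson_ci(self, shape: str, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = proportion_confint(self.counts.get(shape, 0), self.n_samples,
                                    alpha=alpha, method="wilson")
        return float(lo), float(hi)

    def nss_estimate(self, shape: str) -> float:
        return neutral_set_size(self.frequency(shape), self.L)

    def merge(self, other: "ShapeSpectrum") -> "ShapeSpectrum":
        """Sum counts of two spectra built under the same (L, level)."""
        if (self.L, self.level) != (other.L, other.level):
            raise ValueError("cannot merge spectra with different L or level")
        counts = dict(self.counts)
        for s, c in other.counts.items():
            counts[s] = counts.get(s, 0) + c
        return ShapeSpectrum(self.L, self.level,
                             self.n_samples + other.n_samples, counts,
                             self.n_skipped + other.n_skipped,
                             dict(self.metadata))

    def to_frame(self):
        """Spectrum as a DataFrame in the canonical TSV column order."""
        import pandas as pd

        rows = []
        for rank, shape, f, (lo, hi) in rank_spectrum(self):
            rows.append({
                "shape": shape, "level": self.level, "L": self.L,
                "count": self.counts[shape], "n_samples": self.n_samples,
                "freq": f, "ci_low": lo, "ci_high": hi,
                "nss_est": self.nss_estimate(shape),
            })
        return pd.DataFrame(rows, columns=[
            "shape", "level", "L", "count", "n_samples", "freq",
            "ci_low", "ci_high", "nss_est",
        ])


def build_spectrum(seqs: Iterable[str], folder: Folder, level: int,
                   L: Optional[int] = None) -> ShapeSpectrum:
    """Fold and abstract every sequence; count canonical shape strings.

    Sequences rejected by normalization upstream may surface here as
    :class:`SequenceError`; they are skipped and tallied in ``n_skipped``.
    """
    counts: dict[str, int] = {}
    n = 0
    n_skipped = 0
    length = L
    for seq in seqs:
        try:
            structure = folder(seq)
        except SequenceError:
            n_skipped += 1
            continue
        if length is None:
            length = len(seq)
        shape = abstract_shape(parse_dot_bracket(structure), level)
        counts[shape] = counts.get(shape, 0) + 1
        n += 1
    if length is None:
        raise ValueError("cannot infer L from an empty sequence stream")
    return ShapeSpectrum(length, level, n, counts, n_skipped)


def rank_spectrum(spec: ShapeSpectrum,
                  alpha: float = 0.05) -> list[tuple[int, str, float, tuple[float, float]]]:
    """Shapes ranked by descending frequency.

    Ties are broken by plain byte order of the canonical shape string so
    that ranks are reproducible.
    """
    ordered = sorted(spec.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        (rank, shape, count / spec.n_samples, spec.wilson_ci(shape, alpha))
        for rank, (shape, count) in enumerate(ordered, 1)
    ]


def discovery_curve(config: SamplerConfig, folder: Folder, level: int,
                    checkpoints: Sequence[int]) -> list[tuple[int, int]]:
    """Distinct shapes seen after each checkpoint of sampling.

    ``checkpoints`` must be ascending; the sampler is run to the last
    checkpoint (``config.n`` is ignored in favour of it).
    """
    if list(checkpoints) != sorted(checkpoints):
        raise ValueError("checkpoints must be ascending")
    if not checkpoints:
        return []
    n_max = checkpoints[-1]
    seen: set[str] = set()
    curve: list[tuple[int, int]] = []
    it = iter(checkpoints)
    next_cp = next(it)
    n_seen = 0
    stream = sample_sequences(replace(config, n=n_max))
    while next_cp == 0:
        curve.append((0, 0))
        try:
            next_cp = next(it)
        except StopIteration:
            return curve
    for seq in stream:
        seen.add(abstract_shape(parse_dot_bracket(folder(seq)), level))
        n_seen += 1
        if n_seen == next_cp:
            curve.append((n_seen, len(seen)))
            try:
                next_cp = next(it)
            except StopIteration:
                break
    return curve


def neutral_set_size(f: float, L: int) -> float:
    """Neutral-set-size estimate ``f * 4^L`` for a shape of frequency f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    return f * math.pow(4.0, L) if L > 256 else f * float(4 ** L)
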