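"""Synthetic "natural databases" with controlled statistical structure.

Testing the pipeline end to end does not require downloading a real
noncoding-RNA database: what the analysis assumes about such a database is
statistical, and each assumption can be emulated directly.

* ``null`` — uniform random sequences, deduplicated.  Under the null the
  natural spectrum f_p tracks the G-sampling spectrum f_pG by
  construction, so the full pipeline should recover f_pG within its
  confidence intervals (the central parameter-recovery check).
* ``selected`` — accept–reject sampling with a per-shape fitness weight,
  emulating natural selection distorting shape occupancy.
* deposition bias — one shape over-deposited by a multiplier, emulating
  researcher interest in a molecule (the tRNA-cloverleaf effect); the
  over-representation test should flag exactly that shape.
* ``gc_biased`` — shifted GC content, for robustness checks against a
  GC-matched G-sample.

Default scale is L=30, n_natural=5,000 against an n=50,000 G-sample with
the built-in folder: minutes on one CPU, while leaving dozens of distinct
level-5 shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .folding import Folder
from .gsampling import SamplerConfig, sample_sequences
from .natural_comparison import NaturalDataset
from .shape_abstraction import abstract_shape, parse_dot_bracket

#: default synthetic-study conditions
DEFAULT_L = 30
DEFAULT_N_NATURAL = 5_000
DEFAULT_N_GSAMPLE = 50_000
DEFAULT_LEVEL = 5

MODES = ("null", "selected", "deposition_bias", "gc_biased")

_BASES = np.array(list("ACGU"))


class AcceptanceRateError(RuntimeError):
    """Accept–reject sampling fell below the configured acceptance floor."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic database."""

    L: int = DEFAULT_L
    n: int = DEFAULT_N_NATURAL
    seed: int = 0
    mode: str = "null"
    weights: Optional[dict[str, float]] = None  # selected mode
    spike_shape: Optional[str] = None           # deposition_bias mode
    multiplier: float = 1.0                     # deposition_bias mode
    gc: Optional[float] = None                  # gc_biased mode

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("fitness weights must be positive")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")


def _shape_for(seq: str, folder: Folder, level: int) -> str:
    return abstract_shape(parse_dot_bracket(folder(seq)), level)


def _draw_unique(L: int, n: int, rng: np.random.Generator,
                 probs: tuple[float, float, float, float],
                 taken: Optional[set[str]] = None) -> list[str]:
    """n distinct sequences; collisions are resampled (natural databases are
    duplicate-free)."""
    seen: set[str] = set(taken) if taken else set()
    out: list[str] = []
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    while len(out) < n:
        m = max(n - len(out), 16)
        codes = rng.choice(4, size=(m, L), p=p)
        for row in codes:
            seq = "".join(_BASES[row])
            if seq not in seen:
                seen.add(seq)
                out.append(seq)
                if len(out) == n:
                    break
    return out


def generate_null_database(spec: SyntheticSpec, folder: Folder = None,
                           level: int = DEFAULT_LEVEL) -> NaturalDataset:
    """Uniform random deduplicated sequences (folder/level unused: a null
    database is defined at the sequence level)."""
    if spec.mode != "null":
        raise ValueError("spec.mode must be 'null'")
    rng = np.random.default_rng(spec.seed)
    seqs = _draw_unique(spec.L, spec.n, rng, (0.25,) * 4)
    return NaturalDataset(seqs, f"synthetic-null-seed{spec.seed}", spec.L)


def generate_selected_database(spec: SyntheticSpec, folder: Folder,
                               level: int = DEFAULT_LEVEL,
                               acceptance_floor: float = 1e-4) -> NaturalDataset:
    """Accept–reject by per-shape fitness weight.

    A candidate sequence whose shape has weight w is accepted with
    probability w / max(w); shapes absent from the weight map default to
    weight 1.  Equal weights reduce to the null generator's distribution.
    """
    if spec.mode != "selected":
        raise ValueError("spec.mode must be 'selected'")
    weights = spec.weights or {}
    w_max = max(list(weights.values()) + [1.0])
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    kept: list[str] = []
    n_tried = 0
    while len(kept) < spec.n:
        for seq in _draw_unique(spec.L, 256, rng, (0.25,) * 4, taken=seen):
            n_tried += 1
            seen.add(seq)
            w = weights.get(_shape_for(seq, folder, level), 1.0)
            if rng.random() < w / w_max:
                kept.append(seq)
                if len(kept) == spec.n:
                    break
        if n_tried >= 4096 and len(kept) / n_tried < acceptance_floor:
            raise AcceptanceRateError(
                f"acceptance rate {len(kept) / n_tried:.2e} below floor "
                f"{acceptance_floor:.0e}; weights are pathological"
            )
    return NaturalDataset(kept, f"synthetic-selected-seed{spec.seed}", spec.L)


def generate_deposition_bias(base: NaturalDataset, shape: str,
                             multiplier: float, folder: Folder,
                             level: int, seed: int,
                             max_attempts_per_seq: int = 10_000) -> NaturalDataset:
    """Inflate one shape's count by ``multiplier``, leaving others untouched.

    New members are made by point-mutating existing carriers of the target
    shape and keeping mutants that still fold to it (falling back to fresh
    conditional sampling when mutation stalls); duplicates are never added.
    """
    if multiplier == 1.0:
        return base
    rng = np.random.default_rng(seed)
    shapes = [_shape_for(s, folder, level) for s in base.sequences]
    carriers = [s for s, sh in zip(base.sequences, shapes) if sh == shape]
    if not carriers:
        raise ValueError(f"shape {shape!r} absent from the base dataset")
    target = int(round(multiplier * len(carriers)))
    n_new = target - len(carriers)
    seen = set(base.sequences)
    added: list[str] = []
    attempts = 0
    budget = max_attempts_per_seq * max(n_new, 1)
    while len(added) < n_new:
        if attempts < budget // 2:
            # mutate an existing carrier at 1-3 positions
            template = list((carriers + added)[rng.integers(len(carriers) + len(added))])
            for pos in rng.choice(base.L, size=rng.integers(1, 4), replace=False):
                template[pos] = _BASES[rng.integers(4)]
            cand = "".join(template)
        else:
            # conditional rejection sampling from scratch
            cand = "".join(_BASES[rng.integers(4, size=base.L)])
        attempts += 1
        if attempts > budget:
            raise AcceptanceRateError(
                f"could not build {n_new} extra {shape!r} members "
                f"within {budget} attempts"
            )
        if cand in seen:
            continue
        if _shape_for(cand, folder, level) == shape:
            seen.add(cand)
            added.append(cand)
    return NaturalDataset(base.sequences + added,
                          base.source_label + f"+spike{multiplier:g}x",
                          base.L)


def generate_gc_biased(spec: SyntheticSpec, folder: Folder = None,
                       level: int = DEFAULT_LEVEL) -> NaturalDataset:
    """Deduplicated sequences with base distribution set by GC content."""
    if spec.mode != "gc_biased":
        raise ValueError("spec.mode must be 'gc_biased'")
    gc = 0.5 if spec.gc is None else spec.gc
    probs = SamplerConfig(spec.L, 0, spec.seed, gc=gc).probs
    rng = np.random.default_rng(spec.seed)
    seqs = _draw_unique(spec.L, spec.n, rng, probs)
    return NaturalDataset(seqs, f"synthetic-gc{gc:g}-seed{spec.seed}", spec.L)


def generate_database(spec: SyntheticSpec, folder: Folder = None,
                      level: int = DEFAULT_LEVEL) -> NaturalDataset:
    """Dispatch on ``spec.mode`` (deposition bias starts from a null base)."""
    if spec.mode == "null":
        return generate_null_database(spec, folder, level)
    if spec.mode == "selected":
        return generate_selected_database(spec, folder, level)
    if spec.mode == "gc_biased":
        return generate_gc_biased(spec, folder, level)
    if spec.mode == "deposition_bias":
        if spec.spike_shape is None:
            raise ValueError("deposition_bias mode requires spike_shape")
        base = generate_null_database(
            SyntheticSpec(spec.L, spec.n, spec.seed, "null"), folder, level)
        return generate_deposition_bias(base, spec.spike_shape,
                                        spec.multiplier, folder, level,
                                        spec.seed + 1)
    raise ValueError(f"unknown mode {spec.mode!r}")
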