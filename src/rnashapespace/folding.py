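"""Sequence-to-structure folding backends.

Two backends are exposed behind the same "sequence in, dot-bracket out"
contract:

* :func:`fold_maxpair` — a built-in, dependency-free base-pair-maximization
  folder (the classic O(L^3) recursion with a minimum hairpin length),
  deterministic by construction.  It is the default for synthetic pipeline
  tests: fast and reproducible, but it is *not* a thermodynamic model and
  its shape frequencies are not comparable to an energy-based folder's.
* :func:`fold_external` — adapter around the ViennaRNA python bindings
  (minimum-free-energy fold at default Turner parameters, 37 °C), the
  production backend for analyses of natural sequences.  Missing bindings
  raise :class:`BackendMissingError`; silent substitution of one backend for
  another is never performed, because shape frequencies are
  backend-dependent.

Watson–Crick pairs plus GU wobble are allowed throughout; lonely (single)
pairs are legal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from numba import njit

from .secondary_structure import RnaSequence, normalize_sequence

#: default minimum number of unpaired residues closing a hairpin
MIN_HAIRPIN = 3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# allowed pairs: AU, UA, CG, GC, GU, UG
_CAN_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _CAN_PAIR[_a, _b] = True

Folder = Callable[[str], str]


class BackendMissingError(RuntimeError):
    """The requested external folding backend is not installed."""


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: structure, optional energy (kcal/mol), backend id."""

    sequence: str
    structure: str
    energy: Optional[float]
    backend_id: str


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-ACGU residue {exc} in sequence") from exc


@njit(cache=False)
def _nussinov_pairs(codes, can_pair, min_hairpin):  # pragma: no cover - jit
    n = codes.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]  # i unpaired
            for k in range(i + min_hairpin + 1, j + 1):
                if can_pair[codes[i], codes[k]]:
                    cand = 1
                    if k - 1 >= i + 1:
                        cand += m[i + 1, k - 1]
                    if k + 1 <= j:
                        cand += m[k + 1, j]
                    if cand > best:
                        best = cand
            m[i, j] = best

    partner = np.full(n, -1, dtype=np.int32)
    stack_i = np.empty(n + 1, dtype=np.int32)
    stack_j = np.empty(n + 1, dtype=np.int32)
    top = 0
    stack_i[0], stack_j[0] = 0, n - 1
    top = 1
    while top > 0:
        top -= 1
        i, j = stack_i[top], stack_j[top]
        if j - i <= min_hairpin:
            continue
        # tie-break: prefer leaving i unpaired
        if m[i, j] == m[i + 1, j]:
            stack_i[top], stack_j[top] = i + 1, j
            top += 1
            continue
        # else pair i with the smallest admissible k
        for k in range(i + min_hairpin + 1, j + 1):
            if can_pair[codes[i], codes[k]]:
                cand = 1
                if k - 1 >= i + 1:
                    cand += m[i + 1, k - 1]
                if k + 1 <= j:
                    cand += m[k + 1, j]
                if cand == m[i, j]:
                    partner[i] = k
                    partner[k] = i
                    if k - 1 >= i + 1:
                        stack_i[top], stack_j[top] = i + 1, k - 1
                        top += 1
                    if k + 1 <= j:
                        stack_i[top], stack_j[top] = k + 1, j
                        top += 1
                    break
    return partner


def fold_maxpair(seq: Union[str, RnaSequence],
                 min_hairpin: int = MIN_HAIRPIN) -> str:
    """Maximum-base-pairing structure of ``seq`` (deterministic).

    Maximizes the number of allowed pairs subject to hairpin loops of at
    least ``min_hairpin`` unpaired residues.  Ties are broken by preferring
    to leave the leftmost position unpaired and, among pairings, the
    smallest partner index, so outputs are bit-reproducible.
    """
    text = str(seq)
    if len(text) <= min_hairpin + 1:
        return "." * len(text)
    partner = _nussinov_pairs(_encode(text), _CAN_PAIR, min_hairpin)
    out = []
    for i, p in enumerate(partner):
        out.append("." if p < 0 else ("(" if p > i else ")"))
    return "".join(out)


# ---------------------------------------------------------------------------
# external thermodynamic backend (ViennaRNA)
# ---------------------------------------------------------------------------

def _import_vienna():
    try:
        import RNA  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise BackendMissingError(
            "ViennaRNA python bindings not installed; install the viennarna "
            "package or use the built-in fold_maxpair backend explicitly"
        ) from exc
    return RNA


def vienna_backend_id() -> str:
    RNA = _import_vienna()
    return f"viennarna-{RNA.__version__}"


def fold_external(seq: Union[str, RnaSequence],
                  temperature_c: float = 37.0) -> FoldResult:
    """Minimum-free-energy fold via ViennaRNA at default Turner parameters."""
    RNA = _import_vienna()
    text = str(seq)
    md = RNA.md()
    md.temperature = temperature_c
    fc = RNA.fold_compound(text, md)
    structure, mfe = fc.mfe()
    return FoldResult(text, structure, float(mfe), vienna_backend_id())


def suboptimal_structures(seq: Union[str, RnaSequence],
                          delta_e: float,
                          temperature_c: float = 37.0) -> list[FoldResult]:
    """All structures within ``delta_e`` kcal/mol of the MFE, ascending in
    energy; the MFE structure is always included."""
    RNA = _import_vienna()
    text = str(seq)
    md = RNA.md()
    md.temperature = temperature_c
    fc = RNA.fold_compound(text, md)
    backend = vienna_backend_id()
    sols = fc.subopt(int(round(delta_e * 100)))
    results = [
        FoldResult(text, s.structure, float(s.energy), backend) for s in sols
    ]
    results.sort(key=lambda r: (r.energy, r.structure))
    return results


def get_folder(name: str, min_hairpin: int = MIN_HAIRPIN,
               temperature_c: float = 37.0) -> tuple[Folder, str]:
    """Resolve a backend name to ``(callable, backend_id)``.

    ``builtin`` maps to :func:`fold_maxpair`; ``vienna`` to the external
    MFE folder.
    """
    if name == "builtin":
        return (lambda s: fold_maxpair(s, min_hairpin),
                f"builtin-maxpair-h{min_hairpin}")
    if name == "vienna":
        backend = vienna_backend_id()  # fail fast if missing
        return (lambda s: fold_external(s, temperature_c).structure, backend)
    raise ValueError(f"unknown folding backend {name!r}")


def normalize_and_fold(raw: str, folder: Folder) -> str:
    """Normalize then fold; propagates SequenceError for caller-side skips."""
    return folder(str(normalize_sequence(raw)))
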