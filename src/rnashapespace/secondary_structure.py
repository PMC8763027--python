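"""Dot-bracket secondary structures and their loop decomposition.

An RNA secondary structure is a properly nested set of base pairs written in
dot-bracket notation: ``(`` and ``)`` for the two halves of a pair, ``.`` for
an unpaired residue.  Every downstream coarse-graining works on the loop
decomposition computed here: the structure is parsed into a rooted ordered
tree whose internal nodes are *helices* (maximal runs of directly stacked
pairs) and whose leaves are maximal unpaired runs, each annotated with the
loop context it sits in (external loop, hairpin, bulge, internal loop, or
multiloop).

Coordinates in error messages and reported violations are 1-based and
inclusive; the internal representation is 0-based.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO, Union

RNA_ALPHABET = frozenset("ACGU")
_NORMALIZABLE = frozenset("ACGUTacgut")

#: loop contexts an unpaired run can live in
EXTERNAL = "external"
HAIRPIN = "hairpin"
BULGE = "bulge"
INTERNAL = "internal"
MULTI = "multi"


class SequenceError(ValueError):
    """A sequence character outside the normalizable alphabet.

    ``position`` is 1-based.
    """

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


class ParseError(ValueError):
    """Malformed dot-bracket input; ``position`` is 1-based."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class RnaSequence:
    """A normalized RNA sequence over {A, C, G, U}."""

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty sequence", 1)
        for i, c in enumerate(self.residues):
            if c not in RNA_ALPHABET:
                raise SequenceError(
                    f"invalid residue {c!r} at position {i + 1}", i + 1
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def normalize_sequence(raw: str) -> RnaSequence:
    """Uppercase ``raw`` and map T->U; reject anything outside ACGUT.

    DNA-style FASTA exports routinely contain T and lowercase; records with
    other characters (N, gaps, IUPAC ambiguity codes) are rejected so callers
    can skip-and-log them.
    """
    if not raw:
        raise SequenceError("empty sequence", 1)
    for i, c in enumerate(raw):
        if c not in _NORMALIZABLE:
            raise SequenceError(f"invalid residue {c!r} at position {i + 1}", i + 1)
    return RnaSequence(raw.upper().replace("T", "U").replace("t", "U"))


# ---------------------------------------------------------------------------
# structure tree
# ---------------------------------------------------------------------------

@dataclass
class UnpairedRun:
    """A maximal run of unpaired residues; ``start`` 0-based, ``context`` a
    loop-context label assigned during parsing."""

    start: int
    length: int
    context: str = EXTERNAL

    @property
    def end(self) -> int:  # exclusive
        return self.start + self.length


@dataclass
class Helix:
    """A maximal run of directly stacked pairs ``(i, j), (i+1, j-1), ...``
    together with the loop it closes (``children``)."""

    pairs: list[tuple[int, int]]
    children: list[Union["Helix", UnpairedRun]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def loop_type(self) -> str:
        """Type of the loop closed by this helix's innermost pair."""
        n_helices = sum(1 for c in self.children if isinstance(c, Helix))
        n_runs = sum(1 for c in self.children if isinstance(c, UnpairedRun))
        if n_helices == 0:
            return HAIRPIN
        if n_helices == 1:
            return BULGE if n_runs == 1 else INTERNAL
        return MULTI


@dataclass
class StructureTree:
    """Loop decomposition of a dot-bracket structure.

    ``children`` is the external loop: an ordered mix of helices and
    unpaired runs whose in-order rendering reconstructs the input exactly.
    """

    length: int
    children: list[Union[Helix, UnpairedRun]] = field(default_factory=list)

    def helices(self, merged: bool = False) -> int:
        """Number of helices; with ``merged=True``, helices separated only
        by bulges/internal loops count as one (the level-4/5 view)."""

        def walk(nodes: Iterable) -> int:
            total = 0
            for node in nodes:
                if isinstance(node, Helix):
                    if merged:
                        inner = node
                        while inner.loop_type in (BULGE, INTERNAL):
                            inner = next(
                                c for c in inner.children if isinstance(c, Helix)
                            )
                        total += 1 + walk(inner.children)
                    else:
                        total += 1 + walk(node.children)
            return total

        return walk(self.children)


def _pair_table(db: str) -> list[int]:
    """Partner index per position (-1 for unpaired); rejects bad input."""
    if not db:
        raise ParseError("empty structure", 1)
    partner = [-1] * len(db)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {i + 1}", i + 1)
            j = stack.pop()
            partner[j], partner[i] = i, j
        elif c == ".":
            continue
        else:
            # extended bracket alphabets ([,{,<) denote pseudoknots, which are
            # outside the nested notation handled here
            raise ParseError(f"invalid character {c!r} at position {i + 1}", i + 1)
    if stack:
        i = stack[-1]
        raise ParseError(f"unbalanced '(' at position {i + 1}", i + 1)
    return partner


def parse_dot_bracket(db: str) -> StructureTree:
    """Parse a dot-bracket string into its loop-decomposition tree."""
    partner = _pair_table(db)
    n = len(db)

    def parse_region(lo: int, hi: int) -> list[Union[Helix, UnpairedRun]]:
        """Children of the loop spanning positions [lo, hi)."""
        nodes: list[Union[Helix, UnpairedRun]] = []
        i = lo
        while i < hi:
            if partner[i] == -1:
                start = i
                while i < hi and partner[i] == -1:
                    i += 1
                nodes.append(UnpairedRun(start, i - start))
            else:
                # maximal stack of directly nested pairs
                j = partner[i]
                pairs = [(i, j)]
                while i + 1 < j - 1 and partner[i + 1] == j - 1:
                    i, j = i + 1, j - 1
                    pairs.append((i, j))
                helix = Helix(pairs, parse_region(i + 1, j))
                nodes.append(helix)
                i = pairs[0][1] + 1
        return nodes

    tree = StructureTree(n, parse_region(0, n))
    _assign_contexts(tree)
    return tree


def _assign_contexts(tree: StructureTree) -> None:
    for node in tree.children:
        if isinstance(node, UnpairedRun):
            node.context = EXTERNAL

    def walk(helix: Helix) -> None:
        ctx = helix.loop_type
        for child in helix.children:
            if isinstance(child, UnpairedRun):
                child.context = ctx
            else:
                walk(child)

    for node in tree.children:
        if isinstance(node, Helix):
            walk(node)


def render_tree(tree: StructureTree) -> str:
    """Inverse of :func:`parse_dot_bracket` (exact round trip)."""
    out = ["?"] * tree.length

    def walk(nodes: Iterable) -> None:
        for node in nodes:
            if isinstance(node, UnpairedRun):
                for k in range(node.start, node.end):
                    out[k] = "."
            else:
                for i, j in node.pairs:
                    out[i], out[j] = "(", ")"
                walk(node.children)

    walk(tree.children)
    return "".join(out)


def validate_structure(db: str, min_hairpin: int = 3) -> list[str]:
    """Return human-readable violations; empty list means valid.

    Checks balancedness and the minimum-hairpin constraint.  Helices of
    length one (lonely pairs) are legal and never reported.
    """
    try:
        tree = parse_dot_bracket(db)
    except ParseError as exc:
        return [f"balance violation: {exc}"]

    violations: list[str] = []

    def walk(nodes: Iterable) -> None:
        for node in nodes:
            if isinstance(node, Helix):
                if node.loop_type == HAIRPIN:
                    run = sum(
                        c.length for c in node.children
                        if isinstance(c, UnpairedRun)
                    )
                    if run < min_hairpin:
                        i, j = node.pairs[-1]
                        violations.append(
                            f"hairpin closed by pair ({i + 1},{j + 1}) has "
                            f"{run} unpaired residues (< {min_hairpin})"
                        )
                walk(node.children)

    walk(tree.children)
    return violations


# ---------------------------------------------------------------------------
# dot-bracket files: one structure per line, optional '>' header before each
# ---------------------------------------------------------------------------

def read_dot_bracket(source: Union[str, TextIO]) -> list[tuple[str, str]]:
    """Read ``(header, structure)`` records; header is '' when absent."""
    handle: TextIO
    close = False
    if isinstance(source, str):
        handle, close = open(source), True
    else:
        handle = source
    try:
        records: list[tuple[str, str]] = []
        header = ""
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                continue
            try:
                _pair_table(line)
            except ParseError as exc:
                raise ParseError(f"line {lineno}: {exc}", exc.position) from exc
            records.append((header, line))
            header = ""
        return records
    finally:
        if close:
            handle.close()


def write_dot_bracket(records: Iterable[tuple[str, str]],
                      sink: Union[str, TextIO]) -> None:
    handle: TextIO
    close = False
    if isinstance(sink, str):
        handle, close = open(sink, "w"), True
    else:
        handle = sink
    try:
        for header, structure in records:
            if header:
                handle.write(f">{header}\n")
            handle.write(structure + "\n")
    finally:
        if close:
            handle.close()
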