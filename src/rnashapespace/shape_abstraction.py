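"""Five-level abstract shapes of RNA secondary structures.

Abstract shapes coarse-grain a secondary structure into a string over
``[ ] _`` that keeps progressively less detail:

* **level 1** — nesting pattern of all loop types and all unpaired regions;
* **level 2** — all loop types, but unpaired regions only in the external
  loop and in multiloops;
* **level 3** — all loop types, no unpaired regions;
* **level 4** — helix nesting pattern (helices separated only by bulges or
  internal loops merge into one bracket pair) plus external/multiloop
  unpaired regions;
* **level 5** — helix nesting pattern only.

At levels 1–3 every maximal uninterrupted helix owns one bracket pair, so
bulges and internal loops show up as nested brackets; at levels 4–5 the
interruption is erased.  Each maximal unpaired run is a single ``_``.

The open chain (a structure with no pairs) is written ``_`` at every level;
the convention is applied uniformly so that spectra over arbitrary samples
always have a well-defined shape for unfolded sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from .secondary_structure import (
    EXTERNAL,
    MULTI,
    Helix,
    StructureTree,
    UnpairedRun,
    parse_dot_bracket,
)

LEVELS = (1, 2, 3, 4, 5)


class ShapeError(ValueError):
    """Malformed shape string."""


def _keep_underscore(level: int, context: str) -> bool:
    if level == 1:
        return True
    if level in (2, 4):
        return context in (EXTERNAL, MULTI)
    return False  # levels 3, 5


def abstract_shape(tree: StructureTree, level: int) -> str:
    """Abstract shape of a structure tree at the given level (1–5)."""
    if level not in LEVELS:
        raise ValueError(f"level must be in 1..5, got {level}")

    merge = level >= 4

    def render(nodes) -> list[str]:
        out: list[str] = []
        for node in nodes:
            if isinstance(node, UnpairedRun):
                if _keep_underscore(level, node.context):
                    out.append("_")
            else:
                inner = node
                if merge:
                    # follow the chain of helices interrupted only by
                    # bulges/internal loops down to the terminal loop
                    while inner.loop_type in ("bulge", "internal"):
                        inner = next(
                            c for c in inner.children if isinstance(c, Helix)
                        )
                out.append("[")
                out.extend(render(inner.children))
                out.append("]")
        return out

    return _canonical("".join(render(tree.children)))


def shape_of(db: str, level: int) -> str:
    """Convenience: parse a dot-bracket string and abstract it."""
    return abstract_shape(parse_dot_bracket(db), level)


def _canonical(text: str) -> str:
    # maximal unpaired regions are a single underscore; open chain is "_"
    while "__" in text:
        text = text.replace("__", "_")
    return text if text else "_"


def parse_shape(text: str) -> str:
    """Canonicalize a shape string: strip whitespace, validate brackets.

    Accepts the spaced style some tools print (``[ [] [] [] ]``) and returns
    the canonical spaceless form (``[[][][]]``).
    """
    canon = "".join(text.split())
    depth = 0
    for i, c in enumerate(canon):
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise ShapeError(f"unbalanced ']' at position {i + 1}")
        elif c != "_":
            raise ShapeError(f"invalid shape character {c!r} at position {i + 1}")
    if depth != 0:
        raise ShapeError("unbalanced '['")
    if not canon:
        raise ShapeError("empty shape")
    return _canonical(canon)


# ---------------------------------------------------------------------------
# projection: the level-1 string determines every coarser level
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    bracket: bool  # False => underscore leaf
    children: list


def _parse_shape_tree(shape: str) -> list[_Node]:
    root: list[_Node] = []
    stack: list[list[_Node]] = [root]
    for i, c in enumerate(shape):
        if c == "[":
            node = _Node(True, [])
            stack[-1].append(node)
            stack.append(node.children)
        elif c == "]":
            if len(stack) == 1:
                raise ShapeError(f"unbalanced ']' at position {i + 1}")
            stack.pop()
        elif c == "_":
            stack[-1].append(_Node(False, []))
        else:
            raise ShapeError(f"invalid shape character {c!r} at position {i + 1}")
    if len(stack) != 1:
        raise ShapeError("unbalanced '['")
    return root


def project_shape(shape: str, target_level: int) -> str:
    """Rewrite a level-1 shape string to a coarser level.

    Used as an independent oracle for :func:`abstract_shape`: the loop
    context of every underscore is recoverable from the level-1 bracket
    structure alone (root = external loop; a bracket with ≥2 bracket
    children closes a multiloop; exactly one bracket child means the helix
    is interrupted by a bulge/internal loop; none means a hairpin), so
    projecting level 1 must agree with abstracting the structure directly.
    """
    if target_level not in LEVELS:
        raise ValueError(f"level must be in 1..5, got {target_level}")
    nodes = _parse_shape_tree(parse_shape(shape))
    merge = target_level >= 4

    def context(parent_is_root: bool, n_bracket_children: int) -> str:
        if parent_is_root:
            return EXTERNAL
        if n_bracket_children >= 2:
            return MULTI
        if n_bracket_children == 1:
            return "interruption"
        return "hairpin"

    def render(nodes: list[_Node], parent_root: bool) -> list[str]:
        n_brackets = sum(1 for n in nodes if n.bracket)
        ctx = context(parent_root, n_brackets)
        out: list[str] = []
        for node in nodes:
            if not node.bracket:
                if _keep_underscore(target_level, ctx):
                    out.append("_")
                continue
            inner = node
            if merge:
                # a pair enclosing exactly one pair with no bracket siblings
                # is a helix interruption: collapse to a fixed point
                while sum(1 for c in inner.children if c.bracket) == 1:
                    inner = next(c for c in inner.children if c.bracket)
            out.append("[")
            out.extend(render(inner.children, False))
            out.append("]")
        return out

    return _canonical("".join(render(nodes, True)))
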