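"""DeepSMILES converter (branch close-parens and ring-size notation).

DeepSMILES rewrites SMILES so that branches need no open parenthesis — a run
of ``)`` after a branch pops that many levels back up the tree — and ring
bonds are written as a single number at the ring-closing atom giving the ring
size (the bond partner is ``size - 1`` atoms back in written order).  The
syntax removes the paired-symbol constraints of SMILES, which reduces (but
does not eliminate) the chance that random character edits break a string:
valence errors and impossible pops/ring sizes still invalidate it.

The ring number counts atoms along the tree path (the ancestor chain), not
along the written string, so a ring of size 6 is written ``6`` wherever its
branches happen to sit.  SMILES produced by DFS writers (every toolkit
output) always close rings onto an ancestor, which is what the notation
requires; hand-written strings that close a ring between two branch tips
cannot be converted and raise.

:func:`to_deepsmiles` converts a SMILES string textually; :func:`to_smiles`
converts back, returning ``None`` for syntactically broken input (semantic
validity is then up to the SMILES parser).
"""

from __future__ import annotations

import re

__all__ = ["to_deepsmiles", "to_smiles", "DeepSmilesError"]


class DeepSmilesError(ValueError):
    """Input SMILES that cannot be converted to DeepSMILES."""


_ATOM_RE = re.compile(r"\[[^\]]*\]|Br|Cl|[BCNOPSFI]|[bcnops]")
_BOND_CHARS = "-=#:/\\~$"


def _ring_label(n: int) -> str:
    if n > 99:
        raise DeepSmilesError(f"ring span {n} too large to notate")
    return str(n) if n <= 9 else f"%{n:02d}"


def to_deepsmiles(smiles: str) -> str:
    """Convert a SMILES string to DeepSMILES."""
    out: list[str] = []
    i = 0
    atom_count = 0
    path: list[int] = []  # atom index at each tree depth along current chain
    stack: list[int] = []
    open_rings: dict[str, tuple[int, int, str]] = {}
    pending_bond = ""
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        m = _ATOM_RE.match(smiles, i)
        if m:
            out.append(pending_bond + m.group())
            pending_bond = ""
            path.append(atom_count)
            atom_count += 1
            i = m.end()
        elif ch in _BOND_CHARS:
            pending_bond = ch
            i += 1
        elif ch == "(":
            stack.append(len(path))
            i += 1
        elif ch == ")":
            if not stack:
                raise DeepSmilesError(f"unbalanced ')' in {smiles!r}")
            base = stack.pop()
            out.append(")" * (len(path) - base))
            del path[base:]
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                label, i = smiles[i:i + 3], i + 3
            else:
                label, i = ch, i + 1
            if label in open_rings:
                atom, depth, bond = open_rings.pop(label)
                # ring size counts atoms on the tree path, so the opening
                # atom must be an ancestor of the closing atom
                if depth > len(path) or path[depth - 1] != atom:
                    raise DeepSmilesError(
                        f"ring closure not to an ancestor in {smiles!r}")
                bond = bond or pending_bond
                out.append(bond + _ring_label(len(path) - depth + 1))
            else:
                open_rings[label] = (path[-1], len(path), pending_bond)
            pending_bond = ""
        else:
            raise DeepSmilesError(f"unsupported character {ch!r} in {smiles!r}")
    if stack or open_rings:
        raise DeepSmilesError(f"unbalanced SMILES {smiles!r}")
    return "".join(out)


class _Node:
    __slots__ = ("text", "bond", "parent", "children", "rings", "index")

    def __init__(self, text: str, bond: str, parent: "_Node | None", index: int):
        self.text = text
        self.bond = bond
        self.parent = parent
        self.children: list[_Node] = []
        self.rings: list[str] = []  # ring-closure label text, appended in order
        self.index = index


def to_smiles(deepsmiles: str) -> str | None:
    """Convert DeepSMILES back to SMILES, or ``None`` if syntactically broken.

    Broken means: a pop past the root, a ring number reaching before the
    first atom or onto the current atom, a dangling bond symbol, or any
    character outside the grammar.  The returned SMILES may still be
    semantically invalid (valences, aromaticity) — that is the parser's call.
    """
    root: _Node | None = None
    current: _Node | None = None
    atoms: list[_Node] = []
    pending_bond = ""
    next_label = 1
    i = 0
    n = len(deepsmiles)
    while i < n:
        ch = deepsmiles[i]
        m = _ATOM_RE.match(deepsmiles, i)
        if m:
            node = _Node(m.group(), pending_bond, current, len(atoms))
            pending_bond = ""
            if current is None:
                if root is not None:
                    return None  # second fragment: pops went past the root
                root = node
            else:
                current.children.append(node)
            atoms.append(node)
            current = node
            i = m.end()
        elif ch in _BOND_CHARS:
            if pending_bond:
                return None
            pending_bond = ch
            i += 1
        elif ch == ")":
            if pending_bond or current is None:
                return None
            current = current.parent
            if current is None:
                return None
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if i + 2 >= n or not deepsmiles[i + 1:i + 3].isdigit():
                    return None
                size, i = int(deepsmiles[i + 1:i + 3]), i + 3
            else:
                size, i = int(ch), i + 1
            if current is None or size < 2:
                return None
            partner = current
            for _ in range(size - 1):  # walk up the ancestor chain
                partner = partner.parent
                if partner is None:
                    return None
            label = _ring_label(next_label)
            next_label += 1
            partner.rings.append(label)
            current.rings.append(pending_bond + label)
            pending_bond = ""
        else:
            return None
    if root is None or pending_bond:
        return "" if (root is None and not pending_bond) else None

    out: list[str] = []

    def serialize(node: _Node) -> None:
        out.append(node.text)
        out.extend(node.rings)
        for child in node.children[:-1]:
            out.append("(" + child.bond)
            serialize(child)
            out.append(")")
        if node.children:
            out.append(node.children[-1].bond)
            serialize(node.children[-1])

    serialize(root)
    return "".join(out)
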