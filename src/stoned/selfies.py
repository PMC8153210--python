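"""SELFIES codec: a robust molecular string grammar over a 34-token alphabet.

SELFIES (SELF-referencIng Embedded Strings) is a molecular string
representation in which *every* syntactically possible token sequence derives
a valence-correct molecular graph.  Robustness comes from the derivation
rules, not from the strings: bond orders requested by a token are capped by
the remaining valence of the atoms involved, branch and ring tokens that
arrive in a state that cannot host them are skipped, and derivation of a
chain halts once its current atom has no free valence left.  Arbitrary token
edits (replace / delete / insert) therefore always decode to a molecule the
chemistry toolkit accepts, which is the property the rest of this package is
built on.

This module implements the semantically robust subset of the grammar:
neutral organic atoms (C, N, O, S, P, F, Cl, Br, I) with single/double/triple
bonds, branches, and rings.  Charges, isotopes, radicals and stereochemistry
are outside the supported feature set; :func:`encode` raises
:class:`UnsupportedFeatureError` for them.

The public surface is :func:`encode` (SMILES -> token list),
:func:`decode` (token list -> canonical SMILES), :func:`decode_to_mol`,
:data:`ROBUST_ALPHABET` (the 34 mutation tokens) and :func:`tokenize`.
"""

from __future__ import annotations

import re

from rdkit import Chem

__all__ = [
    "ROBUST_ALPHABET",
    "PAD_TOKEN",
    "SelfiesError",
    "UnsupportedFeatureError",
    "tokenize",
    "encode",
    "decode",
    "decode_to_mol",
]


class SelfiesError(ValueError):
    """Malformed SELFIES token or unencodable input."""


class UnsupportedFeatureError(SelfiesError):
    """Molecule uses a feature outside the robust-subset grammar."""


# maximum total bond order (explicit valence) per element; implicit hydrogens
# fill whatever the toolkit's allowed-valence list permits afterwards
_VALENCE_CAP = {
    "C": 4, "N": 3, "O": 2, "S": 6, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_ORDER = {"": 1, "=": 2, "#": 3}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_RDKIT_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}

#: inert padding token: skipped during derivation, used to length-align
#: strings for deterministic interpolation
PAD_TOKEN = "[nop]"

_ATOM_TOKENS = tuple(
    f"[{prefix}{sym}]"
    for sym in ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
    for prefix in ("", "=", "#")
    if _BOND_ORDER[prefix] <= _VALENCE_CAP[sym]
)
_BRANCH_TOKENS = tuple(
    f"[{prefix}Branch{n}]" for n in (1, 2, 3) for prefix in ("", "=", "#")
)
_RING_TOKENS = tuple(
    f"[{prefix}Ring{n}]" for n in (1, 2, 3) for prefix in ("", "=", "#")
)

#: the 34-token semantically robust alphabet used for random mutations:
#: 18 atom tokens, 9 branch tokens, 6 ring tokens and the inert [nop]
#: (triple-bond ring tokens are part of the grammar so every molecule can be
#: encoded, but are too rare to belong to the mutation alphabet)
ROBUST_ALPHABET = _ATOM_TOKENS + _BRANCH_TOKENS + tuple(
    t for t in _RING_TOKENS if not t.startswith("[#")) + (PAD_TOKEN,)
assert len(ROBUST_ALPHABET) == 34

# 16 tokens double as hexadecimal digits for branch lengths / ring distances
_INDEX_TOKENS = (
    "[C]", "[Ring1]", "[Ring2]",
    "[Branch1]", "[=Branch1]", "[#Branch1]",
    "[Branch2]", "[=Branch2]", "[#Branch2]",
    "[O]", "[N]", "[=N]", "[=C]", "[#C]", "[S]", "[P]",
)
_INDEX_OF = {tok: i for i, tok in enumerate(_INDEX_TOKENS)}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")

# parsed token table: token -> (kind, bond_order, payload)
_ATOM, _BRANCH, _RING, _NOP = range(4)
_PARSED: dict[str, tuple[int, int, object]] = {PAD_TOKEN: (_NOP, 0, None)}
for _tok in _ATOM_TOKENS:
    _m = re.fullmatch(r"\[([=#]?)([A-Z][a-z]?)\]", _tok)
    _PARSED[_tok] = (_ATOM, _BOND_ORDER[_m.group(1)], _m.group(2))
for _tok in _BRANCH_TOKENS:
    _m = re.fullmatch(r"\[([=#]?)Branch([123])\]", _tok)
    _PARSED[_tok] = (_BRANCH, _BOND_ORDER[_m.group(1)], int(_m.group(2)))
for _tok in _RING_TOKENS:
    _m = re.fullmatch(r"\[([=#]?)Ring([123])\]", _tok)
    _PARSED[_tok] = (_RING, _BOND_ORDER[_m.group(1)], int(_m.group(2)))


def tokenize(selfies: str) -> list[str]:
    """Split a SELFIES string into bracketed tokens.

    Raises :class:`SelfiesError` if any character falls outside brackets or a
    token is not part of the grammar.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise SelfiesError(f"not a sequence of bracketed tokens: {selfies!r}")
    for tok in tokens:
        if tok not in _PARSED:
            raise SelfiesError(f"unknown token {tok!r}")
    return tokens


def _read_index(tokens: list[str], i: int, n_digits: int) -> tuple[int, int]:
    """Interpret up to ``n_digits`` tokens at ``i`` as a base-16 number."""
    value = 0
    stop = min(i + n_digits, len(tokens))
    for j in range(i, stop):
        value = value * 16 + _INDEX_OF.get(tokens[j], 0)
    return value, stop


class _Graph:
    """Molecular graph accumulated during derivation."""

    __slots__ = ("symbols", "remaining", "bonds", "bonded")

    def __init__(self) -> None:
        self.symbols: list[str] = []
        self.remaining: list[int] = []
        self.bonds: list[tuple[int, int, int]] = []
        self.bonded: set[tuple[int, int]] = set()

    def add_atom(self, symbol: str) -> int:
        self.symbols.append(symbol)
        self.remaining.append(_VALENCE_CAP[symbol])
        return len(self.symbols) - 1

    def add_bond(self, a: int, b: int, order: int) -> None:
        self.bonds.append((a, b, order))
        self.bonded.add((min(a, b), max(a, b)))
        self.remaining[a] -= order
        self.remaining[b] -= order


def _derive(tokens: list[str], graph: _Graph, prev: int | None,
            init_order: int) -> None:
    """Derive one chain (the whole string, or a branch substring).

    ``prev`` is the attachment atom (None at top level); ``init_order`` the
    bond order requested by the enclosing branch token for the first atom.
    """
    pending = init_order if prev is not None else 0
    i = 0
    n = len(tokens)
    while i < n:
        kind, order, payload = _PARSED[tokens[i]]
        i += 1
        if kind == _NOP:
            continue
        if kind == _ATOM:
            symbol = payload
            cap = _VALENCE_CAP[symbol]
            if prev is None:
                prev = graph.add_atom(symbol)
                continue
            avail = graph.remaining[prev]
            if avail == 0:
                break  # chain saturated: rest of this level is discarded
            if pending:
                order = max(order, pending)
                pending = 0
            order = min(order, avail, cap)
            idx = graph.add_atom(symbol)
            graph.add_bond(prev, idx, order)
            prev = idx
        elif kind == _BRANCH:
            if prev is None or graph.remaining[prev] <= 1:
                continue  # state cannot host a branch: skip the token
            length, i = _read_index(tokens, i, payload)
            sub = tokens[i:i + length + 1]
            i += length + 1
            _derive(sub, graph, prev, order)
        else:  # _RING
            if prev is None:
                continue
            distance, i = _read_index(tokens, i, payload)
            partner = max(0, prev - (distance + 1))
            if partner == prev:
                continue
            if (partner, prev) in graph.bonded:
                continue
            order = min(order, graph.remaining[prev],
                        graph.remaining[partner])
            if order < 1:
                continue
            graph.add_bond(partner, prev, order)


def decode_to_mol(tokens: list[str] | str) -> Chem.Mol:
    """Derive the molecular graph for a token sequence.

    Returns a sanitized RDKit molecule; an empty derivation (no atom tokens
    reachable) yields an empty molecule.
    """
    if isinstance(tokens, str):
        tokens = tokenize(tokens)
    else:
        for tok in tokens:
            if tok not in _PARSED:
                raise SelfiesError(f"unknown token {tok!r}")
    # the pad token is inert everywhere: strip it before derivation so it can
    # never be counted as a branch length, index digit or branch content
    graph = _Graph()
    _derive([t for t in tokens if t != PAD_TOKEN], graph, None, 0)
    mol = Chem.RWMol()
    for symbol in graph.symbols:
        mol.AddAtom(Chem.Atom(symbol))
    for a, b, order in graph.bonds:
        mol.AddBond(a, b, _RDKIT_BOND[order])
    mol = mol.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def decode(tokens: list[str] | str) -> str:
    """Decode a token sequence to a canonical SMILES string.

    Never fails on in-alphabet tokens: any sequence derives a valid molecule
    (possibly the empty one, returned as ``""``).
    """
    return Chem.MolToSmiles(decode_to_mol(tokens))


def _check_supported(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _VALENCE_CAP:
            raise UnsupportedFeatureError(
                f"element {atom.GetSymbol()} outside the robust alphabet")
        if atom.GetFormalCharge() != 0:
            raise UnsupportedFeatureError("formal charges are not supported")
        if atom.GetIsotope() != 0:
            raise UnsupportedFeatureError("isotope labels are not supported")
        if atom.GetNumRadicalElectrons() != 0:
            raise UnsupportedFeatureError("radicals are not supported")


def encode(smiles: str) -> list[str]:
    """Encode a SMILES string as SELFIES tokens.

    The traversal follows the atom order of the input string, so different
    SMILES orderings of one molecule give different (all valid) token
    sequences.  Stereochemistry is dropped; the kekulized graph is encoded.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SelfiesError(f"cannot parse SMILES {smiles!r}")
    _check_supported(mol)
    mol = Chem.RWMol(mol)
    Chem.RemoveStereochemistry(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    if mol.GetNumAtoms() == 0:
        return []

    neighbors: list[list[tuple[int, int]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        if bond.GetBondType() not in _ORDER_FROM_RDKIT:
            raise UnsupportedFeatureError(
                f"bond type {bond.GetBondType()} is not supported")
        order = _ORDER_FROM_RDKIT[bond.GetBondType()]
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        neighbors[a].append((b, order))
        neighbors[b].append((a, order))

    position: dict[int, int] = {}  # atom idx -> emission rank
    emitted: set[tuple[int, int]] = set()  # edges already written

    def ring_tokens(order: int, distance: int) -> list[str]:
        digits = _index_digits(distance)
        return [f"[{_BOND_PREFIX[order]}Ring{len(digits)}]"] + digits

    def emit(atom: int, parent: int | None) -> list[str]:
        # root atom token written without a bond prefix; the caller rewrites
        # it (inline child) or puts the order on the branch token
        position[atom] = len(position)
        out = [f"[{mol.GetAtomWithIdx(atom).GetSymbol()}]"]
        pending: list[tuple[int, int]] = []  # unvisited neighbours, in order
        for other, order in neighbors[atom]:
            if other == parent:
                continue
            edge = (min(atom, other), max(atom, other))
            if edge in emitted:
                continue
            if other in position:  # ring closure back to an earlier atom
                emitted.add(edge)
                out.extend(ring_tokens(order, position[atom] - position[other] - 1))
            else:
                pending.append((other, order))
        for other, order in pending:
            edge = (min(atom, other), max(atom, other))
            if edge in emitted:
                continue  # reached through a ring inside an earlier branch
            if other in position:
                emitted.add(edge)
                out.extend(ring_tokens(order, position[atom] - position[other] - 1))
                continue
            emitted.add(edge)
            sub = emit(other, atom)
            more = any(
                (min(atom, o), max(atom, o)) not in emitted
                for o, _ in neighbors[atom] if o != parent
            )
            if more:  # wrap in a branch; order rides on the branch token
                digits = _index_digits(len(sub) - 1)
                out.append(f"[{_BOND_PREFIX[order]}Branch{len(digits)}]")
                out.extend(digits)
                out.extend(sub)
            else:  # inline continuation; order rides on the atom token
                symbol = mol.GetAtomWithIdx(other).GetSymbol()
                sub[0] = f"[{_BOND_PREFIX[order]}{symbol}]"
                out.extend(sub)
        return out

    tokens = emit(0, None)
    for extra in range(1, mol.GetNumAtoms()):
        if extra not in position:
            raise UnsupportedFeatureError(
                "disconnected structures are not supported")
    return tokens


def _index_digits(value: int) -> list[str]:
    """Base-16 digit tokens for a branch length / ring distance."""
    if value < 0 or value >= 16 ** 3:
        raise SelfiesError(f"index {value} out of range")
    digits = []
    v = value
    while True:
        digits.append(_INDEX_TOKENS[v % 16])
        v //= 16
        if v == 0:
            break
    n = max(len(digits), 1)
    # widths are 1, 2 or 3 digit tokens, matching Branch1/2/3 and Ring1/2/3
    return [_INDEX_TOKENS[0]] * (n - len(digits)) + digits[::-1]
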