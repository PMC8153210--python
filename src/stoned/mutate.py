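"""Point mutations and randomized reorderings of molecular strings.

The engine works on :class:`TokenString` objects — a molecule in one string
representation, split into its mutation units.  For SELFIES the unit is the
bracketed token and any edit stays decodable; for SMILES and DeepSMILES the
unit is the single character (two-character element symbols may be corrupted
by an edit — deliberately so, since those representations serve as fragility
baselines).

A *point mutation* is one REPLACE, DELETE or INSERT at a position drawn from
a configurable window of the string, with replacement tokens drawn from a
configurable alphabet.  Chains of mutations are cumulative: element ``i`` of
a chain carries ``i`` mutations.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger

from . import deepsmiles as _ds
from . import selfies as _sf

# decoding deliberately feeds millions of broken strings to the parser;
# keep its error stream quiet
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "Representation",
    "Op",
    "TokenString",
    "MutationSpec",
    "Mutation",
    "INVALID",
    "randomize_orderings",
    "encode",
    "decode",
    "canonical",
    "draw_mutation",
    "apply_mutation",
    "mutate",
    "mutate_chain",
    "random_selfies",
]

#: value returned by :func:`decode` for strings that do not correspond to a
#: molecule (never produced for SELFIES input)
INVALID = None


class Representation(str, enum.Enum):
    SELFIES = "selfies"
    SMILES = "smiles"
    DEEPSMILES = "deepsmiles"


class Op(str, enum.Enum):
    REPLACE = "replace"
    DELETE = "delete"
    INSERT = "insert"


@dataclass(frozen=True)
class TokenString:
    """A molecule in one string representation, tokenized."""

    representation: Representation
    tokens: tuple[str, ...]
    source_smiles: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "representation",
                           Representation(self.representation))

    @property
    def string(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class MutationSpec:
    """How to mutate: ops allowed, chain length, position window, alphabet.

    ``n_mutations`` is the depth of a cumulative mutation chain (1–5 in the
    reference experiments).  ``position_window`` is a fraction interval of
    the string length: ``(0.0, 1.0)`` mutates anywhere, ``(0.9, 1.0)`` only
    the terminal 10% of positions, and so on.  ``uniform_n`` switches
    :func:`mutate_chain` callers from the cumulative chain to drawing the
    number of mutations uniformly from ``1..n_mutations`` per string.
    """

    n_mutations: int = 5
    ops_allowed: tuple[Op, ...] = (Op.REPLACE, Op.DELETE, Op.INSERT)
    position_window: tuple[float, float] = (0.0, 1.0)
    alphabet: tuple[str, ...] = field(default=_sf.ROBUST_ALPHABET)
    rng_seed: int = 0
    uniform_n: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.position_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid position window ({lo}, {hi})")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        if self.n_mutations < 1:
            raise ValueError("n_mutations must be >= 1")
        if not self.ops_allowed:
            raise ValueError("ops_allowed must be non-empty")
        object.__setattr__(self, "ops_allowed",
                           tuple(Op(o) for o in self.ops_allowed))
        object.__setattr__(self, "alphabet", tuple(self.alphabet))


@dataclass(frozen=True)
class Mutation:
    """One drawn point mutation (exposed for instrumented tests/logging)."""

    op: Op
    index: int
    token: str | None  # None for DELETE


#: named position windows used in the reference experiments
WINDOWS = {
    "random": (0.0, 1.0),
    "terminal10": (0.9, 1.0),
    "central10": (0.45, 0.55),
    "initial10": (0.0, 0.1),
}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def canonical(smiles: str) -> str:
    """Canonical (isomeric) SMILES, or raise on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def randomize_orderings(smiles: str, n: int, seed) -> list[str]:
    """``n`` random atom-order enumerations of one molecule (with replacement).

    Every returned string canonicalizes back to the input molecule; a fixed
    seed gives a fixed list.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    rng = _rng(seed)
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(n):
        perm = [int(x) for x in rng.permutation(n_atoms)]
        out.append(Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm),
                                    canonical=False))
    return out


def encode(smiles: str, representation: Representation) -> TokenString:
    """Tokenize a SMILES string in the requested representation.

    The SELFIES encoding follows the atom order of the input string, so
    encoded reorderings are genuinely different token sequences.
    """
    representation = Representation(representation)
    if representation == Representation.SELFIES:
        tokens = tuple(_sf.encode(smiles))
    elif representation == Representation.SMILES:
        if Chem.MolFromSmiles(smiles) is None:
            raise ValueError(f"cannot parse SMILES {smiles!r}")
        tokens = tuple(smiles)
    else:
        tokens = tuple(_ds.to_deepsmiles(smiles))
    return TokenString(representation, tokens, source_smiles=canonical(smiles))


def decode(ts: TokenString) -> str | None:
    """Decode to canonical SMILES, or :data:`INVALID` (``None``).

    SELFIES never decodes to INVALID; SMILES/DeepSMILES strings that fail
    syntax or valence checks do.
    """
    if ts.representation == Representation.SELFIES:
        return _sf.decode(list(ts.tokens))
    if ts.representation == Representation.SMILES:
        smi = ts.string
    else:
        smi = _ds.to_smiles(ts.string)
        if smi is None:
            return INVALID
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        return INVALID
    return Chem.MolToSmiles(mol)


def window_indices(length: int, window: tuple[float, float],
                   insert: bool = False) -> tuple[int, int]:
    """Inclusive index bounds selected by a fractional window.

    A window ``(lo, hi)`` over ``L`` tokens selects integer indices
    ``floor(lo*L) .. ceil(hi*L)-1`` clamped to the string; INSERT may
    additionally target the end position when ``hi == 1.0``.
    """
    lo, hi = window
    start = min(max(math.floor(lo * length), 0), length - 1)
    end = min(max(math.ceil(hi * length) - 1, start), length - 1)
    if insert and hi == 1.0:
        end = length
    return start, end


def draw_mutation(ts: TokenString, spec: MutationSpec, rng) -> Mutation:
    """Draw one point mutation (op, position, token) for ``ts``."""
    rng = _rng(rng)
    ops = spec.ops_allowed
    length = len(ts.tokens)
    while True:
        op = ops[int(rng.integers(len(ops)))]
        if op == Op.DELETE and length <= 1:
            continue  # never derive an empty string; redraw the op kind
        break
    start, end = window_indices(length, spec.position_window,
                                insert=(op == Op.INSERT))
    index = int(rng.integers(start, end + 1))
    token = None
    if op != Op.DELETE:
        token = spec.alphabet[int(rng.integers(len(spec.alphabet)))]
    return Mutation(op, index, token)


def apply_mutation(ts: TokenString, mutation: Mutation) -> TokenString:
    tokens = list(ts.tokens)
    if mutation.op == Op.REPLACE:
        tokens[mutation.index] = mutation.token
    elif mutation.op == Op.DELETE:
        del tokens[mutation.index]
    else:
        tokens.insert(mutation.index, mutation.token)
    return TokenString(ts.representation, tuple(tokens))


def mutate(ts: TokenString, spec: MutationSpec, rng=None) -> TokenString:
    """Apply exactly one seeded point mutation."""
    if not ts.tokens:
        raise ValueError("cannot mutate an empty token string")
    rng = _rng(spec.rng_seed if rng is None else rng)
    return apply_mutation(ts, draw_mutation(ts, spec, rng))


def mutate_chain(ts: TokenString, spec: MutationSpec, n: int,
                 rng=None) -> list[TokenString]:
    """Cumulative chain: element ``i`` (0-based) carries ``i+1`` mutations."""
    if n < 1:
        raise ValueError("chain length must be >= 1")
    rng = _rng(spec.rng_seed if rng is None else rng)
    out = []
    current = ts
    for _ in range(n):
        current = mutate(current, spec, rng)
        out.append(current)
    return out


def random_selfies(length: int, seed) -> TokenString:
    """A random SELFIES drawn uniformly from the 34-token robust alphabet."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    tokens = tuple(_sf.ROBUST_ALPHABET[int(i)]
                   for i in rng.integers(len(_sf.ROBUST_ALPHABET), size=length))
    return TokenString(Representation.SELFIES, tokens)
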