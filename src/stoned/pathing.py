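"""Deterministic interpolation between molecules and median-molecule search.

Two SELFIES strings can be interconverted by aligning them to equal length
(padding the shorter with the inert ``[nop]`` token), listing the ``t``
positions where they differ, and overwriting the start string's tokens with
the target's one position at a time.  Every intermediate decodes to a valid
molecule, so each substitution order gives a *raw path* of ``t`` molecules;
there are exactly ``t!`` such orders.  Raw paths do not increase fingerprint
similarity monotonically; a *chemical path* is extracted by keeping only
steps whose similarity to the target strictly exceeds the last kept step
(the first mutated step is exempt, to avoid holes right at the start).

Chaining pairwise interpolations through three or more reference molecules
generalizes the construction; ranking all visited molecules by joint
similarity to the full reference set yields median-molecule candidates.
Molecules with bridgehead atoms — a junction shared by two rings fused
through more than one bond — can be filtered out, since generated bridged
systems frequently carry Bredt-rule-violating double bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, QED, rdMolDescriptors

from . import selfies as _sf
from .mutate import Representation, TokenString, canonical, encode, \
    randomize_orderings
from .similarity import bulk_tanimoto, fingerprint, joint_from_sims

__all__ = [
    "RawPath",
    "ChemicalPath",
    "MedianCandidate",
    "pad_align",
    "sample_raw_path",
    "count_paths",
    "total_paths",
    "increasing_indices",
    "extract_chemical_path",
    "sample_many_paths",
    "median_search",
    "has_bridgehead",
    "annotate_properties",
    "PROPERTY_PROVIDERS",
]


@dataclass(frozen=True)
class RawPath:
    """One substitution order's molecule sequence from start to target."""

    start_tokens: tuple[str, ...]
    target_tokens: tuple[str, ...]
    steps: tuple[str, ...]  # canonical SMILES after each substitution
    mutated_position_order: tuple[int, ...]
    start_smiles: str
    target_smiles: str


@dataclass(frozen=True)
class ChemicalPath:
    """Monotone-similarity subsequence of a raw path (start included)."""

    molecules: tuple[str, ...]
    sims_to_target: tuple[float, ...]
    sims_to_start: tuple[float, ...]
    fingerprint_kind: str
    properties: dict[str, tuple[float, ...]] | None = None


@dataclass(frozen=True)
class MedianCandidate:
    smiles: str
    sims: tuple[float, ...]
    joint: float
    passes_bridgehead_filter: bool


def pad_align(a: TokenString, b: TokenString
              ) -> tuple[TokenString, TokenString]:
    """Length-align two SELFIES token strings by tail-padding with ``[nop]``.

    The pad token is skipped during derivation, so padding never changes
    what a string decodes to.
    """
    for ts in (a, b):
        if ts.representation != Representation.SELFIES:
            raise ValueError("pad_align requires SELFIES token strings")
    n = max(len(a.tokens), len(b.tokens))
    pad = lambda t: t + (_sf.PAD_TOKEN,) * (n - len(t))
    return (dc_replace(a, tokens=pad(a.tokens)),
            dc_replace(b, tokens=pad(b.tokens)))


def sample_raw_path(a: TokenString, b: TokenString, seed) -> RawPath:
    """Interpolate ``a`` into ``b`` along one random substitution order."""
    a, b = pad_align(a, b)
    differing = [i for i, (x, y) in enumerate(zip(a.tokens, b.tokens))
                 if x != y]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = [differing[int(i)] for i in rng.permutation(len(differing))]
    start_smiles = _sf.decode(list(a.tokens))
    current = list(a.tokens)
    steps = []
    for pos in order:
        current[pos] = b.tokens[pos]
        steps.append(_sf.decode(current))
    if not steps:
        steps = [start_smiles]
    return RawPath(a.tokens, b.tokens, tuple(steps), tuple(order),
                   start_smiles, _sf.decode(list(b.tokens)))


def count_paths(t: int) -> int:
    """Number of substitution orders (= raw paths) for t differing positions."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return math.factorial(t)


def total_paths(e: Sequence[int]) -> int:
    """Total paths over several target representations with e_i differing
    positions each."""
    return sum(count_paths(t) for t in e)


def increasing_indices(sims: Sequence[float]) -> list[int]:
    """Indices kept by the monotone chemical-path filter.

    Index 0 (the start molecule) and index 1 (the first mutated step) are
    always kept; afterwards a step is kept iff its similarity strictly
    exceeds the last kept one.
    """
    kept = [0]
    if len(sims) > 1:
        kept.append(1)
        last = sims[1]
        for i in range(2, len(sims)):
            if sims[i] > last:
                kept.append(i)
                last = sims[i]
    return kept


def extract_chemical_path(raw: RawPath, kind: str = "ecfp4") -> ChemicalPath:
    """Apply the monotone-similarity filter to a raw path."""
    molecules = [raw.start_smiles, *raw.steps]
    fps = [fingerprint(m, kind) for m in molecules]
    to_target = bulk_tanimoto(fingerprint(raw.target_smiles, kind), fps)
    kept = increasing_indices(list(to_target))
    molecules = [molecules[i] for i in kept]
    to_start = bulk_tanimoto(fingerprint(raw.start_smiles, kind),
                             [fingerprint(m, kind) for m in molecules])
    return ChemicalPath(tuple(molecules),
                        tuple(float(to_target[i]) for i in kept),
                        tuple(float(s) for s in to_start), kind)


def sample_many_paths(a: str, b: str, n_ordering_pairs: int, repeats: int,
                      seed: int = 0, kind: str = "ecfp4"
                      ) -> dict[str, dict[str, float]]:
    """Unique chemical-path molecules over ordering pairs × repeats.

    Returns a mapping canonical SMILES -> similarities to both endpoints and
    joint similarity, for every molecule encountered on any chemical path
    between the two molecules.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    orderings_a = randomize_orderings(a, n_ordering_pairs, rng)
    orderings_b = randomize_orderings(b, n_ordering_pairs, rng)
    unique: dict[str, None] = {}
    for ord_a, ord_b in zip(orderings_a, orderings_b):
        ts_a = encode(ord_a, Representation.SELFIES)
        ts_b = encode(ord_b, Representation.SELFIES)
        for _ in range(repeats):
            raw = sample_raw_path(ts_a, ts_b, rng)
            path = extract_chemical_path(raw, kind)
            for mol in path.molecules:
                if mol:
                    unique.setdefault(mol)
    fp_a = fingerprint(canonical(a), kind)
    fp_b = fingerprint(canonical(b), kind)
    out: dict[str, dict[str, float]] = {}
    mols = list(unique)
    fps = [fingerprint(m, kind) for m in mols]
    sims_a = bulk_tanimoto(fp_a, fps)
    sims_b = bulk_tanimoto(fp_b, fps)
    for mol, sa, sb in zip(mols, sims_a, sims_b):
        out[mol] = {"sim_start": float(sa), "sim_target": float(sb),
                    "joint": joint_from_sims([sa, sb])}
    return out


def has_bridgehead(smiles: str) -> bool:
    """True iff the molecule contains a bridged-bicyclic junction atom.

    Ortho-fused systems (naphthalene) have none; norbornane-like bridged
    systems do.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return rdMolDescriptors.CalcNumBridgeheadAtoms(mol) > 0


def median_search(refs: Sequence[str], n_paths: int, seed: int = 0,
                  kind: str = "ecfp4",
                  filter_bridgeheads: bool = False
                  ) -> list[MedianCandidate]:
    """Rank molecules found on generalized paths through the references.

    Each of ``n_paths`` samples shuffles the reference order, draws one
    random ordering per reference, and chains pairwise interpolations
    through the sequence, harvesting every intermediate.  Candidates are
    scored by joint similarity to the full reference set and sorted
    descending (ties broken by SMILES).
    """
    if len(refs) < 2:
        raise ValueError("median search needs at least two references")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    ref_cans = [canonical(r) for r in refs]
    unique: dict[str, None] = {}
    for _ in range(n_paths):
        order = [int(i) for i in rng.permutation(len(ref_cans))]
        orderings = [randomize_orderings(ref_cans[i], 1, rng)[0]
                     for i in order]
        encoded = [encode(o, Representation.SELFIES) for o in orderings]
        for ts_a, ts_b in zip(encoded[:-1], encoded[1:]):
            raw = sample_raw_path(ts_a, ts_b, rng)
            unique.setdefault(raw.start_smiles)
            for mol in raw.steps:
                if mol:
                    unique.setdefault(mol)
    ref_fps = [fingerprint(r, kind) for r in ref_cans]
    candidates = []
    for mol in unique:
        fp = fingerprint(mol, kind)
        sims = tuple(float(bulk_tanimoto(fp, [rf])[0]) for rf in ref_fps)
        candidates.append(MedianCandidate(
            mol, sims, joint_from_sims(sims),
            passes_bridgehead_filter=not has_bridgehead(mol)))
    if filter_bridgeheads:
        candidates = [c for c in candidates if c.passes_bridgehead_filter]
    return sorted(candidates, key=lambda c: (-c.joint, c.smiles))


#: built-in per-molecule property providers for path annotation
PROPERTY_PROVIDERS: dict[str, Callable[[Chem.Mol], float]] = {
    "logp": Descriptors.MolLogP,
    "qed": QED.qed,
}


def annotate_properties(path: ChemicalPath,
                        providers: Sequence[str | tuple[str, Callable]],
                        ) -> ChemicalPath:
    """Attach per-molecule property values (logP, QED, or user callables).

    Provider failures are recorded as NaN rather than raised, so a single
    pathological intermediate cannot abort a path annotation.
    """
    table: dict[str, tuple[float, ...]] = dict(path.properties or {})
    resolved: list[tuple[str, Callable]] = []
    for p in providers:
        if isinstance(p, str):
            if p not in PROPERTY_PROVIDERS:
                raise KeyError(f"unknown property provider {p!r}")
            resolved.append((p, PROPERTY_PROVIDERS[p]))
        else:
            resolved.append(p)
    mols = [Chem.MolFromSmiles(m) for m in path.molecules]
    for name, func in resolved:
        values = []
        for mol in mols:
            try:
                values.append(float(func(mol)))
            except Exception:
                values.append(float("nan"))
        table[name] = tuple(values)
    return dc_replace(path, properties=table)
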