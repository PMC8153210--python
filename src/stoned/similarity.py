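"""Fingerprints, Tanimoto similarity, joint similarity and property distance.

Similarity between molecules is measured on circular and atom-pair
structural fingerprints: ECFP4 (Morgan, radius 2), FCFP4 (the same with
pharmacophoric feature invariants) or atom-pair (AP) fingerprints.  The
fingerprints are sparse *count* vectors and the Tanimoto coefficient is the
count generalization sum(min)/sum(max), the convention used by the
similarity-benchmark lineage this package follows.  On top of the pairwise
Tanimoto coefficient the module defines
the *joint similarity* F(m) of a candidate against a set of reference
molecules.  The plain geometric mean of the per-reference similarities can
score a candidate highly even when it resembles only one reference; F(m)
instead penalizes dispersion among the similarities:

    F(m) = mean(delta) - (max(delta) - min(delta))

where delta_i is the Tanimoto similarity of m to reference i.  This form is
permutation invariant, reduces to delta_1 for a single reference, equals s
when all similarities are s, and for a fixed mean is maximal when the
similarities are equal.  It is isolated behind ``joint_from_sims`` so an
alternative aggregation can be swapped in without touching callers.  F may
be negative; ranking only ever uses relative order, so it is not clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "FINGERPRINT_KINDS",
    "Fingerprint",
    "SimilarityProfile",
    "fingerprint",
    "tanimoto",
    "bulk_tanimoto",
    "joint_from_sims",
    "joint_similarity",
    "geometric_mean_similarity",
    "similarity_profile",
    "minmax_bounds",
    "property_distance",
]

FINGERPRINT_KINDS = ("ecfp4", "fcfp4", "ap")

_GENERATORS: dict[str, object] = {}


def _generator(kind: str):
    if kind not in _GENERATORS:
        if kind == "ecfp4":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
        elif kind == "fcfp4":
            inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=2, atomInvariantsGenerator=inv)
        elif kind == "ap":
            gen = rdFingerprintGenerator.GetAtomPairGenerator()
        else:
            raise ValueError(f"unknown fingerprint kind {kind!r}; "
                             f"choose from {FINGERPRINT_KINDS}")
        _GENERATORS[kind] = gen
    return _GENERATORS[kind]


@dataclass(frozen=True)
class Fingerprint:
    kind: str
    bits: object  # RDKit UIntSparseIntVect (environment counts)


def fingerprint(molecule: str | Chem.Mol, kind: str = "ecfp4") -> Fingerprint:
    """Sparse count fingerprint of a molecule (SMILES or Mol)."""
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"cannot parse SMILES {molecule!r}")
    else:
        mol = molecule
    return Fingerprint(kind, _generator(kind).GetSparseCountFingerprint(mol))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between same-kind fingerprints."""
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kinds differ: {a.kind} vs {b.kind}")
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def bulk_tanimoto(ref: Fingerprint, others: Sequence[Fingerprint]) -> np.ndarray:
    """Tanimoto of one reference against many fingerprints at once."""
    for o in others:
        if o.kind != ref.kind:
            raise ValueError("fingerprint kinds differ")
    if not others:
        return np.empty(0)
    return np.asarray(DataStructs.BulkTanimotoSimilarity(
        ref.bits, [o.bits for o in others]))


def joint_from_sims(sims: Sequence[float]) -> float:
    """Aggregate per-reference similarities into the joint similarity F.

    Single swap-point for the aggregation form used everywhere else.
    """
    if len(sims) == 0:
        raise ValueError("need at least one reference similarity")
    arr = np.asarray(sims, dtype=float)
    return float(arr.mean() - (arr.max() - arr.min()))


def _sims_to_refs(molecule: str | Chem.Mol, refs: Sequence[str | Chem.Mol],
                  kind: str) -> np.ndarray:
    if len(refs) == 0:
        raise ValueError("reference set must be non-empty")
    fp = fingerprint(molecule, kind)
    return np.array([tanimoto(fp, fingerprint(r, kind)) for r in refs])


def joint_similarity(molecule: str | Chem.Mol,
                     refs: Sequence[str | Chem.Mol],
                     kind: str = "ecfp4",
                     form: Callable[[Sequence[float]], float] | None = None,
                     ) -> float:
    """Joint similarity F(m) of a molecule to a set of references."""
    sims = _sims_to_refs(molecule, refs, kind)
    return (form or joint_from_sims)(sims)


def geometric_mean_similarity(molecule: str | Chem.Mol,
                              refs: Sequence[str | Chem.Mol],
                              kind: str = "ecfp4") -> float:
    """Baseline aggregation: geometric mean of per-reference similarities."""
    sims = _sims_to_refs(molecule, refs, kind)
    return float(math.prod(sims) ** (1.0 / len(sims)))


@dataclass(frozen=True)
class SimilarityProfile:
    """A molecule's per-reference similarities and joint score."""

    molecule: str
    references: tuple[str, ...]
    sims: tuple[float, ...]
    joint: float


def similarity_profile(molecule: str, refs: Sequence[str],
                       kind: str = "ecfp4") -> SimilarityProfile:
    sims = _sims_to_refs(molecule, refs, kind)
    return SimilarityProfile(molecule, tuple(refs), tuple(float(s) for s in sims),
                             joint_from_sims(sims))


def minmax_bounds(vectors: Sequence[Sequence[float]]
                  ) -> list[tuple[float, float]]:
    """Per-dimension (min, max) over a pool of property vectors."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError("need a 2-D pool of property vectors")
    return list(zip(arr.min(axis=0).tolist(), arr.max(axis=0).tolist()))


def property_distance(props_m: Sequence[float],
                      props_refs: Sequence[Sequence[float]],
                      bounds: Sequence[tuple[float, float]]) -> float:
    """Normalized property distance of a candidate to a set of references.

    Each dimension is min–max normalized by ``bounds`` (typically from
    :func:`minmax_bounds` over the pooled references and candidates); the
    result is the mean Euclidean distance to the references in that unit
    cube.  Zero iff the candidate matches every reference after
    normalization.
    """
    m = np.asarray(props_m, dtype=float)
    refs = np.asarray(props_refs, dtype=float)
    if refs.ndim != 2 or refs.shape[1] != m.shape[0]:
        raise ValueError("dimension mismatch between candidate and references")
    b = np.asarray(bounds, dtype=float)
    if b.shape != (m.shape[0], 2):
        raise ValueError("need one (min, max) pair per dimension")
    span = b[:, 1] - b[:, 0]
    span[span == 0.0] = 1.0  # constant dimensions contribute no distance
    mn = (m - b[:, 0]) / span
    rn = (refs - b[:, 0]) / span
    return float(np.linalg.norm(rn - mn, axis=1).mean())
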