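# stoned — training-free chemical-space exploration with robust molecular strings

`stoned` implements the STONED family of algorithms: exploration and
interpolation in chemical space by **string manipulations of SELFIES**, a
molecular representation in which *every* token sequence decodes to a valid
molecule.  Because random edits can never produce an invalid structure, the
usual machinery of generative modeling — training data, learned latent
spaces, validity filters — is unnecessary: a single seed molecule and a
random-number generator are enough to build large local chemical subspaces,
interpolate deterministically between two drugs, and discover *median
molecules* that resemble several references at once.

The package is aimed at cheminformaticians and method developers who need
fast, reproducible baselines for molecule generation, library enrichment
around a lead compound, or structure interpolation for multi-objective
design.

## The algorithms

**Local subspace generation.** For a seed molecule, draw `N` random atom
orderings (each gives a different SMILES spelling and hence a different
SELFIES), and apply a cumulative chain of 1–5 *point mutations* — a single
token replacement, deletion or insertion at a random position.  With
`N = 50 000` orderings this yields 250 000 strings, all of which decode.
Unique molecules are collected by canonical SMILES and tabulated by their
Tanimoto similarity δ to the seed at thresholds δ > 0.75, 0.60, 0.40.
Restricting the mutation positions to the **terminal 10%** of the string
concentrates the output near the seed (exploitation); unrestricted
positions explore more broadly.  Fingerprints are sparse count Morgan
(ECFP4-style, radius 2), feature-typed Morgan (FCFP4) or atom-pair, with
the count-Tanimoto `Σ min / Σ max`.

**Deterministic interpolation.** Pad two SELFIES to equal length with the
inert `[nop]` token; if they differ at `t` positions, substituting the
target's tokens one position at a time produces a *raw path* of `t` valid
molecules, and there are exactly `t!` such paths.  A *chemical path* keeps
the subsequence whose similarity to the target strictly increases (the
first mutated step is exempt).  Properties (logP, QED, or any user
callable) can be annotated along the path.

**Joint similarity and median molecules.** For a candidate `m` and
references `M = {m₁ … mₙ}` with similarities `δᵢ`, the geometric mean
`(Πδᵢ)^{1/n}` can score highly while resembling only one reference.  The
package instead ranks by

    F(m) = mean(δ) − (max(δ) − min(δ))

which is permutation invariant, reduces to `δ₁` for one reference, equals
`s` when all `δᵢ = s`, and for a fixed mean is maximal when the profile is
balanced.  Median molecules are harvested from generalized (chained)
interpolation paths through the reference set and ranked by `F`; an
optional filter discards molecules with bridgehead atoms, whose generated
variants frequently violate Bredt's rule.

**Representation fragility baselines.** The same mutation protocol applied
to SMILES or DeepSMILES character strings shows why robustness matters:
only a few percent of mutated strings survive parsing, versus 100% for
SELFIES.

## The 34-token mutation alphabet

Mutations draw from the semantically robust alphabet (18 atom, 9 branch,
6 ring tokens, plus the inert pad):

```
[C] [=C] [#C] [N] [=N] [#N] [O] [=O] [S] [=S] [#S] [P] [=P] [#P]
[F] [Cl] [Br] [I]
[Branch1] [=Branch1] [#Branch1] [Branch2] [=Branch2] [#Branch2]
[Branch3] [=Branch3] [#Branch3]
[Ring1] [=Ring1] [Ring2] [=Ring2] [Ring3] [=Ring3]
[nop]
```

The SELFIES codec (encoder + decoder for this grammar subset) is part of
the package (`stoned.selfies`), as is a DeepSMILES converter
(`stoned.deepsmiles`).  Neutral organic molecules (C, N, O, S, P, F, Cl,
Br, I) are supported; charges, isotopes and stereochemistry are out of
grammar.

## Worked example

```python
from stoned import MutationSpec, generate_subspace

report = generate_subspace("Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
                           n_orderings=1000, spec=MutationSpec(),
                           representation="selfies", rng_seed=0)
print(report.n_strings_generated, report.n_unique)
print(report.threshold_table())
```

prints (seed 0):

```
5000 3708
{'0.75': {'count': 24, 'percent': 0.6472},
 '0.6':  {'count': 132, 'percent': 3.5599},
 '0.4':  {'count': 502, 'percent': 13.5383}}
```

i.e. 1 000 orderings of celecoxib produced 5 000 mutated strings, all
valid, collapsing to 3 708 distinct molecules, of which 13.5% stay within
Tanimoto 0.40 of the seed.  The `examples/` directory walks through each
capability (`01_local_subspace.py`, `02_representation_fragility.py`,
`03_chemical_path.py`, `04_median_molecules.py`); the same operations are
available from the shell via the `stoned` command
(`stoned subspace --help`).

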