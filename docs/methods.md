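# Methods

## The robust string grammar

The package's central primitive is a SELFIES codec (`stoned.selfies`)
implementing the semantically robust subset of the grammar: neutral C, N,
O, S, P and halogen atoms with single/double/triple bonds, branches and
rings.  Robustness is a property of the *derivation rules*, not of the
strings:

- an atom token's requested bond order is capped by the remaining valence
  of both atoms involved (valence caps C 4, N 3, O 2, S 6, P 5,
  halogens 1);
- a branch or ring token arriving in a state that cannot host it (no
  previous atom, or fewer than two free valences for a branch) is skipped;
- branch lengths and ring distances are read from the following 1–3 tokens
  interpreted as base-16 digits via a fixed 16-token table; missing or
  out-of-table digits read as zero;
- a chain whose current atom has no free valence terminates; remaining
  tokens at that level are discarded;
- duplicate ring bonds and self-rings are ignored;
- the pad token `[nop]` is stripped before derivation wherever it occurs.

Under these rules every token sequence derives a valence-correct graph
that the chemistry toolkit sanitizes successfully, which the test suite
asserts exhaustively (all 34 × L single-token edits of reference drugs)
and statistically (hypothesis-generated token soups, ≥10⁵ seeded
mutations).  An empty derivation decodes to the empty string; it cannot
arise from mutants of drug-sized molecules.

The encoder walks the RDKit molecule depth-first in input-SMILES atom
order (so randomized orderings give genuinely different token sequences),
kekulizes, and drops stereochemistry — the grammar encodes the flat
molecular graph.  Charged species, isotopes and radicals raise an
unsupported-feature error.  Encode→decode round trips reproduce the
canonical SMILES for every fixture molecule.

The decoder follows the modern (v2-style) derivation semantics.  The
publication-era codec differed in version-specific details (token
inventory, index tables, state handling); aggregate statistics — validity
fractions, similarity-threshold percentages — are the reproduction
surface, not token-level identity.  The consequences are quantified under
*Fidelity* below.

## Mutation protocol

A point mutation is one REPLACE, DELETE or INSERT, drawn uniformly from
the allowed ops; DELETE on a single-token string redraws the op so the
empty string never arises.  Positions come from a fractional window
`(lo, hi)`: indices `⌊lo·L⌋ … ⌈hi·L⌉−1` of an L-token string, with INSERT
additionally allowed at position L when `hi = 1.0`.  The named windows are
random `(0, 1)`, terminal 10% `(0.9, 1)`, central 10% `(0.45, 0.55)` and
initial 10% `(0, 0.1)`.  Replacement and insertion tokens come from the
34-token robust alphabet for SELFIES; for the SMILES/DeepSMILES fragility
baselines the alphabet is the character vocabulary of the generated
ordering strings themselves (the natural analogue — the paper trail does
not record the original choice).

"1–5 mutations" is implemented as the cumulative chain: each ordering
yields five strings carrying 1, 2, 3, 4, 5 mutations respectively, so
50 000 orderings produce 250 000 strings — the only arithmetic consistent
with the reference experiment's reported totals.  A uniform mode (one
string per ordering, depth drawn from 1–5) is available via
`MutationSpec(uniform_n=True)`.

Each ordering receives an independent child RNG stream spawned from the
run seed, so results are independent of how orderings are partitioned
over workers, and identical seeds give byte-identical reports.

## Similarity

Fingerprints are sparse **count** vectors: Morgan radius 2 (ECFP4-style),
Morgan with pharmacophoric feature invariants (FCFP4) and atom-pair, with
Tanimoto generalized to counts as `Σᵢ min(aᵢ,bᵢ) / Σᵢ max(aᵢ,bᵢ)`.  Count
fingerprints (rather than 2048-bit hashed ones) reproduce the reference
similarity tables; hashed bits depress the δ > 0.40 fractions by roughly
half because colliding environments are counted once.

Joint similarity uses `F(m) = mean(δ) − (max(δ) − min(δ))`, isolated
behind `joint_from_sims` so an alternative aggregation can be swapped in.
F may be negative; ranking uses relative order only, so it is not clamped.
The normalized property distance min–max-normalizes each property
dimension over a caller-supplied pool (typically references plus
candidates) and averages the Euclidean distances to the references;
constant dimensions contribute zero.

## Subspace bookkeeping

Unique molecules are keyed by canonical (RDKit, isomeric) SMILES; the
regenerated seed molecule and empty decodes are excluded.  Threshold
percentages use the number of *unique generated molecules* as denominator
(the convention that makes the reference SMILES row reach 100% at 662
molecules), not the string count.  Scaffold filtering keeps unique
molecules with a substructure match to a SMARTS query and records the
retention fraction.  Second-generation expansion reruns the pipeline on
every (optionally subsampled) first-generation molecule, measuring
similarity still against the original seed and unioning by canonical
SMILES.

## Interpolation and medians

Paths pad at the tail (early tokens dominate structure, so alignment
keeps them fixed) and substitute differing positions in a uniformly random
order.  The chemical-path filter keeps a step iff its similarity to the
target strictly exceeds the last kept step's; strictness guarantees
termination without duplicate plateaus; the first mutated step is exempt
to avoid holes at the start.  Generalized paths through n ≥ 3 references
are chained pairwise interpolations over a seeded random reference order,
behind a small interface so a different construction can replace it.
Bridgehead detection delegates to the toolkit's ring analysis
(`CalcNumBridgeheadAtoms`), which distinguishes bridged from ortho-fused
systems.  Property annotation ships logP and QED providers; user callables
plug in by name, and provider failures record NaN rather than aborting.

## Problem sizes

The full-scale experiments use 50 000 orderings × 5 mutations (250 000
strings) per experiment, matching the reference protocol; a full
acceptance run (`scripts/acceptance.py`) completes in roughly 10–15
minutes on one CPU.  The test suite runs the same pipelines at 5 000
orderings (25 000 strings) per experiment — large enough that binomial
sampling error on the reported percentages is a few hundredths of a point —
plus toy-molecule unit tests.  Threshold percentages drift slowly with
scale (the close-in mutant space saturates before the far space), so
desk-scale and full-scale values differ by design, not noise; full-scale
numbers are the ones to compare against the reference tables.

## Fidelity and known limitations

- **Similarity tables.** At full scale this implementation reproduces the
  reference δ > 0.40 percentages for celecoxib within ~2 points for the
  random (7.5 vs 9.44), central (9.7 vs 11.45) and initial (47.2 vs 49.74)
  windows, and reproduces the table's qualitative percent ordering
  terminal > initial > central > random exactly.  The terminal window
  (71.2 vs 79.91) and aripiprazole (12.5 vs 17.66) fall short by more: the
  close-mutant space of a codec depends on its exact token inventory and
  encoding length, and this grammar's encodings are more compact than the
  publication-era codec's, so the close space saturates earlier.
- **Fragility baselines.** The SMILES/DeepSMILES validity percentages
  depend on protocol details (mutation alphabet, op mix, per-string
  mutation count) that are not recorded in the reference description.
  Under this package's protocol — the same chain protocol as SELFIES, with
  the molecule's own character vocabulary — mutated celecoxib SMILES are
  ~4.6% valid and DeepSMILES ~2.8%, versus the reference 0.30% and 1.44%.
  The qualitative conclusion (robust grammar 100%, character
  representations single-digit percent) is insensitive to these choices;
  the exact percentages and the SMILES/DeepSMILES ordering are not:
  DeepSMILES is *more* fragile than SMILES to insertions here, because an
  atom inserted inside a branch shifts the close-paren pop count and
  scrambles all downstream attachments, whereas SMILES's paired
  parentheses localize the damage.
- **Stereochemistry and charges** are outside the grammar; fixtures are
  stored as achiral, neutral structures.  Count-Morgan similarity ignores
  chirality, so this does not affect the similarity statistics.
- Generated structures are valence-correct but not curated: unstable
  moieties and improbable tautomers appear, as expected for a rules-free
  generator; domain filters (like the bridgehead filter) are the intended
  remedy and can be plugged into the property-provider interface.
- The synthetic fixture set covers drug-like organics; what passing tests
  show is grammar robustness and pipeline correctness on such molecules,
  not performance on organometallics, charged species or macromolecules,
  which the grammar does not admit.
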