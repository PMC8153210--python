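"""Interpolate deterministically between tadalafil and sildenafil.

Aligns the two SELFIES, substitutes differing tokens one at a time in a
random order (every intermediate is a valid molecule), then extracts the
chemical path: the subsequence whose similarity to the target strictly
increases.  logP and QED are annotated along the way.
"""

from stoned.mutate import Representation, encode
from stoned.fixtures import DRUGS
from stoned.pathing import (annotate_properties, count_paths,
                            extract_chemical_path, sample_raw_path)

start = encode(DRUGS["tadalafil"], Representation.SELFIES)
target = encode(DRUGS["sildenafil"], Representation.SELFIES)

raw = sample_raw_path(start, target, seed=7)
t = len(raw.mutated_position_order)
print(f"{t} token positions differ -> {t}! = {count_paths(t):.3e} possible "
      f"raw paths of length {t}")

path = annotate_properties(extract_chemical_path(raw), ["logp", "qed"])
print(f"chemical path: {len(path.molecules)} molecules with strictly "
      f"increasing similarity to the target\n")
print(f"{'sim->target':>11s} {'logP':>6s} {'QED':>5s}  molecule")
for smi, sim, logp, qed in zip(path.molecules, path.sims_to_target,
                               path.properties["logp"],
                               path.properties["qed"]):
    print(f"{sim:11.3f} {logp:6.2f} {qed:5.2f}  {smi}")
print("\nIntermediates blend features of both endpoint drugs; property"
      "\nvalues drift smoothly because structural similarity does.")
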