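"""Generate the local chemical subspace of celecoxib.

Enumerates random atom orderings of the seed, mutates each ordering's
SELFIES 1-5 times, and tabulates how many distinct molecules fall within
ECFP4 similarity thresholds of the seed.  A scaled-down version of the
reference experiment (which uses 50 000 orderings).
"""

from stoned.fixtures import DRUGS, CELECOXIB_SCAFFOLD
from stoned.mutate import MutationSpec
from stoned.subspace import generate_subspace, scaffold_filter

report = generate_subspace(DRUGS["celecoxib"], n_orderings=1000,
                           spec=MutationSpec(), representation="selfies",
                           rng_seed=0)
print(f"strings generated : {report.n_strings_generated}")
print(f"valid decodes     : {report.n_valid} "
      f"({report.validity_percent:.1f}% — SELFIES never fails)")
print(f"unique molecules  : {report.n_unique}")
for threshold, row in report.threshold_table().items():
    print(f"  similarity > {threshold}: {row['count']:6d} "
          f"({row['percent']:.2f}% of unique molecules)")

# restricting mutations to the last 10% of token positions trades
# exploration for exploitation: far more neighbours stay close to the seed
terminal = generate_subspace(DRUGS["celecoxib"], n_orderings=1000,
                             spec=MutationSpec(position_window=(0.9, 1.0)),
                             rng_seed=0)
print(f"\nterminal-10% window: {terminal.threshold_percent(0.40):.1f}% of "
      f"unique molecules stay within similarity 0.40 "
      f"(vs {report.threshold_percent(0.40):.1f}% for random positions)")

kept = scaffold_filter(report, CELECOXIB_SCAFFOLD)
print(f"\nscaffold constraint: {100 * (kept.scaffold_retention or 0):.1f}% "
      f"of unique molecules retain the diarylpyrazole core")
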