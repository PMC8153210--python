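"""Find median molecules between tadalafil and sildenafil.

Harvests all molecules from generalized interpolation paths and ranks them
by joint similarity F(m) = mean(sims) - (max - min), which penalizes
candidates that resemble only one reference.  The geometric mean is shown
for comparison: it happily rewards one-sided similarity.
"""

from stoned.fixtures import DRUGS
from stoned.pathing import median_search
from stoned.similarity import geometric_mean_similarity, joint_similarity

refs = [DRUGS["tadalafil"], DRUGS["sildenafil"]]
candidates = median_search(refs, n_paths=20, seed=3,
                           filter_bridgeheads=True)

print("top 5 median candidates (bridgehead-free):")
print(f"{'joint F':>8s} {'geo-mean':>9s} {'sim_tad':>8s} {'sim_sil':>8s}"
      f"  molecule")
for c in candidates[:5]:
    geo = geometric_mean_similarity(c.smiles, refs)
    print(f"{c.joint:8.3f} {geo:9.3f} {c.sims[0]:8.3f} {c.sims[1]:8.3f}"
          f"  {c.smiles}")

print(f"\nfor comparison, tadalafil itself scores joint "
      f"F = {joint_similarity(refs[0], refs):.3f}: a reference molecule is"
      f"\nmaximally lopsided (similarity 1 to itself, low to the other), so"
      f"\nbalanced in-between structures outrank it.")
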