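"""Exhaustion-trajectory scoring and signature reversal (middle tier).

For the planted middle-immune sample: score the four exhaustion
trajectories by end/start cell counts, extract differential signatures for
the ones that exist, and rank drugs by how strongly their perturbation
signatures reverse each trajectory (1.0 = perfect reversal after the
[0, 1] rescaling; 0.5 = unrelated).
"""

import warnings

import numpy as np

import combosc as csc

warnings.filterwarnings("ignore")

bundle = csc.default_fixture(seed=1)
matrix = csc.normalize_log2_tpm(bundle.matrix)
s2 = bundle.meta[bundle.meta["sample_id"] == "S2"]
sub = matrix.subset_cells(s2["cell_id"].to_numpy(dtype=object))

results = csc.analyze_trajectories(sub, s2)
for r in results:
    score = "NA" if not r.exists else f"{r.score:.3f}"
    n_degs = "-" if r.degs is None else str(len(r.degs))
    print(f"{r.name}: score {score} (start {r.n_start}, end {r.n_end}), "
          f"{n_degs} signature genes")

W = csc.trajectory_drug_matrix(results, bundle.library)
print("\nReversal scores (drugs x trajectories, on [0, 1]):")
print(W.round(3).to_string())
print("\nTop reverser per trajectory:",
      {c: W[c].idxmax() for c in W.columns})

live = [r for r in results if r.exists]
problem = csc.from_response_matrix(
    W, t=np.array([r.n_end for r in live], dtype=float),
    side_effects=bundle.side_effects,
)
solution = csc.solve(problem)
print(f"\nDrugs to pair with checkpoint blockade: "
      f"{' + '.join(solution.selected)} (J = {solution.J:.3f})")
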