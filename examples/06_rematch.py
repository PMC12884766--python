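"""Refine cross-session registration with the re-matching score.

Builds synthetic registration index maps with a planted error, then runs
the greedy registered-score optimization, which recovers the true
assignment from a supplementary reference map.
"""

import numpy as np

from sferlab.rematch import (build_candidates, greedy_optimize,
                             synthetic_index_maps)

fx = synthetic_index_maps(n_neurons=12, n_sessions=13, n_references=5,
                          detect_prob=1.0, rng=np.random.default_rng(3))
maps, lik, truth = fx["maps"], fx["likelihood"], fx["truth"]

neuron = 4
maps[0].indices[6, neuron] = 9   # plant a registration error in the main map
cand = build_candidates(maps, 0, neuron, lik)
sol = greedy_optimize(cand, lik)

print(f"neuron {neuron}: registered score {sol.initial_score:.3f} -> "
      f"{sol.score:.3f} in {sol.iterations} sweep(s)")
print(f"proposed changes at sessions: {list(sol.changed_sessions)}")
print(f"recovered truth: {bool(np.array_equal(sol.J, truth[:, neuron]))}")
print("\nThe score balances pairwise same-cell likelihood against the")
print("number of detected sessions; the planted error is replaced by the")
print("candidate from a supplementary reference map and flagged for review.")
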