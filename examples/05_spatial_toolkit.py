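"""Rate maps, place-cell tests, field identification and decoding.

Builds a synthetic session with planted Gaussian place fields, computes
an event-rate map with wall-aware smoothing, runs the three shuffle
tests, identifies fields, and decodes position with the distance-loss
naive Bayes classifier.
"""

import numpy as np

from sferlab.spatial import (bayes_decode, compute_rate_map, identify_fields,
                             place_cell_tests, spatial_information,
                             synthetic_scene, within_session_stability)

scene = synthetic_scene(n_cells=30, n_frames=12000, n_bins=24,
                        rng=np.random.default_rng(7))

m = compute_rate_map(scene, 0)
si = spatial_information(m)
tests = place_cell_tests(scene, 0, n_shuffles=200, seed=0)
print(f"cell 0: SI = {si:.2f} bits/event, place-cell tests "
      f"{'passed' if tests['passed'] else 'failed'}")

fields = identify_fields(m)
n = scene.n_bins
truth = scene.truth["centers_cm"][0, 0]
print(f"planted field center: ({truth[0]:.0f}, {truth[1]:.0f}) cm")
for f in fields:
    print(f"  found field: center ({f.center_bin % n * 2 + 1}, "
          f"{f.center_bin // n * 2 + 1}) cm, peak {f.peak_rate:.2f} Hz, "
          f"{len(f.bins)} bins")

stab = within_session_stability(scene, 0)
print(f"within-session stability (half vs half): r = {stab:.2f}")

dec = bayes_decode(scene)
print(f"decoding median absolute error: {dec['median_error_cm']:.1f} cm")
print("\nA strongly tuned cell passes all three shuffle tests and its field")
print("is recovered near the planted center; decoding error shrinks as the")
print("population grows (chance level is ~25 cm on this 48 cm arena).")
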