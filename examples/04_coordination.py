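"""Sibling-field coordination under interaction mechanisms.

Simulates population cohorts with and without the two interaction
mechanisms -- Gamma-Poisson satiety assignment of new fields and
neuron-level day-to-day fluctuations -- and prints the diagonal
residuals (observed minus chance co-occurrence) of disappearance,
formation and retention events among sibling pairs.
"""

import numpy as np

from sferlab.config import GeneratorConfig
from sferlab.coordination import simulate_interacting_sfer

for label, toggles in [("pure rule (no interactions)", ()),
                       ("satiety assignment only", ("assignment",)),
                       ("fluctuations only", ("fluctuations",)),
                       ("both mechanisms", ("assignment", "fluctuations"))]:
    cfg = GeneratorConfig(seed=11, n_neurons=300, n_sessions=20)
    out = simulate_interacting_sfer(cfg, toggles=toggles)
    d = out["residuals"]["sibling_diagonal"]
    print(f"{label:30s} disappearance {d[0]:+.4f}  formation {d[1]:+.4f}  "
          f"retention {d[2]:+.4f}")
print("\nPositive diagonal residuals mean sibling fields undergo the same")
print("event together more often than chance: assignment synchronizes")
print("formation; shared fluctuations synchronize disappearance and")
print("retention; the pure rule shows neither.")
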