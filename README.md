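# sferlab

Tools for studying **representational drift of hippocampal place fields
one field at a time**. Chronic calcium imaging can follow the same place
fields across weeks of recordings; each registered field then yields a
binary *field-state sequence* — active (1) or inactive (0) per session,
starting with 1 at formation. `sferlab` implements the single-field
evolution analysis over such sequences, for systems neuroscientists and
modelers who want to quantify, model and simulate how individual fields
persist, vanish and recover.

At its core sit two complementary descriptions of history dependence:

* **duration hazards** — the retention probability grows with the
  retained duration, `r(t_a) = 1 − L1/(t_a + b1)`, while the recovery
  probability decays with the silent duration as a stretched
  exponential, `q(t_i) = a·exp(−(t_i/b)^c)`;
* **the recursive evolution rule** — each field carries a latent
  re-expression probability updated by opposing link functions,

      P_t = s_{t−1}·f(P_{t−1}) + (1 − s_{t−1})·g(P_{t−1}),

  with `f` above and `g` below the diagonal. Their stable fixed points
  act as competing attractors, splitting fields into super-stable and
  almost-drifted pools (dual-fate dynamics).

The package covers the full pipeline: synthetic cohort generation
(Gamma–Poisson field allocation, calibrated hazards, neuron-level
fluctuations, censoring), sequence preparation and registration, hazard
estimation and parametric fits, ten sequence-model families (equal-rate,
state-conditioned, duration hazards, HMM with a fixed emission ladder, a
recursive rule with four link families, a GRU, and four logistic
regressions) compared under a common NLL cross-validation protocol, a
stochastic discrete dynamical-system simulator with a silence gate,
inter-field coordination statistics (chi-square, residual matrices,
satiety-based field assignment), a place-field spatial toolkit (rate
maps, spatial information, shuffle tests, field identification,
distance-loss Bayes decoding), and a registration re-matching optimizer.

## Worked example

Estimate both hazard curves from a calibrated synthetic cohort and fit
their parametric forms (`examples/01_hazard_curves.py`):

```python
from sferlab import GeneratorConfig, generate_state_sequences, prepare_sequences
from sferlab.hazards import (retention_probability, recovery_probability,
                             fit_retention_reciprocal, fit_recovery_kww)

cfg = GeneratorConfig(seed=7)                      # 26 sessions, calibrated curves
cohort = generate_state_sequences(cfg, 5000, mode="hazard")
sequences = prepare_sequences(cohort.activity)

ret = retention_probability(sequences, max_duration=8)
rec = recovery_probability(sequences, max_duration=8)
print(ret.prob_at(1), ret.prob_at(8))   # 0.532 0.892
print(rec.prob_at(1), rec.prob_at(8))   # 0.291 0.033
print(fit_retention_reciprocal(ret))    # ReciprocalFit(L1=0.959, b1=1.062, ...)
print(fit_recovery_kww(rec))            # KWWFit(a=0.493, b=2.301, c=0.750, ...)
```

A field retained one session has a ~53% chance of staying active, rising
to ~89% after eight consecutive sessions; a field silent one session
recovers with ~29% probability, collapsing to ~3% after eight. The
fitted curves recover the generator's calibration (retention pinned at
0.525/0.898, recovery at 0.297/0.035).

Comparing model families on the same kind of data
(`examples/02_model_comparison.py`) prints mean test NLL at step 12:

```
VI  equal rate                 0.6437
I   state-dependent rates      0.3511
II  duration hazards           0.3231
IV  recursive rule (linear)    0.3177
III HMM (10 states)            0.3225
```

History-aware families (II–IV) beat the state-only model, which beats
the unconditional one — the model-comparison signature of
history-dependent single-field evolution. The other examples cover the
drift simulator (`03`), sibling-field coordination (`04`), the spatial
toolkit (`05`) and registration re-matching (`06`).

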