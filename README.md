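# actinf — deep temporal active inference

`actinf` simulates perception, saccadic behaviour and electrophysiology in
agents that read with **hierarchical (deep temporal) active inference**. It is
aimed at computational neuroscientists who want a small, fully inspectable
implementation of discrete-state active inference — categorical generative
models, variational belief updating, expected-free-energy policy selection —
with the two-level temporal nesting that lets a single higher-level transition
(a word) span a whole lower-level sequence (the saccades that read it), and
with simulated rasters, local field potentials and classical violation
responses (MMN-like and P300-like difference waveforms) read directly off the
belief dynamics.

## The model

A generative model at hierarchical level *i* is specified by four parameter
families over categorical states and outcomes:

- **A**⁽ⁱ'ᵐ⁾ — likelihood tensors mapping every combination of hidden-state
  factors to outcomes of modality *m*;
- **B**⁽ⁱ'ⁿ⁾(u) — transition matrices for hidden factor *n* under control u;
- **C**⁽ⁱ'ᵐ⁾ — log prior preferences over outcomes (nats);
- **D**⁽ⁱ'ⁿ⁾ — initial-state priors; below the top level these condition on
  the higher level's hidden states, which is what nests the timescales.

Perception minimises variational free energy F by a gradient flow on
log-expectations ("depolarisations") v, with firing rates s = softmax(v)
driven by state prediction errors (likelihood, forward and backward
messages minus the current log-expectation). Action minimises **expected**
free energy

G(π, τ) = risk + ambiguity = −(epistemic value + pragmatic value),

so behaviour is epistemic (information-seeking) until uncertainty is resolved,
then preference-driven; the policy posterior is softmax(−G) and beliefs are
combined across policies by Bayesian model averaging. One belief epoch is 16
gradient iterations at 16 ms per iteration, i.e. 256 ms per saccade — the
timescale that turns belief updates into simulated electrophysiology.

The bundled **reading model** has six candidate 4-word sentences (words ∈
{flee, feed, wait}, each a 2×2 arrangement of bird/cat/seed icons subject to
vertical and horizontal flips) at level 2, and the current word, fixated
quadrant and flips at level 1. The subject forages letters by saccades,
terminates a word when the posterior word entropy falls below 1/512 nats, and
reports the narrative *happy* or *sad* (wrong feedback carries a −4 nat
preference, i.e. exp(4) ≈ 54× less likely a priori).

## Worked example

```bash
actinf read --seed 0 --out out/
```

prints the behavioural summary of the exemplar trial (sentence 1, all lower
case except the flipped second word):

```json
{
  "saccades_per_word": [1, 2, 2, 2],
  "word_transitions": 4,
  "decision": "report happy",
  "feedback": "right",
  "undecided": false,
  "epochs": 13,
  "total_iterations": 208,
  "total_ms": 3328.0,
  "epoch_ms": 256.0
}
```

Reading this: the first word is identified from a single fixation (a cat in
quadrant 1 can only be *flee* in lower case), each remaining word needs two
saccades, and after the fourth word the subject commits to *happy* and is told
it is right. The trial spans 13 belief epochs ≈ 3.3 s of simulated time.
`actinf violate --out out/` replays the same stimuli and actions under
manipulated priors (vertical-flip prior reversed for the last word; first
sentence 8× less probable; both) and writes the filtered difference waveforms
and a latency table. `actinf validate` checks the engine against an exact
enumeration oracle on random micro-models, and `actinf sample-fixtures`
forward-samples trials from the generative process.

The same functionality is available as a library:

```python
from actinf import ReadingConfig, reading_trial, trial_summary
rec = reading_trial(ReadingConfig(), seed=0)
print(trial_summary(rec)["saccades_per_word"])   # [1, 2, 2, 2]
```

## Layout

- `actinf.model` — model containers, validation, projection, forward sampling,
  YAML round-trip
- `actinf.engine` — prediction errors, free energies, softmax policy
  posterior, Bayesian model averages, iteration traces
- `actinf.scheduler` — descending empirical priors, ascending probabilistic
  evidence, entropy-based termination, asynchronous two-level trials, replay
- `actinf.reading` — word layouts, sentence inventory, model builder,
  violation manipulations
- `actinf.electrophysiology` — rasters, band-passed LFPs, difference
  waveforms, latency measures
- `actinf.experiments` / `actinf.cli` — scripted experiments, manifests, CLI

See `docs/methods.md` for the modelling choices and their rationale.
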