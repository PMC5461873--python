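# Methods

This note documents the model, the numerical scheme, the parameters that
matter, and the design choices made where more than one reasonable
implementation exists. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Generative model and inference scheme

Each hierarchical level is a categorical hidden-Markov generative model with
factorised hidden states: likelihood tensors **A** (one per outcome modality,
one axis per hidden factor), action-conditioned transition matrices **B** (one
family per factor; columns are next-state distributions), log outcome
preferences **C** (nats; zero everywhere means indifference), and initial
state priors **D**. Below the top level, **D** links condition on higher-level
hidden states: a single higher-level transition then spans an entire
lower-level sequence, which is what gives the model its nested timescales.

Perception is a gradient flow on variational free energy. For each policy π,
time τ and factor n, the state prediction error is

ε = (likelihood messages) + mean(forward, backward message) − ln s,

where the likelihood message for a factor is the generalised dot product of
the **A** tensor with the observed outcome vector and the other factors'
current expectations, taken through a log; the forward message is
ln(B·s<sub>τ−1</sub>) (the empirical prior ln D at τ = 0) and the backward
message ln(Bᵀ·s<sub>τ+1</sub>). The depolarisation update is v ← v + κ·ε and
the expectation is s = softmax(v). Two details deserve flagging:

- **Temporal messages are averaged, not summed.** When both neighbours exist
  the forward and backward messages enter at half weight (a lone boundary
  message enters fully). With full weights, a chain of identical slices (a
  static factor such as the sentence, whose **B** is the identity) reinforces
  itself each iteration and any prior gap grows geometrically — an eightfold
  prior disadvantage collapses to an exact zero, destroying the
  global-violation phenomenology. The averaged form is the standard marginal
  message passing convention and keeps static-chain posteriors bounded.
- **Prediction errors are mean-centred.** A constant shift is annihilated by
  the softmax, so the error is reported relative to its mean; "zero error"
  then coincides exactly with the variational fixed point. The free energy
  itself, F(π) = Σ s·(ln s − messages), uses the uncentred quantities; at
  convergence on a single-policy static model, −F is the log evidence (the
  test suite checks F → −ln 0.55 on a worked 2-state example).

Within an epoch v is reset to the log empirical prior (forward-propagated
through **B** for later slices); the information in earlier outcomes re-enters
through the likelihood messages during the descent. These resets are what
produce the perisaccadic transients in the simulated electrophysiology, so
the first of the 16 recorded iteration snapshots is the reset state itself
(the transient includes its starting point).

## Policy evaluation

The expected free energy of a one-step policy decomposes per future epoch as
G = risk + ambiguity = −(epistemic + pragmatic): risk is −H(o) − o·C for the
predicted outcome distribution o, ambiguity is the belief-weighted outcome
entropy of **A**, epistemic value is the mutual information between states
and outcomes (hence non-negative), and pragmatic value is o·C. The policy
posterior is softmax(−G); the variational free energy of past outcomes may be
added (softmax(−F − G)) but is off by default because one-step policies share
their past. Actions are selected by deterministic argmax with ties resolved
to the lowest policy index; a seeded sampling mode is not needed for any of
the bundled experiments.

**Predictive distributions for G come from the exact joint filter, not from
the product of mean-field marginals.** The levels here are small (≤ 72 state
combinations), so the factored prior can be filtered exactly through the
observed outcomes and the per-factor transitions. This choice is load-bearing
twice over. First, a product of marginals leaks probability onto refuted
state combinations whenever factors are correlated (word × flips): the leak
assigns positive "information gain" to re-fixating a quadrant whose letter is
already known, and the agent stares at quadrant 1 instead of foraging. Under
the joint filter, re-observation of a deterministic outcome carries exactly
zero epistemic value and fresh, discriminating quadrants are strictly
preferred. Second, the same leak let the mean-field average explain each
letter observation with a *different* flip setting, occasionally ascending a
confidently wrong word to the sentence level; the evidence passed between
levels and the termination entropy therefore also read the joint filter's
marginals. The mean-field dynamics remain untouched — they are the process
theory that generates the rasters and LFPs — but the quantities routed
between levels and into policy evaluation are computed exactly.

A deliberate consequence: every probability carries the package-wide
log-floor exp(−16), so "certain" beliefs retain a ~10⁻⁷ residual. That
residual is what makes reporting strictly preferable to reading on once the
narrative is resolved — with exactly-delta beliefs the expected free energies
of "report" and "continue" tie — and it implements the task's implicit
confidence criterion: the feedback's information gain r·ln(1/r) exceeds the
risk 4r of being wrong exactly when the subjective error probability r is
small enough.

## Scheduling

The two levels never iterate simultaneously. Each top-level step runs one
16-iteration epoch on the outcomes available so far (head-position
proprioception, feedback, and word evidence ascended from *earlier* steps),
selects an action, and — while undecided and fixating an unread word —
suspends while the lower level runs saccade epochs to termination; the
lower level's word posterior is consumed at the *next* top-level epoch.
Lower-level sequences terminate when the posterior word entropy reaches
1/512 nats (default, configurable) or after at most 4 saccades; the
exemplar trial then comprises 6 top-level epochs (4 word steps, a decision
step, a feedback step) interleaved with 7 saccade epochs: 13 × 256 ms =
3.328 s of simulated time.

Violation replays force-feed the standard trial's recorded stimuli and
actions (letters, saccades, word transitions, the report) while beliefs
evolve freely under manipulated priors: *local* reverses the vertical-flip
prior for the last word only (the flip link conditions on word position),
*global* divides the first sentence's prior by 8 and renormalises, *both*
applies both.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| iterations per epoch | 16 | – | with 16 ms per iteration, one epoch = 256 ms, the saccadic interval |
| ms per iteration | 16 | ms | maps belief iterations onto neuronal time |
| gradient step κ | 0.25 | – | calibrated so converged posteriors match exact enumeration within 10⁻² at 16 iterations (residual 0.75¹⁶ ≈ 1%) |
| termination threshold | 1/512 | nats | uncertainty about the prescribed state at which a sequence stops |
| wrong-feedback preference | −4 | nats | being wrong is exp(4) ≈ 54× less likely a priori than neutral feedback |
| P(no vertical flip) | 7/8 | – | strong lower-case expectation; horizontal flips are uniform (meaning-invariant) |
| global violation factor | 8 | – | prior odds against the inferred sentence |
| LFP band | 4–32 | Hz | canonical theta-to-low-gamma band for the simulated field potentials |
| log floor | exp(−16) | – | bounds prediction errors for impossible states; supplies the residual uncertainty above |

## Sentence inventory

Only the first sentence is fixed by the task ("flee wait feed wait", happy).
The other five were designed so that the exemplar saccade narrative is
produced by inference rather than scripted: some flee-initial sentence
continues with *flee* (word 2 is genuinely uncertain after word 1), some
"flee wait" sentence continues with *wait* (word 3 is uncertain), sentence 4
shares its first three words with sentence 1 and ends *flee* (the 1-vs-4
ambiguity survives to the last word), happy and sad narratives are balanced
3/3, and every partial reading whose surviving candidates agree in category
has a *single* surviving candidate — so the subject can never be sure of the
answer while unsure of the sentence, which is what the epistemic-sufficiency
test checks on sampled trials.

The exemplar stimulus presents word 2 with both flips: the vertical flip is
the "upper case" surprise; the horizontal flip (case- and meaning-invariant)
is required for its letters to occupy the quadrants the saccade narrative
visits. All other words are canonical lower case.

## Simulated electrophysiology

Rasters are the Bayesian model averages of the initial-state expectations
(three word units at level 1, six sentence units at level 2), one column per
16 ms iteration, held during the other level's epochs (sustained,
delay-period-like activity). LFPs are these firing rates linearly upsampled
4× to a 4 ms grid — the 16 ms sampling puts the Nyquist frequency (31.25 Hz)
just below the 32 Hz band edge — and band-passed 4–32 Hz with a zero-phase
second-order Butterworth filter. The perisaccadic analysis aligns to the
onset of the last pre-decision saccade epoch, extracts the segment from that
onset *before* filtering (filtering across the suspension boundary smears
the held-value-to-reset discontinuity into the first ~50 ms of the window,
where it outranks every genuine within-epoch deflection), and measures
extremum latencies over a 0–400 ms window (0–150 ms for the early
component), taking the largest-magnitude deflection across units. Difference
waveforms subtract the standard condition per unit; the interaction is the
difference of difference waveforms, (both − global) − (local − standard).

With these settings (`scripts/acceptance.py`) the early deflection of the
standard first-level response falls at 96 ms and the largest deflection of
the local-violation difference waveform also falls at 96 ms; empirical
mismatch responses peak later (~170 ms) than this scheme's dominant lobe.
The deflection timing is set by the belief-convergence time constant, i.e.
by κ jointly with the iteration count; slowing the descent moves the
dominant lobe later but breaks the enumeration-oracle calibration above,
and the two constraints cannot be satisfied simultaneously. κ keeps its
oracle-calibrated value.

## What the generator does and does not emulate

The forward sampler and the trial process draw states and outcomes from the
same tensors the agent inverts, so the agent is exactly well-specified:
passing tests show that the *scheme* behaves as claimed under its own model,
not that real readers do. Letters are noiseless one-hot symbols (no visual
crowding, acuity fall-off or identification noise); saccades are instant and
always land where intended; words and sentences have no shared orthography,
morphology or grammar; and the trial inventory is six sentences, so
"semantic" context is a six-way categorical variable. The simulated LFPs are
unit activities in arbitrary units — no volume conduction, lead fields or
measurement noise — so comparisons with ERP components are structural
(latencies, orderings, protractedness), not amplitudes in microvolts.

## Known limitations

- Mean-field marginals still drive the displayed dynamics; on flip-heavy
  stimuli they can transiently favour state combinations the joint filter has
  refuted (visible as extra excursions in the traces, not in behaviour).
- The exact joint filter is enumerable only because levels are small; models
  with many factors would need a structured approximation for policy
  evaluation.
- Asynchronous scheduling only; a synchronous variant (levels co-iterating)
  is out of scope.
- No learning of **A**/**B**/**D** parameters, no habits, no precision
  modulation of the policy posterior.
- The local violation leaves the ascended word evidence unchanged (the word
  is still read correctly), so its difference waveform is confined to the
  first level by construction; contextual (global) violations are what reach
  the sentence level.
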