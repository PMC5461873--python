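"""Asynchronous scheduling of belief updates across hierarchical levels.

One higher-level transition spans an entire lower-level sequence: the
higher level descends empirical priors for the lower level's initial
states, suspends while the lower level runs its epochs to termination
(posterior uncertainty about the prescribed factor below a threshold, in
nats), receives the converged posterior back as a probabilistic outcome,
and only then updates its own beliefs and selects the next action.  The
two levels therefore never iterate at the same time, and the global
timeline is a strict interleaving of 16-iteration epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._math import entropy_nats, normalize, one_hot
from .engine import (BeliefState, IterationTrace, init_beliefs,
                     select_action, update_epoch)
from .model import DeepModel, InitialLink, LevelModel, LinkMap

__all__ = [
    "TerminationRule",
    "TrialStimuli",
    "EpochRecord",
    "LevelRunResult",
    "TrialRecord",
    "GenerativeProcess",
    "descend_priors",
    "ascend_evidence",
    "check_termination",
    "run_level",
    "run_trial",
]

#: default uncertainty threshold for terminating a lower-level sequence
DEFAULT_THRESHOLD_NATS = 1.0 / 512.0


@dataclass
class TerminationRule:
    """Terminate a sequence when the Shannon entropy (nats) of the
    monitored factor's Bayesian-model-average posterior falls to the
    threshold or below."""

    threshold_nats: float = DEFAULT_THRESHOLD_NATS
    target_factor: int = 0

    def __post_init__(self):
        if not self.threshold_nats > 0:
            raise ValueError("threshold_nats must be positive")


@dataclass
class TrialStimuli:
    """Fixed true states for a trial; unspecified factors are sampled
    from the generative model's priors."""

    top_states: dict = field(default_factory=dict)
    lower_states: list = field(default_factory=list)   # per top step: {factor: state}

    def lower_for_step(self, t: int) -> dict:
        return self.lower_states[t] if t < len(self.lower_states) else {}


@dataclass
class EpochRecord:
    level_id: int
    label: str
    start_iter: int
    n_iter: int
    start_ms: float


@dataclass
class LevelRunResult:
    beliefs: BeliefState
    actions: list
    fixations: list          # initial state of the controlled factor, then actions
    outcomes: list           # per epoch: per-modality outcome vectors
    traces: list
    terminated: bool
    n_epochs: int


@dataclass
class TrialRecord:
    """Everything a simulated trial produced, iteration-resolved."""

    seed: int
    stimuli: TrialStimuli
    epochs: List[EpochRecord]
    traces: List[IterationTrace]
    top_actions: list
    top_observed: list
    top_beliefs: BeliefState
    lower_runs: list                    # (top step, LevelRunResult)
    saccade_log: list
    decision: Optional[int]
    decision_time: Optional[int]
    feedback: Optional[int]
    undecided: bool
    ms_per_iteration: float
    total_iterations: int

    @property
    def total_ms(self) -> float:
        return self.total_iterations * self.ms_per_iteration


def descend_priors(higher_bma: Sequence[np.ndarray],
                   links: Sequence[InitialLink]) -> List[np.ndarray]:
    """Empirical priors for a lower level's initial states: each
    conditional D link contracted with the higher level's Bayesian model
    averages over its parent factors."""
    priors = []
    for d in links:
        if not d.parent_factors:
            priors.append(np.asarray(d.table, dtype=float).copy())
            continue
        out = np.asarray(d.table, dtype=float)
        for ax_offset, pf in enumerate(d.parent_factors):
            b = np.asarray(higher_bma[pf], dtype=float)
            if out.shape[1] != len(b):
                raise ValueError(
                    f"link for factor {d.factor}: parent factor {pf} has "
                    f"{len(b)} states, table expects {out.shape[1]}"
                )
            out = np.tensordot(out, b, axes=(1, 0))
        priors.append(normalize(out))
    return priors


def ascend_evidence(lower_beliefs: BeliefState, link: LinkMap) -> np.ndarray:
    """Probabilistic outcome for the higher level: the lower level's
    posterior over the linked factor's (static) initial state.

    The exact joint-filter marginal is preferred when available (see the
    engine's ``exact_marginals``): a product of mean-field marginals can
    explain each outcome with a different spatial-transformation setting
    and thereby ascend a confidently wrong word.  Falls back to the
    Bayesian model average at the initial time."""
    if lower_beliefs.n_observed == 0:
        raise RuntimeError("lower level has not processed any outcome yet")
    if lower_beliefs.exact_marginals is not None:
        return normalize(lower_beliefs.exact_marginals[link.evidence_factor].copy())
    return normalize(lower_beliefs.s_bar[link.evidence_factor][0].copy())


def check_termination(beliefs: BeliefState, rule: TerminationRule) -> bool:
    """True when the monitored factor's posterior entropy is at or below
    the threshold (exact joint-filter marginal when available, else the
    most recent Bayesian model average)."""
    if beliefs.exact_marginals is not None:
        post = beliefs.exact_marginals[rule.target_factor]
    else:
        tau = max(beliefs.n_observed - 1, 0)
        post = beliefs.s_bar[rule.target_factor][tau]
    return entropy_nats(normalize(post)) <= rule.threshold_nats


# ---------------------------------------------------------------------------
# generative process (the "world" the agent samples)


class GenerativeProcess:
    """True-state dynamics and outcome generation for one level.

    Outcomes are drawn from the ``A`` columns at the current true states;
    transitions follow the ``B`` columns under the executed action.  With
    deterministic tensors (as in the reading model) the process is exact
    replay-stable; stochastic entries are resolved by the trial RNG.
    """

    def __init__(self, level: LevelModel, rng: np.random.Generator,
                 init_states: Sequence[int]):
        self.level = level
        self.rng = rng
        self.states = [int(s) for s in init_states]

    @classmethod
    def from_priors(cls, level: LevelModel, rng: np.random.Generator,
                    priors: Sequence[np.ndarray], fixed: Optional[dict] = None):
        fixed = fixed or {}
        states = []
        for n, p in enumerate(priors):
            if n in fixed:
                s = int(fixed[n])
                if not (0 <= s < level.factors[n]):
                    raise ValueError(f"invalid fixed state {s} for factor {n}")
                states.append(s)
            else:
                states.append(int(self_rng_choice(rng, p)))
        return cls(level, rng, states)

    def outcomes(self) -> list:
        outs = []
        for m, a in enumerate(self.level.A):
            col = a.table[(slice(None),) + tuple(self.states)]
            outs.append(one_hot(int(self_rng_choice(self.rng, col)),
                                self.level.modalities[m]))
        return outs

    def advance(self, u: int) -> None:
        self.states = [
            int(self_rng_choice(self.rng, self.level.B[n].matrices[u][:, self.states[n]]))
            for n in range(self.level.n_factors)
        ]

    def step(self, u: Optional[int]) -> list:
        if u is not None:
            self.advance(u)
        return self.outcomes()


def self_rng_choice(rng: np.random.Generator, p: np.ndarray) -> int:
    p = normalize(np.asarray(p, dtype=float))
    if np.isclose(p.max(), 1.0):
        return int(np.argmax(p))
    return int(rng.choice(len(p), p=p))


# ---------------------------------------------------------------------------
# single-level sequence


def _compose_actions(level: LevelModel, history: list) -> np.ndarray:
    """Effective policy set: the actions actually taken so far, then each
    candidate policy's own actions, padded by repetition."""
    n_pol = len(level.policies)
    actions = np.zeros((n_pol, level.horizon), dtype=int)
    h = len(history)
    for p, pol in enumerate(level.policies):
        for t in range(level.horizon):
            if t < h:
                actions[p, t] = history[t]
            else:
                acts = pol.actions
                actions[p, t] = acts[min(t - h, len(acts) - 1)]
    return actions


def run_level(level: LevelModel, priors: Sequence[np.ndarray],
              process, rule: TerminationRule,
              kappa: float = 0.25, use_F: bool = False,
              ms_offset: float = 0.0, iter_offset: int = 0,
              level_id: int = 0, label_prefix: str = "",
              forced: Optional[dict] = None) -> LevelRunResult:
    """Run one level's epochs until the termination rule is met or the
    horizon is exhausted.

    ``process`` supplies outcomes: ``process.step(None)`` for the initial
    observation, ``process.step(u)`` after executing action ``u``.  With
    ``forced`` (``{"actions": [...], "outcomes": [...], "n_epochs": k}``)
    the recorded actions and stimuli are replayed verbatim and no
    termination checks apply (beliefs still evolve freely).
    """
    history: list = []
    observed: list = []
    traces: list = []
    if forced is not None:
        first = forced["outcomes"][0]
    else:
        first = process.step(None)
    observed.append(first)
    bs = init_beliefs(level, priors=priors, actions=_compose_actions(level, history))
    init_fix = int(np.argmax(priors[_controlled_factor(level)])) if level.n_factors else 0
    terminated = False
    t = 0
    n_epochs = forced["n_epochs"] if forced is not None else level.horizon
    while True:
        bs.actions = _compose_actions(level, history)
        trace = update_epoch(
            level, bs, observed, kappa=kappa, use_F=use_F,
            ms_offset=ms_offset + (len(traces) * level.iterations_per_step
                                   * level.ms_per_iteration),
            label=f"{label_prefix}epoch{t}", level_id=level_id)
        traces.append(trace)
        if forced is None and check_termination(bs, rule):
            terminated = True
            break
        if t >= n_epochs - 1:
            if forced is not None:
                terminated = True
            break
        if forced is not None:
            u = int(forced["actions"][t])
        else:
            u = select_action(bs, level, t)
        history.append(u)
        if forced is not None:
            observed.append(forced["outcomes"][t + 1])
        else:
            observed.append(process.step(u))
        t += 1
    return LevelRunResult(
        beliefs=bs, actions=list(history),
        fixations=[init_fix] + list(history),
        outcomes=observed, traces=traces,
        terminated=terminated, n_epochs=len(traces))


def _controlled_factor(level: LevelModel) -> int:
    """Heuristic: the factor whose B matrices actually differ across
    actions (the one the policies control)."""
    for n, b in enumerate(level.B):
        mats = b.matrices
        if mats.shape[0] > 1 and not all(
                np.array_equal(mats[0], mats[u]) for u in range(1, mats.shape[0])):
            return n
    return 0


# ---------------------------------------------------------------------------
# full deep trial


def run_trial(model: DeepModel, stimuli: Optional[TrialStimuli] = None,
              rule: Optional[TerminationRule] = None, seed: int = 0,
              kappa: float = 0.25, use_F: bool = False,
              stop_modality: Optional[int] = None, stop_null: int = 0,
              context_factor: Optional[int] = None,
              replay: Optional[TrialRecord] = None) -> TrialRecord:
    """Simulate (or replay) one full trial of a two-level deep model.

    The top level updates once per time step; whenever the true context
    state (``context_factor``) points at an unvisited lower-level
    sequence and no decision has been taken, the lower level runs to
    termination in between, and its posterior is consumed as evidence at
    the *next* top-level epoch (strict asynchrony).  The trial ends when
    an outcome of ``stop_modality`` other than ``stop_null`` is observed
    (e.g. feedback), or when the top horizon is exhausted.

    With ``replay``, the recorded actions and outcomes of an earlier
    trial are force-fed (beliefs differ only through the model's priors)
    -- the device used to probe violation responses with identical
    stimuli and actions.
    """
    if model.n_levels != 2:
        raise NotImplementedError("run_trial orchestrates two-level models")
    rule = rule or TerminationRule()
    lower, top = model.levels[0], model.levels[1]
    link = model.links[0]
    if top.ms_per_iteration != lower.ms_per_iteration:
        raise ValueError("levels must share ms_per_iteration for a global timeline")
    ms_per_it = lower.ms_per_iteration
    rng = np.random.default_rng(seed)
    stimuli = stimuli if stimuli is not None else TrialStimuli()

    top_priors = [np.asarray(d.table, dtype=float) for d in top.D]
    process = GenerativeProcess.from_priors(top, rng, top_priors,
                                            fixed=stimuli.top_states)
    bs_top = init_beliefs(top, actions=_compose_actions(top, []))

    epochs: list = []
    traces: list = []
    lower_runs: list = []
    observed: list = []
    top_actions: list = []
    read_contexts: set = set()
    decision = None
    decision_time = None
    feedback = None
    undecided = False
    it_count = 0
    decided = False

    def record_epoch(level_id: int, label: str, trace: IterationTrace) -> None:
        nonlocal it_count
        epochs.append(EpochRecord(level_id=level_id, label=label,
                                  start_iter=it_count, n_iter=len(trace),
                                  start_ms=it_count * ms_per_it))
        traces.append(trace)
        it_count += len(trace)

    t = 0
    while t < top.horizon:
        if replay is not None:
            if t >= len(replay.top_observed):
                break
            native = [None if o is None else np.asarray(o, dtype=float)
                      for o in replay.top_observed[t]]
            # the linked modality is re-derived below; clear the recorded one
            native[link.evidence_modality] = None
        else:
            native = list(process.outcomes())
            native[link.evidence_modality] = None
        observed.append(native)

        bs_top.actions = _compose_actions(top, top_actions)
        trace = update_epoch(top, bs_top, observed, kappa=kappa, use_F=use_F,
                             ms_offset=it_count * ms_per_it,
                             label=f"top/t{t}", level_id=1)
        record_epoch(1, f"top/t{t}", trace)

        if stop_modality is not None:
            o = observed[t][stop_modality]
            if o is not None and int(np.argmax(o)) != stop_null:
                feedback = int(np.argmax(o))
                break

        if replay is not None:
            if t >= len(replay.top_actions):
                break
            u = int(replay.top_actions[t])
        else:
            u = select_action(bs_top, top, t)
        top_actions.append(u)
        if not decided and _is_decision_action(top, u):
            decided = True
            decision = u
            decision_time = t

        ctx = (process.states[context_factor] if context_factor is not None
               else t)
        do_read = (not decided) and (ctx not in read_contexts)
        if replay is not None:
            do_read = any(step == t for step, _ in replay.lower_runs)
        if do_read:
            read_contexts.add(ctx)
            priors1 = descend_priors([bs_top.s_bar[n][t] for n in range(top.n_factors)],
                                     lower.D)
            forced = None
            if replay is not None:
                rec = next(r for step, r in replay.lower_runs if step == t)
                forced = {"actions": rec.actions, "outcomes": rec.outcomes,
                          "n_epochs": rec.n_epochs}
                sub = None
            else:
                sub = _lower_process(model, process, rng, stimuli.lower_for_step(t))
            res = run_level(lower, priors1, sub, rule, kappa=kappa, use_F=use_F,
                            ms_offset=it_count * ms_per_it, level_id=0,
                            label_prefix=f"word{t}/", forced=forced)
            for tr in res.traces:
                record_epoch(0, tr.label, tr)
            lower_runs.append((t, res))
            observed[t] = list(observed[t])
            observed[t][link.evidence_modality] = ascend_evidence(res.beliefs, link)

        if replay is None:
            process.advance(u)
        t += 1
    else:
        undecided = True

    if feedback is None and not undecided:
        undecided = decision is None

    saccade_log = _saccade_log(lower, lower_runs, ms_per_it)
    return TrialRecord(
        seed=seed, stimuli=stimuli, epochs=epochs, traces=traces,
        top_actions=top_actions, top_observed=observed, top_beliefs=bs_top,
        lower_runs=lower_runs, saccade_log=saccade_log,
        decision=decision, decision_time=decision_time, feedback=feedback,
        undecided=undecided, ms_per_iteration=ms_per_it,
        total_iterations=it_count)


def _is_decision_action(level: LevelModel, u: int) -> bool:
    """An action is a decision if it moves some factor out of its initial
    state irreversibly -- operationally, any action other than action 0
    in the reading convention.  Kept overridable via action_names."""
    if level.action_names:
        return "report" in str(level.action_names[u])
    return u != 0


def _lower_process(model: DeepModel, top_process: GenerativeProcess,
                   rng: np.random.Generator, fixed: dict) -> GenerativeProcess:
    lower = model.levels[0]
    priors = []
    for d in lower.D:
        tab = np.asarray(d.table, dtype=float)
        if d.parent_factors:
            idx = tuple(top_process.states[p] for p in d.parent_factors)
            tab = tab[(slice(None),) + idx]
        priors.append(tab)
    return GenerativeProcess.from_priors(lower, rng, priors, fixed=fixed)


def _saccade_log(lower: LevelModel, lower_runs: list, ms_per_it: float) -> list:
    log = []
    for step, res in lower_runs:
        for k, trace in enumerate(res.traces):
            fix = res.fixations[k] if k < len(res.fixations) else res.fixations[-1]
            letter = None
            if k < len(res.outcomes) and res.outcomes[k] and res.outcomes[k][0] is not None:
                letter = int(np.argmax(res.outcomes[k][0]))
            log.append({
                "word_position": step + 1,           # 1-based, as in reports
                "saccade": k + 1,
                "quadrant": fix + 1,
                "letter_outcome": letter,
                "onset_ms": float(trace.ms[0]),
            })
    return log
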