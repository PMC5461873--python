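"""Single-level variational belief updating and policy selection.

The updates implement a gradient descent on variational free energy for
one level of a deep temporal model.  Per policy and time step, a
log-domain auxiliary variable ``v`` (the "depolarisation") accumulates a
state prediction error -- the difference between log expected states and
the log messages from observed outcomes, the preceding state and the
subsequent state -- and the state expectation is its softmax ("firing
rate").  Policies are scored by expected free energy ``G`` (optionally
plus the variational free energy ``F`` of past outcomes), combined
through a softmax into the policy posterior, and expectations are
averaged over policies into a Bayesian model average that is what
adjacent levels see.

Every iteration of the descent is recorded (16 iterations per time step,
16 ms per iteration by default), which is the substrate for the simulated
electrophysiology in :mod:`actinf.electrophysiology`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import xlogy

from ._math import (EPS_LOG, entropy_nats, log_stable, marginal_over_factor,
                    project, softmax)
from .model import LevelModel

__all__ = [
    "BeliefState",
    "FreeEnergyReport",
    "IterationTrace",
    "NumericalDivergenceError",
    "init_beliefs",
    "state_prediction_error",
    "outcome_prediction_error",
    "policy_free_energy",
    "expected_free_energy",
    "policy_posterior",
    "update_epoch",
    "bma_states",
    "select_action",
]

#: default gradient step size of the free-energy descent
DEFAULT_KAPPA = 0.25


class NumericalDivergenceError(RuntimeError):
    """Depolarisation variables became non-finite during the descent."""

    def __init__(self, iteration: int):
        super().__init__(f"numerical divergence at iteration {iteration}")
        self.iteration = iteration


@dataclass
class FreeEnergyReport:
    """Per-policy free energies (nats) and the two decompositions of G.

    ``G = risk + ambiguity = -(epistemic + pragmatic)`` per policy and
    future time step; epistemic value is a mutual information and is
    therefore non-negative.
    """

    F: np.ndarray
    G: np.ndarray
    epistemic: np.ndarray   # (n_policies, n_future)
    pragmatic: np.ndarray
    risk: np.ndarray
    ambiguity: np.ndarray


@dataclass
class BeliefState:
    """Sufficient statistics of one level's posterior beliefs.

    ``s[n]`` has shape (n_policies, horizon, S_n) and holds the posterior
    expectations per policy and time; ``v`` the matching depolarisations
    (``s = softmax(v)``); ``pi`` the policy posterior; ``s_bar[n]`` the
    Bayesian model averages (horizon, S_n).  ``actions[p, t]`` is the
    control value policy ``p`` prescribes at time ``t`` (past entries are
    the actions actually taken).
    """

    level: LevelModel
    priors: List[np.ndarray]
    actions: np.ndarray
    s: List[np.ndarray]
    v: List[np.ndarray]
    pi: np.ndarray
    s_bar: List[np.ndarray]
    o_pred: List[np.ndarray]
    n_observed: int = 0
    report: Optional[FreeEnergyReport] = None
    #: exact per-factor marginals of the joint filter over the outcomes
    #: observed so far (floored by EPS_LOG); what ascends between levels
    exact_marginals: Optional[List[np.ndarray]] = None


@dataclass
class IterationTrace:
    """Iteration-resolved snapshots of one update epoch."""

    level_id: int
    label: str
    ms: np.ndarray                      # timestamps, one per iteration
    s0: List[np.ndarray]                # per factor: (n_iter, S) BMA at tau=0
    pi: np.ndarray                      # (n_iter, n_policies)
    f_avg: np.ndarray                   # policy-averaged F per iteration

    def __len__(self) -> int:
        return len(self.ms)


def _prior_chain(level: LevelModel, priors, actions_row: np.ndarray) -> List[List[np.ndarray]]:
    """Forward-propagated prior over states per factor and time."""
    chains = []
    for n in range(level.n_factors):
        p = np.asarray(priors[n], dtype=float)
        chain = [p]
        for t in range(1, level.horizon):
            u = int(actions_row[t - 1])
            chain.append(level.B[n].matrices[u] @ chain[-1])
        chains.append(chain)
    return chains


def init_beliefs(level: LevelModel, priors: Optional[Sequence] = None,
                 actions: Optional[np.ndarray] = None) -> BeliefState:
    """Fresh beliefs: depolarisations at the log empirical prior.

    ``priors`` default to the level's unconditional ``D`` vectors (a
    descended empirical prior replaces them below the top level);
    ``actions`` defaults to the level's policy set, padded by repeating
    each policy's last action out to the horizon.
    """
    if priors is None:
        priors = []
        for d in level.D:
            if d.parent_factors:
                raise ValueError(
                    f"factor {d.factor} has a conditional D link; descend a prior first"
                )
            priors.append(np.asarray(d.table, dtype=float))
    priors = [np.asarray(p, dtype=float) for p in priors]
    if actions is None:
        n_pol = len(level.policies)
        actions = np.zeros((n_pol, level.horizon), dtype=int)
        for p, pol in enumerate(level.policies):
            acts = pol.actions
            for t in range(level.horizon):
                actions[p, t] = acts[min(t, len(acts) - 1)]
    actions = np.asarray(actions, dtype=int)
    n_pol = actions.shape[0]
    s, v = [], []
    for n in range(level.n_factors):
        sn = np.zeros((n_pol, level.horizon, level.factors[n]))
        for p in range(n_pol):
            for t, pt in enumerate(_prior_chain(level, priors, actions[p])[n]):
                sn[p, t] = pt
        s.append(sn)
        v.append(log_stable(sn))
    pi = np.full(n_pol, 1.0 / n_pol)
    bs = BeliefState(
        level=level, priors=priors, actions=actions,
        s=[softmax(vn, axis=-1) for vn in v], v=v, pi=pi,
        s_bar=[sn[0].copy() for sn in s],
        o_pred=[np.zeros((n_pol, level.horizon, level.modalities[m]))
                for m in range(level.n_modalities)],
    )
    bma_states(bs)
    return bs


def _log_messages(level: LevelModel, bs: BeliefState, policy: int, tau: int,
                  observed) -> List[np.ndarray]:
    """Unnormalised log messages (likelihood + forward + backward) per factor."""
    msgs = []
    beliefs_tau = [bs.s[n][policy, tau] for n in range(level.n_factors)]
    for n in range(level.n_factors):
        msg = np.zeros(level.factors[n])
        if tau < len(observed):
            for m, o in enumerate(observed[tau]):
                if o is None:
                    continue
                lin = marginal_over_factor(level.A[m].table, o, beliefs_tau, keep=n)
                msg = msg + log_stable(lin)
        # temporal messages are averaged (halved when both neighbours
        # exist): with full weights a static chain of identical slices
        # amplifies any belief gap geometrically instead of preserving it
        if tau == 0:
            fwd = log_stable(bs.priors[n])
        else:
            u = int(bs.actions[policy, tau - 1])
            fwd = log_stable(level.B[n].matrices[u] @ bs.s[n][policy, tau - 1])
        bwd = None
        if tau + 1 < bs.n_observed:
            u = int(bs.actions[policy, tau])
            bwd = log_stable(level.B[n].matrices[u].T @ bs.s[n][policy, tau + 1])
        if bwd is None:
            msg = msg + fwd
        else:
            msg = msg + 0.5 * (fwd + bwd)
        msgs.append(msg)
    return msgs


def state_prediction_error(level: LevelModel, bs: BeliefState, policy: int,
                           tau: int, observed) -> List[np.ndarray]:
    """Mean-centred state prediction error per factor (nats).

    The raw error is ``message - ln s``; a constant shift is annihilated
    by the softmax, so the returned vector is centred, making "no error"
    read as an exactly zero vector at the variational fixed point.
    """
    if not (0 <= tau < level.horizon):
        raise IndexError(f"tau {tau} outside horizon {level.horizon}")
    msgs = _log_messages(level, bs, policy, tau, observed)
    errs = []
    for n, msg in enumerate(msgs):
        e = msg - log_stable(bs.s[n][policy, tau])
        errs.append(e - e.mean())
    return errs


def policy_free_energy(level: LevelModel, bs: BeliefState, policy: int,
                       observed) -> float:
    """Variational free energy of one policy: the expected state
    prediction error under current beliefs, summed over observed epochs."""
    F = 0.0
    for tau in range(bs.n_observed):
        msgs = _log_messages(level, bs, policy, tau, observed)
        for n, msg in enumerate(msgs):
            s = bs.s[n][policy, tau]
            F += float(s @ (log_stable(s) - msg))
    return F


def _ambiguity_tensors(level: LevelModel) -> List[np.ndarray]:
    """Per-modality outcome-entropy tensors H over state combinations."""
    return [-xlogy(a.table, a.table).sum(axis=0) for a in level.A]


def _joint_predictive(level: LevelModel, bs: BeliefState, policy: int,
                      observed, tau: int) -> np.ndarray:
    """Exact joint predictive over state combinations at time ``tau``.

    The factored empirical prior is filtered forward through the outcomes
    observed so far (expected likelihood for probabilistic outcomes) and
    the per-factor transitions of the policy.  Levels are small, so this
    enumeration is cheap; it is used only to score policies -- state
    estimation itself stays mean-field, but a product of marginals leaks
    probability onto refuted state combinations and would make
    re-observing a known outcome look informative.
    """
    J = np.asarray(bs.priors[0], dtype=float).copy()
    for n in range(1, level.n_factors):
        J = np.multiply.outer(J, np.asarray(bs.priors[n], dtype=float))
    J = np.atleast_1d(J)
    for tp in range(tau):
        if tp < len(observed):
            for m, o in enumerate(observed[tp]):
                if o is None:
                    continue
                w = np.tensordot(np.asarray(o, dtype=float), level.A[m].table,
                                 axes=(0, 0))
                J = J * w
        total = J.sum()
        if total <= 0:                      # all mass refuted: fall back flat
            J = np.ones_like(J)
            total = J.sum()
        J = J / total
        u = int(bs.actions[policy, tp])
        for n in range(level.n_factors):
            J = np.moveaxis(
                np.tensordot(level.B[n].matrices[u], J, axes=(1, n)), 0, n)
    total = J.sum()
    return J / total if total > 0 else np.full_like(J, 1.0 / J.size)


def _predict(level: LevelModel, bs: BeliefState, observed=None) -> List[int]:
    """Propagate beliefs one step past the last observed epoch and fill
    predicted outcome distributions for every represented time.

    Observed epochs use the mean-field product (the generalised dot
    product of the A tensor with the policy marginals); the future epoch
    uses the exact joint predictive (see ``_joint_predictive``).
    """
    t_last = bs.n_observed - 1
    future: List[int] = []
    if 0 <= t_last < level.horizon - 1:
        tau = t_last + 1
        for p in range(bs.actions.shape[0]):
            u = int(bs.actions[p, t_last])
            for n in range(level.n_factors):
                bs.s[n][p, tau] = level.B[n].matrices[u] @ bs.s[n][p, t_last]
                bs.v[n][p, tau] = log_stable(bs.s[n][p, tau])
        future = [tau]
    for m in range(level.n_modalities):
        for p in range(bs.actions.shape[0]):
            for tau in range(bs.n_observed):
                beliefs = [bs.s[n][p, tau] for n in range(level.n_factors)]
                bs.o_pred[m][p, tau] = project(level.A[m].table, beliefs)
    if observed is not None:
        for tau in future:
            for p in range(bs.actions.shape[0]):
                J = _joint_predictive(level, bs, p, observed, tau)
                for m in range(level.n_modalities):
                    flat = level.A[m].table.reshape(level.modalities[m], -1)
                    bs.o_pred[m][p, tau] = flat @ J.ravel()
    return future


def outcome_prediction_error(level: LevelModel, bs: BeliefState, policy: int,
                             tau: int, observed=None) -> List[np.ndarray]:
    """Per-modality outcome prediction error whose inner product with the
    predicted outcomes yields G(policy, tau): ``ln o - C`` plus the
    belief-weighted outcome-entropy (ambiguity) of the likelihood."""
    H = _ambiguity_tensors(level)
    future = observed is not None and tau >= bs.n_observed
    if future:
        J = _joint_predictive(level, bs, policy, observed, tau)
    errs = []
    for m in range(level.n_modalities):
        o = bs.o_pred[m][policy, tau]
        if not np.any(o):
            raise ValueError(f"predicted outcomes missing for policy {policy}, tau {tau}")
        C = np.asarray(level.C[m].log_prefs, dtype=float)
        if future:
            amb = float(H[m].ravel() @ J.ravel())
        else:
            beliefs = [bs.s[n][policy, tau] for n in range(level.n_factors)]
            amb = float(project(H[m][None, ...], beliefs)[0])
        errs.append(log_stable(o) - C + amb)
    return errs


def expected_free_energy(level: LevelModel, bs: BeliefState, policy: int,
                         observed, future: Sequence[int]) -> dict:
    """Expected free energy of one policy over the given future epochs,
    with both decompositions (risk + ambiguity; -(epistemic + pragmatic)).

    Predictive distributions come from the exact joint filter; the
    predicted outcome distributions are also written into ``bs.o_pred``.
    """
    H = _ambiguity_tensors(level)
    out = {"G": 0.0, "epistemic": np.zeros(len(future)),
           "pragmatic": np.zeros(len(future)), "risk": np.zeros(len(future)),
           "ambiguity": np.zeros(len(future))}
    for k, tau in enumerate(future):
        J = _joint_predictive(level, bs, policy, observed, tau)
        for m in range(level.n_modalities):
            flat = level.A[m].table.reshape(level.modalities[m], -1)
            o = flat @ J.ravel()
            bs.o_pred[m][policy, tau] = o
            C = np.asarray(level.C[m].log_prefs, dtype=float)
            amb = float(H[m].ravel() @ J.ravel())
            h_o = entropy_nats(o)
            out["risk"][k] += -h_o - float(o @ C)
            out["ambiguity"][k] += amb
            out["epistemic"][k] += h_o - amb
            out["pragmatic"][k] += float(o @ C)
    out["G"] = float(out["risk"].sum() + out["ambiguity"].sum())
    return out


def policy_posterior(F: np.ndarray, G: np.ndarray, use_F: bool = False) -> np.ndarray:
    """Softmax policy expectations from (expected) free energy."""
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if not (np.all(np.isfinite(F)) and np.all(np.isfinite(G))):
        raise ValueError("non-finite free energies")
    return softmax(-(G + F) if use_F else -G)


def bma_states(bs: BeliefState) -> List[np.ndarray]:
    """Bayesian model average of state expectations over policies."""
    bs.s_bar = [np.einsum("p,pts->ts", bs.pi, sn) for sn in bs.s]
    return bs.s_bar


def select_action(bs: BeliefState, level: LevelModel, time: int) -> int:
    """Action of the most probable policy (deterministic argmax; ties to
    the lowest policy index)."""
    return int(bs.actions[int(np.argmax(bs.pi)), time])


def update_epoch(level: LevelModel, bs: BeliefState, observed,
                 n_iterations: Optional[int] = None, kappa: float = DEFAULT_KAPPA,
                 use_F: bool = False, reset: bool = True,
                 ms_offset: float = 0.0, label: str = "",
                 level_id: int = 0) -> IterationTrace:
    """Run one epoch of the free-energy descent (in place).

    ``observed`` is a list over past epochs of per-modality outcome
    vectors (``None`` marks an unobserved modality); probabilistic
    vectors are allowed (evidence ascending from a lower level).  At the
    start of the epoch the depolarisations are reset to the log empirical
    prior, producing the perisaccadic transients of the simulated
    electrophysiology; the information in earlier outcomes re-enters
    through the likelihood messages during the descent.
    """
    if n_iterations is None:
        n_iterations = level.iterations_per_step
    n_pol = bs.actions.shape[0]
    bs.n_observed = len(observed)
    if reset:
        for p in range(n_pol):
            chains = _prior_chain(level, bs.priors, bs.actions[p])
            for n in range(level.n_factors):
                for t in range(level.horizon):
                    bs.v[n][p, t] = log_stable(chains[n][t])
        for n in range(level.n_factors):
            bs.s[n] = softmax(bs.v[n], axis=-1)

    ms = ms_offset + np.arange(n_iterations) * level.ms_per_iteration
    trace_s0 = [np.zeros((n_iterations, level.factors[n]))
                for n in range(level.n_factors)]
    trace_pi = np.zeros((n_iterations, n_pol))
    trace_f = np.zeros(n_iterations)

    # exact joint marginals over everything observed so far; static
    # factors (identity B) read as smoothed initial-state posteriors
    J = _joint_predictive(level, bs, 0, observed, bs.n_observed)
    bs.exact_marginals = []
    for n in range(level.n_factors):
        axes = tuple(a for a in range(level.n_factors) if a != n)
        marg = (J.sum(axis=axes) if axes else J) + EPS_LOG
        bs.exact_marginals.append(marg / marg.sum())

    # policy evaluation: G depends only on the outcomes observed so far
    # and each policy's actions, so it is fixed for the whole epoch
    future = ([bs.n_observed] if bs.n_observed < level.horizon else [])
    reports = [expected_free_energy(level, bs, p, observed, future)
               for p in range(n_pol)]
    G = np.array([r["G"] for r in reports])
    epistemic = np.array([r["epistemic"] for r in reports])
    pragmatic = np.array([r["pragmatic"] for r in reports])
    risk = np.array([r["risk"] for r in reports])
    ambiguity = np.array([r["ambiguity"] for r in reports])

    for it in range(n_iterations):
        # snapshot first (iteration 0 records the reset state, so the
        # perisaccadic transient includes its starting point), then do
        # one Jacobi sweep of the gradient descent on F
        _predict(level, bs, None)   # future o_pred already filled above
        F = np.array([policy_free_energy(level, bs, p, observed) for p in range(n_pol)])
        bs.report = FreeEnergyReport(F=F, G=G, epistemic=epistemic,
                                     pragmatic=pragmatic, risk=risk,
                                     ambiguity=ambiguity)
        bs.pi = policy_posterior(F, G, use_F=use_F)
        bma_states(bs)
        for n in range(level.n_factors):
            trace_s0[n][it] = bs.s_bar[n][0]
        trace_pi[it] = bs.pi
        trace_f[it] = float(bs.pi @ F)

        errs = [[state_prediction_error(level, bs, p, tau, observed)
                 for tau in range(bs.n_observed)] for p in range(n_pol)]
        for p in range(n_pol):
            for tau in range(bs.n_observed):
                for n in range(level.n_factors):
                    bs.v[n][p, tau] = bs.v[n][p, tau] + kappa * errs[p][tau][n]
        for n in range(level.n_factors):
            if not np.all(np.isfinite(bs.v[n])):
                raise NumericalDivergenceError(it)
            bs.s[n][:, :bs.n_observed] = softmax(bs.v[n][:, :bs.n_observed], axis=-1)

    # final housekeeping so the returned beliefs reflect the last sweep
    _predict(level, bs, None)
    F = np.array([policy_free_energy(level, bs, p, observed) for p in range(n_pol)])
    bs.report = FreeEnergyReport(F=F, G=G, epistemic=epistemic,
                                 pragmatic=pragmatic, risk=risk,
                                 ambiguity=ambiguity)
    bs.pi = policy_posterior(F, G, use_F=use_F)
    bma_states(bs)

    return IterationTrace(level_id=level_id, label=label, ms=ms,
                          s0=trace_s0, pi=trace_pi, f_avg=trace_f)
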