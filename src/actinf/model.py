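"""Hierarchical discrete-state generative models.

A generative model is specified, per hierarchical level, by four parameter
families over categorical states and outcomes:

* ``A`` -- likelihood tensors mapping every combination of hidden-state
  levels (one axis per factor) to a distribution over outcomes of one
  modality;
* ``B`` -- action-conditioned transition matrices, one family per hidden
  factor, columns giving the distribution over next states;
* ``C`` -- log prior preferences over outcomes (nats; zero = indifferent);
* ``D`` -- initial-state priors.  At the top level these are unconditional;
  below the top they are links: tensors mapping combinations of
  higher-level hidden states to the initial state of a lower factor, which
  is what gives the hierarchy its nested temporal structure (one
  higher-level transition spans a whole lower-level sequence).

Probabilities are stored in linear space; logs are taken at use sites
(see :mod:`actinf._math`).  All indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

from ._math import normalize, one_hot, project

__all__ = [
    "LikelihoodArray",
    "TransitionArray",
    "PreferenceArray",
    "InitialLink",
    "Policy",
    "LevelModel",
    "LinkMap",
    "DeepModel",
    "DegenerateColumnError",
    "normalize_columns",
    "likelihood_project",
    "one_hot_table",
    "validate_model",
    "sample_trial",
    "save_model",
    "load_model",
]

_TOL = 1e-8


class DegenerateColumnError(ValueError):
    """A conditional table contains an all-zero column."""


def normalize_columns(table) -> np.ndarray:
    """Normalise a non-negative tensor so that every column (axis 0 for a
    fixed setting of the remaining axes) is a categorical distribution."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("table has negative entries")
    sums = t.sum(axis=0)
    bad = np.argwhere(sums == 0)
    if bad.size:
        raise DegenerateColumnError(
            "all-zero column(s) at indices "
            f"{[tuple(int(i) for i in ix) for ix in bad[:8]]}"
        )
    return t / sums


def one_hot_table(n_out: int, cond_shape: Sequence[int],
                  rule: Callable[..., int]) -> np.ndarray:
    """Build a deterministic conditional tensor by placing a one at the
    outcome ``rule(*combination)`` for every combination of conditioning
    indices (and zeros elsewhere)."""
    cond_shape = tuple(int(s) for s in cond_shape)
    table = np.zeros((n_out,) + cond_shape)
    for combo in np.ndindex(*cond_shape):
        table[(rule(*combo),) + combo] = 1.0
    return table


@dataclass
class LikelihoodArray:
    """``A`` tensor for one outcome modality: shape (n_outcomes, S_1..S_N)."""

    modality: int
    table: np.ndarray

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)


@dataclass
class TransitionArray:
    """``B`` family for one hidden factor: shape (n_actions, S, S); column
    ``j`` of ``matrices[u]`` is the distribution over next states from
    state ``j`` under control value ``u``."""

    factor: int
    matrices: np.ndarray

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)

    @property
    def n_actions(self) -> int:
        return self.matrices.shape[0]


@dataclass
class PreferenceArray:
    """``C`` log preferences (nats) over one modality's outcomes."""

    modality: int
    log_prefs: np.ndarray

    def __post_init__(self):
        self.log_prefs = np.asarray(self.log_prefs, dtype=float)


@dataclass
class InitialLink:
    """``D`` prior for one factor's initial state.

    ``parent_factors`` names the higher-level factors that condition the
    prior; ``table`` then has shape (S, *parent_sizes).  An empty tuple
    means an unconditional prior of shape (S,) (always the case at the top
    level).
    """

    factor: int
    table: np.ndarray
    parent_factors: tuple = ()

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        self.parent_factors = tuple(self.parent_factors)


@dataclass
class Policy:
    """A candidate sequence of control values (one integer per time step)."""

    policy_id: int
    actions: np.ndarray

    def __post_init__(self):
        self.actions = np.asarray(self.actions, dtype=int)


@dataclass
class LevelModel:
    """Complete specification of one hierarchical level."""

    factors: list            # state-space size per hidden factor
    modalities: list         # outcome-space size per modality
    A: list                  # list[LikelihoodArray], one per modality
    B: list                  # list[TransitionArray], one per factor
    C: list                  # list[PreferenceArray], one per modality
    D: list                  # list[InitialLink], one per factor
    policies: list           # list[Policy]
    horizon: int
    iterations_per_step: int = 16
    ms_per_iteration: float = 16.0
    factor_names: list = field(default_factory=list)
    modality_names: list = field(default_factory=list)
    action_names: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_modalities(self) -> int:
        return len(self.modalities)

    @property
    def n_actions(self) -> int:
        return self.B[0].n_actions if self.B else 0


@dataclass
class LinkMap:
    """How a (non-top) level talks to the level above it.

    ``evidence_factor`` is the lower-level factor whose converged
    posterior (over its initial state) ascends as a probabilistic outcome
    on the higher level's modality ``evidence_modality``; the descending
    direction is carried by the lower level's conditional ``D`` links.
    """

    evidence_factor: int
    evidence_modality: int


@dataclass
class DeepModel:
    """An ordered stack of levels; ``levels[0]`` is the lowest.

    ``links[i]`` describes the interface between level ``i`` and level
    ``i+1`` and is ``None`` for the top level.
    """

    levels: list
    links: list

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def top(self) -> LevelModel:
        return self.levels[-1]


# ---------------------------------------------------------------------------
# validation


def _check_columns(table: np.ndarray, path: str, report: list) -> None:
    if np.any(table < 0):
        report.append(f"{path}: negative entries")
        return
    sums = table.sum(axis=0)
    bad = np.argwhere(np.abs(sums - 1.0) > _TOL)
    for ix in bad[:4]:
        report.append(
            f"{path}: column {tuple(int(i) for i in ix)} sums to "
            f"{float(sums[tuple(ix)]):.6g} (expected 1)"
        )
    if bad.size > 4 * sums.ndim if sums.ndim else False:
        report.append(f"{path}: ... further column violations suppressed")


def validate_model(model: DeepModel) -> list:
    """Return every invariant violation (empty list = valid model)."""
    report: list = []
    for i, level in enumerate(model.levels):
        tag = f"level[{i}]"
        nf, nm = level.n_factors, level.n_modalities
        if len(level.B) != nf:
            report.append(f"{tag}: {len(level.B)} B arrays for {nf} factors")
        if len(level.A) != nm:
            report.append(f"{tag}: {len(level.A)} A arrays for {nm} modalities")
        if len(level.C) != nm:
            report.append(f"{tag}: {len(level.C)} C arrays for {nm} modalities")
        if len(level.D) != nf:
            for n in range(len(level.D), nf):
                report.append(f"{tag}: missing D for factor {n + 1}")
        for m, a in enumerate(level.A):
            want = (level.modalities[m],) + tuple(level.factors)
            if a.table.shape != want:
                report.append(f"{tag}.A[{m}]: shape {a.table.shape} != {want}")
            else:
                _check_columns(a.table, f"{tag}.A[{m}]", report)
        for n, b in enumerate(level.B):
            s = level.factors[n]
            if b.matrices.ndim != 3 or b.matrices.shape[1:] != (s, s):
                report.append(
                    f"{tag}.B[{n}]: shape {b.matrices.shape} not (n_actions, {s}, {s})"
                )
                continue
            for u in range(b.n_actions):
                _check_columns(b.matrices[u], f"{tag}.B[{n}][action {u}]", report)
        for m, c in enumerate(level.C):
            if c.log_prefs.shape[-1] != level.modalities[m]:
                report.append(f"{tag}.C[{m}]: length {c.log_prefs.shape} != {level.modalities[m]}")
            if not np.all(np.isfinite(c.log_prefs)):
                report.append(f"{tag}.C[{m}]: non-finite preferences")
        for n, d in enumerate(level.D[:nf]):
            s = level.factors[n]
            if d.parent_factors:
                if i + 1 >= model.n_levels:
                    report.append(f"{tag}.D[{n}]: conditional link at the top level")
                    continue
                upper = model.levels[i + 1]
                want = (s,) + tuple(upper.factors[p] for p in d.parent_factors)
                if d.table.shape != want:
                    report.append(f"{tag}.D[{n}]: shape {d.table.shape} != {want}")
                    continue
            elif d.table.shape != (s,):
                report.append(f"{tag}.D[{n}]: shape {d.table.shape} != ({s},)")
                continue
            _check_columns(d.table, f"{tag}.D[{n}]", report)
        for p in level.policies:
            if len(p.actions) > level.horizon:
                report.append(f"{tag}.policy[{p.policy_id}]: longer than horizon")
            if level.n_actions and np.any((p.actions < 0) | (p.actions >= level.n_actions)):
                report.append(f"{tag}.policy[{p.policy_id}]: action index out of range")
        if level.iterations_per_step <= 0:
            report.append(f"{tag}: iterations_per_step must be positive")
        if level.ms_per_iteration <= 0:
            report.append(f"{tag}: ms_per_iteration must be positive")
    for i, link in enumerate(model.links):
        if i == model.n_levels - 1:
            if link is not None:
                report.append(f"links[{i}]: top level cannot have a link")
            continue
        if link is None:
            report.append(f"links[{i}]: missing link for non-top level")
            continue
        lower, upper = model.levels[i], model.levels[i + 1]
        if not (0 <= link.evidence_factor < lower.n_factors):
            report.append(f"links[{i}]: evidence_factor out of range")
        elif not (0 <= link.evidence_modality < upper.n_modalities):
            report.append(f"links[{i}]: evidence_modality out of range")
        elif upper.modalities[link.evidence_modality] != lower.factors[link.evidence_factor]:
            report.append(
                f"links[{i}]: evidence modality size "
                f"{upper.modalities[link.evidence_modality]} != factor size "
                f"{lower.factors[link.evidence_factor]}"
            )
    return report


# ---------------------------------------------------------------------------
# projection and forward sampling


def likelihood_project(A: LikelihoodArray, state_beliefs) -> np.ndarray:
    """Expected outcome distribution o = A (x) s_1 (x) ... (x) s_N."""
    beliefs = [np.asarray(b, dtype=float) for b in state_beliefs]
    if tuple(len(b) for b in beliefs) != A.table.shape[1:]:
        raise ValueError(
            f"belief dimensions {tuple(len(b) for b in beliefs)} do not match "
            f"A state dimensions {A.table.shape[1:]}"
        )
    return project(A.table, beliefs)


def _sample_categorical(rng: np.random.Generator, p: np.ndarray) -> int:
    return int(rng.choice(len(p), p=normalize(p)))


def sample_trial(model: DeepModel, true_states: Optional[dict] = None,
                 seed: int = 0, actions: Optional[dict] = None) -> dict:
    """Forward-sample the generative process.

    The hierarchy is unrolled top-down: initial states are drawn from the
    ``D`` priors (conditioned on the current higher-level states for
    non-top levels), outcomes from the ``A`` columns at the sampled state
    combination, and transitions from the ``B`` matrices under the given
    or uniformly sampled control values.

    Parameters
    ----------
    true_states : optional ``{level_index: {factor_index: state}}`` fixing
        initial states instead of sampling them.
    actions : optional ``{level_index: sequence of control values}``.

    Returns a nested record ``{level: [per-time {states, outcomes, action}]}``
    plus the seed; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    true_states = true_states or {}
    actions = actions or {}
    record = {"seed": int(seed), "levels": {}}

    def init_states(i: int, upper_states: Optional[list]) -> list:
        level = model.levels[i]
        fixed = true_states.get(i, {})
        states = []
        for n, d in enumerate(level.D):
            if n in fixed:
                s = int(fixed[n])
                if not (0 <= s < level.factors[n]):
                    raise ValueError(f"invalid fixed state {s} for level {i} factor {n}")
                states.append(s)
                continue
            col = d.table
            if d.parent_factors:
                idx = tuple(upper_states[p] for p in d.parent_factors)
                col = col[(slice(None),) + idx]
            states.append(_sample_categorical(rng, col))
        return states

    def run(i: int, upper_states: Optional[list]) -> None:
        level = model.levels[i]
        states = init_states(i, upper_states)
        steps = record["levels"].setdefault(i, [])
        level_actions = actions.get(i)
        for t in range(level.horizon):
            outs = []
            for a in level.A:
                idx = (slice(None),) + tuple(states)
                outs.append(_sample_categorical(rng, a.table[idx]))
            if i > 0:
                run(i - 1, states)
            if level_actions is not None:
                u = int(level_actions[min(t, len(level_actions) - 1)])
            else:
                u = int(rng.integers(level.n_actions)) if level.n_actions else 0
            steps.append({
                "time": t,
                "states": list(states),
                "outcomes": outs,
                "outcome_vectors": [one_hot(o, level.modalities[m]).tolist()
                                    for m, o in enumerate(outs)],
                "action": u,
            })
            states = [
                _sample_categorical(rng, level.B[n].matrices[u][:, states[n]])
                for n in range(level.n_factors)
            ]

    run(model.n_levels - 1, None)
    return record


# ---------------------------------------------------------------------------
# plain-text serialization (round-trip YAML)


def _level_to_dict(level: LevelModel) -> dict:
    return {
        "factors": [int(s) for s in level.factors],
        "modalities": [int(s) for s in level.modalities],
        "A": [{"modality": a.modality, "table": a.table.tolist()} for a in level.A],
        "B": [{"factor": b.factor, "matrices": b.matrices.tolist()} for b in level.B],
        "C": [{"modality": c.modality, "log_prefs": c.log_prefs.tolist()} for c in level.C],
        "D": [{"factor": d.factor, "table": d.table.tolist(),
               "parent_factors": list(d.parent_factors)} for d in level.D],
        "policies": [{"policy_id": p.policy_id, "actions": p.actions.tolist()}
                     for p in level.policies],
        "horizon": int(level.horizon),
        "iterations_per_step": int(level.iterations_per_step),
        "ms_per_iteration": float(level.ms_per_iteration),
        "factor_names": list(level.factor_names),
        "modality_names": list(level.modality_names),
        "action_names": list(level.action_names),
    }


def _level_from_dict(d: dict) -> LevelModel:
    return LevelModel(
        factors=list(d["factors"]),
        modalities=list(d["modalities"]),
        A=[LikelihoodArray(a["modality"], np.array(a["table"])) for a in d["A"]],
        B=[TransitionArray(b["factor"], np.array(b["matrices"])) for b in d["B"]],
        C=[PreferenceArray(c["modality"], np.array(c["log_prefs"])) for c in d["C"]],
        D=[InitialLink(x["factor"], np.array(x["table"]), tuple(x["parent_factors"]))
           for x in d["D"]],
        policies=[Policy(p["policy_id"], p["actions"]) for p in d["policies"]],
        horizon=int(d["horizon"]),
        iterations_per_step=int(d["iterations_per_step"]),
        ms_per_iteration=float(d["ms_per_iteration"]),
        factor_names=list(d.get("factor_names", [])),
        modality_names=list(d.get("modality_names", [])),
        action_names=list(d.get("action_names", [])),
    )


def model_to_dict(model: DeepModel) -> dict:
    return {
        "levels": [_level_to_dict(lv) for lv in model.levels],
        "links": [None if ln is None else
                  {"evidence_factor": ln.evidence_factor,
                   "evidence_modality": ln.evidence_modality}
                  for ln in model.links],
    }


def model_from_dict(d: dict) -> DeepModel:
    return DeepModel(
        levels=[_level_from_dict(lv) for lv in d["levels"]],
        links=[None if ln is None else LinkMap(**ln) for ln in d["links"]],
    )


def save_model(model: DeepModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> DeepModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
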