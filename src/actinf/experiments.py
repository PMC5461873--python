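"""Scripted experiments: the exemplar reading trial, the violation
battery (local / global / both), and the engine validation harness.

These functions are the library behind the command-line interface; they
return in-memory results and can optionally export delimited-text tables
plus a manifest (parameter echo and file checksums) for exact
reproduction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._math import normalize
from .electrophysiology import (DEFAULT_BAND, ErpWaveform, above_half_max_ms,
                                difference_waveform, lfp, peak_latency, raster)
from .engine import init_beliefs, update_epoch
from .model import (DeepModel, InitialLink, LevelModel, LikelihoodArray,
                    Policy, PreferenceArray, TransitionArray)
from .reading import ReadingConfig, apply_violation, build_reading_model, exemplar_stimuli
from .scheduler import TerminationRule, TrialRecord, run_trial

__all__ = [
    "ExperimentManifest", "reading_trial", "trial_summary",
    "violation_battery", "perisaccadic_analysis", "validate_engine",
    "export_trial", "random_micro_model",
]

VIOLATION_KINDS = ("local", "global", "both")


@dataclass
class ExperimentManifest:
    experiment: str
    seed: int
    conditions: list
    parameters: dict
    outputs: dict = field(default_factory=dict)   # path -> sha256

    def add_file(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[Path(path).name] = digest

    def write(self, path: Path) -> None:
        payload = {
            "experiment": self.experiment,
            "seed": self.seed,
            "conditions": list(self.conditions),
            "parameters": self.parameters,
            "outputs": self.outputs,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _parameters(config: ReadingConfig) -> dict:
    return {
        "iterations_per_step": config.iterations_per_step,
        "ms_per_iteration": config.ms_per_iteration,
        "epoch_ms": config.iterations_per_step * config.ms_per_iteration,
        "kappa": config.kappa,
        "threshold_nats": config.threshold_nats,
        "band_hz": list(DEFAULT_BAND),
        "wrong_log_pref": config.wrong_log_pref,
        "global_factor": config.global_factor,
        "p_no_vflip": config.p_no_vflip,
        "horizons": {"saccades_per_word": config.saccades_per_word,
                     "top": config.top_horizon},
    }


def reading_trial(config: Optional[ReadingConfig] = None, seed: int = 0,
                  stimuli=None, model: Optional[DeepModel] = None,
                  replay: Optional[TrialRecord] = None,
                  threshold_nats: Optional[float] = None) -> TrialRecord:
    """Run (or replay) one reading trial of the exemplar task."""
    config = config or ReadingConfig()
    model = model or build_reading_model(config)
    stimuli = stimuli if stimuli is not None else exemplar_stimuli(config)
    rule = TerminationRule(threshold_nats or config.threshold_nats, target_factor=0)
    return run_trial(model, stimuli=stimuli, rule=rule, seed=seed,
                     kappa=config.kappa, stop_modality=2, stop_null=0,
                     context_factor=1, replay=replay)


def trial_summary(record: TrialRecord, config: Optional[ReadingConfig] = None) -> dict:
    """Behavioural summary: saccades per word, decision, feedback, timing."""
    config = config or ReadingConfig()
    per_word: Dict[int, int] = {}
    for entry in record.saccade_log:
        per_word[entry["word_position"]] = max(
            per_word.get(entry["word_position"], 0), entry["saccade"])
    decisions = ["next word", "report happy", "report sad"]
    feedback_names = ["nothing", "right", "wrong"]
    return {
        "saccades_per_word": [per_word.get(w + 1, 0)
                              for w in range(config.horizon_words)],
        "word_transitions": len(per_word),
        "decision": (decisions[record.decision]
                     if record.decision is not None else None),
        "feedback": (feedback_names[record.feedback]
                     if record.feedback is not None else None),
        "undecided": record.undecided,
        "epochs": len(record.epochs),
        "total_iterations": record.total_iterations,
        "total_ms": record.total_ms,
        "epoch_ms": config.iterations_per_step * config.ms_per_iteration,
    }


# ---------------------------------------------------------------------------
# violation battery


def violation_battery(config: Optional[ReadingConfig] = None, seed: int = 0,
                      kinds: Sequence[str] = VIOLATION_KINDS) -> dict:
    """Standard trial plus replays under violated priors.

    The standard trial is simulated once; each violated condition reruns
    the belief updating with *exactly the same stimuli and actions*
    (force-fed from the standard record) under the manipulated priors.
    """
    config = config or ReadingConfig()
    for k in kinds:
        if k not in VIOLATION_KINDS:
            raise ValueError(f"unknown violation kind {k!r}")
    base_model = build_reading_model(config)
    records = {"standard": reading_trial(config, seed=seed, model=base_model)}
    for kind in kinds:
        violated = apply_violation(base_model, kind, config)
        records[kind] = reading_trial(config, seed=seed, model=violated,
                                      replay=records["standard"])
    return records


def _analysis_epoch_onset(record: TrialRecord) -> float:
    """Onset (ms) of the last lower-level saccade epoch before the
    decision epoch -- the perisaccadic alignment event."""
    lower_epochs = [e for e in record.epochs if e.level_id == 0]
    if not lower_epochs:
        raise ValueError("record contains no lower-level epochs")
    return float(lower_epochs[-1].start_ms)


def perisaccadic_analysis(records: Dict[str, TrialRecord],
                          window_ms: Tuple[float, float] = (0.0, 400.0),
                          band: Tuple[float, float] = DEFAULT_BAND) -> dict:
    """Filtered perisaccadic responses, difference waveforms and latencies.

    First-level responses are the three word units' Bayesian model
    averages; second-level responses the six sentence units.  All traces
    are band-passed over the whole trial, then aligned to the onset of
    the last pre-decision saccade epoch of the standard trial.
    """
    standard = records["standard"]
    align = _analysis_epoch_onset(standard)
    waves: dict = {}
    for cond, rec in records.items():
        for level_id in (0, 1):
            w = raster(rec, level_id, factor=0)
            # epoch first, then filter: the analysed segment starts at the
            # reset state, so transients from the pre-saccadic suspension
            # boundary never leak into the perisaccadic response
            keep = w.times_ms >= align
            seg = ErpWaveform(w.times_ms[keep], w.values[:, keep], level_id,
                              cond, list(w.unit_labels))
            filt = lfp(seg, band=band)
            filt.align_ms = align
            waves[(cond, level_id)] = filt

    diffs: dict = {}
    for cond in records:
        if cond == "standard":
            continue
        for level_id in (0, 1):
            diffs[(cond, level_id)] = difference_waveform(
                waves[(cond, level_id)], waves[("standard", level_id)])
    if "both" in records and "global" in records and "local" in records:
        for level_id in (0, 1):
            # (both - global) - (local - standard): the interaction
            diffs[("interaction", level_id)] = difference_waveform(
                difference_waveform(waves[("both", level_id)],
                                    waves[("global", level_id)]),
                diffs[("local", level_id)])

    rows = []
    for (cond, level_id), wave in diffs.items():
        lat, amp = peak_latency(wave, window_ms, polarity="absmax")
        rows.append({"condition": cond, "level": str(level_id + 1),
                     "latency_ms": lat, "amplitude": amp,
                     "above_half_max_ms": above_half_max_ms(wave, window_ms)})
    conds = {c for (c, _) in diffs}
    for cond in sorted(conds):
        combined = ErpWaveform(
            diffs[(cond, 0)].times_ms.copy(),
            np.vstack([diffs[(cond, 0)].values, diffs[(cond, 1)].values]),
            0, cond, align_ms=diffs[(cond, 0)].align_ms)
        lat, amp = peak_latency(combined, window_ms, polarity="absmax")
        rows.append({"condition": cond, "level": "1+2", "latency_ms": lat,
                     "amplitude": amp,
                     "above_half_max_ms": above_half_max_ms(combined, window_ms)})
    # early deflection of the standard (unviolated) first-level response
    n1_lat, n1_amp = peak_latency(waves[("standard", 0)], (0.0, 150.0),
                                  polarity="absmax")
    rows.append({"condition": "standard", "level": "1", "latency_ms": n1_lat,
                 "amplitude": n1_amp,
                 "above_half_max_ms": above_half_max_ms(
                     waves[("standard", 0)], (0.0, 150.0))})
    table = pd.DataFrame(rows)
    return {"align_ms": align, "waveforms": waves, "differences": diffs,
            "latencies": table}


# ---------------------------------------------------------------------------
# validation harness (engine vs exact enumeration)


def random_micro_model(rng: np.random.Generator, max_states: int = 4,
                       max_outcomes: int = 5, n_modalities: int = 1) -> LevelModel:
    """A random static single-factor model (one time step, one policy)."""
    S = int(rng.integers(2, max_states + 1))
    A = []
    modalities = []
    for m in range(n_modalities):
        O = int(rng.integers(2, max_outcomes + 1))
        tab = rng.random((O, S)) + 0.05
        tab /= tab.sum(axis=0)
        A.append(LikelihoodArray(m, tab))
        modalities.append(O)
    D = rng.random(S) + 0.05
    return LevelModel(
        factors=[S], modalities=modalities, A=A,
        B=[TransitionArray(0, np.eye(S)[None])],
        C=[PreferenceArray(m, np.zeros(modalities[m])) for m in range(n_modalities)],
        D=[InitialLink(0, D / D.sum())],
        policies=[Policy(0, [0])], horizon=1,
    )


def exact_static_posterior(level: LevelModel, obs: Sequence[int]) -> np.ndarray:
    """Enumeration oracle: exact Bayes posterior of a static single-factor
    model given one observed outcome per modality."""
    post = np.asarray(level.D[0].table, dtype=float).copy()
    for m, o in enumerate(obs):
        post = post * level.A[m].table[o]
    return normalize(post)


def validate_engine(n_models: int = 100, seed: int = 0, kappa: float = 0.25,
                    n_iterations: int = 16) -> dict:
    """Run the enumeration oracle against the engine on random
    micro-models; report posterior errors and free-energy descent."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    descent_violations = 0
    min_epistemic = np.inf
    max_decomp_gap = 0.0
    errors = []
    for _ in range(max(0, n_models)):
        level = random_micro_model(rng)
        obs_idx = [int(rng.integers(level.modalities[m]))
                   for m in range(level.n_modalities)]
        obs = [[np.eye(level.modalities[m])[obs_idx[m]]
                for m in range(level.n_modalities)]]
        bs = init_beliefs(level)
        trace = update_epoch(level, bs, obs, n_iterations=n_iterations,
                             kappa=kappa)
        exact = exact_static_posterior(level, obs_idx)
        err = float(np.max(np.abs(bs.s_bar[0][0] - exact)))
        errors.append(err)
        max_err = max(max_err, err)
        f = trace.f_avg
        if np.any(np.diff(f) > 1e-6):
            descent_violations += 1
        rep = bs.report
        if rep is not None and rep.epistemic.size:
            min_epistemic = min(min_epistemic, float(rep.epistemic.min()))
            gap = np.abs((rep.risk + rep.ambiguity)
                         + (rep.epistemic + rep.pragmatic)).max()
            max_decomp_gap = max(max_decomp_gap, float(gap))
    return {
        "n_models": int(n_models),
        "seed": int(seed),
        "kappa": kappa,
        "n_iterations": n_iterations,
        "max_posterior_error": max_err,
        "mean_posterior_error": float(np.mean(errors)) if errors else 0.0,
        "descent_violations": descent_violations,
        "min_epistemic": None if not np.isfinite(min_epistemic) else min_epistemic,
        "max_decomposition_gap": max_decomp_gap,
        "ok": bool(descent_violations == 0 and max_err < 1e-2),
    }


# ---------------------------------------------------------------------------
# exports


def export_trial(record: TrialRecord, out_dir, config: Optional[ReadingConfig] = None,
                 seed: int = 0, name: str = "reading") -> ExperimentManifest:
    """Write the trial record as delimited-text tables plus a manifest."""
    config = config or ReadingConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = ExperimentManifest(
        experiment=name, seed=seed, conditions=["standard"],
        parameters=_parameters(config))

    sacc = pd.DataFrame(record.saccade_log)
    sacc_path = out / f"{name}_saccades.tsv"
    sacc.to_csv(sacc_path, sep="\t", index=False)
    manifest.add_file(sacc_path)

    rows = []
    for rec, trace in zip(record.epochs, record.traces):
        for n, s0 in enumerate(trace.s0):
            for it in range(s0.shape[0]):
                for unit in range(s0.shape[1]):
                    rows.append({
                        "level": rec.level_id + 1, "epoch": rec.label,
                        "factor": n, "unit": unit,
                        "iteration": rec.start_iter + it,
                        "ms": trace.ms[it], "firing": s0[it, unit],
                    })
    trace_path = out / f"{name}_trace.tsv"
    pd.DataFrame(rows).to_csv(trace_path, sep="\t", index=False)
    manifest.add_file(trace_path)

    summary_path = out / f"{name}_summary.json"
    summary_path.write_text(json.dumps(trial_summary(record, config), indent=2))
    manifest.add_file(summary_path)
    manifest.write(out / f"{name}_manifest.json")
    return manifest
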