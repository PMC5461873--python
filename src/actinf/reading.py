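"""The two-level reading model.

A simulated subject categorises four-word sentences as *happy* or *sad*
narratives.  Each word is a 2x2 visual scene of letters (icons): if the
bird and the cat share a row the word is *flee*; if the bird is next to
the seed it is *feed*; if bird and seed occupy diagonal quadrants it is
*wait*.  Two spatial transformations provide local feature context: a
vertical flip (swapping rows; think upper- versus lower-case font) and a
horizontal flip (swapping columns; the word reads the same either way,
like a palindrome).  A narrative is happy iff neither of its last two
words is *flee*.

The higher level entertains six candidate sentences, tracks which word is
being examined, and holds a decision state (undecided / happy / sad)
whose report actions elicit right/wrong feedback; being wrong carries a
log preference of -4 nats (about 54 times less likely a priori than
neutral feedback), which is what makes the subject forage for evidence
before committing.  The lower level infers the current word, the fixated
quadrant and the two flips from foveal letter samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from copy import deepcopy
from typing import List, Optional, Tuple

import numpy as np
import yaml

from ._math import normalize, one_hot
from .model import (DeepModel, InitialLink, LevelModel, LikelihoodArray,
                    LinkMap, Policy, PreferenceArray, TransitionArray,
                    one_hot_table)
from .scheduler import TrialStimuli

__all__ = [
    "WORDS", "LETTERS", "ReadingConfig", "WordLayout", "word_layout",
    "build_reading_model", "apply_violation", "exemplar_stimuli",
    "sample_stimuli", "save_config", "load_config",
]

WORDS: Tuple[str, ...] = ("flee", "feed", "wait")
LETTERS: Tuple[str, ...] = ("bird", "cat", "seed", "null")
FEEDBACK: Tuple[str, ...] = ("nothing", "right", "wrong")
DECISIONS: Tuple[str, ...] = ("undecided", "happy", "sad")

#: canonical (no-flip) quadrant contents; quadrants are (upper-left,
#: upper-right, lower-left, lower-right).  flee: cat next to bird in the
#: upper row; feed: bird next to seed in the upper row; wait: bird and
#: seed in diagonal quadrants (upper-right / lower-left), so the other
#: diagonal is empty.
_CANONICAL = {
    "flee": ("cat", "bird", "null", "null"),
    "feed": ("bird", "seed", "null", "null"),
    "wait": ("null", "bird", "seed", "null"),
}

#: default sentence inventory.  Only the first sentence is fixed by the
#: task description; the rest are chosen so that (i) every sentence
#: begins with flee or wait and every second word is flee or wait,
#: (ii) sentence 4 shares its first three words with sentence 1 and ends
#' with flee (so the 1-vs-4 ambiguity survives to the last word),
#: (iii) after any partial reading the surviving candidates are of one
#: category only when a single candidate survives (the subject can never
#: be sure of the category while unsure of the sentence), and
#: (iv) happy and sad narratives are balanced 3/3.
DEFAULT_SENTENCES: Tuple[Tuple[str, ...], ...] = (
    ("flee", "wait", "feed", "wait"),
    ("wait", "flee", "wait", "feed"),
    ("wait", "wait", "flee", "wait"),
    ("flee", "wait", "feed", "flee"),
    ("flee", "flee", "wait", "wait"),
    ("flee", "wait", "wait", "flee"),
)


def is_happy(sentence: Tuple[str, ...]) -> bool:
    return "flee" not in sentence[-2:]


@dataclass
class WordLayout:
    """Quadrant contents of one (word, vflip, hflip) scene."""

    word: str
    vflip: bool
    hflip: bool
    quadrants: Tuple[str, str, str, str]

    def letter_at(self, quadrant: int) -> str:
        return self.quadrants[quadrant]


def word_layout(word: str, vflip: bool = False, hflip: bool = False) -> WordLayout:
    """Letter assignment of a word under the spatial flips; a vertical
    flip swaps rows, a horizontal flip swaps columns."""
    if word not in _CANONICAL:
        raise ValueError(f"unknown word {word!r}; expected one of {WORDS}")
    q = list(_CANONICAL[word])
    if vflip:
        q = [q[2], q[3], q[0], q[1]]
    if hflip:
        q = [q[1], q[0], q[3], q[2]]
    return WordLayout(word=word, vflip=bool(vflip), hflip=bool(hflip),
                      quadrants=tuple(q))


@dataclass
class ReadingConfig:
    """Task parameters of the reading simulations."""

    sentences: tuple = DEFAULT_SENTENCES
    happy_set: Optional[tuple] = None          # derived from sentences if None
    wrong_log_pref: float = -4.0               # nats; exp(4) ~ 54x less likely
    p_no_vflip: float = 7.0 / 8.0              # strong prior on lower case
    hflip_prior: tuple = (0.5, 0.5)            # palindromic invariance
    violation: str = "none"                    # none | local | global | both
    global_factor: float = 8.0
    threshold_nats: float = 1.0 / 512.0
    kappa: float = 0.25
    iterations_per_step: int = 16
    ms_per_iteration: float = 16.0
    horizon_words: int = 4
    decision_epochs: int = 2
    saccades_per_word: int = 4

    def __post_init__(self):
        self.sentences = tuple(tuple(s) for s in self.sentences)
        self.hflip_prior = tuple(float(p) for p in self.hflip_prior)
        for i, s in enumerate(self.sentences):
            if len(s) != self.horizon_words:
                raise ValueError(f"sentence {i + 1} has {len(s)} words")
            if s[0] not in ("flee", "wait"):
                raise ValueError(f"sentence {i + 1} must begin with flee or wait")
            if any(w not in WORDS for w in s):
                raise ValueError(f"sentence {i + 1} contains an unknown word")
        derived = tuple(i for i, s in enumerate(self.sentences) if is_happy(s))
        if self.happy_set is None:
            self.happy_set = derived
        elif tuple(sorted(self.happy_set)) != derived:
            raise ValueError(
                "happy_set must contain exactly the sentences whose last two "
                "words avoid flee")
        if self.violation not in ("none", "local", "global", "both"):
            raise ValueError(f"unknown violation kind {self.violation!r}")

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    @property
    def top_horizon(self) -> int:
        return self.horizon_words + self.decision_epochs


def _word_tensor(config: ReadingConfig) -> np.ndarray:
    """p(word | sentence, position): deterministic from the inventory."""
    return one_hot_table(
        len(WORDS), (config.n_sentences, config.horizon_words),
        lambda s, p: WORDS.index(config.sentences[s][p]))


def build_reading_model(config: Optional[ReadingConfig] = None) -> DeepModel:
    """Construct the two-level generative model of the reading task."""
    config = config or ReadingConfig()
    n_sent, n_words = config.n_sentences, config.horizon_words
    word_tab = _word_tensor(config)

    # --- level 2: sentence (n), word position (4), decision (3) ----------
    f2 = [n_sent, n_words, 3]
    m2 = [len(WORDS), n_words, len(FEEDBACK)]
    # word evidence: independent of the decision state
    a_word = np.zeros((len(WORDS), n_sent, n_words, 3))
    for d in range(3):
        a_word[:, :, :, d] = word_tab
    a_loc = one_hot_table(n_words, (n_sent, n_words, 3), lambda s, p, d: p)

    def fb_rule(s, p, d):
        if d == 0:
            return FEEDBACK.index("nothing")
        reported_happy = (d == 1)
        truly_happy = s in config.happy_set
        return FEEDBACK.index("right" if reported_happy == truly_happy else "wrong")

    a_fb = one_hot_table(len(FEEDBACK), (n_sent, n_words, 3), fb_rule)

    ident = lambda n: np.eye(n)
    b_sent = TransitionArray(0, np.stack([ident(n_sent)] * 3))
    advance = np.zeros((n_words, n_words))
    for p in range(n_words):
        advance[min(p + 1, n_words - 1), p] = 1.0
    b_pos = TransitionArray(1, np.stack([advance, ident(n_words), ident(n_words)]))
    # report actions move undecided to the reported category; categories
    # themselves are absorbing
    to_happy = np.array([[0., 0., 0.], [1., 1., 0.], [0., 0., 1.]])
    to_sad = np.array([[0., 0., 0.], [0., 1., 0.], [1., 0., 1.]])
    b_dec = TransitionArray(2, np.stack([ident(3), to_happy, to_sad]))

    c_word = PreferenceArray(0, np.zeros(len(WORDS)))
    c_loc = PreferenceArray(1, np.zeros(n_words))
    c_fb = PreferenceArray(2, np.array([0.0, 0.0, config.wrong_log_pref]))

    sent_prior = np.full(n_sent, 1.0 / n_sent)
    d2 = [
        InitialLink(0, sent_prior),
        InitialLink(1, one_hot(0, n_words)),
        InitialLink(2, one_hot(0, 3)),
    ]
    level2 = LevelModel(
        factors=f2, modalities=m2,
        A=[LikelihoodArray(0, a_word), LikelihoodArray(1, a_loc),
           LikelihoodArray(2, a_fb)],
        B=[b_sent, b_pos, b_dec],
        C=[c_word, c_loc, c_fb], D=d2,
        policies=[Policy(i, [i]) for i in range(3)],
        horizon=config.top_horizon,
        iterations_per_step=config.iterations_per_step,
        ms_per_iteration=config.ms_per_iteration,
        factor_names=["sentence", "word_position", "decision"],
        modality_names=["word", "word_location", "feedback"],
        action_names=["next word", "report happy", "report sad"],
    )

    # --- level 1: word (3), letter location (4), vflip (2), hflip (2) ----
    f1 = [len(WORDS), 4, 2, 2]
    m1 = [len(LETTERS), 4]
    a_letter = one_hot_table(
        len(LETTERS), tuple(f1),
        lambda w, q, v, h: LETTERS.index(word_layout(WORDS[w], bool(v), bool(h)).letter_at(q)))
    a_prop = one_hot_table(4, tuple(f1), lambda w, q, v, h: q)

    saccade = np.zeros((4, 4, 4))
    for u in range(4):
        saccade[u, u, :] = 1.0
    b1 = [
        TransitionArray(0, np.stack([ident(3)] * 4)),
        TransitionArray(1, saccade),
        TransitionArray(2, np.stack([ident(2)] * 4)),
        TransitionArray(3, np.stack([ident(2)] * 4)),
    ]
    vflip_cols = np.tile(np.array([[config.p_no_vflip], [1 - config.p_no_vflip]]),
                         (1, n_words))
    d1 = [
        InitialLink(0, word_tab, parent_factors=(0, 1)),
        InitialLink(1, one_hot(0, 4)),
        InitialLink(2, vflip_cols, parent_factors=(1,)),
        InitialLink(3, np.asarray(config.hflip_prior, dtype=float)),
    ]
    level1 = LevelModel(
        factors=f1, modalities=m1,
        A=[LikelihoodArray(0, a_letter), LikelihoodArray(1, a_prop)],
        B=b1,
        C=[PreferenceArray(0, np.zeros(len(LETTERS))),
           PreferenceArray(1, np.zeros(4))],
        D=d1,
        policies=[Policy(i, [i]) for i in range(4)],
        horizon=config.saccades_per_word,
        iterations_per_step=config.iterations_per_step,
        ms_per_iteration=config.ms_per_iteration,
        factor_names=["word", "letter_location", "vflip", "hflip"],
        modality_names=["letter", "letter_location"],
        action_names=[f"saccade to quadrant {q + 1}" for q in range(4)],
    )

    model = DeepModel(levels=[level1, level2],
                      links=[LinkMap(evidence_factor=0, evidence_modality=0), None])
    if config.violation != "none":
        model = apply_violation(model, config.violation, config)
    return model


def apply_violation(model: DeepModel, kind: str,
                    config: Optional[ReadingConfig] = None) -> DeepModel:
    """Return a copy of the model with violated prior beliefs.

    local  -- the vertical-flip prior is reversed for, and only for, the
              last word (the D link conditions on word position);
    global -- the prior probability of the first sentence is decreased by
              ``global_factor`` (then renormalised);
    both   -- both manipulations;  none -- an identical copy.

    Stimuli and actions are never touched here: violated runs replay the
    standard trial's stimuli and actions under these different priors.
    """
    config = config or ReadingConfig()
    if kind not in ("none", "local", "global", "both"):
        raise ValueError(f"unknown violation kind {kind!r}")
    out = deepcopy(model)
    if kind in ("local", "both"):
        d_vflip = out.levels[0].D[2]
        d_vflip.table[:, -1] = d_vflip.table[::-1, -1].copy()
    if kind in ("global", "both"):
        d_sent = out.levels[1].D[0]
        d_sent.table[0] /= config.global_factor
        d_sent.table = normalize(d_sent.table)
    return out


# ---------------------------------------------------------------------------
# stimuli


def exemplar_stimuli(config: Optional[ReadingConfig] = None) -> TrialStimuli:
    """The exemplar trial: sentence 1 presented in lower case except the
    second word, whose vertical flip makes it upper case (its horizontal
    flip is also on, which leaves both case and meaning unchanged but
    places its letters on the occupied diagonal)."""
    config = config or ReadingConfig()
    flips = [(0, 0)] * config.horizon_words
    flips[1] = (1, 1)
    return TrialStimuli(
        top_states={0: 0, 1: 0, 2: 0},
        lower_states=[{2: v, 3: h} for v, h in flips],
    )


def sample_stimuli(config: ReadingConfig, seed: int) -> TrialStimuli:
    """Draw a trial's true states from the generative priors."""
    rng = np.random.default_rng(seed)
    sentence = int(rng.integers(config.n_sentences))
    flips = [{2: int(rng.random() < (1 - config.p_no_vflip)),
              3: int(rng.random() < config.hflip_prior[1])}
             for _ in range(config.horizon_words)]
    return TrialStimuli(top_states={0: sentence, 1: 0, 2: 0}, lower_states=flips)


# ---------------------------------------------------------------------------
# config serialization (same plain-text dialect as the model store)


def save_config(config: ReadingConfig, path) -> None:
    d = {
        "sentences": [list(s) for s in config.sentences],
        "wrong_log_pref": config.wrong_log_pref,
        "p_no_vflip": config.p_no_vflip,
        "hflip_prior": list(config.hflip_prior),
        "violation": config.violation,
        "global_factor": config.global_factor,
        "threshold_nats": config.threshold_nats,
        "kappa": config.kappa,
        "iterations_per_step": config.iterations_per_step,
        "ms_per_iteration": config.ms_per_iteration,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_config(path) -> ReadingConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ReadingConfig(**d)
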