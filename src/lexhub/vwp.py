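"""Pre-test battery and the Visual World Paradigm simulation harness.

After training, the model is (1) pre-tested on all four training tasks —
comprehension tasks are scored by cosine-nearest-neighbor classification
of the final semantic activation, orienting tasks by whether the eye unit
of the target's location is the most active — and (2) run through six VWP
display conditions.  A display holds four items; the spoken word's visual
referent is present (TP) or absent (TA), and the displayed competitors
overlap the spoken target visually, semantically (near + far neighbor) or
phonologically (onset + rhyme competitor).

In a test trial the display is visible from tick 0 and the target's speech
starts at tick 5 (one phoneme slot per tick), leaving the first five ticks
for visual pre-processing.  Gaze is read out each tick as the Luce ratio
of the four eye units.  Each condition crosses every target set with all
24 spatial arrangements of its four display items.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .network import Network, Trial, run_trial
from .training import (
    TRAIN_TICKS,
    NoiseSpec,
    _display_vision,
    _one_hot,
    ambient_vector,
    staggered_phonology,
)

__all__ = [
    "SPEECH_ONSET",
    "CONDITIONS",
    "CONDITION_ROLES",
    "Display",
    "FixationRecord",
    "PretestResult",
    "luce_ratio",
    "build_displays",
    "run_vwp_trial",
    "run_condition",
    "pretest_comprehension",
    "pretest_orienting",
    "pretest_all",
]

SPEECH_ONSET = 5  # tick at which the first phoneme of the spoken target appears
DEFAULT_TEST_TICKS = 30

#: display composition per condition (role of each of the four display items)
CONDITION_ROLES = {
    "visual_TP": ("target", "visual_comp", "distractor", "distractor"),
    "visual_TA": ("visual_comp", "distractor", "distractor", "distractor"),
    "semantic_TP": ("target", "near_sem", "far_sem", "distractor"),
    "semantic_TA": ("near_sem", "far_sem", "distractor", "distractor"),
    "phon_TP": ("target", "onset_comp", "rhyme_comp", "distractor"),
    "phon_TA": ("onset_comp", "rhyme_comp", "distractor", "distractor"),
}

CONDITIONS = tuple(CONDITION_ROLES)


@dataclass(frozen=True)
class Display:
    """One spatial arrangement of four items for a given condition."""

    condition: str
    set_id: int
    permutation: int  # 0..23
    item_ids: tuple   # item id per location 0..3
    roles: tuple      # role label per location
    target_word: int  # spoken word (the set's target item, even when absent)


@dataclass
class FixationRecord:
    """Per-tick Luce ratios of the four eye units for one display."""

    display: Display
    ratios: np.ndarray  # (T_test, 4), one column per location
    speech_onset: int = SPEECH_ONSET
    instantiation: int = 0

    @property
    def T(self) -> int:
        return self.ratios.shape[0]

    def role_mean(self, role: str, window=None) -> float:
        """Mean ratio for a role over a tick window (duplicates averaged)."""
        cols = [i for i, r in enumerate(self.display.roles) if r == role]
        if not cols:
            raise ValueError(f"role {role!r} absent from {self.display.condition}")
        lo, hi = window if window is not None else (0, self.T)
        return float(self.ratios[lo:hi, cols].mean())


def luce_ratio(activations) -> np.ndarray:
    """Normalise eye activations to a probability vector (Luce choice rule).

    An all-zero vector maps to the uniform distribution; negative input is
    a contract violation.
    """
    a = np.asarray(activations, dtype=float)
    if (a < 0).any():
        raise ValueError("Luce ratio requires non-negative activations")
    s = a.sum(axis=-1, keepdims=True)
    uniform = np.full_like(a, 1.0 / a.shape[-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, a / np.where(s > 0, s, 1.0), uniform)
    return out


def build_displays(corpus: Corpus, condition: str, seed: int = 0) -> list:
    """All 24 spatial permutations of each target set's display items.

    Distractors are drawn from the corpus fillers (unrelated to every item
    by construction), without replacement within a display, deterministic
    per (set, condition, seed).
    """
    if condition not in CONDITION_ROLES:
        raise ValueError(f"unknown condition {condition!r}")
    roles = CONDITION_ROLES[condition]
    filler_ids = [it.id for it in corpus.fillers]
    n_distract = roles.count("distractor")
    if len(filler_ids) < n_distract:
        raise ValueError("not enough fillers to draw display distractors")
    displays = []
    for ts in corpus.target_sets:
        set_id = corpus.item(ts["target"]).set_id
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, CONDITIONS.index(condition), set_id])
        )
        distractors = list(rng.choice(filler_ids, size=n_distract, replace=False))
        base = []
        for role in roles:
            base.append(int(distractors.pop()) if role == "distractor" else ts[role])
        for p, perm in enumerate(itertools.permutations(range(4))):
            displays.append(
                Display(
                    condition=condition,
                    set_id=set_id,
                    permutation=p,
                    item_ids=tuple(base[j] for j in perm),
                    roles=tuple(roles[j] for j in perm),
                    target_word=ts["target"],
                )
            )
    return displays


def run_vwp_trial(
    net: Network,
    corpus: Corpus,
    display: Display,
    T_test: int = DEFAULT_TEST_TICKS,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
) -> FixationRecord:
    """Simulate one display: visual scene from tick 0, speech from tick 5.

    Pre-onset phoneme slots carry ambient noise; the spoken form is always
    the uncorrupted canonical phonology (training noise never applies at
    test).  Semantics and eye run free; Luce ratios are recorded per tick.
    """
    if T_test < SPEECH_ONSET + corpus.config.word_len:
        raise ValueError("T_test too short for the speech signal to complete")
    noise = noise or NoiseSpec()
    rng = rng if rng is not None else np.random.default_rng(0)
    cc = corpus.config
    slots = corpus.inventory.encode_word(
        corpus.item(display.target_word).phonology
    ).reshape(cc.word_len, cc.phon_features)
    trial = Trial(
        T=T_test,
        vision=_display_vision(corpus, display.item_ids, T_test),
        phonology=staggered_phonology(
            slots,
            T_test,
            onset=SPEECH_ONSET,
            ambient=ambient_vector(cc.phon_dim, noise, rng),
        ),
        task="vwp",
        meta={"display": display},
    )
    hist = run_trial(net, trial)
    return FixationRecord(display=display, ratios=luce_ratio(hist.eye))


def run_condition(
    net: Network,
    corpus: Corpus,
    condition: str,
    T_test: int = DEFAULT_TEST_TICKS,
    seed: int = 0,
    noise: NoiseSpec | None = None,
    instantiation: int = 0,
) -> list:
    """All displays of a condition (n_sets x 24 records); deterministic per seed."""
    displays = build_displays(corpus, condition, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101, CONDITIONS.index(condition)]))
    records = []
    for d in displays:
        rec = run_vwp_trial(net, corpus, d, T_test=T_test, noise=noise, rng=rng)
        rec.instantiation = instantiation
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# pre-test battery
# ---------------------------------------------------------------------------


@dataclass
class PretestResult:
    """Accuracy of one training task over the whole corpus."""

    task: str
    accuracy: float
    n_trials: int
    per_item: dict = field(default_factory=dict)  # item id -> (n_correct, n_trials)
    at_least_3_of_4: float | None = None  # orienting tasks only
    ties: int = 0


def _nearest_semantic(corpus: Corpus, activation: np.ndarray):
    """Cosine-nearest corpus item for a semantic activation; ties flagged."""
    M = corpus.semantic_matrix()
    norms = np.linalg.norm(M, axis=1) * np.linalg.norm(activation)
    sims = (M @ activation) / norms
    best = float(sims.max())
    winners = np.flatnonzero(sims == best)
    return int(winners[0]), len(winners) > 1


def pretest_comprehension(
    net: Network,
    corpus: Corpus,
    task: str,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    T: int = TRAIN_TICKS,
) -> PretestResult:
    """Score vis->sem or phon->sem mapping by nearest-neighbor classification.

    Noise fills every slot that carries no target-related input.  For the
    visual task the target is tested once in each of the four locations;
    classification ties count as errors.
    """
    if task not in ("vis_to_sem", "phon_to_sem"):
        raise ValueError(f"not a comprehension task: {task!r}")
    noise = noise or NoiseSpec()
    test_noise = NoiseSpec(noise.ambient_low, noise.ambient_high, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cc = corpus.config
    per_item = {}
    n_correct = n_total = ties = 0
    for item in corpus.items:
        correct = []
        if task == "vis_to_sem":
            for loc in range(4):
                vision = ambient_vector(4 * cc.visual_features, test_noise, rng)
                a, b = loc * cc.visual_features, (loc + 1) * cc.visual_features
                vision[a:b] = item.visual
                trial = Trial(
                    T=T,
                    vision=np.tile(vision, (T, 1)),
                    phonology=np.tile(ambient_vector(cc.phon_dim, test_noise, rng), (T, 1)),
                    eye_clamp=_one_hot(loc),
                    eye_clamp_on=np.ones(T, dtype=bool),
                    task=task,
                )
                hist = run_trial(net, trial)
                pred, tie = _nearest_semantic(corpus, hist.semantics[-1])
                ties += tie
                correct.append(pred == item.id and not tie)
        else:
            slots = corpus.inventory.encode_word(item.phonology).reshape(
                cc.word_len, cc.phon_features
            )
            trial = Trial(
                T=T,
                vision=np.tile(ambient_vector(4 * cc.visual_features, test_noise, rng), (T, 1)),
                phonology=staggered_phonology(
                    slots, T, onset=0, ambient=ambient_vector(cc.phon_dim, test_noise, rng)
                ),
                task=task,
            )
            hist = run_trial(net, trial)
            pred, tie = _nearest_semantic(corpus, hist.semantics[-1])
            ties += tie
            correct.append(pred == item.id and not tie)
        per_item[item.id] = (sum(correct), len(correct))
        n_correct += sum(correct)
        n_total += len(correct)
    return PretestResult(
        task=task,
        accuracy=n_correct / n_total,
        n_trials=n_total,
        per_item=per_item,
        ties=ties,
    )


def pretest_orienting(
    net: Network,
    corpus: Corpus,
    task: str,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    T: int = TRAIN_TICKS,
) -> PretestResult:
    """Score phon->loc or sem->loc orienting over the whole corpus.

    Each item is tested once per location among three randomly drawn
    co-displayed items; a trial is correct when the eye unit of the
    target's location is strictly maximal at the final tick.  Reports
    overall accuracy and the fraction of items correct on at least 3 of
    their 4 trials.
    """
    if task not in ("phon_to_loc", "sem_to_loc"):
        raise ValueError(f"not an orienting task: {task!r}")
    noise = noise or NoiseSpec()
    test_noise = NoiseSpec(noise.ambient_low, noise.ambient_high, 0.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    cc = corpus.config
    per_item = {}
    n_correct = n_total = ties = 0
    n_good_items = 0
    other_ids = np.arange(len(corpus))
    for item in corpus.items:
        correct = []
        for loc in range(4):
            others = rng.choice(other_ids[other_ids != item.id], size=3, replace=False)
            ids = list(others)
            ids.insert(loc, item.id)
            if task == "phon_to_loc":
                slots = corpus.inventory.encode_word(item.phonology).reshape(
                    cc.word_len, cc.phon_features
                )
                trial = Trial(
                    T=T,
                    vision=_display_vision(corpus, ids, T),
                    phonology=staggered_phonology(
                        slots, T, onset=0,
                        ambient=ambient_vector(cc.phon_dim, test_noise, rng),
                    ),
                    task=task,
                )
            else:
                trial = Trial(
                    T=T,
                    vision=_display_vision(corpus, ids, T),
                    phonology=np.tile(
                        ambient_vector(cc.phon_dim, test_noise, rng), (T, 1)
                    ),
                    sem_clamp=item.semantic_vector(cc.sem_features),
                    sem_clamp_on=np.ones(T, dtype=bool),
                    task=task,
                )
            eye = run_trial(net, trial).eye[-1]
            top = eye.max()
            tie = (eye == top).sum() > 1
            ties += tie
            correct.append(bool(eye[loc] == top and not tie))
        per_item[item.id] = (sum(correct), len(correct))
        n_correct += sum(correct)
        n_total += len(correct)
        n_good_items += sum(correct) >= 3
    return PretestResult(
        task=task,
        accuracy=n_correct / n_total,
        n_trials=n_total,
        per_item=per_item,
        at_least_3_of_4=n_good_items / len(corpus.items),
        ties=ties,
    )


def pretest_all(net: Network, corpus: Corpus, noise=None, seed: int = 0) -> dict:
    """Run the full four-task pre-test battery; returns task -> PretestResult."""
    return {
        "vis_to_sem": pretest_comprehension(net, corpus, "vis_to_sem", noise, seed),
        "phon_to_sem": pretest_comprehension(net, corpus, "phon_to_sem", noise, seed),
        "phon_to_loc": pretest_orienting(net, corpus, "phon_to_loc", noise, seed),
        "sem_to_loc": pretest_orienting(net, corpus, "sem_to_loc", noise, seed),
    }
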