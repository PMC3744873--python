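"""The four cross-modal training tasks, noise regimes, and the training loop.

Each trial spans 15 ticks (0–14).  Tick 0 carries the initial inputs; error
masks open once activation has had time to propagate:

===================  ======================  =========================  ==================
task                 phonology               semantics                  eye
===================  ======================  =========================  ==================
vision -> semantics  ambient noise           target, ticks 3–14         input (clamped)
phonology -> sem.    staggered speech        target, ticks 5–14         unconstrained
phonology -> loc.    staggered speech        unconstrained              target, ticks 5–14
semantics -> loc.    ambient noise           input (clamped), 0–14      target, ticks 2–14
===================  ======================  =========================  ==================

Speech unfolds one phoneme slot per tick; the fifth tick (when the fourth
phoneme — the uniqueness point relative to an onset competitor — has been
heard) opens the error window of the phonologically driven tasks.
Phonologically driven orienting is sampled four times less often than the
other tasks.  In the noisy regime each bit of the phonological form is
flipped with probability 0.2, freshly per training trial, on the input
side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus
from .network import Network, NetworkConfig, Trial, apply_update, bptt_gradients

__all__ = [
    "TRAIN_TICKS",
    "NoiseSpec",
    "TaskSchedule",
    "TASKS",
    "network_config_for",
    "ambient_vector",
    "staggered_phonology",
    "corrupt_phonology",
    "build_trial",
    "build_trial_vis_to_sem",
    "build_trial_phon_to_sem",
    "build_trial_phon_to_loc",
    "build_trial_sem_to_loc",
    "sample_task",
    "train",
]

TRAIN_TICKS = 15  # recorded states, ticks 0-14

TASKS = ("vis_to_sem", "phon_to_sem", "phon_to_loc", "sem_to_loc")

# first tick of the error window per task (inclusive; runs to the last tick)
ERROR_ONSET = {
    "vis_to_sem": 3,
    "phon_to_sem": 5,
    "phon_to_loc": 5,
    "sem_to_loc": 2,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Input-noise parameters.

    ``ambient_low``/``ambient_high`` bound the uniform, time-invariant
    background noise fed to slots carrying no target-related signal.
    ``phon_flip_p`` is the per-bit flip probability applied to the
    phonological form in the noisy training regime (0 disables it).
    """

    ambient_low: float = 0.0
    ambient_high: float = 0.1
    phon_flip_p: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.phon_flip_p <= 1.0:
            raise ValueError("phon_flip_p must be a probability")


@dataclass(frozen=True)
class TaskSchedule:
    """Relative sampling weights of the four tasks (phon->loc 4x rarer by default)."""

    weights: tuple = (4.0, 4.0, 1.0, 4.0)  # order of TASKS

    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("schedule weights must be positive")
        return w / w.sum()


def network_config_for(corpus: Corpus, n_hub: int = 400, loss: str = "sse") -> NetworkConfig:
    """Network layer sizes matching a corpus's representation sizes."""
    cc = corpus.config
    return NetworkConfig(
        n_slots=4,
        visual_per_slot=cc.visual_features,
        word_len=cc.word_len,
        phon_per_slot=cc.phon_features,
        n_sem=cc.sem_features,
        n_eye=4,
        n_hub=n_hub,
        loss=loss,
    )


def ambient_vector(n: int, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Time-invariant background noise: one uniform draw per unit per trial."""
    return rng.uniform(noise.ambient_low, noise.ambient_high, size=n)


def corrupt_phonology(
    phon: np.ndarray, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit of a binary phonological pattern independently with prob. p."""
    phon = np.asarray(phon)
    flips = rng.random(phon.shape) < p
    return np.where(flips, 1 - phon, phon)


def staggered_phonology(
    slots: np.ndarray,
    T: int,
    onset: int,
    ambient: np.ndarray,
) -> np.ndarray:
    """Unfold a word one phoneme slot per tick.

    ``slots`` is (word_len, features_per_slot); slot k carries its phoneme
    from tick ``onset + k`` onward and ``ambient`` noise before that.
    Returns a (T, word_len * features) input stream.
    """
    word_len, F = slots.shape
    amb = np.asarray(ambient).reshape(word_len, F)
    P = np.empty((T, word_len * F))
    for k in range(word_len):
        col = slice(k * F, (k + 1) * F)
        start = min(onset + k, T)
        P[:start, col] = amb[k]
        P[start:, col] = slots[k]
    return P


def _display_vision(corpus: Corpus, item_ids, T: int) -> np.ndarray:
    v = np.concatenate([np.asarray(corpus.item(i).visual, dtype=float) for i in item_ids])
    return np.tile(v, (T, 1))


def _one_hot(loc: int, n: int = 4) -> np.ndarray:
    v = np.zeros(n)
    v[loc] = 1.0
    return v


def _window(T: int, start: int) -> np.ndarray:
    m = np.zeros(T, dtype=bool)
    m[start:] = True
    return m


def _phon_slots(corpus: Corpus, item_id: int, noise: NoiseSpec, rng) -> np.ndarray:
    """Per-slot feature encoding of a word, bit-corrupted in the noisy regime."""
    cc = corpus.config
    enc = corpus.inventory.encode_word(corpus.item(item_id).phonology)
    if noise.phon_flip_p > 0:
        enc = corrupt_phonology(enc, noise.phon_flip_p, rng)
    return enc.reshape(cc.word_len, cc.phon_features)


def build_trial_vis_to_sem(
    corpus: Corpus, rng: np.random.Generator, noise: NoiseSpec, T: int = TRAIN_TICKS
) -> Trial:
    items = rng.choice(len(corpus), size=4, replace=False)
    loc = int(rng.integers(4))
    target = corpus.item(int(items[loc]))
    cc = corpus.config
    return Trial(
        T=T,
        vision=_display_vision(corpus, items, T),
        phonology=np.tile(ambient_vector(cc.phon_dim, noise, rng), (T, 1)),
        eye_clamp=_one_hot(loc),
        eye_clamp_on=np.ones(T, dtype=bool),
        sem_target=target.semantic_vector(cc.sem_features),
        sem_mask=_window(T, ERROR_ONSET["vis_to_sem"]),
        task="vis_to_sem",
        meta={"target": target.id, "loc": loc, "items": items.tolist()},
    )


def build_trial_phon_to_sem(
    corpus: Corpus, rng: np.random.Generator, noise: NoiseSpec, T: int = TRAIN_TICKS
) -> Trial:
    target = corpus.item(int(rng.integers(len(corpus))))
    cc = corpus.config
    n_vis = 4 * cc.visual_features
    slots = _phon_slots(corpus, target.id, noise, rng)
    return Trial(
        T=T,
        vision=np.tile(ambient_vector(n_vis, noise, rng), (T, 1)),
        phonology=staggered_phonology(
            slots, T, onset=0, ambient=ambient_vector(cc.phon_dim, noise, rng)
        ),
        sem_target=target.semantic_vector(cc.sem_features),
        sem_mask=_window(T, ERROR_ONSET["phon_to_sem"]),
        task="phon_to_sem",
        meta={"target": target.id},
    )


def build_trial_phon_to_loc(
    corpus: Corpus, rng: np.random.Generator, noise: NoiseSpec, T: int = TRAIN_TICKS
) -> Trial:
    items = rng.choice(len(corpus), size=4, replace=False)
    loc = int(rng.integers(4))
    target = corpus.item(int(items[loc]))
    cc = corpus.config
    slots = _phon_slots(corpus, target.id, noise, rng)
    return Trial(
        T=T,
        vision=_display_vision(corpus, items, T),
        phonology=staggered_phonology(
            slots, T, onset=0, ambient=ambient_vector(cc.phon_dim, noise, rng)
        ),
        eye_target=_one_hot(loc),
        eye_mask=_window(T, ERROR_ONSET["phon_to_loc"]),
        task="phon_to_loc",
        meta={"target": target.id, "loc": loc, "items": items.tolist()},
    )


def build_trial_sem_to_loc(
    corpus: Corpus, rng: np.random.Generator, noise: NoiseSpec, T: int = TRAIN_TICKS
) -> Trial:
    items = rng.choice(len(corpus), size=4, replace=False)
    loc = int(rng.integers(4))
    target = corpus.item(int(items[loc]))
    cc = corpus.config
    return Trial(
        T=T,
        vision=_display_vision(corpus, items, T),
        phonology=np.tile(ambient_vector(cc.phon_dim, noise, rng), (T, 1)),
        sem_clamp=target.semantic_vector(cc.sem_features),
        sem_clamp_on=np.ones(T, dtype=bool),
        eye_target=_one_hot(loc),
        eye_mask=_window(T, ERROR_ONSET["sem_to_loc"]),
        task="sem_to_loc",
        meta={"target": target.id, "loc": loc, "items": items.tolist()},
    )


_BUILDERS = {
    "vis_to_sem": build_trial_vis_to_sem,
    "phon_to_sem": build_trial_phon_to_sem,
    "phon_to_loc": build_trial_phon_to_loc,
    "sem_to_loc": build_trial_sem_to_loc,
}


def build_trial(task: str, corpus, rng, noise, T: int = TRAIN_TICKS) -> Trial:
    return _BUILDERS[task](corpus, rng, noise, T)


def sample_task(schedule: TaskSchedule, rng: np.random.Generator) -> str:
    return TASKS[int(rng.choice(len(TASKS), p=schedule.probabilities()))]


def train(
    net: Network,
    corpus: Corpus,
    n_trials: int,
    rate: float = 0.05,
    schedule: TaskSchedule | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    log_every: int = 10_000,
):
    """Online SGD over randomly interleaved tasks; deterministic per seed.

    Modifies ``net`` in place and returns ``(net, log)`` where ``log`` is a
    DataFrame of running mean masked loss per task at each logging
    interval.  Aborts with a diagnostic on non-finite loss.
    """
    schedule = schedule or TaskSchedule()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    running = {task: [] for task in TASKS}
    log_rows = []
    for i in range(n_trials):
        task = sample_task(schedule, rng)
        trial = build_trial(task, corpus, rng, noise)
        grads, loss = bptt_gradients(net, trial)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at trial {i} (task={task}); "
                f"max |W_in|={np.abs(net.W_in).max():.3g}"
            )
        apply_update(net, grads, rate)
        running[task].append(loss)
        if (i + 1) % log_every == 0:
            row = {"trial": i + 1}
            for t in TASKS:
                row[t] = float(np.mean(running[t])) if running[t] else np.nan
                running[t] = []
            log_rows.append(row)
    net.meta.update(
        {
            "trials": net.meta.get("trials", 0) + n_trials,
            "regime": "noisy" if noise.phon_flip_p > 0 else "noiseless",
            "corpus_seed": corpus.seed,
        }
    )
    return net, pd.DataFrame(log_rows)
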