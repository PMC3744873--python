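"""Artificial lexicon generation under controlled cross-modal overlap.

The model is trained and tested on a fully synthetic lexicon in which the
degree of overlap between any two words is controlled separately in three
modalities:

* **phonology** — a word is a fixed sequence of six phonemes drawn from a
  20-phoneme inventory; each phoneme is a 10-bit feature vector.  Onset
  competitors share exactly the first three phonemes with their target,
  rhyme competitors exactly the final three; unrelated words never share
  three consecutive same-position phonemes (hence never a first-four or
  final-four overlap).
* **vision** — a 20-bit feature vector.  A visual competitor copies 10
  randomly chosen feature positions from its target and shares the rest at
  chance; all other pairs share features at chance (p = 0.5).
* **semantics** — 8 active features out of 200.  Near neighbors share
  exactly 4 of the target's 8 features, far neighbors exactly 2, and every
  unrelated pair shares at most 1.

A corpus holds 20 target sets (target + onset, rhyme, visual, near- and
far-semantic competitor) plus unrelated fillers, 200 items in total by
default.  Generation is rejection sampling, deterministic given a seed;
semantic feature sets are drawn feature-by-feature with conflict masking so
that the pairwise max-1-shared-feature constraint remains satisfiable as
the corpus fills up.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorpusConfig",
    "PhonemeInventory",
    "Item",
    "Corpus",
    "ValidationReport",
    "GenerationError",
    "cosine_distance",
    "sample_phoneme_inventory",
    "generate_phonological_form",
    "make_onset_competitor",
    "make_rhyme_competitor",
    "make_visual_competitor",
    "make_semantic_neighbor",
    "assemble_corpus",
    "validate_corpus",
    "distance_summary",
    "DISTANCE_RELATIONS",
]

#: roles of the six items making up one target set, in id order
SET_ROLES = ("target", "onset_comp", "rhyme_comp", "visual_comp", "near_sem", "far_sem")

#: relations reported by :func:`distance_summary`
DISTANCE_RELATIONS = (
    "onset",
    "rhyme",
    "phon_unrelated",
    "near_sem",
    "far_sem",
    "sem_unrelated",
    "visual_comp",
    "visual_unrelated",
)


class GenerationError(RuntimeError):
    """Rejection-sampling budget exhausted while building a corpus."""


@dataclass(frozen=True)
class CorpusConfig:
    """Sizes and constraint parameters of the artificial lexicon."""

    n_sets: int = 20
    n_fillers: int = 80
    word_len: int = 6
    n_phonemes: int = 20
    phon_features: int = 10
    visual_features: int = 20
    sem_features: int = 200
    sem_active: int = 8
    near_shared: int = 4
    far_shared: int = 2
    visual_copied: int = 10
    onset_shared: int = 3
    rhyme_shared: int = 3
    max_consecutive_shared: int = 2
    max_sem_shared_unrelated: int = 1
    max_item_tries: int = 2000
    max_restarts: int = 50

    @property
    def n_items(self) -> int:
        return self.n_sets * len(SET_ROLES) + self.n_fillers

    @property
    def phon_dim(self) -> int:
        """Length of the concatenated per-slot phonological encoding."""
        return self.word_len * self.phon_features


@dataclass(frozen=True)
class PhonemeInventory:
    """Phoneme id -> binary feature vector lookup (rows are phonemes)."""

    features: np.ndarray  # (n_phonemes, phon_features) of {0,1}

    def __post_init__(self):
        f = np.asarray(self.features)
        if f.ndim != 2:
            raise ValueError("inventory features must be a 2-D binary matrix")
        object.__setattr__(self, "features", f.astype(np.int8))

    @property
    def n_phonemes(self) -> int:
        return self.features.shape[0]

    def encode_word(self, phonology) -> np.ndarray:
        """Concatenated per-slot feature encoding of a phoneme sequence."""
        return self.features[np.asarray(phonology)].ravel().astype(float)


@dataclass(frozen=True)
class Item:
    """One lexical concept: phonological, visual and semantic form plus role."""

    id: int
    phonology: tuple  # word_len phoneme ids
    visual: np.ndarray  # (visual_features,) of {0,1}
    semantics: frozenset  # sem_active feature indices
    role: str
    set_id: int | None = None

    def semantic_vector(self, n_features: int) -> np.ndarray:
        v = np.zeros(n_features)
        v[list(self.semantics)] = 1.0
        return v


@dataclass
class Corpus:
    """A generated lexicon: items, phoneme inventory, target-set index."""

    items: list  # of Item, ids 0..n-1 in order
    inventory: PhonemeInventory
    target_sets: list  # of dict role -> item id
    seed: int
    config: CorpusConfig = field(default_factory=CorpusConfig)

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: int) -> Item:
        return self.items[item_id]

    @property
    def fillers(self) -> list:
        return [it for it in self.items if it.role == "filler"]

    # -- array views -------------------------------------------------------

    def words(self) -> np.ndarray:
        """(n_items, word_len) array of phoneme ids."""
        return np.array([it.phonology for it in self.items], dtype=np.int64)

    def semantic_matrix(self) -> np.ndarray:
        """(n_items, sem_features) binary indicator matrix."""
        m = np.zeros((len(self.items), self.config.sem_features))
        for it in self.items:
            m[it.id, list(it.semantics)] = 1.0
        return m

    def visual_matrix(self) -> np.ndarray:
        return np.array([it.visual for it in self.items], dtype=float)

    def phonological_matrix(self) -> np.ndarray:
        """(n_items, word_len * phon_features) concatenated feature encodings."""
        return np.array([self.inventory.encode_word(it.phonology) for it in self.items])

    # -- serialization -----------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "inventory": self.inventory.features.tolist(),
            "target_sets": self.target_sets,
            "items": [
                {
                    "id": it.id,
                    "phonology": list(it.phonology),
                    "visual": np.asarray(it.visual).astype(int).tolist(),
                    "semantics": sorted(it.semantics),
                    "role": it.role,
                    "set_id": it.set_id,
                }
                for it in self.items
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Corpus":
        with open(path) as fh:
            doc = json.load(fh)
        cfg = CorpusConfig(**doc["config"])
        items = [
            Item(
                id=d["id"],
                phonology=tuple(d["phonology"]),
                visual=np.array(d["visual"], dtype=np.int8),
                semantics=frozenset(d["semantics"]),
                role=d["role"],
                set_id=d["set_id"],
            )
            for d in doc["items"]
        ]
        sets = [{k: int(v) for k, v in s.items()} for s in doc["target_sets"]]
        return cls(
            items=items,
            inventory=PhonemeInventory(np.array(doc["inventory"])),
            target_sets=sets,
            seed=doc["seed"],
            config=cfg,
        )

    def to_csv(self, path) -> None:
        rows = [
            {
                "id": it.id,
                "role": it.role,
                "set_id": it.set_id,
                "phonemes": " ".join(str(p) for p in it.phonology),
                "visual": "".join(str(int(b)) for b in it.visual),
                "semantics": " ".join(str(f) for f in sorted(it.semantics)),
            }
            for it in self.items
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------


def cosine_distance(u, v) -> float:
    """1 - cosine similarity; in [0, 1] for non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance undefined for a zero-norm vector")
    return float(1.0 - (u @ v) / (nu * nv))


def sample_phoneme_inventory(
    seed, n_phonemes: int = 20, n_features: int = 10
) -> PhonemeInventory:
    """Sample ``n_phonemes`` distinct binary feature vectors, p(active) = 0.5.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.  Duplicate
    vectors are resampled so every phoneme is distinct.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        feats = rng.integers(0, 2, size=(n_phonemes, n_features))
        if len({tuple(row) for row in feats}) == n_phonemes:
            return PhonemeInventory(feats)
    raise GenerationError("could not sample a duplicate-free phoneme inventory")


# ---------------------------------------------------------------------------
# phonological forms
# ---------------------------------------------------------------------------


def _word_ok(word: np.ndarray, accepted: np.ndarray, cfg: CorpusConfig) -> bool:
    """Check the within-word repeat limit and the unrelated-overlap rules.

    ``accepted`` holds the phonologically *unrelated* words already in the
    corpus (the designated onset/rhyme partner is excluded by the caller).
    A candidate is rejected if any phoneme occurs more than twice, or if it
    shares more than ``max_consecutive_shared`` consecutive same-position
    phonemes with an accepted word (which also rules out any first-four or
    final-four overlap).
    """
    counts = np.bincount(word, minlength=cfg.n_phonemes)
    if counts.max(initial=0) > 2:
        return False
    if accepted.size == 0:
        return True
    eq = accepted == word  # (n, word_len)
    win = cfg.max_consecutive_shared + 1
    for start in range(cfg.word_len - win + 1):
        if eq[:, start : start + win].all(axis=1).any():
            return False
    return True


def generate_phonological_form(
    cfg: CorpusConfig,
    accepted: np.ndarray,
    rng: np.random.Generator,
    fixed: dict | None = None,
    forbidden: dict | None = None,
) -> tuple:
    """Rejection-sample a legal 6-phoneme word.

    Parameters
    ----------
    accepted : array (n, word_len)
        Phonologically unrelated words already accepted.
    fixed : dict position -> phoneme id
        Slots copied from a designated partner (onset/rhyme overlap).
    forbidden : dict position -> set of phoneme ids
        Slots that must differ from given values (e.g. the fourth phoneme
        of an onset competitor must differ from the target's).
    """
    fixed = fixed or {}
    forbidden = forbidden or {}
    free = [p for p in range(cfg.word_len) if p not in fixed]
    word = np.empty(cfg.word_len, dtype=np.int64)
    for pos, ph in fixed.items():
        word[pos] = ph
    for _ in range(cfg.max_item_tries):
        draw = rng.integers(0, cfg.n_phonemes, size=len(free))
        word[free] = draw
        if any(word[pos] in bad for pos, bad in forbidden.items()):
            continue
        if _word_ok(word, accepted, cfg):
            return tuple(int(p) for p in word)
    raise GenerationError(
        "phonological rejection-sampling budget exhausted "
        f"(fixed={fixed}, {len(accepted)} accepted words)"
    )


def make_onset_competitor(
    target_phonology, cfg: CorpusConfig, accepted: np.ndarray, rng: np.random.Generator
) -> tuple:
    """Word sharing exactly the first ``onset_shared`` phonemes with the target.

    The next position must differ (no two words share their initial four
    phonemes); ``accepted`` must exclude the target itself.
    """
    k = cfg.onset_shared
    fixed = {i: target_phonology[i] for i in range(k)}
    forbidden = {k: {target_phonology[k]}}
    return generate_phonological_form(cfg, accepted, rng, fixed, forbidden)


def make_rhyme_competitor(
    target_phonology, cfg: CorpusConfig, accepted: np.ndarray, rng: np.random.Generator
) -> tuple:
    """Word sharing exactly the final ``rhyme_shared`` phonemes with the target."""
    k = cfg.rhyme_shared
    L = cfg.word_len
    fixed = {L - 1 - i: target_phonology[L - 1 - i] for i in range(k)}
    forbidden = {L - 1 - k: {target_phonology[L - 1 - k]}}
    return generate_phonological_form(cfg, accepted, rng, fixed, forbidden)


# ---------------------------------------------------------------------------
# visual forms
# ---------------------------------------------------------------------------


def make_visual_competitor(
    target_visual: np.ndarray, cfg: CorpusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Copy ``visual_copied`` random positions from the target; share the rest at chance."""
    n = cfg.visual_features
    copied = rng.choice(n, size=cfg.visual_copied, replace=False)
    target_visual = np.asarray(target_visual, dtype=np.int8)
    shared = rng.random(n) < 0.5  # chance-level sharing on the free positions
    shared[copied] = True
    return np.where(shared, target_visual, 1 - target_visual).astype(np.int8)


# ---------------------------------------------------------------------------
# semantic feature sets
# ---------------------------------------------------------------------------


class _SemanticPool:
    """Greedy sampler of 8-feature sets under the max-1-shared constraint.

    Accepted sets are indexed; sampling a new set proceeds feature by
    feature: as soon as a candidate shares one feature with an accepted
    unrelated set, all of that set's features become forbidden, so the
    final overlap can never exceed one.  Designated overlaps (near/far
    neighbors) are passed in as ``init`` features with the partner marked
    exempt.
    """

    def __init__(self, n_features: int, rng: np.random.Generator):
        self.n_features = n_features
        self.rng = rng
        self.sets: list[np.ndarray] = []
        self.feat_items: list[list[int]] = [[] for _ in range(n_features)]

    def add(self, feats) -> int:
        idx = len(self.sets)
        arr = np.asarray(sorted(feats), dtype=np.int64)
        self.sets.append(arr)
        for f in arr:
            self.feat_items[f].append(idx)
        return idx

    def sample(
        self,
        n_pick: int,
        init=(),
        excluded=(),
        exempt=(),
        tries: int = 400,
    ):
        """Return ``init`` plus ``n_pick`` further features, or None on failure."""
        exempt = set(exempt)
        init = list(init)
        for _ in range(tries):
            allowed = np.ones(self.n_features, dtype=bool)
            allowed[list(excluded)] = False
            allowed[init] = False
            count = np.zeros(len(self.sets), dtype=np.int64)
            for f in init:
                for i in self.feat_items[f]:
                    if i not in exempt:
                        count[i] += 1
                        allowed[self.sets[i]] = False
            chosen = []
            ok = True
            for _ in range(n_pick):
                cand = np.flatnonzero(allowed)
                if cand.size == 0:
                    ok = False
                    break
                f = int(self.rng.choice(cand))
                chosen.append(f)
                allowed[f] = False
                for i in self.feat_items[f]:
                    if i not in exempt:
                        allowed[self.sets[i]] = False
            if ok:
                return frozenset(init + chosen)
        return None


def make_semantic_neighbor(
    target_semantics: frozenset,
    n_shared: int,
    pool: _SemanticPool,
    cfg: CorpusConfig,
    rng: np.random.Generator,
    target_index: int,
    avoid_pair: frozenset | None = None,
):
    """Feature set sharing exactly ``n_shared`` features with the target.

    The remaining features keep every unrelated pair at <= 1 shared feature.
    ``avoid_pair`` (the already-built sibling neighbor) constrains the
    choice of inherited target features so the two neighbors themselves
    stay unrelated.
    """
    tgt = sorted(target_semantics)
    if n_shared >= len(tgt):
        return frozenset(tgt)
    for _ in range(cfg.max_item_tries):
        shared = rng.choice(tgt, size=n_shared, replace=False).tolist()
        if avoid_pair is not None and len(set(shared) & avoid_pair) > 1:
            continue
        out = pool.sample(
            n_pick=cfg.sem_active - n_shared,
            init=[int(f) for f in shared],
            excluded=tgt,
            exempt=(target_index,),
        )
        if out is not None:
            return out
    raise GenerationError(
        f"semantic neighbor generation failed (n_shared={n_shared})"
    )


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


def _assemble_once(cfg: CorpusConfig, rng: np.random.Generator, seed: int) -> Corpus:
    inventory = sample_phoneme_inventory(rng, cfg.n_phonemes, cfg.phon_features)
    n_struct = cfg.n_sets * len(SET_ROLES)
    n_items = cfg.n_items

    # --- phonology ---------------------------------------------------------
    words: list[tuple] = []
    accepted = np.empty((0, cfg.word_len), dtype=np.int64)

    def push(word):
        nonlocal accepted
        words.append(word)
        accepted = np.vstack([accepted, np.asarray(word, dtype=np.int64)])

    # ids: set s occupies 6s .. 6s+5 in SET_ROLES order, fillers afterwards
    for s in range(cfg.n_sets):
        target = generate_phonological_form(cfg, accepted, rng)
        push(target)
        tgt_row = accepted[:-1]  # everything except the target itself
        push(make_onset_competitor(target, cfg, tgt_row, rng))
        # rhyme competitor: unrelated to everyone but its target
        unrel = np.vstack([accepted[: 6 * s + 0], accepted[6 * s + 1 :]])
        push(make_rhyme_competitor(target, cfg, unrel, rng))
        for _ in range(3):  # visual_comp, near_sem, far_sem: generic words
            push(generate_phonological_form(cfg, accepted, rng))
    for _ in range(cfg.n_fillers):
        push(generate_phonological_form(cfg, accepted, rng))

    # --- semantics ---------------------------------------------------------
    pool = _SemanticPool(cfg.sem_features, rng)
    semantics: list = [None] * n_items
    for s in range(cfg.n_sets):
        tid = 6 * s
        tgt = pool.sample(cfg.sem_active)
        if tgt is None:
            raise GenerationError("semantic pool exhausted while placing a target")
        t_idx = pool.add(tgt)
        semantics[tid] = tgt
        near = make_semantic_neighbor(tgt, cfg.near_shared, pool, cfg, rng, t_idx)
        n_idx = pool.add(near)
        semantics[tid + 4] = near
        near_shared_feats = frozenset(near & tgt)
        far = make_semantic_neighbor(
            tgt, cfg.far_shared, pool, cfg, rng, t_idx, avoid_pair=near_shared_feats
        )
        pool.add(far)
        semantics[tid + 5] = far
    generic_ids = [
        i for i in range(n_items) if semantics[i] is None
    ]  # onset/rhyme/visual comps and fillers
    for i in generic_ids:
        feats = pool.sample(cfg.sem_active)
        if feats is None:
            raise GenerationError("semantic pool exhausted while placing an item")
        pool.add(feats)
        semantics[i] = feats

    # --- vision ------------------------------------------------------------
    visual = rng.integers(0, 2, size=(n_items, cfg.visual_features)).astype(np.int8)
    for s in range(cfg.n_sets):
        visual[6 * s + 3] = make_visual_competitor(visual[6 * s], cfg, rng)

    # --- build items -------------------------------------------------------
    items = []
    target_sets = []
    for s in range(cfg.n_sets):
        target_sets.append({role: 6 * s + j for j, role in enumerate(SET_ROLES)})
        for j, role in enumerate(SET_ROLES):
            i = 6 * s + j
            items.append(
                Item(
                    id=i,
                    phonology=words[i],
                    visual=visual[i],
                    semantics=semantics[i],
                    role=role,
                    set_id=s,
                )
            )
    for i in range(n_struct, n_items):
        items.append(
            Item(
                id=i,
                phonology=words[i],
                visual=visual[i],
                semantics=semantics[i],
                role="filler",
                set_id=None,
            )
        )
    return Corpus(
        items=items,
        inventory=inventory,
        target_sets=target_sets,
        seed=seed,
        config=cfg,
    )


def assemble_corpus(config: CorpusConfig | None = None, seed: int = 0) -> Corpus:
    """Generate a corpus satisfying every overlap constraint; deterministic per seed.

    On rejection-budget exhaustion the whole corpus is restarted from the
    next substream of the seeded generator, up to ``config.max_restarts``
    times.
    """
    cfg = config or CorpusConfig()
    ss = np.random.SeedSequence(seed)
    last_err = None
    for child in ss.spawn(cfg.max_restarts):
        rng = np.random.default_rng(child)
        try:
            return _assemble_once(cfg, rng, seed)
        except GenerationError as err:  # restart with a fresh stream
            last_err = err
    raise GenerationError(f"corpus generation failed after restarts: {last_err}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Outcome of a full pairwise constraint scan."""

    violations: list  # of (rule, detail) tuples
    n_items: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        if self.ok:
            return f"corpus of {self.n_items} items: all constraints satisfied"
        lines = [f"corpus of {self.n_items} items: {len(self.violations)} violation(s)"]
        lines += [f"  {rule}: {detail}" for rule, detail in self.violations]
        return "\n".join(lines)


def validate_corpus(corpus: Corpus) -> ValidationReport:
    """Brute-force check of every construction rule; never raises."""
    cfg = corpus.config
    out = []
    n = len(corpus)
    words = corpus.words()
    sem = corpus.semantic_matrix()

    if n != cfg.n_items:
        out.append(("corpus_size", f"expected {cfg.n_items} items, found {n}"))
    if len(corpus.target_sets) != cfg.n_sets:
        out.append(("n_sets", f"expected {cfg.n_sets} sets"))

    for it in corpus.items:
        if len(it.phonology) != cfg.word_len:
            out.append(("word_length", f"item {it.id}"))
        if np.bincount(words[it.id], minlength=cfg.n_phonemes).max() > 2:
            out.append(("max_2_identical_phonemes", f"item {it.id}"))
        if len(it.semantics) != cfg.sem_active:
            out.append(("sem_cardinality", f"item {it.id}"))

    # designated relations
    phon_exempt = set()
    sem_exempt = set()
    for s, ts in enumerate(corpus.target_sets):
        t = ts["target"]
        for role, k in (("onset_comp", cfg.onset_shared),):
            c = ts[role]
            phon_exempt.add(frozenset((t, c)))
            if not np.array_equal(words[t][:k], words[c][:k]):
                out.append(("onset_shares_first_3", f"set {s}"))
            if words[t][k] == words[c][k]:
                out.append(("onset_first_4_distinct", f"set {s}"))
        c = ts["rhyme_comp"]
        k = cfg.rhyme_shared
        phon_exempt.add(frozenset((t, c)))
        if not np.array_equal(words[t][-k:], words[c][-k:]):
            out.append(("rhyme_shares_final_3", f"set {s}"))
        if words[t][-k - 1] == words[c][-k - 1]:
            out.append(("rhyme_final_4_distinct", f"set {s}"))
        for role, want in (("near_sem", cfg.near_shared), ("far_sem", cfg.far_shared)):
            c = ts[role]
            sem_exempt.add(frozenset((t, c)))
            got = int(sem[t] @ sem[c])
            if got != want:
                out.append((f"{role}_shares_{want}", f"set {s}: shares {got}"))
        c = ts["visual_comp"]
        agree = int((corpus.items[t].visual == corpus.items[c].visual).sum())
        if agree < cfg.visual_copied:
            out.append(
                ("visual_comp_min_shared", f"set {s}: {agree} < {cfg.visual_copied}")
            )

    # unrelated pairs: phonological consecutive-overlap rule
    win = cfg.max_consecutive_shared + 1
    for i in range(n):
        eq = words[i + 1 :] == words[i]  # (n-i-1, word_len)
        hit = np.zeros(eq.shape[0], dtype=bool)
        for start in range(cfg.word_len - win + 1):
            hit |= eq[:, start : start + win].all(axis=1)
        for off in np.flatnonzero(hit):
            j = i + 1 + int(off)
            if frozenset((i, j)) not in phon_exempt:
                out.append(
                    ("unrelated_max_2_consecutive_phonemes", f"items {i},{j}")
                )

    # unrelated pairs: semantic max-1-shared rule
    overlap = sem @ sem.T
    ii, jj = np.nonzero(np.triu(overlap, k=1) > cfg.max_sem_shared_unrelated)
    for i, j in zip(ii.tolist(), jj.tolist()):
        if frozenset((i, j)) not in sem_exempt:
            out.append(
                (
                    "unrelated_max_1_sem_feature",
                    f"items {i},{j}: share {int(overlap[i, j])}",
                )
            )

    return ValidationReport(violations=out, n_items=n)


# ---------------------------------------------------------------------------
# distance statistics
# ---------------------------------------------------------------------------


def _pairwise_cosine(target_vec: np.ndarray, others: np.ndarray) -> np.ndarray:
    nt = np.linalg.norm(target_vec)
    no = np.linalg.norm(others, axis=1)
    return 1.0 - (others @ target_vec) / (nt * no)


def distance_summary(corpora) -> pd.DataFrame:
    """Mean and sd of cosine distance per relation, pooled over corpora.

    Phonological distances use the concatenated per-slot feature encoding,
    visual distances the 20-bit vectors, semantic distances the 200-dim
    indicator vectors.  Returns a DataFrame indexed by relation with
    columns ``mean``, ``std`` and ``n_pairs``.
    """
    if not corpora:
        raise ValueError("need at least one corpus")
    vals = {rel: [] for rel in DISTANCE_RELATIONS}
    for corpus in corpora:
        phon = corpus.phonological_matrix()
        sem = corpus.semantic_matrix()
        vis = corpus.visual_matrix()
        n = len(corpus)
        for ts in corpus.target_sets:
            t = ts["target"]
            vals["onset"].append(cosine_distance(phon[t], phon[ts["onset_comp"]]))
            vals["rhyme"].append(cosine_distance(phon[t], phon[ts["rhyme_comp"]]))
            vals["near_sem"].append(cosine_distance(sem[t], sem[ts["near_sem"]]))
            vals["far_sem"].append(cosine_distance(sem[t], sem[ts["far_sem"]]))
            vals["visual_comp"].append(
                cosine_distance(vis[t], vis[ts["visual_comp"]])
            )
            others = np.ones(n, dtype=bool)
            others[t] = False
            phon_unrel = others.copy()
            phon_unrel[[ts["onset_comp"], ts["rhyme_comp"]]] = False
            sem_unrel = others.copy()
            sem_unrel[[ts["near_sem"], ts["far_sem"]]] = False
            vis_unrel = others.copy()
            vis_unrel[ts["visual_comp"]] = False
            vals["phon_unrelated"].extend(_pairwise_cosine(phon[t], phon[phon_unrel]))
            vals["sem_unrelated"].extend(_pairwise_cosine(sem[t], sem[sem_unrel]))
            vals["visual_unrelated"].extend(_pairwise_cosine(vis[t], vis[vis_unrel]))
    rows = {
        rel: {
            "mean": float(np.mean(v)),
            "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
            "n_pairs": len(v),
        }
        for rel, v in vals.items()
    }
    return pd.DataFrame(rows).T.loc[list(DISTANCE_RELATIONS)]
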