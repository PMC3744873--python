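"""Experiment orchestration: corpora x instantiations x training regimes.

The full design trains one model instantiation per generated corpus (six
by default), in a noiseless and a noisy-speech regime, pre-tests each
model on the four training tasks, runs the six VWP display conditions and
summarises every contrast in an effect table.  All randomness derives
deterministically from a single master seed; a JSON manifest and
per-stage checkpoint files make a run resumable and bit-reproducible.

``scaled_profile`` shrinks the design (corpus, hub capacity, trial counts,
instantiations) proportionally for desk-scale runs that preserve the
qualitative effect pattern.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, vwp
from .corpus import Corpus, CorpusConfig, assemble_corpus, validate_corpus
from .network import init_network, load_network, save_network
from .training import NoiseSpec, TaskSchedule, network_config_for, train

__all__ = ["ExperimentConfig", "scaled_profile", "run_experiment", "derive_seed"]

REGIMES = ("noiseless", "noisy")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a full experiment bit-exactly."""

    n_instantiations: int = 6
    corpus: CorpusConfig = field(default_factory=CorpusConfig)
    n_hub: int = 400
    rate: float = 0.05
    n_trials_noiseless: int = 1_000_000
    noisy_multiplier: float = 1.5  # noisy regime runs 50% more trials
    phon_flip_p: float = 0.2
    ambient_high: float = 0.1
    schedule: TaskSchedule = field(default_factory=TaskSchedule)
    T_test: int = 30
    master_seed: int = 0
    regimes: tuple = REGIMES
    log_every: int = 10_000
    loss: str = "sse"

    def n_trials(self, regime: str) -> int:
        if regime == "noiseless":
            return self.n_trials_noiseless
        return int(round(self.n_trials_noiseless * self.noisy_multiplier))

    def noise(self, regime: str) -> NoiseSpec:
        flip = self.phon_flip_p if regime == "noisy" else 0.0
        return NoiseSpec(0.0, self.ambient_high, flip)


def scaled_profile(config: ExperimentConfig, factor: float) -> ExperimentConfig:
    """Proportionally shrunk design for desk-scale runs.

    Scales target-set count (floor 5 so every display condition keeps a
    by-item sample), filler count, training trials, instantiation count
    and hub capacity.  The hub floor is 200 units: the item-at-location
    binding that the orienting tasks require does not shrink with the
    lexicon, and smaller hubs plateau below pre-test criterion on it.
    ``factor`` must lie in (0, 1]; factor 1 is the identity.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError("factor must be in (0, 1]")
    if round(config.corpus.n_sets * factor) < 1:
        raise ValueError("factor leaves no target set")
    cc = config.corpus
    scaled_corpus = dataclasses.replace(
        cc,
        n_sets=max(5, int(round(cc.n_sets * factor))),
        n_fillers=max(8, int(round(cc.n_fillers * factor))),
    )
    return dataclasses.replace(
        config,
        corpus=scaled_corpus,
        n_hub=max(200, int(round(config.n_hub * factor))),
        n_trials_noiseless=max(1, int(round(config.n_trials_noiseless * factor))),
        n_instantiations=max(1, int(round(config.n_instantiations * factor))),
    )


def derive_seed(master_seed: int, *parts) -> int:
    """Deterministic sub-seed below 2**31 from the master seed and a path."""
    key = [int(master_seed)] + [
        p if isinstance(p, int) else int.from_bytes(str(p).encode(), "little") % (2**32)
        for p in parts
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _train_or_load(config, corpus, inst, regime, out_dir):
    path = out_dir / f"net_inst{inst}_{regime}.npz"
    net_cfg = network_config_for(corpus, n_hub=config.n_hub, loss=config.loss)
    if path.exists():
        return load_network(path)
    net = init_network(net_cfg, seed=derive_seed(config.master_seed, inst, regime, "init"))
    net, log = train(
        net,
        corpus,
        n_trials=config.n_trials(regime),
        rate=config.rate,
        schedule=config.schedule,
        noise=config.noise(regime),
        seed=derive_seed(config.master_seed, inst, regime, "train"),
        log_every=config.log_every,
    )
    log.to_csv(out_dir / f"trainlog_inst{inst}_{regime}.csv", index=False)
    save_network(net, path)
    return net


def run_experiment(config: ExperimentConfig, out_dir, plots: bool = False) -> dict:
    """Full pipeline; writes artifacts under ``out_dir`` and returns results.

    Per instantiation: assemble + validate corpus, train per regime,
    pre-test, run the six display conditions.  Across instantiations:
    fixation records are pooled per regime and condition, the effect table
    computed and written as CSV.  Existing network checkpoints are reused,
    so an interrupted run resumes at the training stage it stopped in.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    records_by_regime: dict = {r: {c: [] for c in vwp.CONDITIONS} for r in config.regimes}
    pretests: dict = {}
    for inst in range(config.n_instantiations):
        corpus = assemble_corpus(
            config.corpus, seed=derive_seed(config.master_seed, inst, "corpus")
        )
        report = validate_corpus(corpus)
        if not report.ok:
            raise RuntimeError(f"instantiation {inst}: invalid corpus\n{report.summary()}")
        corpus.to_json(out_dir / f"corpus_inst{inst}.json")
        for regime in config.regimes:
            net = _train_or_load(config, corpus, inst, regime, out_dir)
            noise = config.noise(regime)
            pres = vwp.pretest_all(
                net, corpus, noise=noise, seed=derive_seed(config.master_seed, inst, regime, "pretest")
            )
            pretests[(inst, regime)] = pres
            for condition in vwp.CONDITIONS:
                recs = vwp.run_condition(
                    net,
                    corpus,
                    condition,
                    T_test=config.T_test,
                    seed=derive_seed(config.master_seed, inst, regime, condition),
                    noise=noise,
                    instantiation=inst,
                )
                records_by_regime[regime][condition].extend(recs)
    effects = analysis.effect_table(records_by_regime)
    effects.to_csv(out_dir / "effect_table.csv", index=False)
    pretest_rows = [
        {
            "instantiation": inst,
            "regime": regime,
            "task": task,
            "accuracy": res.accuracy,
            "at_least_3_of_4": res.at_least_3_of_4,
        }
        for (inst, regime), pres in pretests.items()
        for task, res in pres.items()
    ]
    pd.DataFrame(pretest_rows).to_csv(out_dir / "pretest.csv", index=False)
    for regime in config.regimes:
        for condition in vwp.CONDITIONS:
            recs = records_by_regime[regime][condition]
            analysis.records_to_frame(recs).to_csv(
                out_dir / f"records_{regime}_{condition}.csv", index=False
            )
            if plots:
                analysis.plot_timecourses(
                    recs,
                    out_dir / f"timecourse_{regime}_{condition}.png",
                    title=f"{condition} ({regime})",
                )
    manifest = {
        "config": dataclasses.asdict(config),
        "master_seed": config.master_seed,
        "elapsed_s": time.time() - t0,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return {
        "effects": effects,
        "pretests": pretests,
        "records": records_by_regime,
        "out_dir": out_dir,
    }
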