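"""Recurrent hub-and-spoke network: forward dynamics and BPTT gradients.

Four modality-specific layers (vision 80, phonology 60, semantics 200, eye
4 units) communicate exclusively through a 400-unit self-connected central
hub.  At each discrete tick the hub integrates the previous tick's layer
activations; semantics and eye are then read out from the new hub state:

    hub(t)  = sigmoid(x(t-1) @ W_in + b_hub)
    out(t)  = sigmoid(hub(t) @ W_out + b_out)

where ``x`` concatenates vision, phonology, semantics, eye and hub
activations.  Vision and phonology are always externally clamped;
semantics and eye are clamped when a trial defines them as input and
free-running otherwise.  Clamped values override the computed read-out and
block gradient flow into the clamp at that tick.

Training minimises summed squared error (optionally cross-entropy) on
masked (layer, tick) cells via backpropagation through the full unrolled
trial, with plain online SGD.  Targeted layers are teacher-forced by
default: once a layer's error window opens, the target value (not the
layer's own read-out) is what the hub sees on the next tick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = [
    "NetworkConfig",
    "Trial",
    "Network",
    "History",
    "Gradients",
    "init_network",
    "run_trial",
    "trial_loss",
    "bptt_gradients",
    "apply_update",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes and numerical options of the hub-and-spoke architecture."""

    n_slots: int = 4          # visual display locations
    visual_per_slot: int = 20
    word_len: int = 6
    phon_per_slot: int = 10
    n_sem: int = 200
    n_eye: int = 4
    n_hub: int = 400
    init_range: float = 0.1
    loss: str = "sse"  # or "cross_entropy"
    dtype: str = "float64"  # float32 roughly halves training time

    @property
    def n_vis(self) -> int:
        return self.n_slots * self.visual_per_slot

    @property
    def n_phon(self) -> int:
        return self.word_len * self.phon_per_slot

    @property
    def n_in(self) -> int:
        return self.n_vis + self.n_phon + self.n_sem + self.n_eye + self.n_hub

    @property
    def n_out(self) -> int:
        return self.n_sem + self.n_eye


@dataclass
class Trial:
    """Per-tick input streams, optional clamps, and masked error targets.

    ``vision`` and ``phonology`` are always-defined external inputs of
    shape (T, n).  Semantics and eye each carry an optional constant clamp
    vector with a per-tick on/off switch, and an optional constant target
    vector with a per-tick error mask.  A layer is never clamped and
    targeted at the same tick.

    With ``teacher_force`` (the default for training trials) a targeted
    layer propagates the *target* value to the next tick once its error
    window opens, while the error itself is computed on the free sigmoid
    read-out.  This keeps the hub's recurrent input clean during learning
    and truncates gradient flow exactly as a clamp does; without it the
    layer's own (initially random) read-out is fed back, which compounds
    error over ticks and destabilises online training.
    """

    T: int
    vision: np.ndarray      # (T, n_vis)
    phonology: np.ndarray   # (T, n_phon)
    sem_clamp: np.ndarray | None = None   # (n_sem,)
    sem_clamp_on: np.ndarray | None = None  # (T,) bool
    eye_clamp: np.ndarray | None = None
    eye_clamp_on: np.ndarray | None = None
    sem_target: np.ndarray | None = None
    sem_mask: np.ndarray | None = None    # (T,) bool
    eye_target: np.ndarray | None = None
    eye_mask: np.ndarray | None = None
    teacher_force: bool = True
    task: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        T = self.T
        if self.vision.shape[0] != T or self.phonology.shape[0] != T:
            raise ValueError("input streams must span all T ticks")
        for name in ("sem_clamp_on", "eye_clamp_on", "sem_mask", "eye_mask"):
            v = getattr(self, name)
            if v is None:
                setattr(self, name, np.zeros(T, dtype=bool))
            elif v.shape != (T,):
                raise ValueError(f"{name} must have shape (T,)")
        if (self.sem_clamp_on & self.sem_mask).any():
            raise ValueError("semantic layer clamped and targeted at the same tick")
        if (self.eye_clamp_on & self.eye_mask).any():
            raise ValueError("eye layer clamped and targeted at the same tick")
        if self.sem_mask[0] or self.eye_mask[0]:
            raise ValueError("tick 0 is an initial condition and cannot carry error")


@dataclass
class Network:
    """Weights of the hub-and-spoke network (input-side and read-out blocks).

    ``W_in`` stacks the vision->hub, phonology->hub, semantics->hub,
    eye->hub and hub->hub blocks row-wise; ``W_out`` stacks hub->semantics
    and hub->eye column-wise.  Block views are exposed as properties.
    """

    config: NetworkConfig
    W_in: np.ndarray   # (n_in, n_hub)
    b_hub: np.ndarray  # (n_hub,)
    W_out: np.ndarray  # (n_hub, n_out)
    b_out: np.ndarray  # (n_out,)
    meta: dict = field(default_factory=dict)

    def _in_slices(self):
        c = self.config
        edges = np.cumsum([0, c.n_vis, c.n_phon, c.n_sem, c.n_eye, c.n_hub])
        return {
            name: slice(int(a), int(b))
            for name, a, b in zip(
                ("vision", "phonology", "semantics", "eye", "hub"), edges, edges[1:]
            )
        }

    @property
    def W_vision_hub(self) -> np.ndarray:
        return self.W_in[self._in_slices()["vision"]]

    @property
    def W_phon_hub(self) -> np.ndarray:
        return self.W_in[self._in_slices()["phonology"]]

    @property
    def W_sem_hub(self) -> np.ndarray:
        return self.W_in[self._in_slices()["semantics"]]

    @property
    def W_eye_hub(self) -> np.ndarray:
        return self.W_in[self._in_slices()["eye"]]

    @property
    def W_hub_hub(self) -> np.ndarray:
        return self.W_in[self._in_slices()["hub"]]

    @property
    def W_hub_sem(self) -> np.ndarray:
        return self.W_out[:, : self.config.n_sem]

    @property
    def W_hub_eye(self) -> np.ndarray:
        return self.W_out[:, self.config.n_sem :]

    def copy(self) -> "Network":
        return Network(
            config=self.config,
            W_in=self.W_in.copy(),
            b_hub=self.b_hub.copy(),
            W_out=self.W_out.copy(),
            b_out=self.b_out.copy(),
            meta=dict(self.meta),
        )


@dataclass
class History:
    """Recorded activations of every layer at every tick of one trial."""

    vision: np.ndarray     # (T, n_vis)
    phonology: np.ndarray  # (T, n_phon)
    semantics: np.ndarray  # (T, n_sem) as propagated (clamp overrides)
    eye: np.ndarray        # (T, n_eye)
    hub: np.ndarray        # (T, n_hub)
    out_computed: np.ndarray  # (T, n_out) sigmoid read-out before clamping

    @property
    def T(self) -> int:
        return self.hub.shape[0]


@dataclass
class Gradients:
    W_in: np.ndarray
    b_hub: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray


def init_network(config: NetworkConfig | None = None, seed: int = 0) -> Network:
    """Weights and biases uniform in [-init_range, init_range], per seed."""
    cfg = config or NetworkConfig()
    rng = np.random.default_rng(seed)
    r = cfg.init_range
    dt = np.dtype(cfg.dtype)
    return Network(
        config=cfg,
        W_in=rng.uniform(-r, r, size=(cfg.n_in, cfg.n_hub)).astype(dt),
        b_hub=rng.uniform(-r, r, size=cfg.n_hub).astype(dt),
        W_out=rng.uniform(-r, r, size=(cfg.n_hub, cfg.n_out)).astype(dt),
        b_out=rng.uniform(-r, r, size=cfg.n_out).astype(dt),
        meta={"seed": seed},
    )


def run_trial(net: Network, trial: Trial) -> History:
    """Forward pass over all T ticks.

    Tick 0 holds the initial condition: clamped layers take their clamp or
    input value, free-running units start at 0.5 (the sigmoid of zero net
    input).
    """
    cfg = net.config
    T = trial.T
    ns = cfg.n_sem
    dt = net.W_in.dtype
    V = np.asarray(trial.vision, dtype=dt)
    P = np.asarray(trial.phonology, dtype=dt)
    S = np.empty((T, ns), dtype=dt)
    E = np.empty((T, cfg.n_eye), dtype=dt)
    H = np.empty((T, cfg.n_hub), dtype=dt)
    O = np.full((T, cfg.n_out), 0.5, dtype=dt)

    S[0] = trial.sem_clamp if trial.sem_clamp_on[0] else 0.5
    E[0] = trial.eye_clamp if trial.eye_clamp_on[0] else 0.5
    H[0] = 0.5

    x = np.empty(cfg.n_in, dtype=dt)
    for t in range(1, T):
        x[: cfg.n_vis] = V[t - 1]
        x[cfg.n_vis : cfg.n_vis + cfg.n_phon] = P[t - 1]
        x[cfg.n_vis + cfg.n_phon : cfg.n_vis + cfg.n_phon + ns] = S[t - 1]
        x[cfg.n_in - cfg.n_hub - cfg.n_eye : cfg.n_in - cfg.n_hub] = E[t - 1]
        x[cfg.n_in - cfg.n_hub :] = H[t - 1]
        H[t] = _sigmoid(x @ net.W_in + net.b_hub)
        O[t] = _sigmoid(H[t] @ net.W_out + net.b_out)
        if trial.sem_clamp_on[t]:
            S[t] = trial.sem_clamp
        elif trial.teacher_force and trial.sem_mask[t]:
            S[t] = trial.sem_target
        else:
            S[t] = O[t, :ns]
        if trial.eye_clamp_on[t]:
            E[t] = trial.eye_clamp
        elif trial.teacher_force and trial.eye_mask[t]:
            E[t] = trial.eye_target
        else:
            E[t] = O[t, ns:]
    return History(vision=V, phonology=P, semantics=S, eye=E, hub=H, out_computed=O)


def _masked_targets(trial: Trial, cfg: NetworkConfig):
    """(T, n_out) target matrix and boolean mask from the trial's windows."""
    T = trial.T
    Y = np.zeros((T, cfg.n_out))
    M = np.zeros((T, cfg.n_out), dtype=bool)
    if trial.sem_target is not None:
        Y[:, : cfg.n_sem] = trial.sem_target
        M[:, : cfg.n_sem] = trial.sem_mask[:, None]
    if trial.eye_target is not None:
        Y[:, cfg.n_sem :] = trial.eye_target
        M[:, cfg.n_sem :] = trial.eye_mask[:, None]
    return Y, M


def trial_loss(history: History, trial: Trial, net_or_cfg=None, loss: str | None = None):
    """Masked loss with a per-tick, per-layer breakdown.

    Returns ``(total, breakdown)`` where ``breakdown`` maps layer name to a
    length-T array of per-tick summed loss.
    """
    cfg = getattr(net_or_cfg, "config", net_or_cfg)
    if cfg is None:
        cfg = NetworkConfig(
            n_sem=history.semantics.shape[1],
            n_eye=history.eye.shape[1],
            n_hub=history.hub.shape[1],
        )
    kind = loss or cfg.loss
    Y, M = _masked_targets(trial, cfg)
    A = history.out_computed
    if kind == "cross_entropy":
        eps = 1e-12
        cell = -(Y * np.log(A + eps) + (1 - Y) * np.log(1 - A + eps))
    elif kind == "sse":
        cell = 0.5 * (A - Y) ** 2
    else:
        raise ValueError(f"unknown loss {kind!r}")
    cell = np.where(M, cell, 0.0)
    breakdown = {
        "semantics": cell[:, : cfg.n_sem].sum(axis=1),
        "eye": cell[:, cfg.n_sem :].sum(axis=1),
    }
    return float(cell.sum()), breakdown


def bptt_gradients(net: Network, trial: Trial, history: History | None = None):
    """Exact gradients of the masked trial loss by full unrolled backprop.

    Clamped layer activations block gradient flow (the propagated value is
    the clamp, not the sigmoid read-out), and tick 0 is an initial
    condition with no parameter dependence.  Returns ``(grads, loss)``.
    """
    cfg = net.config
    T = trial.T
    ns = cfg.n_sem
    hist = history or run_trial(net, trial)
    Y, M = _masked_targets(trial, cfg)
    A = hist.out_computed
    H = hist.hub

    if cfg.loss == "cross_entropy":
        dnet_loss = np.where(M, A - Y, 0.0)  # dL/d net_out, sigmoid+CE
    elif cfg.loss == "sse":
        dnet_loss = np.where(M, (A - Y) * A * (1 - A), 0.0)
    else:
        raise ValueError(f"unknown loss {cfg.loss!r}")

    sl = net._in_slices()
    # semantics and eye rows are adjacent in W_in: one fused feedback block
    W_out_fb = net.W_in[sl["semantics"].start : sl["eye"].stop]  # (n_out, n_hub)
    W_hub_in = net.W_in[sl["hub"]]

    D_out = np.zeros((T, cfg.n_out))
    D_hub = np.zeros((T, cfg.n_hub))
    d_hub_next = np.zeros(cfg.n_hub)  # dL/d net_hub at t+1
    for t in range(T - 1, 0, -1):
        d_out = dnet_loss[t].copy()
        if t < T - 1:
            # activations at t feed the hub net at t+1 (free-running only)
            d_act = W_out_fb @ d_hub_next
            # a clamped or teacher-forced value is a constant: no gradient path
            free = np.ones(cfg.n_out, dtype=bool)
            if trial.sem_clamp_on[t] or (trial.teacher_force and trial.sem_mask[t]):
                free[:ns] = False
            if trial.eye_clamp_on[t] or (trial.teacher_force and trial.eye_mask[t]):
                free[ns:] = False
            d_out += np.where(free, d_act * A[t] * (1 - A[t]), 0.0)
        d_H = net.W_out @ d_out
        if t < T - 1:
            d_H += W_hub_in @ d_hub_next
        d_hub = d_H * H[t] * (1 - H[t])
        D_out[t] = d_out
        D_hub[t] = d_hub
        d_hub_next = d_hub

    X = np.concatenate(
        [hist.vision, hist.phonology, hist.semantics, hist.eye, hist.hub], axis=1
    )
    grads = Gradients(
        W_in=X[: T - 1].T @ D_hub[1:],
        b_hub=D_hub[1:].sum(axis=0),
        W_out=H.T @ D_out,
        b_out=D_out.sum(axis=0),
    )
    loss, _ = trial_loss(hist, trial, net)
    return grads, loss


def apply_update(net: Network, grads: Gradients, rate: float = 0.05) -> Network:
    """Plain online SGD step, in place: w <- w - rate * g."""
    net.W_in -= rate * grads.W_in
    net.b_hub -= rate * grads.b_hub
    net.W_out -= rate * grads.W_out
    net.b_out -= rate * grads.b_out
    return net


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_network(net: Network, path) -> None:
    """Write weights as an .npz archive with a JSON metadata sidecar."""
    import dataclasses as _dc

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez(
        path,
        W_in=net.W_in,
        b_hub=net.b_hub,
        W_out=net.W_out,
        b_out=net.b_out,
    )
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"config": _dc.asdict(net.config), "meta": net.meta}, fh)


def load_network(path) -> Network:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no network archive at {path}")
    sidecar = path.with_suffix(".json")
    try:
        with np.load(path) as arc:
            arrays = {k: arc[k] for k in ("W_in", "b_hub", "W_out", "b_out")}
        with open(sidecar) as fh:
            doc = json.load(fh)
    except Exception as err:
        raise IOError(f"corrupt or incomplete network archive at {path}: {err}") from err
    return Network(config=NetworkConfig(**doc["config"]), meta=doc["meta"], **arrays)
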