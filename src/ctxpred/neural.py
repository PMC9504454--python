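"""The convolutional + bidirectional-LSTM context model.

The network consumes the one-hot encoded context of 2F bases around a
position (the focus base is excluded — it is the prediction target) and
emits a probability distribution over the four bases:

* one or two 1-D convolutional layers act as a "word encoding" of short
  motifs (kernel length 3 or 4, i.e. tri- or quadro-nucleotides), ReLU
  activated;
* one or more bidirectional LSTM layers read the encoded sequence; the
  final layer contributes the concatenated last hidden state of the two
  directions;
* an optional ReLU dense layer and a 4-way softmax output head.

Training minimizes the categorical cross-entropy of the focus base over
a randomly sampled fraction of the qualified positions, organized in
"rounds" that each end with a validation pass; the per-round log exposes
overfitting.  Given a seed and single-threaded execution two runs are
bit-identical.

Follows the same Model/Results pattern as the count models and satisfies
the common prediction contract, so every scorer in
:mod:`ctxpred.evaluate` applies unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import COMPLEMENT
from .nn import Adam, BiLSTM, Conv1D, Dense, ReLU, Sequential, softmax, softmax_xent
from .sequences import ContextWindow, GenomeSequence, build_position_mask

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainingLog",
    "ContextLSTM",
    "NeuralResults",
    "sample_training_positions",
    "load_neural_results",
]


@dataclass
class ArchitectureSpec:
    """Hyperparameters of the conv-biLSTM context network.

    The defaults mirror the shape of a flank-50 model: one convolution of
    64 filters with kernel 4, two bidirectional LSTM layers of 100 units,
    and the fixed 4-way softmax head.  ``tiny()`` gives a desk-scale
    variant used throughout the tests.
    """

    flank_size: int = 50
    conv_layers: list = field(default_factory=lambda: [(64, 4)])
    lstm_layers: list = field(default_factory=lambda: [100, 100])
    dense_units: int | None = None

    def __post_init__(self) -> None:
        if self.flank_size < 1:
            raise ValueError("flank_size must be >= 1")
        if not 1 <= len(self.conv_layers) <= 2:
            raise ValueError("one or two convolutional layers are supported")
        for filters, kernel in self.conv_layers:
            if kernel not in (3, 4):
                raise ValueError("convolution kernels must be 3 or 4 (tri-/quadro-nucleotides)")
            if filters < 1:
                raise ValueError("filter count must be >= 1")
        if not self.lstm_layers:
            raise ValueError("at least one bidirectional LSTM layer is required")

    @classmethod
    def tiny(cls, flank_size: int = 5) -> "ArchitectureSpec":
        return cls(flank_size=flank_size, conv_layers=[(16, 3)], lstm_layers=[16])

    def to_dict(self) -> dict:
        return {"flank_size": self.flank_size,
                "conv_layers": [list(c) for c in self.conv_layers],
                "lstm_layers": list(self.lstm_layers),
                "dense_units": self.dense_units}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["conv_layers"] = [tuple(c) for c in d["conv_layers"]]
        return cls(**d)


@dataclass
class TrainingConfig:
    """Sampling, schedule and reproducibility settings for training."""

    sample_fraction: float = 1.0 / 3.0
    rounds: int = 5
    batches_per_round: int = 200
    batch_size: int = 128
    validation_size: int = 2048
    learning_rate: float = 3e-3
    seed: int = 0
    train_chromosomes: list | None = None
    validation_chromosomes: list | None = None

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        for name in ("rounds", "batches_per_round", "batch_size", "validation_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainingLog:
    """One row per completed round: losses are mean categorical cross-entropy."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)

    @property
    def n_rounds(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "round": np.arange(1, self.n_rounds + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        })


def build_network(spec: ArchitectureSpec, rng: np.random.Generator) -> Sequential:
    """Instantiate the layer stack for a spec (softmax applied separately)."""
    layers = []
    c_in = 4
    for filters, kernel in spec.conv_layers:
        layers.append(Conv1D(c_in, filters, kernel, rng))
        layers.append(ReLU())
        c_in = filters
    for li, hidden in enumerate(spec.lstm_layers):
        last = li == len(spec.lstm_layers) - 1
        layers.append(BiLSTM(c_in, hidden, rng, return_sequences=not last))
        c_in = 2 * hidden
    if spec.dense_units:
        layers.append(Dense(c_in, spec.dense_units, rng))
        layers.append(ReLU())
        c_in = spec.dense_units
    layers.append(Dense(c_in, 4, rng))
    return Sequential(layers)


def sample_training_positions(genome: GenomeSequence, mask, fraction: float,
                              seed: int) -> np.ndarray:
    """Seeded uniform sample without replacement of qualified positions."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    disq = getattr(mask, "disqualified", mask)
    qualified = np.flatnonzero(~np.asarray(disq, dtype=bool))
    if qualified.size == 0:
        raise ValueError("no qualified positions to sample from")
    if fraction == 1.0:
        return qualified
    rng = np.random.default_rng(seed)
    n = int(round(fraction * qualified.size))
    return np.sort(rng.choice(qualified, size=n, replace=False))


_EYE4 = np.eye(4)


def _one_hot_contexts(codes: np.ndarray, positions: np.ndarray, flank: int) -> np.ndarray:
    """(n, 2F, 4) one-hot contexts; positions must be qualified."""
    offs = np.concatenate([np.arange(-flank, 0), np.arange(1, flank + 1)])
    ctx = codes[positions[:, None] + offs[None, :]].astype(np.int64)
    return _EYE4[ctx]


class ContextLSTM:
    """Model object: genomes + architecture + training configuration.

    ``fit()`` trains the network and returns :class:`NeuralResults`.
    """

    def __init__(self, genomes, spec: ArchitectureSpec | None = None,
                 config: TrainingConfig | None = None):
        if isinstance(genomes, GenomeSequence):
            genomes = [genomes]
        self.genomes = list(genomes)
        self.spec = spec if spec is not None else ArchitectureSpec()
        self.config = config if config is not None else TrainingConfig()

    def _pools(self):
        """(training pool, validation pool) as (genome index, position) pairs."""
        cfg = self.config
        F = self.spec.flank_size

        def pool(names):
            pairs = []
            for gi, g in enumerate(self.genomes):
                if names is not None and g.name not in names:
                    continue
                mask = build_position_mask(g, F)
                pos = mask.qualified_positions
                pairs.append(np.column_stack([np.full(pos.size, gi), pos]))
            if not pairs:
                raise ValueError("no qualified positions in the requested chromosomes")
            return np.concatenate(pairs)

        train_pool = pool(cfg.train_chromosomes)
        val_pool = pool(cfg.validation_chromosomes) if cfg.validation_chromosomes else train_pool
        return train_pool, val_pool

    def fit(self) -> "NeuralResults":
        cfg = self.config
        spec = self.spec
        rng = np.random.default_rng(cfg.seed)
        net = build_network(spec, rng)
        opt = Adam(net.params, lr=cfg.learning_rate)
        train_pool, val_pool = self._pools()

        # validation sample first, then removed from the training pool so
        # the batch stream never touches it; when the pools are shared the
        # validation take is capped at half so training data always remains
        cap = val_pool.shape[0] if val_pool is not train_pool else max(1, val_pool.shape[0] // 2)
        n_val = min(cfg.validation_size, cap)
        val_idx = rng.choice(val_pool.shape[0], size=n_val, replace=False)
        val_pairs = val_pool[val_idx]
        if val_pool is train_pool:
            keep = np.ones(train_pool.shape[0], dtype=bool)
            keep[val_idx] = False
            train_pool = train_pool[keep]

        n_train = int(round(cfg.sample_fraction * train_pool.shape[0]))
        if n_train < 1:
            raise ValueError("empty training sample")
        train_pairs = train_pool[rng.choice(train_pool.shape[0], size=n_train, replace=False)]

        codes = [g.codes for g in self.genomes]
        F = spec.flank_size

        def gather(pairs):
            xs, ys = [], []
            for gi in np.unique(pairs[:, 0]):
                pos = pairs[pairs[:, 0] == gi, 1]
                xs.append(_one_hot_contexts(codes[gi], pos, F))
                ys.append(codes[gi][pos].astype(np.int64))
            return np.concatenate(xs), np.concatenate(ys)

        x_val, y_val = gather(val_pairs)
        log = TrainingLog()
        for _ in range(cfg.rounds):
            losses = []
            for _ in range(cfg.batches_per_round):
                take = rng.choice(train_pairs.shape[0], size=min(cfg.batch_size, train_pairs.shape[0]),
                                  replace=False)
                xb, yb = gather(train_pairs[take])
                logits = net.forward(xb)
                loss, _, dlogits = softmax_xent(logits, yb)
                if not np.isfinite(loss):
                    raise RuntimeError("training diverged: non-finite loss")
                net.backward(dlogits)
                opt.step(net.grads)
                losses.append(loss)
            val_logits = _forward_chunked(net, x_val)
            val_loss, val_p, _ = softmax_xent(val_logits, y_val)
            log.train_loss.append(float(np.mean(losses)))
            log.val_loss.append(float(val_loss))
            log.val_accuracy.append(float((np.argmax(val_p, axis=1) == y_val).mean()))
        return NeuralResults(spec, net, log, config=cfg,
                             n_training_positions=n_train)


def _forward_chunked(net: Sequential, x: np.ndarray, chunk: int = 4096) -> np.ndarray:
    outs = [net.forward(x[i : i + chunk]) for i in range(0, x.shape[0], chunk)]
    return np.concatenate(outs) if outs else np.empty((0, 4))


class NeuralResults:
    """A trained context network plus its training log.

    Satisfies the common prediction contract of the count models:
    ``predict_positions`` / ``disqualified`` / ``predict``.
    """

    def __init__(self, spec: ArchitectureSpec, network: Sequential,
                 training_log: TrainingLog, config: TrainingConfig | None = None,
                 n_training_positions: int = 0):
        self.spec = spec
        self.network = network
        self.training_log = training_log
        self.config = config
        self.n_training_positions = int(n_training_positions)

    kind = "lstm"

    @property
    def k(self) -> int:
        return self.spec.flank_size

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters

    # -- prediction contract ----------------------------------------------
    def disqualified(self, genome: GenomeSequence) -> np.ndarray:
        return build_position_mask(genome, self.spec.flank_size).disqualified

    def predict_positions(self, genome: GenomeSequence, positions: np.ndarray,
                          bidirectional: bool = False) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        probs = self._forward_codes(genome.codes, positions)
        if bidirectional:
            rc = COMPLEMENT[genome.codes][::-1].copy()
            rev = self._forward_codes(rc, len(genome) - 1 - positions)
            probs = 0.5 * (probs + rev[:, ::-1])
        return probs

    def _forward_codes(self, codes, positions):
        x = _one_hot_contexts(codes, positions, self.spec.flank_size)
        return softmax(_forward_chunked(self.network, x))

    def predict_batch(self, contexts) -> np.ndarray:
        """(n, 4) distributions for a list of ContextWindow objects."""
        F = self.spec.flank_size
        xs = np.empty((len(contexts), 2 * F, 4))
        for i, ctx in enumerate(contexts):
            if ctx.flank_size != F:
                raise ValueError(f"context flank {ctx.flank_size} != model flank {F}")
            xs[i, :F] = _EYE4[np.asarray(ctx.left, dtype=np.int64)]
            xs[i, F:] = _EYE4[np.asarray(ctx.right, dtype=np.int64)]
        return softmax(_forward_chunked(self.network, xs))

    def predict(self, context: ContextWindow) -> np.ndarray:
        return self.predict_batch([context])[0]

    # -- reporting and serialization --------------------------------------
    def summary(self) -> str:
        lines = [
            f"Conv-biLSTM context model (flank {self.spec.flank_size})",
            "=" * 44,
            f"conv layers          {self.spec.conv_layers}",
            f"biLSTM layers        {self.spec.lstm_layers}",
            f"dense units          {self.spec.dense_units}",
            f"trainable parameters {self.n_parameters:,}",
            f"training positions   {self.n_training_positions:,}",
            f"rounds completed     {self.training_log.n_rounds}",
        ]
        if self.training_log.n_rounds:
            lines.append(f"final val loss       {self.training_log.val_loss[-1]:.4f} nats")
            lines.append(f"final val accuracy   {self.training_log.val_accuracy[-1]:.4f}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Checkpoint: .npz of weights plus an embedded JSON sidecar."""
        meta = {
            "spec": self.spec.to_dict(),
            "n_training_positions": self.n_training_positions,
            "seed": self.config.seed if self.config else None,
            "log": {"train_loss": self.training_log.train_loss,
                    "val_loss": self.training_log.val_loss,
                    "val_accuracy": self.training_log.val_accuracy},
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.network.params)}
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                            **arrays)


def load_neural_results(path) -> NeuralResults:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        spec = ArchitectureSpec.from_dict(meta["spec"])
        net = build_network(spec, np.random.default_rng(0))
        for i, p in enumerate(net.params):
            p[...] = z[f"p{i}"]
        log = TrainingLog(**meta["log"])
        return NeuralResults(spec, net, log,
                             n_training_positions=meta["n_training_positions"])
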