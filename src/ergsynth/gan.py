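"""Conditional GAN for class-conditioned ERG waveform synthesis.

A generator maps (latent vector, one-hot class label) to a waveform on a
normalized [-1, 1] scale; a discriminator maps (waveform, label) to a
real-vs-synthetic logit.  Both are small fully connected networks trained
adversarially with the non-saturating binary cross-entropy objective and
Adam — adequate for few-hundred-sample signals learned from tiny datasets.
Forward and backward passes are written directly in numpy, which keeps the
training loop bit-reproducible from a single seed.

Usage follows the model/results idiom::

    model = ConditionalWaveformGAN(train_waveforms, GanConfig(epochs=300, seed=7))
    res = model.fit()                 # CGANResults
    fake = res.sample("male", n=34, seed=11)

``train_cgan`` / ``generate`` are functional aliases over the same objects.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ErgWaveform, LA3

__all__ = [
    "GanConfig",
    "AugmentationPolicy",
    "ConditionalWaveformGAN",
    "CGANResults",
    "GanTrainingError",
    "train_cgan",
    "generate",
    "balance_with_synthetic",
    "la3_plausibility",
]


class GanTrainingError(RuntimeError):
    """Raised when adversarial training degenerates (non-finite losses)."""


@dataclass(frozen=True)
class GanConfig:
    """Hyperparameters of the conditional GAN.

    ``signal_length`` is inferred from the training data when None.
    ``reject_implausible`` turns on morphology-gated rejection sampling for
    LA3 generators (off by default: post-hoc smoothing is the standard
    treatment of generator artifacts).  ``matched_conditioning`` trains the
    discriminator on (real waveform, wrong label) pairs as an extra fake
    term — the matching-aware scheme that makes the discriminator score
    label–waveform consistency, without which the class condition carries
    almost no gradient next to a few hundred signal dimensions.
    """

    latent_dim: int = 64
    generator_hidden: tuple[int, ...] = (128, 256)
    discriminator_hidden: tuple[int, ...] = (256, 128)
    condition_encoding: str = "one-hot"
    learning_rate_g: float = 2e-4
    learning_rate_d: float = 2e-4
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0
    signal_length: int | None = None
    normalization: str = "minmax"
    reject_implausible: bool = False
    matched_conditioning: bool = True

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs and batch_size must be ≥ 1")
        if self.condition_encoding != "one-hot":
            raise ValueError("only one-hot condition encoding is supported")
        if self.normalization != "minmax":
            raise ValueError("only per-dataset min-max normalization is supported")


@dataclass(frozen=True)
class AugmentationPolicy:
    """How many synthetic minority waveforms to add to a training set.

    With ``balance_to_parity`` off, the addition is
    ``round(synth_fraction × initial dataset size)`` — the 20 %-of-initial
    rule by default; with it on, exactly the count needed to reach class
    parity.
    """

    synth_fraction: float = 0.20
    target_class: str = "male"
    balance_to_parity: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.synth_fraction <= 1.0):
            raise ValueError("synth_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# minimal dense network with hand-written backprop


def _leaky(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float = 0.2) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


class _Mlp:
    """Fully connected stack: leaky-ReLU hidden layers, configurable output."""

    def __init__(self, rng: np.random.Generator, sizes: Sequence[int], out_act: str):
        self.W = [rng.normal(0.0, 0.02, (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.out_act = out_act
        # Adam state
        self._m = [np.zeros_like(p) for p in self.W + self.b]
        self._v = [np.zeros_like(p) for p in self.W + self.b]
        self._t = 0

    def forward(self, x: np.ndarray):
        pre = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            pre.append((h, z))
            if i < last:
                h = _leaky(z)
            elif self.out_act == "tanh":
                h = np.tanh(z)
            else:  # linear logit output
                h = z
        return h, pre

    def backward(self, pre, d_out: np.ndarray):
        """Accumulate parameter grads for a given output grad; return input grad."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        last = len(self.W) - 1
        d = d_out
        for i in range(last, -1, -1):
            h, z = pre[i]
            if i == last:
                dz = d * (1 - np.tanh(z) ** 2) if self.out_act == "tanh" else d
            else:
                dz = d * _leaky_grad(z)
            gW[i] = h.T @ dz
            gb[i] = dz.sum(axis=0)
            d = dz @ self.W[i].T
        return gW, gb, d

    def adam_step(self, gW, gb, lr: float, beta1: float = 0.5, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._t += 1
        params = self.W + self.b
        grads = gW + gb
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1**self._t)
            vhat = v / (1 - beta2**self._t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"], out[f"b{i}"] = W, b
        return out

    @classmethod
    def from_state(cls, state: dict[str, np.ndarray], out_act: str) -> "_Mlp":
        obj = cls.__new__(cls)
        n = len([k for k in state if k.startswith("W")])
        obj.W = [np.asarray(state[f"W{i}"]) for i in range(n)]
        obj.b = [np.asarray(state[f"b{i}"]) for i in range(n)]
        obj.out_act = out_act
        obj._m = [np.zeros_like(p) for p in obj.W + obj.b]
        obj._v = [np.zeros_like(p) for p in obj.W + obj.b]
        obj._t = 0
        return obj


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------


class ConditionalWaveformGAN:
    """Conditional GAN model over a single-stimulus waveform collection.

    The training set must contain waveforms of one stimulus with uniform
    length and sampling rate; class labels are the ``sex`` field.  ``fit``
    runs the configured number of adversarial epochs and returns a
    :class:`CGANResults`.
    """

    def __init__(self, waveforms: Sequence[ErgWaveform], config: GanConfig | None = None):
        if not waveforms:
            raise ValueError("empty training set")
        stimuli = {w.stimulus for w in waveforms}
        if len(stimuli) != 1:
            raise ValueError(f"one generator per stimulus; got {sorted(stimuli)}")
        lengths = {w.samples.size for w in waveforms}
        rates = {w.fs for w in waveforms}
        if len(lengths) != 1 or len(rates) != 1:
            raise ValueError("training waveforms must share length and sampling rate")
        self.config = config or GanConfig()
        self.stimulus = stimuli.pop()
        self.fs = rates.pop()
        self.signal_length = lengths.pop()
        if self.config.signal_length not in (None, self.signal_length):
            raise ValueError(
                f"config signal_length {self.config.signal_length} does not match "
                f"data length {self.signal_length}"
            )
        self.classes = sorted({w.sex for w in waveforms})
        counts = {c: sum(w.sex == c for w in waveforms) for c in self.classes}
        if len(self.classes) < 2 and min(counts.values()) < self.config.batch_size:
            raise ValueError("need ≥ 2 classes or ≥ batch_size examples of one class")
        self.X = np.stack([w.samples for w in waveforms])
        self.y = np.array([self.classes.index(w.sex) for w in waveforms])
        self.x_min = float(self.X.min())
        self.x_max = float(self.X.max())
        if self.x_max == self.x_min:
            raise ValueError("degenerate training set: constant amplitudes")

    # normalized scale helpers
    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    def _denormalize(self, Xn: np.ndarray) -> np.ndarray:
        return (Xn + 1.0) / 2.0 * (self.x_max - self.x_min) + self.x_min

    def _one_hot(self, labels: np.ndarray) -> np.ndarray:
        out = np.zeros((labels.size, len(self.classes)))
        out[np.arange(labels.size), labels] = 1.0
        return out

    def fit(self) -> "CGANResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n_classes = len(self.classes)
        L = self.signal_length
        gen = _Mlp(rng, [cfg.latent_dim + n_classes, *cfg.generator_hidden, L], "tanh")
        dis = _Mlp(rng, [L + n_classes, *cfg.discriminator_hidden, 1], "linear")
        Xn = self._normalize(self.X)
        n = Xn.shape[0]
        bs = min(cfg.batch_size, n)
        log = {"epoch": [], "loss_d": [], "loss_g": []}
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            ld_sum = lg_sum = 0.0
            n_batches = 0
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                real = Xn[idx]
                cond = self._one_hot(self.y[idx])
                m = real.shape[0]

                # --- discriminator step
                z = rng.standard_normal((m, cfg.latent_dim))
                fake, _ = gen.forward(np.concatenate([z, cond], axis=1))
                lr_in = np.concatenate([real, cond], axis=1)
                lf_in = np.concatenate([fake, cond], axis=1)
                logit_r, pre_r = dis.forward(lr_in)
                logit_f, pre_f = dis.forward(lf_in)
                # BCE with logits: real target 1, fake target 0
                loss_d = float(np.mean(np.logaddexp(0.0, -logit_r))
                               + np.mean(np.logaddexp(0.0, logit_f)))
                d_r = (_sigmoid(logit_r) - 1.0) / m
                d_f = _sigmoid(logit_f) / m
                gWr, gbr, _ = dis.backward(pre_r, d_r)
                gWf, gbf, _ = dis.backward(pre_f, d_f)
                gW = [a + b for a, b in zip(gWr, gWf)]
                gb = [a + b for a, b in zip(gbr, gbf)]
                if cfg.matched_conditioning and n_classes > 1:
                    # real waveforms paired with a wrong label are fakes too:
                    # forces the discriminator to score label consistency
                    wrong = self._one_hot((self.y[idx] + 1 +
                                           rng.integers(0, n_classes - 1, m)) % n_classes)
                    logit_w, pre_w = dis.forward(np.concatenate([real, wrong], axis=1))
                    loss_d += 0.5 * float(np.mean(np.logaddexp(0.0, logit_w)))
                    d_w = 0.5 * _sigmoid(logit_w) / m
                    gWw, gbw, _ = dis.backward(pre_w, d_w)
                    gW = [a + b for a, b in zip(gW, gWw)]
                    gb = [a + b for a, b in zip(gb, gbw)]
                dis.adam_step(gW, gb, cfg.learning_rate_d)

                # --- generator step (non-saturating loss)
                z = rng.standard_normal((m, cfg.latent_dim))
                g_in = np.concatenate([z, cond], axis=1)
                fake, pre_g = gen.forward(g_in)
                logit_f, pre_f = dis.forward(np.concatenate([fake, cond], axis=1))
                loss_g = float(np.mean(np.logaddexp(0.0, -logit_f)))
                d_f = (_sigmoid(logit_f) - 1.0) / m
                _, _, d_in = dis.backward(pre_f, d_f)
                gWg, gbg, _ = gen.backward(pre_g, d_in[:, :L])
                gen.adam_step(gWg, gbg, cfg.learning_rate_g)

                if not (np.isfinite(loss_d) and np.isfinite(loss_g)):
                    raise GanTrainingError(
                        f"non-finite loss at epoch {epoch}: D={loss_d}, G={loss_g}"
                    )
                ld_sum += loss_d
                lg_sum += loss_g
                n_batches += 1
            log["epoch"].append(epoch)
            log["loss_d"].append(ld_sum / max(n_batches, 1))
            log["loss_g"].append(lg_sum / max(n_batches, 1))
        return CGANResults(
            model=self, _generator=gen,
            training_log=pd.DataFrame(log),
        )


@dataclass
class CGANResults:
    """Trained conditional generator plus its training log and metadata."""

    model: ConditionalWaveformGAN
    _generator: _Mlp
    training_log: pd.DataFrame

    @property
    def stimulus(self) -> str:
        return self.model.stimulus

    @property
    def fs(self) -> float:
        return self.model.fs

    @property
    def signal_length(self) -> int:
        return self.model.signal_length

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    def sample(self, label: str, n: int, seed: int = 0) -> list[ErgWaveform]:
        """Draw ``n`` synthetic waveforms conditioned on ``label``.

        Deterministic given ``seed``; outputs are de-normalized to µV and
        tagged ``provenance='synthetic'``.
        """
        if n < 1:
            raise ValueError("n must be ≥ 1")
        if label not in self.model.classes:
            raise ValueError(f"unknown label {label!r}; known: {self.model.classes}")
        cfg = self.model.config
        rng = np.random.default_rng(seed)
        idx = self.model.classes.index(label)
        waves: list[ErgWaveform] = []
        attempts = 0
        while len(waves) < n:
            m = n - len(waves)
            z = rng.standard_normal((m, cfg.latent_dim))
            cond = np.zeros((m, len(self.model.classes)))
            cond[:, idx] = 1.0
            fake, _ = self._generator.forward(np.concatenate([z, cond], axis=1))
            batch = self.model._denormalize(fake)
            for j, row in enumerate(batch):
                w = ErgWaveform(
                    samples=row, fs=self.fs, stimulus=self.stimulus,
                    subject_id=f"synthetic-{label}-{len(waves):04d}",
                    eye="right", sex=label, provenance="synthetic",
                    replicate_index=0,
                )
                if cfg.reject_implausible and self.stimulus == LA3:
                    ptp_max = 3.0 * (self.model.x_max - self.model.x_min)
                    if not la3_plausibility(w, ptp_max):
                        continue
                waves.append(w)
                if len(waves) == n:
                    break
            attempts += 1
            if attempts > 200:
                raise GanTrainingError("rejection sampling failed to find plausible samples")
        return waves

    def summary(self) -> str:
        cfg = self.model.config
        last = self.training_log.iloc[-1]
        lines = [
            "Conditional GAN results",
            "=" * 46,
            f"stimulus:        {self.stimulus}",
            f"classes:         {', '.join(self.classes)}",
            f"signal length:   {self.signal_length} samples @ {self.fs:g} Hz",
            f"training set:    {self.model.X.shape[0]} waveforms",
            f"epochs:          {cfg.epochs} (batch {cfg.batch_size})",
            f"latent dim:      {cfg.latent_dim}",
            f"final loss D/G:  {last['loss_d']:.4f} / {last['loss_g']:.4f}",
            f"amplitude range: [{self.model.x_min:.2f}, {self.model.x_max:.2f}] µV",
        ]
        return "\n".join(lines)

    def save(self, path: str | os.PathLike) -> None:
        """Write a binary weight checkpoint plus a JSON sidecar (``path.json``)."""
        np.savez(path, **self._generator.state())
        sidecar = {
            "stimulus": self.stimulus, "fs": self.fs,
            "signal_length": self.signal_length, "classes": self.classes,
            "x_min": self.model.x_min, "x_max": self.model.x_max,
            "config": dataclasses.asdict(self.model.config),
        }
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "CGANResults":
        with open(str(path) + ".json", "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        raw = dict(np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz"))
        cfg_d = sidecar["config"]
        cfg_d["generator_hidden"] = tuple(cfg_d["generator_hidden"])
        cfg_d["discriminator_hidden"] = tuple(cfg_d["discriminator_hidden"])
        cfg = GanConfig(**cfg_d)
        model = ConditionalWaveformGAN.__new__(ConditionalWaveformGAN)
        model.config = cfg
        model.stimulus = sidecar["stimulus"]
        model.fs = sidecar["fs"]
        model.signal_length = sidecar["signal_length"]
        model.classes = list(sidecar["classes"])
        model.x_min = sidecar["x_min"]
        model.x_max = sidecar["x_max"]
        model.X = np.zeros((0, model.signal_length))
        model.y = np.zeros(0, dtype=int)
        gen = _Mlp.from_state(raw, "tanh")
        return cls(model=model, _generator=gen, training_log=pd.DataFrame())


def la3_plausibility(
    w: ErgWaveform,
    ptp_max: float,
    a_window: tuple[float, float] = (0.005, 0.025),
    b_window: tuple[float, float] = (0.015, 0.060),
) -> bool:
    """Morphology gate for generated LA3 waveforms.

    Requires the global minimum (candidate a-wave) inside ``a_window``, the
    global maximum after it and inside ``b_window``, and peak-to-peak
    amplitude no more than ``ptp_max``.
    """
    t = w.times
    i_min = int(np.argmin(w.samples))
    i_max = int(np.argmax(w.samples))
    t_min, t_max = t[i_min], t[i_max]
    return bool(
        a_window[0] <= t_min <= a_window[1]
        and b_window[0] <= t_max <= b_window[1]
        and t_max > t_min
        and np.ptp(w.samples) <= ptp_max
    )


def train_cgan(train_set: Sequence[ErgWaveform], config: GanConfig | None = None) -> CGANResults:
    """Functional alias: build and fit a :class:`ConditionalWaveformGAN`."""
    return ConditionalWaveformGAN(train_set, config).fit()


def generate(results: CGANResults, label: str, n: int, seed: int = 0) -> list[ErgWaveform]:
    """Functional alias for :meth:`CGANResults.sample`."""
    return results.sample(label, n, seed)


def balance_with_synthetic(
    train_set: Sequence[ErgWaveform],
    results: CGANResults,
    policy: AugmentationPolicy | None = None,
    seed: int = 0,
    initial_size: int | None = None,
    postprocess=None,
) -> list[ErgWaveform]:
    """Append generated target-class waveforms to a training set.

    ``initial_size`` is the pre-split real dataset size the 20 % rule refers
    to (defaults to the training-set size).  ``postprocess`` is an optional
    callable applied to each synthetic waveform (e.g. the Fourier low-pass).
    Real records are never modified or dropped.
    """
    policy = policy or AugmentationPolicy()
    counts = {s: sum(w.sex == s for w in train_set) for s in {w.sex for w in train_set}}
    if policy.target_class not in counts:
        raise ValueError(f"target class {policy.target_class!r} absent from training set")
    if policy.balance_to_parity:
        n_add = max(counts.values()) - counts[policy.target_class]
        if n_add < 0:
            raise ValueError("parity policy would require removing records")
    else:
        base = initial_size if initial_size is not None else len(train_set)
        n_add = int(round(policy.synth_fraction * base))
    if n_add == 0:
        return list(train_set)
    synthetic = results.sample(policy.target_class, n_add, seed=seed)
    if postprocess is not None:
        synthetic = [postprocess(w) for w in synthetic]
    return list(train_set) + synthetic
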