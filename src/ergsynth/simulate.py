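"""Physiologically shaped synthetic ERG waveform generation.

The light-adapted single-flash (LA3) response is modelled as a sum of a
negative Gaussian lobe (the a-wave, cone photoreceptor hyperpolarization),
a positive Gaussian lobe (the b-wave, bipolar/amacrine origin) and a
Gaussian-windowed sinusoid riding on the ascending limb (the oscillatory
potentials, OPs).  The 30 Hz flicker steady-state response is modelled as a
30 Hz fundamental plus low-order harmonics.  Both models are continuous in
time; sampling, additive white noise and slow baseline drift are applied at
simulation time.

A study-emulation fixture mirrors the composition of a pediatric ISCEV
reference cohort: 170 LA3 waveforms (60 male / 110 female, 85 per eye) and
67 flicker waveforms (18 male / 49 female, 33 left / 34 right), with subject
identifiers reused across eyes to mimic within-subject replicates and males
forming the minority class.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "La3Params",
    "FlickerParams",
    "SexEffect",
    "ErgWaveform",
    "SubjectVariability",
    "la3_model",
    "flicker_model",
    "simulate_la3",
    "simulate_flicker30",
    "make_study_fixture",
    "default_sex_effect",
    "child_seed",
]

LA3 = "LA3"
FLICKER30 = "FLICKER30"

#: default sampling rate (Hz) and record durations (s)
DEFAULT_FS = 1000.0
LA3_DURATION = 0.25
FLICKER_DURATION = 0.30  # nine full 30 Hz cycles


class ParameterError(ValueError):
    """Raised when waveform-model parameters violate their invariants."""


def child_seed(root: int, name: str) -> int:
    """Derive a reproducible per-purpose seed below 2**31 from a root seed."""
    h = np.uint64(root & 0x7FFFFFFF)
    for ch in name:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61 - 1))
    return int(h) % (2**31)


@dataclass(frozen=True)
class La3Params:
    """Generative parameters of the LA3 waveform kernel.

    Amplitudes in microvolts, times and widths in seconds.  ``a_amp`` is the
    a-wave trough depth (positive number; the trough itself is negative),
    ``b_amp`` the b-wave peak height, ``op_*`` the oscillatory-potential
    envelope (amplitude, carrier frequency in Hz, center, width),
    ``noise_sd`` the additive white-noise level and ``baseline_drift`` the
    amplitude scale of a slow random offset/ramp.
    """

    a_amp: float = 10.0
    a_time: float = 0.015
    a_width: float = 0.004
    b_amp: float = 25.0
    b_time: float = 0.032
    b_width: float = 0.008
    op_amp: float = 2.0
    op_freq: float = 120.0
    op_center: float = 0.024
    op_width: float = 0.006
    noise_sd: float = 2.0
    baseline_drift: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.a_time < self.b_time):
            raise ParameterError(
                f"a-wave must precede b-wave: a_time={self.a_time}, b_time={self.b_time}"
            )
        if min(self.a_width, self.b_width, self.op_width) <= 0:
            raise ParameterError("all widths must be positive")
        if self.a_amp <= 0 or self.b_amp <= 0:
            raise ParameterError("a_amp and b_amp must be positive")
        if self.op_amp < 0 or self.noise_sd < 0:
            raise ParameterError("op_amp and noise_sd must be non-negative")
        if self.op_freq <= 0:
            raise ParameterError("op_freq must be positive")


@dataclass(frozen=True)
class FlickerParams:
    """Generative parameters of the 30 Hz flicker steady-state waveform.

    ``amp`` is the fundamental amplitude (µV), ``harmonic_amps`` the 2nd,
    3rd, ... harmonic amplitudes.  The fundamental frequency is fixed at
    30 Hz by the stimulus.
    """

    amp: float = 15.0
    phase: float = 0.0
    fundamental: float = 30.0
    harmonic_amps: tuple[float, ...] = (4.0, 1.5)
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.fundamental != 30.0:
            raise ParameterError("flicker fundamental is fixed at 30 Hz")
        if self.amp < 0 or self.noise_sd < 0:
            raise ParameterError("amp and noise_sd must be non-negative")
        if any(a < 0 for a in self.harmonic_amps):
            raise ParameterError("harmonic amplitudes must be non-negative")
        object.__setattr__(self, "harmonic_amps", tuple(self.harmonic_amps))


@dataclass(frozen=True)
class SexEffect:
    """Per-parameter shifts applied to one sex class relative to the other.

    ``scale`` entries multiply the named parameter, ``offset`` entries add to
    it; both are applied (scale first) to waveforms of ``target_sex`` only.
    An empty effect is the identity.
    """

    scale: dict[str, float] = field(default_factory=dict)
    offset: dict[str, float] = field(default_factory=dict)
    target_sex: str = "male"

    def apply(self, params):
        """Return a copy of ``params`` with the effect applied."""
        names = {f.name for f in dataclasses.fields(params)}
        unknown = (set(self.scale) | set(self.offset)) - names
        if unknown:
            raise ParameterError(f"SexEffect refers to unknown parameters: {sorted(unknown)}")
        updates = {}
        for name in set(self.scale) | set(self.offset):
            value = getattr(params, name)
            value = value * self.scale.get(name, 1.0) + self.offset.get(name, 0.0)
            updates[name] = value
        return replace(params, **updates) if updates else params

    @classmethod
    def identity(cls) -> "SexEffect":
        return cls()


def default_sex_effect(stimulus: str = LA3) -> SexEffect:
    """Default male-vs-female parameter shift: a modest, detectable effect.

    LA3: male b-wave amplitude scaled ×0.9 and time-to-peak delayed 1.5 ms.
    Flicker: male fundamental amplitude ×0.9 and phase advanced 0.2 rad.
    """
    if stimulus == LA3:
        return SexEffect(scale={"b_amp": 0.9}, offset={"b_time": 0.0015})
    if stimulus == FLICKER30:
        return SexEffect(scale={"amp": 0.9}, offset={"phase": 0.2})
    raise ParameterError(f"unknown stimulus {stimulus!r}")


@dataclass
class ErgWaveform:
    """One fixed-length ERG record: samples (µV) plus acquisition metadata."""

    samples: np.ndarray
    fs: float
    stimulus: str
    subject_id: str
    eye: str = "right"
    sex: str = "female"
    provenance: str = "real"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ParameterError("waveform needs at least 2 samples in a 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("waveform samples must be finite")
        if self.fs <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.stimulus not in (LA3, FLICKER30):
            raise ParameterError(f"unknown stimulus {self.stimulus!r}")
        if self.eye not in ("left", "right"):
            raise ParameterError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.sex not in ("male", "female"):
            raise ParameterError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.provenance not in ("real", "synthetic"):
            raise ParameterError(f"provenance must be 'real' or 'synthetic'")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def copy(self) -> "ErgWaveform":
        return ErgWaveform(
            samples=self.samples.copy(),
            fs=self.fs,
            stimulus=self.stimulus,
            subject_id=self.subject_id,
            eye=self.eye,
            sex=self.sex,
            provenance=self.provenance,
            replicate_index=self.replicate_index,
        )

    def key(self) -> tuple:
        return (self.subject_id, self.eye, self.sex, self.stimulus,
                self.provenance, self.replicate_index)


def la3_model(t, params: La3Params):
    """Noiseless continuous LA3 kernel evaluated at times ``t`` (seconds).

    Negative Gaussian trough at ``a_time``, positive Gaussian peak at
    ``b_time``, plus a Gaussian-windowed sinusoid (the OPs) centered on the
    ascending limb.  With ``op_amp = 0`` the kernel is exactly the sum of the
    two Gaussian lobes.
    """
    t = np.asarray(t, dtype=float)
    a_lobe = -params.a_amp * np.exp(-((t - params.a_time) ** 2) / (2 * params.a_width**2))
    b_lobe = params.b_amp * np.exp(-((t - params.b_time) ** 2) / (2 * params.b_width**2))
    ops = (
        params.op_amp
        * np.exp(-((t - params.op_center) ** 2) / (2 * params.op_width**2))
        * np.sin(2 * np.pi * params.op_freq * (t - params.op_center))
    )
    return a_lobe + b_lobe + ops


def flicker_model(t, params: FlickerParams):
    """Noiseless continuous flicker kernel: 30 Hz fundamental + harmonics.

    Harmonic k (k = 2, 3, ...) carries phase k·phase so that a phase change
    translates the whole periodic waveshape in time.
    """
    t = np.asarray(t, dtype=float)
    y = params.amp * np.sin(2 * np.pi * params.fundamental * t + params.phase)
    for k, amp_k in enumerate(params.harmonic_amps, start=2):
        y = y + amp_k * np.sin(2 * np.pi * params.fundamental * k * t + k * params.phase)
    return y


def _check_sampling(params, fs: float, duration: float) -> None:
    if duration * fs < 2:
        raise ParameterError("duration·fs must be at least 2 samples")
    nyquist = fs / 2
    if isinstance(params, La3Params):
        if params.op_freq >= nyquist:
            raise ParameterError(f"op_freq {params.op_freq} Hz ≥ Nyquist {nyquist} Hz")
        if params.b_time >= duration:
            raise ParameterError(
                f"duration {duration}s too short to contain b_time {params.b_time}s"
            )
    else:
        top = params.fundamental * (1 + len(params.harmonic_amps))
        if top >= nyquist:
            raise ParameterError(f"highest harmonic {top} Hz ≥ Nyquist {nyquist} Hz")


def _noisify(kernel: np.ndarray, noise_sd: float, drift: float, rng: np.random.Generator):
    y = kernel.copy()
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=y.size)
    if drift > 0:
        ramp = np.linspace(0.0, 1.0, y.size)
        y += rng.normal(0.0, drift) + rng.normal(0.0, drift) * ramp
    return y


def _simulate(model, params_cls, stimulus, base_params, sex_effect, n_per_class,
              fs, duration, seed, subject_prefix):
    if not isinstance(base_params, params_cls):
        raise ParameterError(f"expected {params_cls.__name__}")
    sex_effect = sex_effect or SexEffect.identity()
    _check_sampling(base_params, fs, duration)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    out: list[ErgWaveform] = []
    for sex in ("male", "female"):
        count = int(n_per_class.get(sex, 0))
        if count < 0:
            raise ParameterError("n_per_class entries must be non-negative")
        p = sex_effect.apply(base_params) if sex == sex_effect.target_sex else base_params
        _check_sampling(p, fs, duration)
        kernel = model(t, p)
        for i in range(count):
            y = _noisify(kernel, p.noise_sd, getattr(p, "baseline_drift", 0.0), rng)
            out.append(
                ErgWaveform(
                    samples=y, fs=fs, stimulus=stimulus,
                    subject_id=f"{subject_prefix}{sex[0].upper()}{i:03d}",
                    eye="right", sex=sex, provenance="real", replicate_index=0,
                )
            )
    return out


def simulate_la3(
    params: La3Params,
    sex_effect: SexEffect | None = None,
    n_per_class: dict[str, int] | None = None,
    fs: float = DEFAULT_FS,
    duration: float = LA3_DURATION,
    seed: int = 0,
    subject_prefix: str = "S",
) -> list[ErgWaveform]:
    """Simulate labelled LA3 waveforms: kernel + white noise, sex effect on one class.

    Deterministic given ``seed``.  With ``noise_sd = 0`` every waveform
    equals the sampled noiseless kernel.
    """
    n_per_class = n_per_class if n_per_class is not None else {"male": 1, "female": 1}
    return _simulate(la3_model, La3Params, LA3, params, sex_effect, n_per_class,
                     fs, duration, seed, subject_prefix)


def simulate_flicker30(
    params: FlickerParams,
    sex_effect: SexEffect | None = None,
    n_per_class: dict[str, int] | None = None,
    fs: float = DEFAULT_FS,
    duration: float = FLICKER_DURATION,
    seed: int = 0,
    subject_prefix: str = "S",
) -> list[ErgWaveform]:
    """Simulate labelled 30 Hz flicker waveforms (fundamental + harmonics + noise)."""
    n_per_class = n_per_class if n_per_class is not None else {"male": 1, "female": 1}
    return _simulate(flicker_model, FlickerParams, FLICKER30, params, sex_effect,
                     n_per_class, fs, duration, seed, subject_prefix)


@dataclass(frozen=True)
class SubjectVariability:
    """Between-subject spread of waveform parameters in the study fixture.

    Amplitude-like parameters get a multiplicative lognormal-style factor with
    coefficient of variation ``amp_cv``; peak times get additive Gaussian
    jitter with SD ``time_sd`` seconds; widths a multiplicative factor with CV
    ``width_cv``; flicker phase additive jitter with SD ``phase_sd`` radians.
    Defaults reflect typical inter-individual variability of pediatric
    light-adapted ERG amplitudes and implicit times.
    """

    amp_cv: float = 0.15
    time_sd: float = 0.0015
    width_cv: float = 0.08
    phase_sd: float = 0.2

    def draw_la3(self, base: La3Params, rng: np.random.Generator) -> La3Params:
        def mul(cv):
            return float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0

        return replace(
            base,
            a_amp=base.a_amp * mul(self.amp_cv),
            b_amp=base.b_amp * mul(self.amp_cv),
            op_amp=base.op_amp * mul(self.amp_cv),
            a_time=max(1e-3, base.a_time + rng.normal(0.0, self.time_sd) * 0.5),
            b_time=base.b_time + rng.normal(0.0, self.time_sd),
            a_width=base.a_width * mul(self.width_cv),
            b_width=base.b_width * mul(self.width_cv),
        )

    def draw_flicker(self, base: FlickerParams, rng: np.random.Generator) -> FlickerParams:
        def mul(cv):
            return float(np.exp(rng.normal(0.0, cv))) if cv > 0 else 1.0

        factor = mul(self.amp_cv)
        return replace(
            base,
            amp=base.amp * factor,
            harmonic_amps=tuple(a * factor for a in base.harmonic_amps),
            phase=base.phase + rng.normal(0.0, self.phase_sd),
        )


# Table-matched composition: (sex, eye) -> waveform count.
_LA3_CELLS = {("male", "left"): 30, ("male", "right"): 30,
              ("female", "left"): 55, ("female", "right"): 55}
_FLICKER_CELLS = {("male", "left"): 9, ("male", "right"): 9,
                  ("female", "left"): 24, ("female", "right"): 25}


def _fixture_records(stimulus, cells, base, sex_effect, variability, fs, duration,
                     model, rng_subjects, rng_noise):
    # one parameter draw per subject; each subject contributes one waveform per eye
    out = []
    for sex in ("male", "female"):
        n_left = cells[(sex, "left")]
        n_right = cells[(sex, "right")]
        n_subjects = max(n_left, n_right)
        for i in range(n_subjects):
            sid = f"{stimulus[:2]}-{sex[0].upper()}{i:03d}"
            p = sex_effect.apply(base) if sex == sex_effect.target_sex else base
            if isinstance(p, La3Params):
                p = variability.draw_la3(p, rng_subjects)
            else:
                p = variability.draw_flicker(p, rng_subjects)
            _check_sampling(p, fs, duration)
            t = np.arange(int(round(duration * fs))) / fs
            kernel = model(t, p)
            for eye, n_eye in (("left", n_left), ("right", n_right)):
                if i >= n_eye:
                    continue
                y = _noisify(kernel, p.noise_sd, getattr(p, "baseline_drift", 0.0), rng_noise)
                out.append(ErgWaveform(samples=y, fs=fs, stimulus=stimulus,
                                       subject_id=sid, eye=eye, sex=sex,
                                       provenance="real", replicate_index=0))
    return out


def make_study_fixture(
    la3_params: La3Params | None = None,
    flicker_params: FlickerParams | None = None,
    sex_effect: SexEffect | None = None,
    flicker_sex_effect: SexEffect | None = None,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    variability: SubjectVariability | None = None,
) -> list[ErgWaveform]:
    """Build the study-emulation dataset with exact cohort composition.

    LA3: 170 waveforms, 60 male / 110 female, 85 per eye (males 30/30,
    females 55/55).  Flicker: 67 waveforms, 18 male / 49 female, 33 left /
    34 right (males 9/9, females 24/25).  Composition is identical for every
    seed; only the waveform samples change.  Subject identifiers are shared
    across the two eyes of a subject.
    """
    la3_params = la3_params or La3Params()
    flicker_params = flicker_params or FlickerParams()
    sex_effect = sex_effect if sex_effect is not None else default_sex_effect(LA3)
    if flicker_sex_effect is None:
        flicker_sex_effect = (
            default_sex_effect(FLICKER30)
            if (sex_effect.scale or sex_effect.offset)
            else SexEffect.identity()
        )
    variability = variability or SubjectVariability()
    rng_subjects = np.random.default_rng(child_seed(seed, "fixture-subjects"))
    rng_noise = np.random.default_rng(child_seed(seed, "fixture-noise"))
    records = _fixture_records(LA3, _LA3_CELLS, la3_params, sex_effect, variability,
                               fs, LA3_DURATION, la3_model, rng_subjects, rng_noise)
    records += _fixture_records(FLICKER30, _FLICKER_CELLS, flicker_params,
                                flicker_sex_effect, variability, fs, FLICKER_DURATION,
                                flicker_model, rng_subjects, rng_noise)
    return records
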