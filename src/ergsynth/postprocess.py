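"""Fourier low-pass smoothing of waveforms.

Generated signals carry broadband generator noise that has no physiological
counterpart; decomposing a waveform into its discrete Fourier components and
zeroing every bin above a cutoff removes it while leaving the slow a-/b-wave
morphology (and, at the default 150 Hz cutoff, the 100–150 Hz oscillatory
potentials) intact.  The truncation is hard (bins above the cutoff are set
exactly to zero), which makes the operator linear, idempotent and
energy-non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ErgWaveform

__all__ = ["LowpassSpec", "fourier_lowpass"]


@dataclass(frozen=True)
class LowpassSpec:
    """Hard spectral truncation above ``cutoff`` Hz."""

    cutoff: float = 150.0
    mode: str = "hard"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.mode != "hard":
            raise ValueError("only hard truncation is supported")


def fourier_lowpass(w: ErgWaveform, spec: LowpassSpec | None = None) -> ErgWaveform:
    """Zero all DFT bins above the cutoff and invert; metadata preserved."""
    spec = spec or LowpassSpec()
    nyquist = w.fs / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz")
    spectrum = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(w.samples.size, d=1.0 / w.fs)
    spectrum[freqs > spec.cutoff] = 0.0
    out = w.copy()
    out.samples = np.fft.irfft(spectrum, n=w.samples.size)
    return out
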