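"""Time-domain feature extraction from ERG waveforms.

For the LA3 single-flash response the clinically standard parameters are the
a-wave time-to-trough ``ta`` and amplitude ``la`` and the b-wave
time-to-peak ``tb`` and amplitude ``lb``, located by peak detection within
physiological search windows.  ``la`` is measured from the pre-stimulus
baseline to the trough; ``lb`` trough-to-peak by default (the ISCEV
convention), with a baseline-to-peak switch.  For the 30 Hz flicker
steady-state train, ``lb`` is the mean peak-to-adjacent-trough amplitude over
steady-state cycles (the first cycle is discarded as onset transient) and
``tb`` the within-cycle latency of the first steady-state peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import FLICKER30, LA3, ErgWaveform

__all__ = [
    "TimeDomainFeatures",
    "FeatureExtractionError",
    "extract_la3_features",
    "extract_flicker_features",
    "feature_table",
    "FeatureTable",
    "DEFAULT_A_WINDOW",
    "DEFAULT_B_WINDOW",
]

#: default LA3 search windows (seconds): standard light-adapted latency ranges
DEFAULT_A_WINDOW = (0.005, 0.025)
DEFAULT_B_WINDOW = (0.015, 0.060)
#: baseline reference segment: the first 5 ms of the record
BASELINE_SECONDS = 0.005


class FeatureExtractionError(ValueError):
    """Raised when peak detection fails on a record (flat/monotone/degenerate)."""


@dataclass(frozen=True)
class TimeDomainFeatures:
    """The ta/la/tb/lb feature vector of one waveform.

    Times in seconds, amplitudes in µV (non-negative).  For flicker records
    only ``tb`` and ``lb`` are populated; ``ta``/``la`` are None.
    """

    ta: float | None
    la: float | None
    tb: float
    lb: float

    def as_dict(self) -> dict[str, float | None]:
        return {"ta_s": self.ta, "la_uv": self.la, "tb_s": self.tb, "lb_uv": self.lb}


def _window_slice(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = np.nonzero((t >= lo) & (t <= hi))[0]
    if idx.size < 3:
        raise FeatureExtractionError(f"window [{lo}, {hi}] s contains fewer than 3 samples")
    return idx


def extract_la3_features(
    w: ErgWaveform,
    a_window: tuple[float, float] = DEFAULT_A_WINDOW,
    b_window: tuple[float, float] = DEFAULT_B_WINDOW,
    lb_mode: str = "trough_to_peak",
) -> TimeDomainFeatures:
    """Locate the a-wave trough and b-wave peak and measure their latencies/amplitudes.

    ``ta`` is the time of the global minimum inside ``a_window``; ``tb`` the
    time of the global maximum inside ``b_window`` restricted to ``t > ta``.
    Ties break to the earliest sample.  Raises
    :class:`FeatureExtractionError` on flat or monotone windows (no usable
    extremum).
    """
    if w.stimulus != LA3:
        raise FeatureExtractionError(f"expected LA3 record, got {w.stimulus}")
    if lb_mode not in ("trough_to_peak", "baseline_to_peak"):
        raise ValueError(f"unknown lb_mode {lb_mode!r}")
    if not (a_window[0] < a_window[1] and b_window[0] < b_window[1]):
        raise ValueError("windows must be non-empty intervals")
    if a_window[0] > b_window[0]:
        raise ValueError("a_window must start no later than b_window")
    t = w.times
    y = w.samples
    if b_window[1] > w.duration:
        raise ValueError("b_window extends beyond the record")
    if np.ptp(y) == 0:
        raise FeatureExtractionError("flat signal")

    baseline = float(np.mean(y[t < BASELINE_SECONDS]))

    a_idx = _window_slice(t, *a_window)
    ya = y[a_idx]
    i_tr = a_idx[int(np.argmin(ya))]
    # a monotone window has its minimum at an edge and no interior local minimum
    interior_min = np.any((ya[1:-1] <= ya[:-2]) & (ya[1:-1] <= ya[2:]))
    if not interior_min:
        raise FeatureExtractionError("no a-wave trough inside the search window")
    ta = float(t[i_tr])
    trough = float(y[i_tr])

    b_idx = _window_slice(t, *b_window)
    b_idx = b_idx[t[b_idx] > ta]
    if b_idx.size < 3:
        raise FeatureExtractionError("b-window after the trough is too short")
    yb = y[b_idx]
    interior_max = np.any((yb[1:-1] >= yb[:-2]) & (yb[1:-1] >= yb[2:]))
    if not interior_max:
        raise FeatureExtractionError("no b-wave peak inside the search window")
    i_pk = b_idx[int(np.argmax(yb))]
    tb = float(t[i_pk])
    peak = float(y[i_pk])

    la = abs(baseline - trough)
    lb = peak - trough if lb_mode == "trough_to_peak" else peak - baseline
    if lb < 0:
        raise FeatureExtractionError("b-wave peak below reference level")
    return TimeDomainFeatures(ta=ta, la=la, tb=tb, lb=lb)


def extract_flicker_features(w: ErgWaveform) -> TimeDomainFeatures:
    """Cycle-averaged flicker amplitude and within-cycle peak latency.

    Peaks are detected with a minimum spacing of 80 % of the 30 Hz period;
    the first cycle is discarded.  ``lb`` averages each steady-state peak
    minus the trough that follows it; ``tb`` is the latency of the first
    steady-state peak from its own cycle onset (cycle k starts at k/30 s).
    """
    if w.stimulus != FLICKER30:
        raise FeatureExtractionError(f"expected FLICKER30 record, got {w.stimulus}")
    y = w.samples
    if np.ptp(y) == 0:
        raise FeatureExtractionError("flat signal")
    period = 1.0 / 30.0
    distance = max(1, int(0.8 * period * w.fs))
    peaks, _ = find_peaks(y, distance=distance)
    troughs, _ = find_peaks(-y, distance=distance)
    t = w.times
    steady = peaks[t[peaks] >= period]
    if steady.size < 2:
        raise FeatureExtractionError("fewer than 2 steady-state cycles detected")
    amps = []
    for p in steady:
        following = troughs[troughs > p]
        if following.size == 0:
            continue
        amps.append(y[p] - y[following[0]])
    if len(amps) < 1:
        raise FeatureExtractionError("no peak/trough pairs in steady state")
    lb = float(np.mean(amps))
    first = steady[0]
    tb = float(t[first] - np.floor(t[first] / period) * period)
    return TimeDomainFeatures(ta=None, la=None, tb=tb, lb=lb)


@dataclass
class FeatureTable:
    """Extracted features plus the exclusion log of records that failed."""

    table: pd.DataFrame
    exclusions: list[tuple[tuple, str]]

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def feature_table(
    dataset: Sequence[ErgWaveform],
    a_window: tuple[float, float] = DEFAULT_A_WINDOW,
    b_window: tuple[float, float] = DEFAULT_B_WINDOW,
    lb_mode: str = "trough_to_peak",
) -> FeatureTable:
    """One feature row per waveform of a single stimulus.

    Rows whose extraction fails are excluded and logged with the reason;
    the exclusion count is available on the returned object.
    """
    if not dataset:
        raise ValueError("empty dataset")
    stimuli = {w.stimulus for w in dataset}
    if len(stimuli) != 1:
        raise ValueError(f"mixed stimuli in one feature table: {sorted(stimuli)}")
    stimulus = stimuli.pop()
    rows = []
    exclusions: list[tuple[tuple, str]] = []
    for w in dataset:
        try:
            if stimulus == LA3:
                f = extract_la3_features(w, a_window, b_window, lb_mode)
            else:
                f = extract_flicker_features(w)
        except FeatureExtractionError as err:
            exclusions.append((w.key(), str(err)))
            continue
        rows.append({
            "subject_id": w.subject_id, "eye": w.eye, "sex": w.sex,
            "stimulus": w.stimulus, "provenance": w.provenance,
            "replicate_index": w.replicate_index, **f.as_dict(),
        })
    columns = ["subject_id", "eye", "sex", "stimulus", "provenance",
               "replicate_index", "ta_s", "la_uv", "tb_s", "lb_uv"]
    table = pd.DataFrame(rows, columns=columns)
    return FeatureTable(table=table, exclusions=exclusions)


def feature_columns(stimulus: str) -> list[str]:
    """Classifier feature columns for a stimulus: 4 for LA3, 2 for flicker."""
    return ["ta_s", "la_uv", "tb_s", "lb_uv"] if stimulus == LA3 else ["tb_s", "lb_uv"]
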