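import numpy as np
import pytest

from ergsynth import GanConfig, La3Params, make_study_fixture, train_cgan
from ergsynth.simulate import LA3, FLICKER30


@pytest.fixture(scope="session")
def study_fixture():
    """Default study-emulation dataset (Table-matched composition, seed 0)."""
    return make_study_fixture(seed=0)


@pytest.fixture(scope="session")
def la3_records(study_fixture):
    return [w for w in study_fixture if w.stimulus == LA3]


@pytest.fixture(scope="session")
def flicker_records(study_fixture):
    return [w for w in study_fixture if w.stimulus == FLICKER30]


@pytest.fixture(scope="session")
def trained_la3_gan(la3_records):
    """One fully trained LA3 generator shared across tests (300 epochs)."""
    return train_cgan(la3_records, GanConfig(epochs=300, seed=7))


def dense_la3_oracle(params: La3Params, duration=0.25, fs=1000.0, oversample=32,
                     a_window=(0.005, 0.025), b_window=(0.015, 0.060),
                     baseline_s=0.005):
    """Brute-force feature truth on a dense grid of the continuous LA3 kernel.

    Locates the trough (global min in the a-window) and peak (global max in
    the b-window after the trough) on an ``oversample``-times finer grid and
    applies the extractor's amplitude definitions (la baseline-to-trough, lb
    trough-to-peak).  The baseline is the mean of the first 5 ms at the
    record's own sampling rate — it is a convention on the sampled record,
    shared by truth and extractor, not a quantity peak detection estimates.
    """
    from ergsynth import la3_model

    t = np.arange(int(round(duration * fs * oversample))) / (fs * oversample)
    y = la3_model(t, params)
    t_rec = np.arange(int(round(duration * fs))) / fs
    baseline = la3_model(t_rec[t_rec < baseline_s], params).mean()
    a_mask = (t >= a_window[0]) & (t <= a_window[1])
    i_tr = np.flatnonzero(a_mask)[np.argmin(y[a_mask])]
    ta, trough = t[i_tr], y[i_tr]
    b_mask = (t >= b_window[0]) & (t <= b_window[1]) & (t > ta)
    i_pk = np.flatnonzero(b_mask)[np.argmax(y[b_mask])]
    tb, peak = t[i_pk], y[i_pk]
    return {"ta": ta, "la": abs(baseline - trough), "tb": tb, "lb": peak - trough}


def random_la3_params(rng: np.random.Generator) -> La3Params:
    """Physiologically plausible randomized kernel parameters.

    Ranges keep the extrema inside the default search windows and the
    baseline segment clear of the a-wave lobe.  A valid LA3 kernel has a
    measurable a-wave: draws whose b-wave lobe is broad enough to erode the
    trough below 85 % of its nominal depth (in the limit, no interior minimum
    at all — a waveform with no a-wave) are rejected and redrawn, verified on
    a dense grid.  The OP envelope sits on the ascending limb, clear of both
    the trough and the baseline segment.
    """
    from ergsynth import la3_model

    while True:
        a_time = rng.uniform(0.013, 0.019)
        b_time = rng.uniform(0.028, 0.042)
        p = La3Params(
            a_amp=rng.uniform(6.0, 15.0),
            a_time=a_time,
            a_width=rng.uniform(0.0042, 0.005),
            b_amp=rng.uniform(18.0, 35.0),
            b_time=b_time,
            b_width=rng.uniform(0.006, 0.010),
            op_amp=rng.uniform(0.0, 0.8),
            op_freq=120.0,
            op_center=a_time + 0.65 * (b_time - a_time),
            op_width=0.003,
            noise_sd=0.0,
        )
        t = np.linspace(0.005, 0.025, 2001)
        y = la3_model(t, p)
        i = int(np.argmin(y))
        interior = 0 < i < len(t) - 1 and y[i] < min(y[0], y[-1]) - 0.5
        if interior and dense_la3_oracle(p)["la"] >= 0.85 * p.a_amp:
            return p
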