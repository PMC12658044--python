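"""Minimal M/EEG preprocessing and word-aligned epoching.

The chain is deliberately small: zero-phase band-pass 0.1-40 Hz, resample
to 50 Hz, robust per-channel scaling (median/IQR over the whole recording),
hard clamp to [-5, 5].  No artifact or bad-channel handling — downstream
models are expected to cope with whatever survives.

Epochs are 3-s windows starting at each word onset; baseline correction
subtracts the per-channel mean over the first 0.5 s of the window itself.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import EpochSet, Recording, validate_events

logger = logging.getLogger(__name__)

TARGET_RATE_HZ = 50.0
BAND_HZ = (0.1, 40.0)
CLAMP = 5.0
WINDOW_S = 3.0
BASELINE_S = 0.5


class UnsupportedRateError(ValueError):
    """Input sampling rate too low for the 0.1-40 Hz chain."""


def _rational_ratio(fs_in: float, fs_out: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return frac.numerator, frac.denominator


def preprocess_recording(raw: Recording,
                         target_rate_hz: float = TARGET_RATE_HZ) -> Recording:
    """Band-pass, resample, robust-scale and clamp one recording.

    Order: 4th-order Butterworth band-pass (zero-phase, forward-backward) ->
    polyphase resampling to ``target_rate_hz`` -> per-channel centering by
    the median and scaling by the interquartile range (computed over the
    whole recording; constant channels are scaled by 1 with a warning) ->
    hard clamp to [-5, 5].
    """
    fs = raw.sampling_rate_hz
    if fs < 100.0:
        raise UnsupportedRateError(f"sampling rate {fs} Hz < 100 Hz")
    if raw.signal.shape[0] < 10 * fs:
        raise ValueError("need at least 10 s of data")

    sos = sps.butter(4, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, raw.signal, axis=0)

    up, down = _rational_ratio(fs, target_rate_hz)
    x = sps.resample_poly(x, up, down, axis=0)

    med = np.median(x, axis=0)
    q75, q25 = np.percentile(x, [75, 25], axis=0)
    iqr = q75 - q25
    # a channel is degenerate when its spread is zero or negligible next to
    # the other channels (e.g. a constant channel reduced to filter residue):
    # dividing by such an IQR would only amplify numerical noise
    degenerate = (iqr <= 1e-12) | (iqr < 1e-8 * iqr.max())
    if degenerate.any():
        logger.warning("constant channel(s) %s: IQR=0, scaling by 1",
                       np.flatnonzero(degenerate).tolist())
        iqr = np.where(degenerate, 1.0, iqr)
    x = (x - med) / iqr
    x = np.clip(x, -CLAMP, CLAMP)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values after preprocessing")
    return Recording(signal=x, sampling_rate_hz=target_rate_hz,
                     sensor_positions=raw.sensor_positions,
                     subject_id=raw.subject_id)


def epoch_events(rec: Recording, events: pd.DataFrame,
                 tmin_s: float = 0.0, window_s: float = WINDOW_S,
                 baseline_s: float = BASELINE_S) -> EpochSet:
    """Cut one window per event and baseline-correct it.

    A window covers ``[onset + tmin_s, onset + tmin_s + window_s)``, mapped
    to the nearest sample; events whose window does not fully fit in the
    recording are dropped (count logged and stored).  Baseline correction
    subtracts, per channel, the mean over the first ``baseline_s`` seconds
    of the window.  Overlapping windows are allowed.
    """
    validate_events(events)
    fs = rec.sampling_rate_hz
    n_total = rec.signal.shape[0]
    t = int(round(window_s * fs))
    n_base = int(round(baseline_s * fs))

    X, words, sids, subs, onsets = [], [], [], [], []
    n_dropped = 0
    for row in events.itertuples(index=False):
        start = int(round((row.onset + tmin_s) * fs))
        stop = start + t
        if start < 0 or stop > n_total:
            n_dropped += 1
            continue
        win = rec.signal[start:stop].copy()
        if n_base > 0:
            win -= win[:n_base].mean(axis=0, keepdims=True)
        X.append(win)
        words.append(str(row.word))
        sids.append(row.sentence_id)
        subs.append(str(row.subject))
        onsets.append(float(row.onset))
    if n_dropped:
        logger.info("dropped %d events whose window does not fit", n_dropped)
    Xarr = np.stack(X, axis=0) if X else np.empty((0, t, rec.n_sensors))
    return EpochSet(X=Xarr, words=words, sentence_ids=sids, subject_ids=subs,
                    sampling_rate_hz=fs, tmin_s=tmin_s, window_s=window_s,
                    baseline_s=baseline_s, n_dropped=n_dropped,
                    onsets=np.asarray(onsets))
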