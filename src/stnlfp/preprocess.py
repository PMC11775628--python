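"""Raw-signal conditioning: channel selection, demeaning, decimation, filtering.

The chain follows the order: three-channel demeaning (common-average
reference), anti-aliased downsampling to 1000 Hz, linear detrending, 2nd-order
Butterworth band-pass 1-100 Hz, 2nd-order band-stop 59-61 Hz.  All filters are
applied forward-backward (zero phase) so that response-locked timing is not
skewed by group delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .datamodel import NO_RESPONSE, ConfigError, Recording, SchemaError


@dataclass
class PreprocConfig:
    """Conditioning parameters (defaults follow the analysis protocol)."""

    fs_target: float = 1000.0
    bandpass: tuple = (1.0, 100.0)
    bandpass_order: int = 2
    notch: tuple = (59.0, 61.0)
    notch_order: int = 2
    zero_phase: bool = True

    def validate(self, fs_raw: float) -> None:
        if self.fs_target > fs_raw:
            raise ConfigError(f"fs_target {self.fs_target} must not exceed fs_raw {fs_raw}")
        if self.bandpass[1] >= self.fs_target / 2.0:
            raise ConfigError("band-pass upper edge must be below fs_target/2")
        if fs_raw <= 2.0 * self.bandpass[1]:
            raise ConfigError("fs_raw must exceed twice the band-pass upper edge")


def _trial_period_indices(
    rec: Recording, trials: pd.DataFrame, deadline_ms: float = 1000.0
) -> np.ndarray:
    """Sample indices of the concatenated trial periods (stimulus to response)."""
    sub = trials[trials["depth"] == rec.subregion]
    sub = sub[sub["response_side"] != NO_RESPONSE]
    fs = rec.fs_raw
    idx = []
    for _, tr in sub.iterrows():
        i0 = int(round((tr["stim_onset_s"] - rec.t0) * fs))
        i1 = int(round((tr["stim_onset_s"] + tr["rt_ms"] / 1000.0 - rec.t0) * fs))
        i0, i1 = max(i0, 0), min(i1, rec.n_samples)
        if i1 > i0:
            idx.append(np.arange(i0, i1))
    if not idx:
        raise ConfigError("no trial period overlaps the recording")
    return np.concatenate(idx)


def select_channel(rec: Recording, trials: pd.DataFrame) -> int:
    """Index of the channel with the highest variance over the trial periods.

    Variance is computed over the concatenation of all stimulus-to-response
    segments; ties break to the lowest index.
    """
    idx = _trial_period_indices(rec, trials)
    variances = rec.channels[:, idx].var(axis=1)
    return int(np.argmax(variances))


def demean_channels(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from each channel.

    This common-average reference cancels any component shared by the three
    microelectrodes (line interference, common-mode noise); the output's
    cross-channel mean is identically zero.
    """
    if rec.channels.shape[0] != 3:
        raise SchemaError("demeaning requires exactly 3 channels")
    mean = rec.channels.mean(axis=0, keepdims=True)
    return Recording(
        subject_id=rec.subject_id,
        hemisphere=rec.hemisphere,
        subregion=rec.subregion,
        channels=rec.channels - mean,
        fs_raw=rec.fs_raw,
        t0=rec.t0,
    )


def _resample(trace: np.ndarray, fs_raw: float, fs_target: float) -> np.ndarray:
    if fs_raw == fs_target:
        return trace
    frac = Fraction(fs_target / fs_raw).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    if up == 1:
        # integer-factor decimation with the polyphase anti-alias filter
        return sps.resample_poly(trace, 1, down)
    return sps.resample_poly(trace, up, down)


def condition_signal(
    trace: np.ndarray, fs_raw: float, cfg: PreprocConfig | None = None
) -> np.ndarray:
    """Downsample to fs_target, detrend and apply band-pass + notch filters.

    Returns the conditioned trace at ``cfg.fs_target`` (default 1000 Hz).
    """
    cfg = cfg or PreprocConfig()
    cfg.validate(fs_raw)
    x = np.asarray(trace, dtype=np.float64)
    if x.ndim != 1:
        raise SchemaError("condition_signal expects a single channel")
    x = _resample(x, fs_raw, cfg.fs_target)
    x = sps.detrend(x, type="linear")
    sos_bp = sps.butter(
        cfg.bandpass_order, cfg.bandpass, btype="bandpass", fs=cfg.fs_target, output="sos"
    )
    sos_notch = sps.butter(
        cfg.notch_order, cfg.notch, btype="bandstop", fs=cfg.fs_target, output="sos"
    )
    if cfg.zero_phase:
        x = sps.sosfiltfilt(sos_bp, x)
        x = sps.sosfiltfilt(sos_notch, x)
    else:
        x = sps.sosfilt(sos_bp, x)
        x = sps.sosfilt(sos_notch, x)
    return x


def preprocess_recording(
    rec: Recording, trials: pd.DataFrame, cfg: PreprocConfig | None = None
) -> tuple[np.ndarray, float, int]:
    """Full conditioning chain for one recording.

    Selects the highest-trial-variance channel, demeans across the three
    channels, and conditions the selected channel.  Returns
    ``(trace, fs_target, channel_index)``.
    """
    cfg = cfg or PreprocConfig()
    ch = select_channel(rec, trials)
    demeaned = demean_channels(rec)
    trace = condition_signal(demeaned.channels[ch], rec.fs_raw, cfg)
    return trace, cfg.fs_target, ch
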