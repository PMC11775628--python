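"""Time-frequency decomposition, baseline normalization, trial QC and binning.

Band power is estimated by convolution with complex Morlet wavelets
(implemented as frequency-domain Gaussian filters applied to the analytic
signal), with the number of cycles ramping linearly from 4 at the lowest
analyzed frequency to 12 at the highest.  Response-locked epochs cover
[-380, 0) ms before the button response; the per-trial baseline is an
equal-length window drawn either from the preceding intertrial period
(default) or from the [-480, -100) ms pre-response window (``baseline_policy
= "literal_preresponse"``).  Trials whose broadband power does not differ
from their baseline (paired t-test) are excluded from further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.fft import fft, fftfreq, ifft, next_fast_len

from .datamodel import (
    NO_RESPONSE,
    BandEpoch,
    ConfigError,
    NumericalError,
    Recording,
    SchemaError,
    relabel_hemisphere,
)
from .preprocess import PreprocConfig, preprocess_recording

#: half-support of a wavelet, in units of its Gaussian SD sigma_t.
_SUPPORT_SD = 3.5


@dataclass
class TFConfig:
    """Time-frequency and epoching parameters."""

    freqs: np.ndarray = field(default_factory=lambda: np.arange(2.0, 101.0, 1.0))
    cycles_range: tuple = (4.0, 12.0)
    theta_band: tuple = (4.0, 7.0)
    beta_band: tuple = (12.0, 22.0)
    analysis_window_ms: tuple = (-380.0, 0.0)
    n_bins: int = 4
    baseline_policy: str = "intertrial"  # or "literal_preresponse"
    baseline_len_ms: float = 380.0
    baseline_gap_ms: float = 100.0  # gap between baseline end and its anchor
    qc_alpha: float = 0.05
    qc_broadband: bool = True

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        for band in (self.theta_band, self.beta_band):
            if band[0] < self.freqs.min() or band[1] > self.freqs.max():
                raise ConfigError(f"band {band} outside analyzed frequencies")
        length = self.analysis_window_ms[1] - self.analysis_window_ms[0]
        if length <= 0 or round(length) % self.n_bins:
            raise ConfigError("analysis window length must be divisible by n_bins")
        if self.baseline_policy not in ("intertrial", "literal_preresponse"):
            raise ConfigError(f"unknown baseline_policy {self.baseline_policy!r}")

    def cycles(self) -> np.ndarray:
        """Cycles per frequency: linear ramp over the analyzed frequency vector."""
        lo, hi = self.cycles_range
        f = self.freqs
        if len(f) == 1:
            return np.array([lo])
        return lo + (hi - lo) * (f - f.min()) / (f.max() - f.min())


@dataclass
class TFMap:
    """Time x frequency power map with per-frequency edge flags."""

    freqs: np.ndarray
    power: np.ndarray        # (n_freqs, n_samples)
    edge_samples: np.ndarray  # per frequency: samples invalid at each edge
    fs: float


def _max_edge(cfg: TFConfig, fs: float) -> int:
    sigma_t = cfg.cycles() / (2.0 * np.pi * cfg.freqs)
    return int(np.ceil(_SUPPORT_SD * sigma_t.max() * fs))


def _morlet_rows(
    trace: np.ndarray, fs: float, freqs: np.ndarray, cycles: np.ndarray, chunk: int = 8
):
    """Yield (freq-slice, power rows) for the Morlet decomposition.

    The trace is Fourier transformed once; each wavelet is a Gaussian filter
    on the positive-frequency axis (peak gain 1, doubled for analyticity) and
    power is the squared magnitude of the filtered analytic signal.
    """
    n = len(trace)
    sigma_t = cycles / (2.0 * np.pi * freqs)
    pad = int(np.ceil(2.0 * _SUPPORT_SD * sigma_t.max() * fs))
    nfft = next_fast_len(n + pad)
    spec = fft(trace, nfft)
    fgrid = fftfreq(nfft, 1.0 / fs)
    pos = fgrid > 0
    for i0 in range(0, len(freqs), chunk):
        sl = slice(i0, min(i0 + chunk, len(freqs)))
        f0 = freqs[sl, None]
        sf = (freqs[sl] / cycles[sl])[:, None]
        win = np.zeros((f0.shape[0], nfft))
        win[:, pos] = 2.0 * np.exp(-0.5 * ((fgrid[pos] - f0) / sf) ** 2)
        analytic = ifft(spec * win, axis=1)[:, :n]
        yield sl, np.abs(analytic) ** 2


def morlet_power(trace: np.ndarray, fs: float, cfg: TFConfig | None = None) -> TFMap:
    """Full Morlet time-frequency power map of a conditioned trace.

    Raises :class:`SchemaError` if the trace is shorter than the support of
    the longest (lowest-frequency) wavelet.
    """
    cfg = cfg or TFConfig()
    trace = np.asarray(trace, dtype=np.float64)
    freqs, cycles = cfg.freqs, cfg.cycles()
    sigma_t = cycles / (2.0 * np.pi * freqs)
    support = int(np.ceil(2.0 * _SUPPORT_SD * sigma_t.max() * fs))
    if len(trace) <= support:
        raise SchemaError(
            f"trace of {len(trace)} samples shorter than the longest wavelet "
            f"support ({support} samples)"
        )
    power = np.empty((len(freqs), len(trace)))
    for sl, rows in _morlet_rows(trace, fs, freqs, cycles):
        power[sl] = rows
    edge = np.ceil(_SUPPORT_SD * sigma_t * fs).astype(int)
    return TFMap(freqs=freqs, power=power, edge_samples=edge, fs=fs)


def band_power(tfmap: TFMap, band: tuple[float, float]) -> np.ndarray:
    """Mean power across the band's frequency rows (inclusive bounds)."""
    lo, hi = band
    if lo < tfmap.freqs.min() or hi > tfmap.freqs.max():
        raise ConfigError(f"band {band} outside analyzed frequencies")
    rows = (tfmap.freqs >= lo) & (tfmap.freqs <= hi)
    return tfmap.power[rows].mean(axis=0)


def band_power_series(
    trace: np.ndarray, fs: float, cfg: TFConfig | None = None
) -> tuple[dict[str, np.ndarray], int]:
    """Theta/beta/broadband power time courses without storing the full map.

    Accumulates band means frequency-chunk by frequency-chunk, so memory
    stays O(n_samples) regardless of the frequency grid.  Returns
    ``({"theta", "beta", "broadband"}, edge_samples)`` where ``edge_samples``
    is the largest per-frequency invalid edge (set by the lowest frequency).
    """
    cfg = cfg or TFConfig()
    trace = np.asarray(trace, dtype=np.float64)
    freqs, cycles = cfg.freqs, cfg.cycles()
    bands = {"theta": cfg.theta_band, "beta": cfg.beta_band,
             "broadband": (freqs.min(), freqs.max())}
    masks = {k: (freqs >= b[0]) & (freqs <= b[1]) for k, b in bands.items()}
    acc = {k: np.zeros(len(trace)) for k in bands}
    for sl, rows in _morlet_rows(trace, fs, freqs, cycles):
        for k, m in masks.items():
            sel = m[sl]
            if sel.any():
                acc[k] += rows[sel].sum(axis=0)
    out = {k: acc[k] / masks[k].sum() for k in bands}
    return out, _max_edge(cfg, fs)


# ---------------------------------------------------------------------------
# normalization, QC and binning
# ---------------------------------------------------------------------------

def db_normalize(epoch_power: np.ndarray, baseline_power: np.ndarray) -> np.ndarray:
    """Decibel-normalize a power series: 10*log10(power / mean(baseline))."""
    base = float(np.mean(baseline_power))
    if base <= 0:
        raise NumericalError("baseline mean power must be positive for dB scaling")
    return 10.0 * np.log10(np.asarray(epoch_power, dtype=np.float64) / base)


def zscore_epoch(
    epoch_power: np.ndarray,
    baseline_power: np.ndarray,
    pooled_mean: float | None = None,
    pooled_sd: float | None = None,
) -> np.ndarray:
    """z-score a power series against baseline statistics.

    By default the mean/SD come from the supplied baseline window; the
    pipeline passes per-subject pooled statistics (all of a subject's
    baselines within subregion x band) via ``pooled_mean``/``pooled_sd``.
    """
    m = float(np.mean(baseline_power)) if pooled_mean is None else pooled_mean
    s = float(np.std(baseline_power, ddof=1)) if pooled_sd is None else pooled_sd
    if s <= 0:
        raise NumericalError("baseline SD must be positive for z-scoring")
    return (np.asarray(epoch_power, dtype=np.float64) - m) / s


def qc_trial(
    epoch_power: np.ndarray, baseline_power: np.ndarray, qc_alpha: float = 0.05
) -> tuple[bool, float]:
    """Paired t-test of the analysis window against its baseline window.

    Samplewise differences of the two equal-length windows are tested
    against zero; the trial is *included* iff the two-sided p-value falls
    below ``qc_alpha`` (i.e. only trials whose power deviates measurably
    from baseline carry condition information).  Degenerate cases: a
    zero-variance *null* difference (epoch identical to baseline) is
    excluded; a zero-variance non-null difference (constant offset) is a
    certain deviation and is included.
    """
    a = np.asarray(epoch_power, dtype=np.float64)
    b = np.asarray(baseline_power, dtype=np.float64)
    if a.shape != b.shape:
        raise SchemaError("QC requires equal-length paired windows")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return False, 1.0
        return True, 0.0
    t, p = spstats.ttest_rel(a, b)
    return bool(p < qc_alpha), float(p)


def bin_power(series: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Average a window series over ``n_bins`` equal, contiguous time bins.

    For the default [-380, 0) ms window the bins cover [-380,-285),
    [-285,-190), [-190,-95) and [-95,0) ms, bin 1 earliest.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or len(series) % n_bins:
        raise SchemaError(
            f"series of length {series.shape} not divisible into {n_bins} bins"
        )
    return series.reshape(n_bins, -1).mean(axis=1)


# ---------------------------------------------------------------------------
# epoch extraction
# ---------------------------------------------------------------------------

def extract_epochs(
    band_series: dict[str, np.ndarray],
    fs: float,
    trials: pd.DataFrame,
    cfg: TFConfig,
    recording_hemisphere: str,
    subject_id: str,
    subregion: str,
    t0: float = 0.0,
    edge_samples: int = 0,
) -> tuple[list[BandEpoch], list[dict]]:
    """Cut response-locked theta/beta epochs for every correct trial.

    Only correct trials are analysed; error/omission/too-early trials are
    recorded in the drop log, as are trials whose analysis or baseline
    window would leave the valid part of the recording.  Each included
    candidate receives the broadband QC test; its outcome is shared by the
    trial's theta and beta epochs.

    Returns ``(epochs, dropped)`` where ``dropped`` rows carry
    ``trial_id`` and a ``reason`` code.
    """
    n = len(band_series["broadband"])
    w0, w1 = (int(round(v * fs / 1000.0)) for v in cfg.analysis_window_ms)
    blen = int(round(cfg.baseline_len_ms * fs / 1000.0))
    gap = int(round(cfg.baseline_gap_ms * fs / 1000.0))

    epochs: list[BandEpoch] = []
    dropped: list[dict] = []
    sub = trials[trials["depth"] == subregion]
    for _, tr in sub.iterrows():
        tid = int(tr["trial_id"])
        if tr["accuracy"] != "correct" or tr["response_side"] == NO_RESPONSE:
            dropped.append({"trial_id": tid, "reason": f"not_correct:{tr['accuracy']}"})
            continue
        i_resp = int(round((tr["stim_onset_s"] + tr["rt_ms"] / 1000.0 - t0) * fs))
        a0, a1 = i_resp + w0, i_resp + w1
        if cfg.baseline_policy == "intertrial":
            i_stim = int(round((tr["stim_onset_s"] - t0) * fs))
            b1 = i_stim - gap
            b0 = b1 - blen
        else:  # literal_preresponse: [-480, -100) ms before the response
            b1 = i_resp - gap
            b0 = b1 - blen
        lo, hi = edge_samples, n - edge_samples
        if a0 < lo or a1 > hi or b0 < lo or b1 > hi:
            dropped.append({"trial_id": tid, "reason": "out_of_bounds"})
            continue

        bb_epoch = band_series["broadband"][a0:a1]
        bb_base = band_series["broadband"][b0:b1]
        included, qc_p = qc_trial(bb_epoch, bb_base, cfg.qc_alpha)
        hemi_rel = relabel_hemisphere(recording_hemisphere, tr["response_side"])
        for band in ("theta", "beta"):
            series = band_series[band]
            if not cfg.qc_broadband:
                included, qc_p = qc_trial(series[a0:a1], series[b0:b1], cfg.qc_alpha)
            epochs.append(
                BandEpoch(
                    subject_id=subject_id,
                    subregion=subregion,
                    hemisphere_rel=hemi_rel,
                    correspondence=tr["correspondence"],
                    band=band,
                    trial_id=tid,
                    power_trace=series[a0:a1],
                    baseline_power=series[b0:b1],
                    broadband_trace=bb_epoch,
                    broadband_baseline=bb_base,
                    included=included,
                    qc_p=qc_p,
                )
            )
        if not included:
            dropped.append({"trial_id": tid, "reason": "qc_not_significant"})
    return epochs, dropped


def analyze_recording(
    rec: Recording,
    trials: pd.DataFrame,
    pre_cfg: PreprocConfig | None = None,
    tf_cfg: TFConfig | None = None,
) -> tuple[list[BandEpoch], list[dict]]:
    """Preprocess one recording and extract its response-locked band epochs."""
    pre_cfg = pre_cfg or PreprocConfig()
    tf_cfg = tf_cfg or TFConfig()
    trace, fs, _ = preprocess_recording(rec, trials, pre_cfg)
    series, edge = band_power_series(trace, fs, tf_cfg)
    return extract_epochs(
        series, fs, trials, tf_cfg, rec.hemisphere, rec.subject_id, rec.subregion,
        t0=rec.t0, edge_samples=edge,
    )


# ---------------------------------------------------------------------------
# PowerCell assembly
# ---------------------------------------------------------------------------

def powercells_from_epochs(
    epochs: list[BandEpoch], cfg: TFConfig | None = None
) -> pd.DataFrame:
    """Aggregate included epochs into the PowerCell table.

    Per trial and band, the analysis window is (a) divided by its own
    baseline mean (the power-*ratio* series modelled after log transform)
    and (b) z-scored against per-subject pooled baseline statistics within
    subregion x band (retained for plotting).  Both series are averaged over
    the four time bins, then across that subject's included trials within
    each (subregion, relative hemisphere, correspondence, bin) cell.
    """
    cfg = cfg or TFConfig()
    if not epochs:
        return pd.DataFrame(
            columns=[
                "subject_id", "subregion", "hemisphere_rel", "correspondence",
                "band", "time_bin", "power_ratio", "power_z", "n_trials",
            ]
        )
    pooled: dict[tuple, tuple[float, float]] = {}
    groups: dict[tuple, list[np.ndarray]] = {}
    for ep in epochs:
        groups.setdefault((ep.subject_id, ep.subregion, ep.band), []).append(
            ep.baseline_power
        )
    for key, baselines in groups.items():
        allb = np.concatenate(baselines)
        pooled[key] = (float(allb.mean()), float(allb.std(ddof=1)))

    rows = []
    for ep in epochs:
        if not ep.included:
            continue
        base_mean = float(ep.baseline_power.mean())
        if base_mean <= 0:
            continue
        pm, ps = pooled[(ep.subject_id, ep.subregion, ep.band)]
        ratio_bins = bin_power(ep.power_trace / base_mean, cfg.n_bins)
        z_bins = bin_power(zscore_epoch(ep.power_trace, ep.baseline_power, pm, ps),
                           cfg.n_bins)
        for b in range(cfg.n_bins):
            rows.append(
                (ep.subject_id, ep.subregion, ep.hemisphere_rel, ep.correspondence,
                 ep.band, b + 1, ratio_bins[b], z_bins[b])
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "subregion", "hemisphere_rel", "correspondence",
            "band", "time_bin", "power_ratio", "power_z",
        ],
    )
    cells = (
        df.groupby(
            ["subject_id", "subregion", "hemisphere_rel", "correspondence",
             "band", "time_bin"],
            as_index=False,
        )
        .agg(power_ratio=("power_ratio", "mean"), power_z=("power_z", "mean"),
             n_trials=("power_ratio", "size"))
        .sort_values(
            ["subject_id", "band", "subregion", "hemisphere_rel",
             "correspondence", "time_bin"],
            ignore_index=True,
        )
    )
    return cells


def baseline_band_summary(epochs: list[BandEpoch]) -> pd.DataFrame:
    """Per-subject baseline band power in dB, by subregion and band.

    The per-trial baseline-window mean power is averaged over all of a
    subject's correct-trial epochs within subregion x band (across
    hemispheres) and expressed as 10*log10(power) (dB re 1 a.u.^2).  These
    are the resting-level quantities correlated with behaviour.
    """
    rows: dict[tuple, list[float]] = {}
    for ep in epochs:
        rows.setdefault((ep.subject_id, ep.subregion, ep.band), []).append(
            float(ep.baseline_power.mean())
        )
    out = [
        {
            "subject_id": k[0],
            "subregion": k[1],
            "band": k[2],
            "baseline_db": 10.0 * np.log10(np.mean(v)),
            "n_trials": len(v),
        }
        for k, v in sorted(rows.items())
    ]
    return pd.DataFrame(out)
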