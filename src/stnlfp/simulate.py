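"""Synthetic cohorts emulating intraoperative STN recordings and Simon behaviour.

The generator produces the statistical structure the downstream analysis
assumes, at two tiers:

* a **signal tier** — raw three-channel microelectrode traces (pink noise,
  50/60-Hz-style line interference, ongoing narrowband theta/beta activity and
  response-locked oscillatory bursts whose gain depends on subregion,
  correspondence and response laterality) paired with a time-locked Simon
  trial table; this tier exercises the full preprocessing and spectral chain;
* a **cell tier** (:func:`simulate_powercells`) — normalized band-power cells
  drawn directly from the mixed-model generative structure, cheap enough for
  the hundreds of replicate cohorts the Monte-Carlo calibration and power
  checks require.

Behaviour follows a dual-process race: a deliberate colour-rule response with
ex-Gaussian latency (plus a Simon cost on non-corresponding trials) races an
occasionally launched automatic impulse toward the stimulus side.  Captured
impulses produce the fast-error signature of the conditional accuracy
function on NC trials.  Subject-level baseline beta and impulse strength are
coupled through a Gaussian copula so that the *observable* ventral
baseline-beta / Simon-accuracy association matches the configured target rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .datamodel import (
    HEMISPHERES,
    NO_RESPONSE,
    SUBREGIONS,
    ConfigError,
    Recording,
    validate_trials,
)


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


@dataclass
class SimConfig:
    """Full generative parameterization of signals and behaviour.

    Amplitudes are in arbitrary voltage units of the raw trace; the pink
    noise floor has unit standard deviation per channel, so band amplitudes
    are relative to it.
    """

    n_subjects: int = 10
    trials_per_block: int = 144
    blocks_per_depth: int = 2
    fs_raw: float = 11000.0
    bilateral: bool = True

    # --- signal composition -------------------------------------------------
    pink_exponent: float = 1.0
    noise_amp: float = 0.55           # per-channel pink-noise SD (1-100 Hz band)
    common_amp: float = 0.28          # shared (common-mode) pink-noise SD
    line_amp: float = 0.5             # 60 Hz line amplitude (common mode)
    line_freq: float = 60.0
    theta_base: float = 0.85          # response-locked theta burst amplitude
    beta_base: float = 1.8            # response-locked beta burst amplitude
    theta_ongoing: float = 0.35       # continuous narrowband theta SD
    beta_ongoing: float = 0.5         # continuous narrowband beta SD
    channel_gains: tuple = (1.0, 0.75, 0.55)  # neural gain per microelectrode

    # --- condition-dependent burst gains ------------------------------------
    effect_theta_dorsal_NC: float = 1.5   # theta gain on dorsal NC trials
    effect_beta_ipsi_NC: float = 1.4      # beta gain, ipsilateral hemisphere, NC
    effect_beta_dorsal: float = 1.3       # beta gain offset in dorsal recordings
    subject_sd: float = 0.10              # SD of the log-scale subject intercept

    # --- behaviour ----------------------------------------------------------
    rt_mu: float = 430.0              # ex-Gaussian Gaussian mean (ms)
    rt_sigma: float = 60.0            # ex-Gaussian Gaussian SD (ms)
    rt_tau: float = 150.0             # ex-Gaussian exponential mean (ms)
    simon_rt_shift_ms: float = 40.0   # NC - Cs deliberate-route RT cost
    suppression_gain: float = 0.0     # late-RT shrinkage of the Simon cost
    p_impulse_error: float = 0.05     # fast impulse-capture probability (NC errors)
    p_nc_residual: float = 0.07       # residual suppression-failure rate on NC
    p_lapse: float = 0.09             # colour-rule lapse probability
    p_too_early: float = 0.01
    impulse_shift_ms: float = 280.0   # impulse latency = shift + Exp(scale)
    impulse_scale_ms: float = 60.0
    deadline_ms: float = 1000.0
    iti_range_ms: tuple = (750.0, 1250.0)
    lead_in_s: float = 3.0            # quiet head/tail so wavelet edges are clean

    # --- subject-level variability and coupling ------------------------------
    subject_rt_sd: float = 30.0
    subject_impulse_sd: float = 0.8   # log-normal SD of the impulse strength
    subject_beta_sd: float = 0.4      # log-normal SD of the baseline-beta level
    baseline_beta_behavior_rho: float = 0.8

    # --- cell-tier parameters -------------------------------------------------
    theta_cell_base: float = 0.65     # grand mean of log theta power ratio
    beta_cell_base: float = 1.50      # grand mean of log beta power ratio
    effect_transfer: float = 0.5      # log burst gain -> log power-ratio slope
    corr_slope_sd: float = 0.05       # subject random slope SD for correspondence
    time_slope_sd: float = 0.03       # nested random time-bin slope SD
    cell_noise_sd: float = 0.12       # residual SD of a PowerCell value

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 144 <= self.trials_per_block <= 190:
            raise ConfigError("trials_per_block must lie in [144, 190]")
        if self.blocks_per_depth < 1:
            raise ConfigError("blocks_per_depth must be >= 1")
        for name in (
            "noise_amp", "common_amp", "line_amp", "theta_base", "beta_base",
            "theta_ongoing", "beta_ongoing", "effect_theta_dorsal_NC",
            "effect_beta_ipsi_NC", "effect_beta_dorsal",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_impulse_error", "p_lapse", "p_too_early"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.baseline_beta_behavior_rho <= 1.0:
            raise ConfigError("baseline_beta_behavior_rho must lie in [-1, 1]")
        if self.rt_mu >= self.deadline_ms:
            raise ConfigError("rt_mu must be below the response deadline")
        if self.fs_raw <= 200.0:
            raise ConfigError("fs_raw must exceed 200 Hz")


# ---------------------------------------------------------------------------
# subject-level effects and the baseline-beta / behaviour coupling
# ---------------------------------------------------------------------------

def _impulse_win_prob(cfg: SimConfig) -> float:
    """P(impulse beats the deliberate response), by fixed-seed Monte Carlo.

    A deterministic numerical estimate (independent of cfg.seed) used to
    translate the target observable correlation into a latent copula
    correlation.
    """
    r = np.random.default_rng(987654321)
    n = 4000
    rt_del = cfg.rt_mu + r.normal(0, cfg.rt_sigma, n) + r.exponential(cfg.rt_tau, n)
    t_imp = cfg.impulse_shift_ms + r.exponential(cfg.impulse_scale_ms, n)
    return float(np.mean(t_imp < rt_del))


def _latent_copula_r(cfg: SimConfig) -> float:
    """Latent Gaussian-copula correlation for the beta/behaviour coupling.

    The configured ``baseline_beta_behavior_rho`` targets the *observable*
    Spearman association between a subject's ventral baseline-beta level and
    their accuracy Simon effect.  The latter is estimated from a finite
    number of trials, which attenuates any latent coupling; the latent
    correlation is therefore the target divided by an analytic attenuation
    factor (signal SD over total SD of the per-subject accuracy effect).
    """
    rho = cfg.baseline_beta_behavior_rho
    if rho == 0.0:
        return 0.0
    w = _impulse_win_prob(cfg)
    s2 = cfg.subject_impulse_sd ** 2
    # subject NC-error rate = (capture + residual) x lognormal strength factor
    rate = cfg.p_impulse_error * w + cfg.p_nc_residual
    var_signal = (rate ** 2) * (np.exp(s2) - 1.0)
    n_nc = cfg.trials_per_block * cfg.blocks_per_depth / 2.0
    c_bar = rate + cfg.p_lapse
    var_noise = c_bar * (1 - c_bar) / n_nc + cfg.p_lapse * (1 - cfg.p_lapse) / n_nc
    atten = np.sqrt(var_signal / (var_signal + var_noise))
    # Pearson latent correlation giving Spearman rho for a Gaussian copula.
    # The Pearson attenuation factor understates the attenuation of a *rank*
    # correlation when the trait distribution is skewed (neighbouring ranks
    # in the thin part of the distribution are noise-dominated); squaring it
    # is an empirical correction calibrated by Monte Carlo.
    r_target = 2.0 * np.sin(np.pi * abs(rho) / 6.0)
    r = min(r_target / max(atten ** 2, 1e-6), 0.99)
    return float(np.sign(rho) * r)


def draw_subject_effects(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Draw the per-subject random effects shared across that subject's data.

    Returns one dict per subject with keys ``rt_shift`` (ms),
    ``beta_intercept`` (multiplicative baseline-beta level), ``q_impulse``
    (fast-capture probability), ``nc_residual`` (residual NC
    suppression-failure rate), ``lapse``, and ``power_effect``
    (multiplicative burst-amplitude random effect).  One log-normal
    impulse-strength factor scales both NC error channels, so a subject's
    conflict susceptibility is a single trait coupled to their baseline-beta
    level through the copula.
    """
    n = cfg.n_subjects
    r_lat = _latent_copula_r(cfg)
    z_b = rng.standard_normal(n)
    z_ind = rng.standard_normal(n)
    z_q = r_lat * z_b + np.sqrt(max(0.0, 1.0 - r_lat ** 2)) * z_ind
    s2 = cfg.subject_impulse_sd ** 2
    strength = np.exp(cfg.subject_impulse_sd * z_q - 0.5 * s2)
    q = np.clip(cfg.p_impulse_error * strength, 0.0, 0.9)
    resid = np.clip(cfg.p_nc_residual * strength, 0.0, 0.9)
    beta_int = np.exp(cfg.subject_beta_sd * z_b)
    rt_shift = rng.normal(0.0, cfg.subject_rt_sd, n)
    pow_eff = np.exp(rng.normal(0.0, cfg.subject_sd, n))
    corr_slope = rng.normal(0.0, cfg.corr_slope_sd, n)
    return [
        {
            "rt_shift": float(rt_shift[i]),
            "beta_intercept": float(beta_int[i]),
            "q_impulse": float(q[i]),
            "nc_residual": float(resid[i]),
            "lapse": cfg.p_lapse,
            "power_effect": float(pow_eff[i]),
            "corr_slope": float(corr_slope[i]),
        }
        for i in range(n)
    ]


_NEUTRAL_EFFECTS = {
    "rt_shift": 0.0,
    "beta_intercept": 1.0,
    "q_impulse": None,    # falls back to cfg.p_impulse_error
    "nc_residual": None,  # falls back to cfg.p_nc_residual
    "lapse": None,        # falls back to cfg.p_lapse
    "power_effect": 1.0,
    "corr_slope": 0.0,
}


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _simulate_block(
    cfg: SimConfig,
    rng: np.random.Generator,
    depth: str,
    block: int,
    trial0: int,
    t_cursor: float,
    eff: dict,
) -> tuple[pd.DataFrame, float]:
    n = cfg.trials_per_block
    q = eff["q_impulse"] if eff["q_impulse"] is not None else cfg.p_impulse_error
    resid = eff["nc_residual"] if eff["nc_residual"] is not None else cfg.p_nc_residual
    lapse = eff["lapse"] if eff["lapse"] is not None else cfg.p_lapse

    # balanced Cs/NC within the block (difference at most 1 when n is odd)
    corr = np.array(["Cs"] * (n - n // 2) + ["NC"] * (n // 2))
    rng.shuffle(corr)
    stim_side = np.where(rng.random(n) < 0.5, "left", "right")
    correct_side = np.where(
        corr == "Cs", stim_side, np.where(stim_side == "left", "right", "left")
    )

    iti = rng.uniform(*cfg.iti_range_ms, n)
    base = (
        cfg.rt_mu
        + eff["rt_shift"]
        + rng.normal(0.0, cfg.rt_sigma, n)
        + rng.exponential(cfg.rt_tau, n)
    )
    base = np.maximum(base, 80.0)
    # Simon cost on the deliberate route; optional shrinkage at slow RTs
    # (selective suppression building up over time)
    w_slow = 1.0 / (1.0 + np.exp(-(base - (cfg.rt_mu + cfg.rt_tau)) / 100.0))
    shift = cfg.simon_rt_shift_ms * (1.0 - cfg.suppression_gain * w_slow)
    rt_del = base + np.where(corr == "NC", shift, 0.0)

    impulse_on = rng.random(n) < q
    t_imp = cfg.impulse_shift_ms + rng.exponential(cfg.impulse_scale_ms, n)
    # The location-driven impulse races the deliberate colour-rule response.
    # On Cs trials both routes issue the same (correct) response, so capture
    # is only observable on NC trials, where the winning impulse produces a
    # fast error toward the stimulus side.  Incompletely suppressed impulses
    # can also break through at the deliberate latency (residual
    # suppression failures), so NC errors are not exclusively fast.
    captured = impulse_on & (t_imp < rt_del) & (corr == "NC")
    residual = (~captured) & (rng.random(n) < resid) & (corr == "NC")
    lapsed = rng.random(n) < lapse

    rt = np.where(captured, t_imp, rt_del)
    resp = np.where(
        captured | residual,
        stim_side,
        np.where(lapsed, np.where(correct_side == "left", "right", "left"), correct_side),
    )

    too_early = rng.random(n) < cfg.p_too_early
    omission = (~too_early) & (rt > cfg.deadline_ms)
    responded = ~(too_early | omission)

    accuracy = np.where(resp == correct_side, "correct", "error")
    accuracy = np.where(omission, "omission", accuracy)
    accuracy = np.where(too_early, "too_early", accuracy)
    resp = np.where(responded, resp, NO_RESPONSE)
    rt_out = np.where(responded, rt, np.nan)

    # event timeline (seconds): ITI, stimulus, response (or deadline)
    shown = np.where(responded, rt, cfg.deadline_ms)
    onsets = np.empty(n)
    t = t_cursor
    for i in range(n):
        t += iti[i] / 1000.0
        onsets[i] = t
        t += shown[i] / 1000.0

    df = pd.DataFrame(
        {
            "trial_id": np.arange(trial0, trial0 + n),
            "block": block,
            "depth": depth,
            "stim_onset_s": onsets,
            "stim_side": stim_side,
            "correct_side": correct_side,
            "response_side": resp,
            "rt_ms": rt_out,
            "correspondence": corr,
            "accuracy": accuracy,
            "iti_prev_ms": iti,
        }
    )
    return df, t


def simulate_behavior(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    subject_effects: dict | None = None,
) -> pd.DataFrame:
    """Simulate one subject's Simon-task trial table (all depths and blocks).

    Stimulus-onset times restart at the lead-in for each depth: the two
    depths correspond to separate recording sessions with their own clocks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eff = dict(_NEUTRAL_EFFECTS, **(subject_effects or {}))
    frames = []
    trial0 = 0
    for depth in SUBREGIONS:
        t_cursor = cfg.lead_in_s
        for b in range(cfg.blocks_per_depth):
            df, t_cursor = _simulate_block(cfg, rng, depth, b, trial0, t_cursor, eff)
            frames.append(df)
            trial0 += len(df)
    return validate_trials(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def pink_noise(
    n: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f**exponent noise normalized to unit SD within the 1-100 Hz band.

    Normalizing by the in-band (LFP analysis band) SD rather than the total
    SD makes the effective noise floor independent of the raw sampling rate:
    the same configuration then yields the same burst-to-background ratios
    whether synthesized at 44 kHz, 11 kHz or a desk-scale rate.
    """
    white = rng.standard_normal(n)
    x = white
    if exponent != 0.0:
        nfft = next_fast_len(n)
        spec = rfft(white, nfft)
        f = rfftfreq(nfft, 1.0 / fs)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        x = irfft(spec * scale, nfft)[:n]
    sos = sps.butter(2, (1.0, 100.0), btype="bandpass", fs=fs, output="sos")
    sd = sps.sosfilt(sos, x).std()
    return x / sd if sd > 0 else x


def _narrowband(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD band-limited noise (ongoing oscillatory activity)."""
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_burst(
    out: np.ndarray,
    fs: float,
    center_s: float,
    dur_s: float,
    freq: float,
    amp: float,
    phase: float,
) -> None:
    half = dur_s / 2.0
    i0 = max(int(round((center_s - half) * fs)), 0)
    i1 = min(int(round((center_s + half) * fs)), len(out))
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs
    win = np.hanning(i1 - i0)
    out[i0:i1] += amp * win * np.cos(2.0 * np.pi * freq * t + phase)


def simulate_recording(
    cfg: SimConfig,
    trials: pd.DataFrame,
    subregion: str,
    hemisphere: str,
    rng: np.random.Generator | None = None,
    subject_effects: dict | None = None,
    subject_id: str = "sim",
) -> Recording:
    """Synthesize the raw 3-channel trace for one depth x hemisphere session.

    The neural component (ongoing narrowband activity plus response-locked
    theta/beta bursts) enters each microelectrode with a channel-specific
    gain; independent pink noise and a common-mode component (line
    interference plus shared low-frequency noise) are superimposed, so that
    channel selection and three-channel demeaning are both exercised.

    Burst amplitude = base x condition gains x subject random effect, with
    the beta gains depending on the recording subregion and on whether this
    hemisphere is ipsilateral to the trial's response.
    """
    if subregion not in SUBREGIONS or hemisphere not in HEMISPHERES:
        raise ConfigError(f"invalid subregion/hemisphere: {subregion}/{hemisphere}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    eff = dict(_NEUTRAL_EFFECTS, **(subject_effects or {}))

    sub = trials[trials["depth"] == subregion]
    if len(sub) == 0:
        raise ConfigError(f"trial table has no trials at depth {subregion!r}")
    ends = sub["stim_onset_s"] + np.where(
        sub["rt_ms"].notna(), sub["rt_ms"], cfg.deadline_ms
    ) / 1000.0
    dur = float(ends.max()) + 2.0
    fs = cfg.fs_raw
    n = int(round(dur * fs))
    t_ax = np.arange(n) / fs

    dorsal = subregion == "dorsal"
    pow_eff = eff["power_effect"]
    responded = sub[sub["response_side"] != NO_RESPONSE]
    beta_level = cfg.beta_ongoing * eff["beta_intercept"]

    def neural_channel() -> np.ndarray:
        # Each microelectrode (2 mm apart) sees predominantly local activity:
        # its own ongoing narrowband realization and its own burst phases,
        # sharing only the response-locked timing and the condition gains.
        x = cfg.theta_ongoing * _narrowband(n, fs, (4.0, 7.0), rng)
        x += beta_level * _narrowband(n, fs, (12.0, 22.0), rng)
        for _, tr in responded.iterrows():
            t_resp = tr["stim_onset_s"] + tr["rt_ms"] / 1000.0
            center = t_resp - 0.150 + rng.uniform(-0.05, 0.05)
            dur_b = rng.uniform(0.30, 0.40)
            nc = tr["correspondence"] == "NC"
            ipsi = hemisphere == tr["response_side"]

            g_theta = cfg.effect_theta_dorsal_NC if (dorsal and nc) else 1.0
            amp_t = cfg.theta_base * g_theta * pow_eff
            _add_burst(x, fs, center, dur_b, rng.uniform(4.5, 6.5), amp_t,
                       rng.uniform(0, 2 * np.pi))

            g_beta = (cfg.effect_beta_ipsi_NC if (ipsi and nc) else 1.0)
            g_beta *= cfg.effect_beta_dorsal if dorsal else 1.0
            amp_b = cfg.beta_base * g_beta * pow_eff * eff["beta_intercept"]
            _add_burst(x, fs, center, dur_b, rng.uniform(13.0, 20.0), amp_b,
                       rng.uniform(0, 2 * np.pi))
        return x

    common = cfg.line_amp * np.sin(
        2.0 * np.pi * cfg.line_freq * t_ax + rng.uniform(0, 2 * np.pi)
    )
    common += cfg.common_amp * pink_noise(n, fs, cfg.pink_exponent, rng)

    channels = np.empty((3, n))
    for i, gain in enumerate(cfg.channel_gains):
        channels[i] = (
            gain * neural_channel()
            + cfg.noise_amp * pink_noise(n, fs, cfg.pink_exponent, rng)
            + common
        )
    return Recording(
        subject_id=subject_id,
        hemisphere=hemisphere,
        subregion=subregion,
        channels=channels,
        fs_raw=fs,
        t0=0.0,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """One subject's trial table, truth effects, and lazily built recordings."""

    subject_id: str
    trials: pd.DataFrame
    effects: dict
    _cfg: SimConfig = field(repr=False, default=None)
    _rec_seeds: dict = field(repr=False, default_factory=dict)

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(sorted({h for h, _ in self._rec_seeds}))

    def recording_keys(self) -> list[tuple[str, str]]:
        return sorted(self._rec_seeds)

    def make_recording(self, hemisphere: str, subregion: str) -> Recording:
        """(Re)build a recording deterministically from its stored seed."""
        seed = self._rec_seeds[(hemisphere, subregion)]
        rng = np.random.default_rng(seed)
        return simulate_recording(
            self._cfg, self.trials, subregion, hemisphere, rng,
            self.effects, self.subject_id,
        )


@dataclass
class Cohort:
    config: SimConfig
    subjects: list[SubjectData]

    def __iter__(self) -> Iterator[SubjectData]:
        return iter(self.subjects)


def simulate_cohort(cfg: SimConfig, include_signals: bool = True) -> Cohort:
    """Simulate the full cohort: behaviour, subject effects and recordings.

    Recordings are exposed lazily (``SubjectData.make_recording``) so that a
    cohort's raw signals never need to be resident in memory at once; each is
    regenerated bit-identically from a per-recording seed derived from
    ``cfg.seed``.  With ``include_signals=False`` only behaviour and subject
    truth are generated (used by the behaviour-tier Monte-Carlo checks).
    """
    root = np.random.SeedSequence(cfg.seed)
    eff_ss, *subj_ss = root.spawn(cfg.n_subjects + 1)
    effects = draw_subject_effects(cfg, np.random.default_rng(eff_ss))

    hemis = list(HEMISPHERES) if cfg.bilateral else ["left"]
    subjects = []
    for i, ss in enumerate(subj_ss):
        beh_ss, rec_ss = ss.spawn(2)
        trials = simulate_behavior(cfg, np.random.default_rng(beh_ss), effects[i])
        rec_seeds = {}
        if include_signals:
            children = rec_ss.spawn(len(hemis) * len(SUBREGIONS))
            k = 0
            for h in hemis:
                for d in SUBREGIONS:
                    rec_seeds[(h, d)] = children[k]
                    k += 1
        subjects.append(
            SubjectData(
                subject_id=f"S{i:02d}",
                trials=trials,
                effects=effects[i],
                _cfg=cfg,
                _rec_seeds=rec_seeds,
            )
        )
    return Cohort(config=cfg, subjects=subjects)


# ---------------------------------------------------------------------------
# cell tier
# ---------------------------------------------------------------------------

def simulate_powercells(
    cfg: SimConfig,
    band: str,
    rng: np.random.Generator | None = None,
    effects: list[dict] | None = None,
) -> pd.DataFrame:
    """Draw normalized band-power cells directly from the mixed-model structure.

    Each row is one (subject, subregion, relative hemisphere, correspondence,
    time bin) cell on the power-*ratio* scale.  The log-scale cell mean is
    the band's grand mean plus ``effect_transfer * log(burst gain)`` for the
    condition gains configured on the signal tier, plus a subject random
    intercept, a subject random slope for correspondence, a random time-bin
    slope nested within subregion x correspondence, and residual noise.

    This tier makes replicate-heavy calibration of the statistical model
    (type-I error, contrast power) feasible; it deliberately bypasses the
    signal chain, which the signal tier covers.
    """
    if band not in ("theta", "beta"):
        raise ConfigError(f"unknown band {band!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if effects is None:
        effects = draw_subject_effects(cfg, rng)

    base = cfg.theta_cell_base if band == "theta" else cfg.beta_cell_base
    rows = []
    bins = np.arange(1, 5)
    bin_c = bins - 2.5  # centered time-bin covariate for the random slope
    for i, eff in enumerate(effects):
        u0 = np.log(eff["power_effect"]) if eff["power_effect"] else 0.0
        u_corr = eff["corr_slope"]
        for s in SUBREGIONS:
            for c in ("Cs", "NC"):
                t_slope = rng.normal(0.0, cfg.time_slope_sd)
                for h in ("ipsilateral", "contralateral"):
                    if band == "theta":
                        gain = cfg.effect_theta_dorsal_NC if (s == "dorsal" and c == "NC") else 1.0
                    else:
                        gain = cfg.effect_beta_ipsi_NC if (h == "ipsilateral" and c == "NC") else 1.0
                        gain *= cfg.effect_beta_dorsal if s == "dorsal" else 1.0
                    mu = base + cfg.effect_transfer * np.log(gain)
                    mu += u0 + (u_corr if c == "NC" else 0.0)
                    vals = mu + t_slope * bin_c + rng.normal(0.0, cfg.cell_noise_sd, 4)
                    for b, v in zip(bins, vals):
                        rows.append(
                            (f"S{i:02d}", s, h, c, band, int(b), float(np.exp(v)), np.nan, 1)
                        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "subregion", "hemisphere_rel", "correspondence",
            "band", "time_bin", "power_ratio", "power_z", "n_trials",
        ],
    )


def null_config(**overrides) -> SimConfig:
    """A SimConfig with every condition effect switched off (null generator)."""
    base = dict(
        effect_theta_dorsal_NC=1.0,
        effect_beta_ipsi_NC=1.0,
        effect_beta_dorsal=1.0,
        simon_rt_shift_ms=0.0,
        p_impulse_error=0.0,
        p_nc_residual=0.0,
        baseline_beta_behavior_rho=0.0,
        suppression_gain=0.0,
    )
    base.update(overrides)
    return SimConfig(**base)
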