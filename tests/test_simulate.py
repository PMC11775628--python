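import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.stats import spearmanr, ttest_ind

from stnlfp import SimConfig, simulate_behavior, simulate_cohort, simulate_recording
from stnlfp.behavior import subject_measures, trim_rts
from stnlfp.datamodel import ConfigError
from stnlfp.simulate import null_config, simulate_powercells


def test_config_validation():
    with pytest.raises(ConfigError):
        SimConfig(trials_per_block=100)
    with pytest.raises(ConfigError):
        SimConfig(rt_mu=1200.0)
    with pytest.raises(ConfigError):
        SimConfig(p_impulse_error=1.5)


def test_seed_determinism_at_every_granularity(tiny_cfg):
    a = simulate_cohort(tiny_cfg)
    b = simulate_cohort(tiny_cfg)
    assert a.subjects[0].trials.equals(b.subjects[0].trials)
    ra = a.subjects[1].make_recording("left", "dorsal")
    rb = b.subjects[1].make_recording("left", "dorsal")
    assert np.array_equal(ra.channels, rb.channels)
    c = simulate_cohort(dataclasses.replace(tiny_cfg, seed=12))
    assert not c.subjects[0].trials["rt_ms"].equals(a.subjects[0].trials["rt_ms"])


def test_null_config_has_no_simon_effect():
    frames = [
        simulate_behavior(null_config(seed=s)).assign(subject_id=f"S{s}")
        for s in range(12)
    ]
    t = pd.concat(frames, ignore_index=True)
    ok = t[t["accuracy"] == "correct"]
    cs = ok.loc[ok["correspondence"] == "Cs", "rt_ms"]
    nc = ok.loc[ok["correspondence"] == "NC", "rt_ms"]
    diff = nc.mean() - cs.mean()
    se = np.sqrt(cs.var() / len(cs) + nc.var() / len(nc))
    assert abs(diff) < 3.5 * se
    resp = t[t["response_side"] != "none"]
    acc = resp.groupby("correspondence")["accuracy"].apply(lambda a: (a == "correct").mean())
    assert abs(acc["Cs"] - acc["NC"]) < 0.02


def test_simon_rt_shift_recovered_at_large_n():
    frames = [simulate_behavior(SimConfig(seed=s)) for s in range(20)]
    t = pd.concat(frames, ignore_index=True)
    assert len(t) >= 10_000
    ok = t[t["accuracy"] == "correct"]
    diff = (
        ok.loc[ok["correspondence"] == "NC", "rt_ms"].mean()
        - ok.loc[ok["correspondence"] == "Cs", "rt_ms"].mean()
    )
    assert abs(diff - 40.0) <= 5.0


def test_impulse_errors_concentrate_in_fastest_bin():
    cfg = SimConfig(p_impulse_error=0.3, seed=21)
    t = simulate_behavior(cfg).assign(subject_id="S0")
    resp = trim_rts(t)
    resp = resp[(resp["response_side"] != "none") & (resp["correspondence"] == "NC")]
    q = resp["rt_ms"].quantile([0.25, 0.75])
    fast = resp[resp["rt_ms"] <= q[0.25]]
    slow = resp[resp["rt_ms"] >= q[0.75]]
    assert (fast["accuracy"] == "correct").mean() < (slow["accuracy"] == "correct").mean()


def _welch_band(x, fs, band):
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), int(fs)))
    sel = (f >= band[0]) & (f <= band[1])
    return p[sel].mean()


def test_burst_spectral_selectivity(rng):
    """Generated bursts put >=5x more power in their own band (periodogram oracle)."""
    from stnlfp.simulate import _add_burst

    fs = 1000.0
    for band, carrier in (((4, 7), 5.5), ((12, 22), 16.0)):
        x = np.zeros(int(20 * fs))
        for k in range(30):
            _add_burst(x, fs, 0.4 + 0.65 * k, 0.35, carrier, 1.0, rng.uniform(0, 2 * np.pi))
        own = _welch_band(x, fs, band)
        other = _welch_band(x, fs, (12, 22) if band == (4, 7) else (4, 7))
        assert own >= 5.0 * other


def test_white_noise_degenerate_config(rng):
    cfg = SimConfig(
        line_amp=0.0, pink_exponent=0.0, theta_base=0.0, beta_base=0.0,
        theta_ongoing=0.0, beta_ongoing=0.0, common_amp=0.0,
        blocks_per_depth=1, fs_raw=4000.0, seed=2,
    )
    trials = simulate_behavior(cfg, np.random.default_rng(3))
    rec = simulate_recording(cfg, trials, "dorsal", "left", np.random.default_rng(4))
    f, p = sps.welch(rec.channels[0], fs=rec.fs_raw, nperseg=4096)
    sel = (f > 1) & (f < rec.fs_raw / 2 * 0.9)
    slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
    assert abs(slope) < 0.1


def test_dorsal_nc_theta_gain_detected_by_welch_oracle():
    """Pre-response theta power: dorsal NC > Cs (one-sided, p<0.01, ~200 trials)."""
    cfg = SimConfig(effect_theta_dorsal_NC=2.0, fs_raw=4000.0, seed=6)
    trials = simulate_behavior(cfg, np.random.default_rng(7))
    rec = simulate_recording(cfg, trials, "dorsal", "left", np.random.default_rng(8))
    sub = trials[(trials["depth"] == "dorsal") & (trials["response_side"] != "none")]
    assert len(sub) >= 200
    powers = {"Cs": [], "NC": []}
    for _, tr in sub.iterrows():
        t_resp = tr["stim_onset_s"] + tr["rt_ms"] / 1000.0
        i1 = int(t_resp * rec.fs_raw)
        i0 = i1 - int(0.380 * rec.fs_raw)
        powers[tr["correspondence"]].append(
            _welch_band(rec.channels[0][i0:i1], rec.fs_raw, (4, 7))
        )
    t, p = ttest_ind(powers["NC"], powers["Cs"], alternative="greater")
    assert p < 0.01


def test_cohort_bookkeeping():
    cohort = simulate_cohort(SimConfig(seed=0), include_signals=False)
    assert len(cohort.subjects) == 10
    full = simulate_cohort(SimConfig(n_subjects=2, blocks_per_depth=1, fs_raw=4000.0, seed=0))
    keys = full.subjects[0].recording_keys()
    assert keys == [("left", "dorsal"), ("left", "ventral"),
                    ("right", "dorsal"), ("right", "ventral")]
    # per-subject effects shared across that subject's recordings
    assert full.subjects[0].effects is full.subjects[0].effects


def _cohort_rho(seed, **overrides):
    cfg = SimConfig(seed=seed, **overrides)
    cohort = simulate_cohort(cfg, include_signals=False)
    betas, effects = [], []
    for subj in cohort:
        m = subject_measures(trim_rts(subj.trials.assign(subject_id=subj.subject_id)))
        effects.append(m.loc[m["depth"] == "ventral", "simon_acc_pct"].iloc[0])
        betas.append(subj.effects["beta_intercept"])
    return spearmanr(betas, effects)[0]


def test_beta_behavior_coupling_strength():
    rhos = np.array([_cohort_rho(500 + i) for i in range(50)])
    assert (rhos >= 0.5).mean() >= 0.7
    assert rhos.mean() > 0.5


def test_beta_behavior_coupling_null():
    rhos = np.array(
        [_cohort_rho(700 + i, baseline_beta_behavior_rho=0.0) for i in range(150)]
    )
    assert abs(rhos.mean()) < 0.08


def test_powercell_tier_structure():
    cells = simulate_powercells(SimConfig(seed=3), "theta")
    assert len(cells) == 10 * 2 * 2 * 2 * 4
    key = ["subject_id", "subregion", "hemisphere_rel", "correspondence", "time_bin"]
    assert not cells.duplicated(subset=key).any()
    assert (cells["power_ratio"] > 0).all()
    a = simulate_powercells(SimConfig(seed=3), "beta")
    b = simulate_powercells(SimConfig(seed=3), "beta")
    assert a.equals(b)
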