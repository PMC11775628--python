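"""Shared domain types, label conventions and invariants.

Coordinate conventions used throughout the package:

* event times are stored in **seconds from recording start** (``t0``);
* analysis windows are expressed in **milliseconds relative to the button
  response** (time 0 = response), half-open ``[-380, 0)``;
* hemispheres are recorded as anatomical ``left``/``right`` and analysed as
  ``ipsilateral``/``contralateral`` **relative to the responding hand**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
SUBREGIONS = ("dorsal", "ventral")
CORRESPONDENCE_LEVELS = ("Cs", "NC")
REL_HEMISPHERES = ("ipsilateral", "contralateral")
ACCURACY_LEVELS = ("correct", "error", "omission", "too_early")
BANDS = ("theta", "beta")

#: minimum raw sampling rate (Hz); the LFP analysis extends to 100 Hz so the
#: raw signal must at least satisfy Nyquist for that band.
MIN_FS_RAW = 200.0


class StnLfpError(Exception):
    """Base class for all labelled errors raised by this package."""


class LabelError(StnLfpError, ValueError):
    """An enum-like field received a value outside its allowed labels."""


class SchemaError(StnLfpError, ValueError):
    """A container violates the on-disk schema (channels, version, columns)."""


class ConsistencyError(StnLfpError, ValueError):
    """Cross-field invariant violated (e.g. correspondence vs stimulus side)."""


class ConfigError(StnLfpError, ValueError):
    """An infeasible or inconsistent configuration object."""


class NumericalError(StnLfpError, ValueError):
    """A numerically invalid operation (zero baseline, zero variance...)."""


def _check_label(value: str, allowed: tuple[str, ...], name: str) -> str:
    if value not in allowed:
        raise LabelError(f"{name} must be one of {allowed}, got {value!r}")
    return value


def classify_correspondence(stim_side: str, correct_side: str) -> str:
    """Classify a Simon trial as corresponding (Cs) or non-corresponding (NC).

    A trial is corresponding when the task-irrelevant stimulus location and
    the colour-rule response side agree; otherwise the location-driven
    impulse conflicts with the instructed response (NC).
    """
    _check_label(stim_side, HEMISPHERES, "stim_side")
    _check_label(correct_side, HEMISPHERES, "correct_side")
    return "Cs" if stim_side == correct_side else "NC"


def relabel_hemisphere(recording_hemisphere: str, response_side: str) -> str:
    """Relabel an anatomical hemisphere relative to the responding hand.

    The recording hemisphere is *ipsilateral* when it matches the side of the
    hand that produced the response, *contralateral* otherwise.
    """
    _check_label(recording_hemisphere, HEMISPHERES, "recording_hemisphere")
    _check_label(response_side, HEMISPHERES, "response_side")
    if recording_hemisphere == response_side:
        return "ipsilateral"
    return "contralateral"


@dataclass
class Recording:
    """One depth x hemisphere multichannel microelectrode recording.

    ``channels`` holds three parallel voltage traces (arbitrary units) as a
    ``(3, n_samples)`` array sampled at ``fs_raw``; ``t0`` is the recording
    start time in seconds (event times in the trial table are relative to it).
    """

    subject_id: str
    hemisphere: str
    subregion: str
    channels: np.ndarray
    fs_raw: float = 44000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        _check_label(self.hemisphere, HEMISPHERES, "hemisphere")
        _check_label(self.subregion, SUBREGIONS, "subregion")
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 2 or self.channels.shape[0] != 3:
            raise SchemaError(
                "Recording requires exactly 3 channels of equal length; "
                f"got array of shape {self.channels.shape}"
            )
        if not np.all(np.isfinite(self.channels)):
            raise SchemaError("Recording channels contain non-finite values")
        if self.fs_raw <= MIN_FS_RAW:
            raise SchemaError(
                f"fs_raw must exceed {MIN_FS_RAW} Hz (2 x 100 Hz analysis band), "
                f"got {self.fs_raw}"
            )

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_raw


#: canonical column order of the trial-table CSV schema.
TRIAL_COLUMNS = [
    "trial_id",
    "block",
    "depth",
    "stim_onset_s",
    "stim_side",
    "correct_side",
    "response_side",
    "rt_ms",
    "correspondence",
    "accuracy",
    "iti_prev_ms",
]

#: sentinel used in the CSV for "no response" / "not applicable".
NO_RESPONSE = "none"


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the schema and its invariants.

    Checks column presence, label domains, Cs/NC consistency with the
    stimulus/correct sides, and response/RT coherence. Returns the table with
    canonical column order and dtypes.

    Raises
    ------
    SchemaError
        missing or extra-typed columns.
    ConsistencyError
        a row whose correspondence label contradicts its sides, or a
        responded trial without an RT (and vice versa).
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    t = trials.loc[:, TRIAL_COLUMNS].copy()
    t["trial_id"] = t["trial_id"].astype(int)
    t["block"] = t["block"].astype(int)
    t["rt_ms"] = pd.to_numeric(t["rt_ms"], errors="coerce")
    t["iti_prev_ms"] = pd.to_numeric(t["iti_prev_ms"], errors="coerce")

    for col, allowed in [
        ("depth", SUBREGIONS),
        ("stim_side", HEMISPHERES),
        ("correct_side", HEMISPHERES),
        ("correspondence", CORRESPONDENCE_LEVELS),
        ("accuracy", ACCURACY_LEVELS),
    ]:
        bad = set(t[col].unique()) - set(allowed)
        if bad:
            raise LabelError(f"column {col!r} contains invalid labels {sorted(bad)}")
    bad_resp = set(t["response_side"].unique()) - set(HEMISPHERES) - {NO_RESPONSE}
    if bad_resp:
        raise LabelError(f"column 'response_side' contains invalid labels {sorted(bad_resp)}")

    expected = np.where(t["stim_side"] == t["correct_side"], "Cs", "NC")
    mism = t.index[t["correspondence"].to_numpy() != expected]
    if len(mism):
        raise ConsistencyError(
            f"correspondence label contradicts stim/correct sides in rows {list(mism[:5])}"
        )
    responded = t["response_side"] != NO_RESPONSE
    if (responded & t["rt_ms"].isna()).any():
        raise ConsistencyError("responded trials must carry an rt_ms")
    if ((~responded) & t["rt_ms"].notna()).any():
        raise ConsistencyError("trials without a response must have empty rt_ms")
    return t


@dataclass
class BandEpoch:
    """Response-locked band-power epoch for one included-candidate trial.

    ``power_trace`` covers the analysis window [-380, 0) ms relative to the
    button response at the analysis rate (1000 Hz); ``baseline_power`` is the
    equal-length baseline window drawn per the configured baseline policy.
    ``broadband_*`` carry the 1-100 Hz mean-power series used by the trial QC
    test; ``included`` is the outcome of that test.
    """

    subject_id: str
    subregion: str
    hemisphere_rel: str
    correspondence: str
    band: str
    trial_id: int
    power_trace: np.ndarray
    baseline_power: np.ndarray
    broadband_trace: np.ndarray | None = None
    broadband_baseline: np.ndarray | None = None
    included: bool = True
    qc_p: float = field(default=np.nan)

    def __post_init__(self) -> None:
        _check_label(self.subregion, SUBREGIONS, "subregion")
        _check_label(self.hemisphere_rel, REL_HEMISPHERES, "hemisphere_rel")
        _check_label(self.correspondence, CORRESPONDENCE_LEVELS, "correspondence")
        _check_label(self.band, BANDS, "band")
        self.power_trace = np.asarray(self.power_trace, dtype=np.float64)
        self.baseline_power = np.asarray(self.baseline_power, dtype=np.float64)
        if self.power_trace.shape != self.baseline_power.shape:
            raise SchemaError("analysis and baseline windows must have equal length")


#: columns of the PowerCell table, the unit of analysis of the mixed model.
POWERCELL_COLUMNS = [
    "subject_id",
    "subregion",
    "hemisphere_rel",
    "correspondence",
    "band",
    "time_bin",
    "power_ratio",
    "power_z",
    "n_trials",
]
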