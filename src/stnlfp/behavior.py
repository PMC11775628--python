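"""Simon-task behavioural battery.

RT trimming (150 ms anticipation cutoff, then a single-pass mean + 3 SD rule
within subject x depth x correspondence), condition summaries, distributional
analyses (delta plots across rank-ordered RT bins and conditional accuracy
functions), and paired t-tests with Cohen's d.

Conventions: accuracy denominators count responded trials only (omissions and
too-early trials are excluded); conditional accuracy functions are computed on
responded trials including errors, delta plots on correct trials only.
Subject-level measures are aggregated first; group inference is a paired
t-test over subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .datamodel import NO_RESPONSE, NumericalError, SchemaError

RT_FLOOR_MS = 150.0
SD_CRITERION = 3.0


def trim_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove anticipations and slow outliers from responded trials.

    RTs below 150 ms are removed first; then, within each subject x depth x
    correspondence cell, RTs strictly above mean + 3 SD of the remaining
    responded trials are removed (one pass, no re-iteration).  Non-responded
    trials (omission/too-early) pass through untouched so accuracy analyses
    retain them.
    """
    t = trials.copy()
    responded = t["response_side"] != NO_RESPONSE
    keep = ~responded | (t["rt_ms"] >= RT_FLOOR_MS)
    t = t[keep].copy()

    group_cols = [c for c in ("subject_id", "depth", "correspondence") if c in t.columns]
    resp = t["response_side"] != NO_RESPONSE
    stats = (
        t[resp]
        .groupby(group_cols)["rt_ms"]
        .agg(["mean", "std"])
        .rename(columns={"mean": "_m", "std": "_s"})
    )
    t = t.join(stats, on=group_cols)
    cut = t["_m"] + SD_CRITERION * t["_s"].fillna(0.0)
    keep = ~resp | (t["rt_ms"] <= cut) | cut.isna()
    return t[keep].drop(columns=["_m", "_s"]).reset_index(drop=True)


def _responded(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["response_side"] != NO_RESPONSE]


def condition_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean correct-trial RT and percent-correct per depth x correspondence.

    Expects a trimmed table.  Accuracy = correct / responded trials (in %).
    When a ``subject_id`` column is present, subject-level means are computed
    first and then averaged, so each subject carries equal weight.
    """
    r = _responded(trials).copy()
    r["correct"] = (r["accuracy"] == "correct").astype(float)
    by_subject = "subject_id" in r.columns
    keys = ["depth", "correspondence"] + (["subject_id"] if by_subject else [])
    g = r.groupby(keys)
    per = g.apply(
        lambda d: pd.Series(
            {
                "mean_rt_ms": d.loc[d["correct"] == 1.0, "rt_ms"].mean(),
                "accuracy_pct": 100.0 * d["correct"].mean(),
            }
        ),
        include_groups=False,
    ).reset_index()
    if by_subject:
        per = (
            per.groupby(["depth", "correspondence"], as_index=False)[
                ["mean_rt_ms", "accuracy_pct"]
            ].mean()
        )
    return per.sort_values(["depth", "correspondence"], ignore_index=True)


def simon_effects(summary: pd.DataFrame) -> pd.DataFrame:
    """NC - Cs RT cost and Cs - NC accuracy cost per depth, from a summary."""
    wide_rt = summary.pivot(index="depth", columns="correspondence", values="mean_rt_ms")
    wide_ac = summary.pivot(index="depth", columns="correspondence", values="accuracy_pct")
    out = pd.DataFrame(
        {
            "simon_rt_ms": wide_rt["NC"] - wide_rt["Cs"],
            "simon_acc_pct": wide_ac["Cs"] - wide_ac["NC"],
        }
    ).reset_index()
    return out


def quantile_bins(rts: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Assign rank-ordered RTs to equal-sized bins (1 = fastest).

    A stable sort keeps tied RTs in input order; with remainder ``r``, the
    first ``r`` bins receive one extra trial.  Returns the bin label of each
    input element, aligned to input order.
    """
    rts = np.asarray(rts, dtype=np.float64)
    n = len(rts)
    if n < n_bins:
        raise SchemaError(f"need at least {n_bins} trials to form {n_bins} bins")
    order = np.argsort(rts, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1
    labels_sorted = np.repeat(np.arange(1, n_bins + 1), sizes)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def delta_plot(
    cs_rts: np.ndarray, nc_rts: np.ndarray, n_bins: int = 4
) -> pd.DataFrame:
    """Interference across the RT distribution (one subject's correct trials).

    Cs and NC RTs are binned separately; per bin ``b`` the interference is
    ``d_b = meanRT_NC,b - meanRT_Cs,b`` plotted at
    ``x_b = (meanRT_NC,b + meanRT_Cs,b) / 2``.
    """
    cs_rts, nc_rts = np.asarray(cs_rts, float), np.asarray(nc_rts, float)
    rows = []
    for b in range(1, n_bins + 1):
        m_cs = cs_rts[quantile_bins(cs_rts, n_bins) == b].mean()
        m_nc = nc_rts[quantile_bins(nc_rts, n_bins) == b].mean()
        rows.append((b, (m_nc + m_cs) / 2.0, m_nc - m_cs))
    return pd.DataFrame(rows, columns=["bin", "mean_rt", "interference"])


def final_delta_slope(delta: pd.DataFrame) -> float:
    """Slope of the delta plot between its last two bins.

    The most sensitive index of selective impulse suppression: a negative
    final slope means interference shrinks at the slow end of the RT
    distribution.
    """
    d = delta.sort_values("bin").iloc[-2:]
    dx = d["mean_rt"].iloc[1] - d["mean_rt"].iloc[0]
    if dx == 0:
        raise NumericalError("final delta slope undefined: equal bin mean RTs")
    return float((d["interference"].iloc[1] - d["interference"].iloc[0]) / dx)


def conditional_accuracy(
    trials: pd.DataFrame, n_bins: int = 4
) -> pd.DataFrame:
    """Percent correct per RT bin and correspondence (one subject x depth).

    Binning runs over all *responded* trials (errors included), separately
    within Cs and NC; depressed accuracy in the fastest NC bin indexes
    capture by the location-driven response impulse.
    """
    r = _responded(trials)
    rows = []
    for corr, d in r.groupby("correspondence"):
        bins = quantile_bins(d["rt_ms"].to_numpy(), n_bins)
        for b in range(1, n_bins + 1):
            sel = d[bins == b]
            if len(sel) == 0:
                raise SchemaError(f"empty RT bin {b} for {corr}")
            rows.append((corr, b, 100.0 * (sel["accuracy"] == "correct").mean()))
    return pd.DataFrame(rows, columns=["correspondence", "bin", "accuracy_pct"])


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided paired t-test with Cohen's d (mean diff / SD of diffs)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise SchemaError("paired_t requires two equal-length vectors, n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, 0.0
        raise NumericalError("zero-variance non-zero differences: t undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * spstats.t.sf(abs(t), n - 1)
    return float(t), float(p), float(d.mean() / sd)


def subject_measures(trials: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Per subject x depth behavioural measures on a trimmed table.

    Columns: mean correct RT and accuracy per correspondence, the Simon RT
    and accuracy effects, the final delta slope and the fastest-NC-bin
    accuracy.  Subjects lacking enough trials for a distributional measure
    get NaN there.
    """
    rows = []
    for (subj, depth), d in trials.groupby(["subject_id", "depth"]):
        r = _responded(d)
        corr_rt = {}
        acc = {}
        for c in ("Cs", "NC"):
            dc = r[r["correspondence"] == c]
            corr_rt[c] = dc.loc[dc["accuracy"] == "correct", "rt_ms"].mean()
            acc[c] = 100.0 * (dc["accuracy"] == "correct").mean() if len(dc) else np.nan
        cs_ok = r[(r["correspondence"] == "Cs") & (r["accuracy"] == "correct")]["rt_ms"]
        nc_ok = r[(r["correspondence"] == "NC") & (r["accuracy"] == "correct")]["rt_ms"]
        slope = np.nan
        if len(cs_ok) >= n_bins and len(nc_ok) >= n_bins:
            slope = final_delta_slope(
                delta_plot(cs_ok.to_numpy(), nc_ok.to_numpy(), n_bins)
            )
        nc_resp = r[r["correspondence"] == "NC"]
        nc_bin1 = np.nan
        if len(nc_resp) >= n_bins:
            caf = conditional_accuracy(nc_resp, n_bins)
            nc_bin1 = float(
                caf.loc[(caf["correspondence"] == "NC") & (caf["bin"] == 1),
                        "accuracy_pct"].iloc[0]
            )
        rows.append(
            {
                "subject_id": subj,
                "depth": depth,
                "rt_cs": corr_rt["Cs"],
                "rt_nc": corr_rt["NC"],
                "acc_cs": acc["Cs"],
                "acc_nc": acc["NC"],
                "simon_rt_ms": corr_rt["NC"] - corr_rt["Cs"],
                "simon_acc_pct": acc["Cs"] - acc["NC"],
                "final_delta_slope": slope,
                "nc_acc_bin1_pct": nc_bin1,
            }
        )
    return pd.DataFrame(rows)


def behavior_summary(trials: pd.DataFrame, n_bins: int = 4) -> pd.DataFrame:
    """Group-level behavioural table (per depth) with paired tests.

    Aggregates :func:`subject_measures` across subjects and tests NC vs Cs
    RT and accuracy per depth (paired t, Cohen's d).  Mirrors the standard
    condition-summary layout of Simon-task reports.
    """
    trimmed = trim_rts(trials)
    per = subject_measures(trimmed, n_bins)
    rows = []
    for depth, d in per.groupby("depth"):
        t_rt, p_rt, d_rt = paired_t(d["rt_nc"], d["rt_cs"])
        t_ac, p_ac, d_ac = paired_t(d["acc_cs"], d["acc_nc"])
        rows.append(
            {
                "depth": depth,
                "n_subjects": len(d),
                "rt_cs": d["rt_cs"].mean(),
                "rt_nc": d["rt_nc"].mean(),
                "acc_cs": d["acc_cs"].mean(),
                "acc_nc": d["acc_nc"].mean(),
                "simon_rt_ms": d["simon_rt_ms"].mean(),
                "simon_acc_pct": d["simon_acc_pct"].mean(),
                "final_delta_slope": d["final_delta_slope"].mean(),
                "nc_acc_bin1_pct": d["nc_acc_bin1_pct"].mean(),
                "t_rt": t_rt, "p_rt": p_rt, "d_rt": d_rt,
                "t_acc": t_ac, "p_acc": p_ac, "d_acc": d_ac,
            }
        )
    return pd.DataFrame(rows)
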