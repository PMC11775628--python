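"""Published group-level summary values from the original intraoperative study.

These tables are inputs for arithmetic cross-checks: marginal means quoted in
the original report must equal unweighted averages of the corresponding cell
entries, and the Simon effects must equal the NC - Cs differences of the
condition cells.  They are *not* targets the synthetic pipeline is fitted to —
patient recordings are not public, so the synthetic generator reproduces the
qualitative structure, not these numbers.

Known internal inconsistencies of the published tables (documented in
docs/methods.md): the ventral Simon RT quoted in the text (34.8 ms) differs
from the cell difference (599.2 - 568.2 = 31.0 ms), and the contralateral
Cs/NC beta marginals quoted in the text appear swapped relative to the cell
averages.  Cross-checks here always report the cell arithmetic.
"""

from __future__ import annotations

import pandas as pd

#: group condition means: RT (ms) and accuracy (% correct) per depth.
BEHAVIOR_TABLE = pd.DataFrame(
    [
        ("dorsal", "Cs", 583.0, 88.54),
        ("dorsal", "NC", 625.1, 81.89),
        ("ventral", "Cs", 568.2, 89.32),
        ("ventral", "NC", 599.2, 84.98),
    ],
    columns=["depth", "correspondence", "mean_rt_ms", "accuracy_pct"],
)

#: distributional measures: final delta slope and fastest-NC-bin accuracy.
DISTRIBUTIONAL_TABLE = pd.DataFrame(
    [
        ("dorsal", 0.08, 71.07),
        ("ventral", -0.11, 69.01),
    ],
    columns=["depth", "final_delta_slope", "nc_acc_bin1_pct"],
)

#: mean log-transformed theta power per condition cell.
THETA_CELLS = pd.DataFrame(
    [
        ("dorsal", "Cs", "ipsilateral", 0.67),
        ("dorsal", "Cs", "contralateral", 0.68),
        ("dorsal", "NC", "ipsilateral", 0.76),
        ("dorsal", "NC", "contralateral", 0.84),
        ("ventral", "Cs", "ipsilateral", 0.64),
        ("ventral", "Cs", "contralateral", 0.60),
        ("ventral", "NC", "ipsilateral", 0.66),
        ("ventral", "NC", "contralateral", 0.65),
    ],
    columns=["subregion", "correspondence", "hemisphere_rel", "log_power"],
)

#: mean log-transformed beta power per condition cell.
BETA_CELLS = pd.DataFrame(
    [
        ("dorsal", "Cs", "ipsilateral", 1.45),
        ("dorsal", "Cs", "contralateral", 1.75),
        ("dorsal", "NC", "ipsilateral", 1.65),
        ("dorsal", "NC", "contralateral", 1.73),
        ("ventral", "Cs", "ipsilateral", 1.48),
        ("ventral", "Cs", "contralateral", 1.55),
        ("ventral", "NC", "ipsilateral", 1.65),
        ("ventral", "NC", "contralateral", 1.47),
    ],
    columns=["subregion", "correspondence", "hemisphere_rel", "log_power"],
)

#: published baseline-power / behaviour Spearman correlations.
CORRELATION_TABLE = pd.DataFrame(
    [
        ("dorsal", "theta", "simon_rt_ms", -0.24),
        ("dorsal", "beta", "simon_rt_ms", 0.26),
        ("ventral", "theta", "simon_rt_ms", 0.08),
        ("ventral", "beta", "simon_rt_ms", 0.32),
        ("dorsal", "theta", "simon_acc_pct", -0.26),
        ("dorsal", "beta", "simon_acc_pct", -0.26),
        ("ventral", "theta", "simon_acc_pct", 0.12),
        ("ventral", "beta", "simon_acc_pct", 0.78),
    ],
    columns=["subregion", "band", "measure", "rho"],
)


def marginal_mean(cells: pd.DataFrame, **levels: str) -> float:
    """Unweighted average of the cell means matching the given factor levels.

    E.g. ``marginal_mean(THETA_CELLS, subregion="dorsal")`` averages the four
    dorsal cells — the quantity quoted as the dorsal marginal mean.
    """
    d = cells
    for col, val in levels.items():
        d = d[d[col] == val]
    if len(d) == 0:
        raise ValueError(f"no cells match {levels!r}")
    return float(d["log_power"].mean())


def simon_effect_rt(depth: str) -> float:
    """NC - Cs mean RT difference (ms) from the behaviour condition cells."""
    d = BEHAVIOR_TABLE[BEHAVIOR_TABLE["depth"] == depth].set_index("correspondence")
    return float(d.loc["NC", "mean_rt_ms"] - d.loc["Cs", "mean_rt_ms"])


def simon_effect_acc(depth: str) -> float:
    """Cs - NC accuracy difference (percentage points) from the cells."""
    d = BEHAVIOR_TABLE[BEHAVIOR_TABLE["depth"] == depth].set_index("correspondence")
    return float(d.loc["Cs", "accuracy_pct"] - d.loc["NC", "accuracy_pct"])
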