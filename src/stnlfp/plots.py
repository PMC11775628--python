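"""Diagnostic figures for the behavioural distributional analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .behavior import conditional_accuracy, delta_plot, trim_rts


def plot_distributional(trials: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Delta plot and conditional accuracy function per depth (group level).

    Trials are pooled across subjects after trimming; one PNG per figure is
    written to ``out_dir`` and the paths returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = trim_rts(trials)
    paths = []
    for depth, d in t.groupby("depth"):
        ok = d[d["accuracy"] == "correct"]
        cs = ok.loc[ok["correspondence"] == "Cs", "rt_ms"].to_numpy()
        nc = ok.loc[ok["correspondence"] == "NC", "rt_ms"].to_numpy()
        delta = delta_plot(cs, nc)
        caf = conditional_accuracy(d[d["response_side"] != "none"])

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        axes[0].plot(delta["mean_rt"], delta["interference"], "o-k")
        axes[0].set_xlabel("mean RT (ms)")
        axes[0].set_ylabel("NC - Cs interference (ms)")
        axes[0].set_title(f"delta plot ({depth})")
        for corr, style in (("Cs", "o-k"), ("NC", "s--b")):
            sel = caf[caf["correspondence"] == corr]
            axes[1].plot(sel["bin"], sel["accuracy_pct"], style, label=corr)
        axes[1].set_xlabel("RT bin (1 = fastest)")
        axes[1].set_ylabel("accuracy (%)")
        axes[1].set_title(f"conditional accuracy ({depth})")
        axes[1].legend()
        fig.tight_layout()
        path = out_dir / f"distributional_{depth}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
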