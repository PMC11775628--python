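"""End-to-end orchestration: simulate/ingest -> preprocess -> spectral ->
behaviour -> statistics, with reproducible report generation.

A run is fully determined by its :class:`RunConfig` (which embeds the
generator, preprocessing, time-frequency and model configurations plus the
seed): re-running with the same configuration yields byte-identical CSV
outputs.  Every excluded trial appears exactly once in the QC log with a
reason code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavior_summary, subject_measures, trim_rts
from .preprocess import PreprocConfig
from .simulate import Cohort, SimConfig, simulate_cohort
from .spectral import (
    TFConfig,
    analyze_recording,
    baseline_band_summary,
    powercells_from_epochs,
)
from .stats import (
    ModelResult,
    ModelSpec,
    cell_contrast,
    correlation_table,
    fit_mixed,
    prepare_model_frame,
)

log = logging.getLogger("stnlfp")

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Complete, serializable parameterization of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    pre: PreprocConfig = field(default_factory=PreprocConfig)
    tf: TFConfig = field(default_factory=TFConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    seed: int | None = None  # overrides sim.seed when given
    out_dir: str = "stnlfp_run"
    log_level: str = "INFO"

    def resolved_sim(self) -> SimConfig:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {
            "sim": enc(self.sim),
            "pre": enc(self.pre),
            "tf": enc(self.tf),
            "model": enc(self.model),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = SimConfig(**{k: _tupled(v) for k, v in d.get("sim", {}).items()})
        pre = PreprocConfig(**{k: _tupled(v) for k, v in d.get("pre", {}).items()})
        tf_kwargs = {k: _tupled(v) for k, v in d.get("tf", {}).items()}
        if "freqs" in tf_kwargs:
            tf_kwargs["freqs"] = np.asarray(tf_kwargs["freqs"], dtype=float)
        tf = TFConfig(**tf_kwargs)
        model = ModelSpec(**d.get("model", {}))
        return cls(
            sim=sim, pre=pre, tf=tf, model=model,
            seed=d.get("seed"), out_dir=d.get("out_dir", "stnlfp_run"),
            log_level=d.get("log_level", "INFO"),
        )

    def scientific_dict(self) -> dict:
        """The config without run-local bookkeeping (output path, log level)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.scientific_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


# ---------------------------------------------------------------------------
# cohort-level analysis
# ---------------------------------------------------------------------------

def analyze_cohort(
    cohort: Cohort,
    pre_cfg: PreprocConfig | None = None,
    tf_cfg: TFConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run preprocessing and the spectral chain over every cohort recording.

    Recordings are regenerated lazily one at a time, so memory stays bounded
    by a single raw trace.  Returns ``(powercells, baselines, qc_log)``.
    """
    pre_cfg = pre_cfg or PreprocConfig()
    tf_cfg = tf_cfg or TFConfig()
    all_epochs = []
    qc_rows = []
    for subj in cohort:
        for hemi, depth in subj.recording_keys():
            rec = subj.make_recording(hemi, depth)
            log.info("spectral: subject=%s hemisphere=%s depth=%s (%.0f s)",
                     subj.subject_id, hemi, depth, rec.duration_s)
            epochs, dropped = analyze_recording(rec, subj.trials, pre_cfg, tf_cfg)
            all_epochs.extend(epochs)
            for row in dropped:
                qc_rows.append(
                    {"subject_id": subj.subject_id, "hemisphere": hemi,
                     "depth": depth, **row}
                )
    cells = powercells_from_epochs(all_epochs, tf_cfg)
    baselines = baseline_band_summary(all_epochs)
    qc_log = pd.DataFrame(qc_rows, columns=["subject_id", "hemisphere", "depth",
                                            "trial_id", "reason"])
    return cells, baselines, qc_log


#: the comparisons of interest, as (name, band, cell_a, cell_b).
DEFAULT_CONTRASTS = [
    ("theta_dorsal_nc_vs_cs", "theta",
     {"subregion": "dorsal", "correspondence": "NC"},
     {"subregion": "dorsal", "correspondence": "Cs"}),
    ("theta_ventral_nc_vs_cs", "theta",
     {"subregion": "ventral", "correspondence": "NC"},
     {"subregion": "ventral", "correspondence": "Cs"}),
    ("beta_ipsi_nc_vs_cs", "beta",
     {"hemisphere_rel": "ipsilateral", "correspondence": "NC"},
     {"hemisphere_rel": "ipsilateral", "correspondence": "Cs"}),
    ("beta_contra_nc_vs_cs", "beta",
     {"hemisphere_rel": "contralateral", "correspondence": "NC"},
     {"hemisphere_rel": "contralateral", "correspondence": "Cs"}),
    ("beta_dorsal_vs_ventral", "beta",
     {"subregion": "dorsal"}, {"subregion": "ventral"}),
]


def fit_band_models(
    cells: pd.DataFrame, model_spec: ModelSpec | None = None
) -> tuple[dict[str, ModelResult], pd.DataFrame]:
    """Fit the theta and beta mixed models and the standard contrasts."""
    model_spec = model_spec or ModelSpec()
    models: dict[str, ModelResult] = {}
    contrast_rows = []
    for band in ("theta", "beta"):
        frame = prepare_model_frame(cells, band)
        models[band] = fit_mixed(frame, model_spec)
    for name, band, a, b in DEFAULT_CONTRASTS:
        c = cell_contrast(models[band], a, b)
        contrast_rows.append(
            {"contrast": name, "band": band, "estimate": c.estimate,
             "se": c.se, "t": c.t, "df": c.df, "p": c.p}
        )
    return models, pd.DataFrame(contrast_rows)


@dataclass
class RunResult:
    """All tables produced by one end-to-end run."""

    behavior: pd.DataFrame
    subject_behavior: pd.DataFrame
    powercells: pd.DataFrame
    baselines: pd.DataFrame
    theta_model: ModelResult
    beta_model: ModelResult
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    qc_log: pd.DataFrame
    out_dir: Path | None = None


def run_all(cfg: RunConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline and (optionally) write the report bundle.

    Stages: simulate -> preprocess -> spectral -> behaviour -> statistics.
    The report bundle contains the behaviour summary, theta/beta cell-mean
    and fixed-effect tables, the contrast table, the baseline/behaviour
    correlation table, the QC log, and a provenance JSON (config, hash,
    seed, package version).
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    sim = cfg.resolved_sim()

    log.info("simulate: %d subjects, seed=%d", sim.n_subjects, sim.seed)
    cohort = simulate_cohort(sim)
    trials = pd.concat(
        [s.trials.assign(subject_id=s.subject_id) for s in cohort],
        ignore_index=True,
    )

    cells, baselines, qc_log = analyze_cohort(cohort, cfg.pre, cfg.tf)

    log.info("behaviour: %d trials", len(trials))
    beh = behavior_summary(trials)
    subj_beh = subject_measures(trim_rts(trials))

    log.info("statistics: mixed models and contrasts")
    models, contrasts = fit_band_models(cells, cfg.model)
    correlations = correlation_table(baselines, subj_beh)

    result = RunResult(
        behavior=beh,
        subject_behavior=subj_beh,
        powercells=cells,
        baselines=baselines,
        theta_model=models["theta"],
        beta_model=models["beta"],
        contrasts=contrasts,
        correlations=correlations,
        qc_log=qc_log,
    )
    if write:
        result.out_dir = write_bundle(result, cfg)
    return result


def write_bundle(result: RunResult, cfg: RunConfig) -> Path:
    """Write the report bundle with deterministic formatting."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False, float_format=_FLOAT_FMT)

    save(result.behavior, "behavior_summary.csv")
    save(result.subject_behavior, "subject_behavior.csv")
    save(result.powercells, "powercells.csv")
    save(result.baselines, "baselines.csv")
    for band, model in (("theta", result.theta_model), ("beta", result.beta_model)):
        save(model.cell_means, f"{band}_cell_means.csv")
        save(model.fixed_table.assign(ladder_step=model.ladder_step),
             f"{band}_fixed_effects.csv")
    save(result.contrasts, "contrasts.csv")
    save(result.correlations, "correlations.csv")
    save(result.qc_log, "qc_log.csv")

    provenance = {
        "package": "stnlfp",
        "version": __version__,
        "config": cfg.scientific_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.resolved_sim().seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return out
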