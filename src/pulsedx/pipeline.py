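"""End-to-end orchestration: simulate → preprocess → extract → fit → evaluate.

The evaluation grid mirrors the candidate-variable comparison of the study
design: one-variable discriminant functions for each of ⟨PP⟩, PP^max,
⟨MPA⟩ and MPA^max, the four-variable ("sum") discriminant function, and the
mixed-variable sequential threshold model, each scored on the entire data
and by leave-one-out cross-validation with accuracy and MCC.

Every intermediate (cohort CSV, feature CSV, model JSON, predictions,
report) is persisted with a manifest so each printed number is recomputable
from files on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .discriminant import FisherDiscriminant, loocv
from .features import feature_table, write_feature_csv
from .metrics import accuracy, confusion, mcc
from .thresholds import MixedThreshold
from .waveform import extract_amplitude_matrix

CANONICAL_STAGES = ("simulate", "preprocess", "extract", "fit", "evaluate")
SINGLE_VARIABLES = ("PP_avg", "PP_max", "MPA_avg", "MPA_max")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    stages: tuple = CANONICAL_STAGES
    seed: int = 0
    out_dir: str | Path = "pulsedx_run"
    mode: str = "amplitudes"              # "amplitudes" or "waveforms"
    n_subjects: int = 70
    prevalence_excess: float = 44.0 / 70.0
    noise_sd: float = synthetic.DEFAULT_NOISE_SD
    excess_scale: float = synthetic.DEFAULT_EXCESS_SCALE
    focal_tilt: float = synthetic.DEFAULT_FOCAL_TILT
    primary: str = "PP_avg"
    secondary: str = "PP_max"
    priors: str = "proportional"
    verbosity: int = 1

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if stages != CANONICAL_STAGES[:len(stages)] or not stages:
            raise ValueError(
                f"stages must be a non-empty prefix of {CANONICAL_STAGES}")
        if self.mode not in ("amplitudes", "waveforms"):
            raise ValueError("mode must be 'amplitudes' or 'waveforms'")
        self.stages = stages

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class RunReport:
    """Per-stage summaries plus the candidate-variable evaluation grid."""

    seed: int
    stages_run: tuple
    stage_summaries: dict
    grid: list = field(default_factory=list)   # rows of dicts
    artifacts: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "seed": self.seed,
            "stages_run": list(self.stages_run),
            "stage_summaries": self.stage_summaries,
            "grid": self.grid,
            "artifacts": {k: str(v) for k, v in self.artifacts.items()},
        }, indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [
            "# pulsedx run report",
            "",
            f"- seed: {self.seed}",
            f"- stages: {', '.join(self.stages_run)}",
            "",
        ]
        for stage, summ in self.stage_summaries.items():
            lines.append(f"- {stage}: {summ}")
        if self.grid:
            lines += [
                "",
                "| model | train acc | train MCC | LOOCV acc | LOOCV MCC |",
                "|---|---|---|---|---|",
            ]
            for row in self.grid:
                lines.append(
                    f"| {row['model']} | {row['train_accuracy']:.1%} | "
                    f"{row['train_mcc']:.2f} | {row['cv_accuracy']:.1%} | "
                    f"{row['cv_mcc']:.2f} |")
        return "\n".join(lines) + "\n"


def _lda_row(name, df, features, priors):
    X = df[list(features)].to_numpy(dtype=float)
    y = list(df["label"])
    res = FisherDiscriminant(X, y, priors=priors, feature_names=list(features)).fit()
    tab = res.training_table()
    cv = loocv(lambda Xt, yt: FisherDiscriminant(Xt, yt, priors=priors).fit(), X, y)
    return {
        "model": name, "variables": list(features),
        "train_accuracy": accuracy(tab), "train_mcc": mcc(tab),
        "cv_accuracy": cv.accuracy, "cv_mcc": cv.mcc,
    }, res


class _MixedFitterAdapter:
    """loocv-compatible wrapper: X columns are (primary, secondary) raw values."""

    def __init__(self, primary: str, secondary: str):
        self.primary, self.secondary = primary, secondary

    def __call__(self, X, y):
        res = MixedThreshold(X[:, 0], X[:, 1], y, primary_name=self.primary,
                             secondary_name=self.secondary).fit()

        class _P:
            def predict(_self, Xnew):
                return res.predict(np.atleast_2d(Xnew)[:, 0],
                                   np.atleast_2d(Xnew)[:, 1])
        return _P()


def evaluate_grid(df: pd.DataFrame, primary: str = "PP_avg",
                  secondary: str = "PP_max", priors: str = "proportional"
                  ) -> tuple[list, dict]:
    """The Table-7-style comparison grid on one feature table.

    Returns (grid rows, fitted models keyed by row name).
    """
    rows, models = [], {}
    for var in SINGLE_VARIABLES:
        row, res = _lda_row(var, df, [var], priors)
        rows.append(row)
        models[var] = res
    row, res = _lda_row("sum", df, SINGLE_VARIABLES, priors)
    rows.append(row)
    models["sum"] = res

    mixed = MixedThreshold.from_dataframe(df, primary=primary,
                                          secondary=secondary).fit()
    X2 = df[[primary, secondary]].to_numpy(dtype=float)
    y = list(df["label"])
    cv = loocv(_MixedFitterAdapter(primary, secondary), X2, y)
    tab = confusion(y, mixed.predict(X2[:, 0], X2[:, 1]))
    rows.append({
        "model": f"mixed({primary}|{secondary})",
        "variables": [primary, secondary],
        "train_accuracy": accuracy(tab), "train_mcc": mcc(tab),
        "cv_accuracy": cv.accuracy, "cv_mcc": cv.mcc,
    })
    models["mixed"] = mixed
    return rows, models


def run(config: RunConfig) -> RunReport:
    """Execute the configured stage prefix; persist every intermediate."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summaries: dict = {}
    artifacts: dict = {}
    labels = matrices = df = None
    report_grid: list = []

    for stage in config.stages:
        if stage == "simulate":
            spec = synthetic.CohortSpec(
                n_subjects=config.n_subjects,
                prevalence_excess=config.prevalence_excess,
                noise_sd=config.noise_sd, excess_scale=config.excess_scale,
                focal_tilt=config.focal_tilt, seed=config.seed)
            labels, matrices = synthetic.simulate_amplitude_cohort(spec)
            cohort_path = out / "cohort.csv"
            synthetic.write_cohort_csv(labels, matrices, cohort_path)
            artifacts["cohort"] = cohort_path
            summaries["simulate"] = {
                "n_subjects": len(labels), "mode": config.mode,
                "n_excess": labels.count("excess"), "seed": config.seed,
                "rng_streams": f"[seed, counter] counters 0..{len(labels)-1}",
            }
            if config.mode == "waveforms":
                protocol = synthetic.PressureProtocol()
                wf_spec = synthetic.WaveformSpec(seed=config.seed)
                wf_dir = out / "waveforms"
                true_matrices = matrices
                n_files = 0
                for s_idx, m in enumerate(true_matrices):
                    for rec in synthetic.simulate_subject_records(
                            spec, wf_spec, protocol, s_idx, m):
                        synthetic.write_waveform_csv(rec, wf_dir, m.subject_id)
                        n_files += 1
                artifacts["waveforms"] = wf_dir
                summaries["simulate"]["n_waveform_files"] = n_files
        elif stage == "preprocess":
            if config.mode == "waveforms":
                protocol = synthetic.PressureProtocol()
                wf_spec = synthetic.WaveformSpec(seed=config.seed)
                spec = synthetic.CohortSpec(
                    n_subjects=config.n_subjects,
                    prevalence_excess=config.prevalence_excess,
                    noise_sd=config.noise_sd, excess_scale=config.excess_scale,
                    seed=config.seed)
                new_matrices = []
                for s_idx, m in enumerate(matrices):
                    records = synthetic.simulate_subject_records(
                        spec, wf_spec, protocol, s_idx, m)
                    new_matrices.append(
                        extract_amplitude_matrix(records, subject_id=m.subject_id))
                matrices = new_matrices
                matrices_path = out / "matrices.csv"
                synthetic.write_cohort_csv(labels, matrices, matrices_path)
                artifacts["matrices"] = matrices_path
                summaries["preprocess"] = {"n_subjects": len(matrices),
                                           "rejections": 0}
            else:
                summaries["preprocess"] = {"skipped": "amplitude-level cohort"}
        elif stage == "extract":
            df = feature_table(matrices, labels)
            features_path = out / "features.csv"
            write_feature_csv(df, features_path)
            artifacts["features"] = features_path
            summaries["extract"] = {"n_rows": len(df),
                                    "n_feature_columns": df.shape[1] - 2}
        elif stage == "fit":
            grid, models = evaluate_grid(df, primary=config.primary,
                                         secondary=config.secondary,
                                         priors=config.priors)
            for name, res in models.items():
                model_path = out / f"model_{name}.json"
                model_path.write_text(res.to_json())
                artifacts[f"model_{name}"] = model_path
            summaries["fit"] = {"n_models": len(models)}
            # stash for the evaluate stage
            summaries["fit"]["_grid"] = grid
        elif stage == "evaluate":
            grid = summaries["fit"].pop("_grid")
            report_grid = grid
            grid_path = out / "evaluation_grid.json"
            grid_path.write_text(json.dumps(grid, indent=2, sort_keys=True))
            artifacts["evaluation_grid"] = grid_path
            summaries["evaluate"] = {"n_rows": len(grid)}

    grid_rows = report_grid if "evaluate" in summaries else []
    if "_grid" in summaries.get("fit", {}):
        summaries["fit"].pop("_grid")
    rel_artifacts = {k: str(Path(v).relative_to(out)) for k, v in artifacts.items()}
    report = RunReport(seed=config.seed, stages_run=config.stages,
                       stage_summaries=summaries, grid=grid_rows,
                       artifacts=rel_artifacts)
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
    manifest = dict(rel_artifacts)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if config.verbosity:
        print(report.to_markdown())
    return report
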