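"""End-to-end driver: simulate -> preprocess -> screen -> fit-clinical ->
mirna-search -> combine -> evaluate.

Every stage reads its inputs from and writes its outputs to a run
directory in plain-text formats (CSV/TSV/JSON/key=value model files), so a
completed stage can be re-run from disk bit-identically.  All randomness
flows from the single config seed; each stage derives a named sub-seed.
A machine-readable manifest records the seed, config hash and output
hashes; identical seed + config implies an identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from ._stream import subseed
from .clinical import DiagnosticIndexModel, LinearIndex, univariate_screen
from .combine import fit_combined
from .discriminant import PanelSearch
from .evaluation import delong_paired, roc_analysis
from .preprocess import ExpressionMatrix, preprocess_pipeline

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs with study-condition defaults."""

    seed: int = 0
    # cohort
    n_patients: int = 178
    event_fraction: float = 29 / 178
    n_target_probes: int = 2565
    n_informative: int = 6
    informative_effect: float = 1.0
    flagged_spot_rate: float = 0.001
    # preprocessing
    cv_threshold: float = 0.15
    flag_threshold: int = 10
    trim_fraction: float = 0.05
    sd_multiplier: float = 2.0
    # screening / modelling
    alpha: float = 0.05
    # panel search
    k_max: int = 10
    beam: int = 10
    epsilon: float = 0.002
    # evaluation
    cutoff_rule: str = "youden"
    version: str = "epcmir-0.1.0"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"config: unknown keys {sorted(bad)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()

    def cohort_spec(self) -> cohort_mod.CohortSpec:
        spec = cohort_mod.table2_defaults()
        informative = tuple((f"miR-syn-{i + 1:04d}", self.informative_effect)
                            for i in range(self.n_informative))
        return spec.with_(
            n_patients=self.n_patients, event_fraction=self.event_fraction,
            n_target_probes=self.n_target_probes, informative_probes=informative,
            flagged_spot_rate=self.flagged_spot_rate,
            seed=subseed(self.seed, "simulate"),
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(config: RunConfig, outdir: Path) -> None:
    cohort, raw = cohort_mod.generate_cohort(config.cohort_spec())
    cohort_mod.write_cohort(cohort, outdir / "cohort.csv")
    raw.to_tsv(outdir / "signals.tsv", outdir / "flags.tsv")


@_stage("preprocess")
def stage_preprocess(config: RunConfig, outdir: Path) -> None:
    raw = cohort_mod.ProbeSignalMatrix.from_tsv(outdir / "signals.tsv", outdir / "flags.tsv")
    report, expr = preprocess_pipeline(
        raw, cv_threshold=config.cv_threshold, flag_threshold=config.flag_threshold,
        trim_fraction=config.trim_fraction, sd_multiplier=config.sd_multiplier)
    report.to_csv(outdir / "qc_report.csv")
    expr.to_tsv(outdir / "expression.tsv")


@_stage("screen")
def stage_screen(config: RunConfig, outdir: Path) -> None:
    cohort = cohort_mod.read_cohort(outdir / "cohort.csv")
    screen = univariate_screen(cohort, alpha=config.alpha)
    screen.drop(columns=["summary"]).to_csv(outdir / "screen.csv")


@_stage("fit-clinical")
def stage_fit_clinical(config: RunConfig, outdir: Path) -> None:
    cohort = cohort_mod.read_cohort(outdir / "cohort.csv")
    screen = pd.read_csv(outdir / "screen.csv", index_col="variable")
    res = DiagnosticIndexModel.from_screen(cohort, screen).fit()
    res.index_model.to_text(outdir / "clinical_model.txt")


@_stage("mirna-search")
def stage_mirna_search(config: RunConfig, outdir: Path) -> None:
    cohort = cohort_mod.read_cohort(outdir / "cohort.csv")
    expr = ExpressionMatrix.from_tsv(outdir / "expression.tsv")
    y = cohort.loc[expr.values.columns, "early_deterioration"].to_numpy()
    result = PanelSearch(expr, y, k_max=config.k_max, beam=config.beam,
                         epsilon=config.epsilon).fit()
    result.to_json(outdir / "panel_search.json")
    result.mean_auc_table().to_csv(outdir / "mean_auc_curve.csv")


@_stage("combine")
def stage_combine(config: RunConfig, outdir: Path) -> None:
    cohort = cohort_mod.read_cohort(outdir / "cohort.csv")
    expr = ExpressionMatrix.from_tsv(outdir / "expression.tsv")
    clinical = LinearIndex.from_text(outdir / "clinical_model.txt")
    with open(outdir / "panel_search.json") as fh:
        search = json.load(fh)
    finals = search["levels"][str(search["k_star"])]
    cohort_kept = cohort.loc[expr.values.columns]
    for i, cand in enumerate(finals, start=1):
        model = fit_combined(cohort_kept, expr, cand["probes"],
                             clinical_vars=tuple(clinical.coefficients))
        model.index_model.to_text(outdir / f"combined_model_{i:02d}.txt")


@_stage("evaluate")
def stage_evaluate(config: RunConfig, outdir: Path) -> None:
    cohort = cohort_mod.read_cohort(outdir / "cohort.csv")
    expr = ExpressionMatrix.from_tsv(outdir / "expression.tsv")
    kept = list(expr.values.columns)
    y = cohort.loc[kept, "early_deterioration"].to_numpy()
    clinical = LinearIndex.from_text(outdir / "clinical_model.txt")
    clin_scores = clinical.evaluate(cohort.loc[kept]).to_numpy()
    # lower clinical index = deterioration-like when Alb/Hb dominate; orient
    # the score so higher predicts the event before ROC analysis
    orient = 1.0 if roc_analysis(clin_scores, y).auc >= 0.5 else -1.0
    rows = [roc_analysis(orient * clin_scores, y, config.cutoff_rule).metrics_row("clinical")]

    with open(outdir / "panel_search.json") as fh:
        search = json.load(fh)
    finals = search["levels"][str(search["k_star"])]
    for i, cand in enumerate(finals, start=1):
        X = expr.values.loc[cand["probes"], kept].to_numpy(dtype=float).T
        scores = X @ np.asarray(cand["weights"]) + cand["intercept"]
        rows.append(roc_analysis(scores, y, config.cutoff_rule).metrics_row(f"miR-model-{i:02d}"))

    delong_rows = []
    for i in range(1, len(finals) + 1):
        comb = LinearIndex.from_text(outdir / f"combined_model_{i:02d}.txt")
        probes = [v for v in comb.coefficients if v in expr.values.index]
        design = cohort.loc[kept].copy()
        design["ps"] = design["ps"].astype(int)
        for p in probes:
            design[p] = expr.values.loc[p, kept].to_numpy(dtype=float)
        scores = comb.evaluate(design).to_numpy()
        sign = 1.0 if roc_analysis(scores, y).auc >= 0.5 else -1.0
        rows.append(roc_analysis(sign * scores, y, config.cutoff_rule).metrics_row(f"comb-model-{i:02d}"))
        dl = delong_paired(sign * scores, orient * clin_scores, y)
        delong_rows.append({"comparison": f"comb-model-{i:02d} vs clinical",
                            "auc_combined": dl.auc1, "auc_clinical": dl.auc2,
                            "delta_auc": dl.delta, "z": dl.z, "p_value": dl.p_value})

    pd.DataFrame(rows).set_index("model").to_csv(outdir / "model_report.csv")
    pd.DataFrame(delong_rows).set_index("comparison").to_csv(outdir / "delong.csv")


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "screen": stage_screen,
    "fit-clinical": stage_fit_clinical,
    "mirna-search": stage_mirna_search,
    "combine": stage_combine,
    "evaluate": stage_evaluate,
}


def run_pipeline(config: RunConfig, outdir, stages=None) -> Path:
    """Run the listed stages (default: all, in order) into ``outdir``.

    Writes ``manifest.json`` with the seed, config hash, per-file sha256
    hashes and the event count; returns the run directory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise PipelineError(f"unknown stage {name!r}")
        STAGES[name](config, outdir)

    outputs = {p.name: _hash_file(p) for p in sorted(outdir.glob("*"))
               if p.is_file() and p.name != "manifest.json"}
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "version": config.version, "outputs": outputs}
    cohort_path = outdir / "cohort.csv"
    if cohort_path.exists():
        manifest["n_events"] = int(cohort_mod.read_cohort(cohort_path)["early_deterioration"].sum())
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
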