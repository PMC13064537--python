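"""End-to-end orchestration: generate -> build cohort -> score -> fit -> sensitivity.

Each run writes its artifacts into a run directory together with a
manifest of content hashes; rerunning with the same configuration and
seed reproduces the manifest byte-for-byte.  A single global seed is
expanded into fixed per-stage substreams so that stage ordering cannot
perturb downstream randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import build_analysis_table, utilization_measures
from .cohort import apply_exclusions, attach_physician
from .exceptions import ConfigurationError, InputError, PipelineStageError
from .models import ModelSpec, compare_models, correlation_matrix, fit_outcome_model
from .regularity import (
    DEFAULT_WINDOW,
    SENSITIVITY_WINDOWS,
    ObservationWindow,
    window_sensitivity,
)
from .synthetic import GeneratorConfig, generate_cohort, inject_exclusion_cases, write_cohort, read_cohort
from .synthetic import _stream  # per-stage substreams

__all__ = ["RunConfig", "run_pipeline", "report", "load_run_config", "OUTCOME_SPECS"]

log = logging.getLogger("rvikit")

#: The three adjusted outcome models of the analysis.
OUTCOME_SPECS = (
    ModelSpec("n_hospitalizations_30d", "negbin", label="hospitalizations"),
    ModelSpec("n_ed_visits_30d", "negbin", label="ed_visits"),
    ModelSpec("acute_care_death", "logistic", label="acute_care_death"),
)

_STAGE_IDS = {"generate": 0, "inject": 8, "build": 1, "score": 2, "fit": 3, "sensitivity": 4}


@dataclass
class RunConfig:
    """Reproducible-run description (JSON or YAML on disk)."""

    outdir: str = "runs/run"
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    exposure_window: ObservationWindow = DEFAULT_WINDOW
    sensitivity_windows: tuple = SENSITIVITY_WINDOWS
    inject_violations: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def validate(self):
        self.generator.validate()
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")


def _window_from(obj) -> ObservationWindow:
    if isinstance(obj, ObservationWindow):
        return obj
    return ObservationWindow(int(obj[0]), int(obj[1]))


def load_run_config(path) -> RunConfig:
    """Load a run configuration from a JSON or YAML file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = raw or {}
    gen_raw = raw.pop("generator", {})
    if isinstance(gen_raw, str):
        gen_path = (path.parent / gen_raw) if not Path(gen_raw).is_absolute() else Path(gen_raw)
        if not gen_path.exists():
            raise ConfigurationError(f"generator config path does not exist: {gen_raw}")
        gtext = gen_path.read_text()
        gen_raw = json.loads(gtext) if gen_path.suffix == ".json" else yaml.safe_load(gtext)
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(gen_raw) - known
    if unknown:
        raise ConfigurationError(f"unknown generator fields: {sorted(unknown)}")
    if "death_window" in gen_raw:
        gen_raw["death_window"] = tuple(date.fromisoformat(d) for d in gen_raw["death_window"])
    gen = GeneratorConfig(**gen_raw)
    cfg = RunConfig(
        outdir=raw.get("outdir", "runs/run"),
        seed=int(raw.get("seed", 0)),
        generator=gen,
        exposure_window=_window_from(raw.get("exposure_window", DEFAULT_WINDOW)),
        sensitivity_windows=tuple(
            _window_from(w) for w in raw.get("sensitivity_windows", SENSITIVITY_WINDOWS)
        ),
        inject_violations=raw.get("inject_violations", {}),
        log_level=raw.get("log_level", "INFO"),
    )
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        fh.write(f"# rvikit artifact; seed={seed}\n")
        df.to_csv(fh, index=False)


def _log_line(outdir: Path, msg: str) -> None:
    log.info(msg)
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"{datetime.now(timezone.utc).isoformat()} {msg}\n")


def stage_generate(config: RunConfig, outdir: Path) -> None:
    gen = dataclasses.replace(config.generator, seed=config.seed)
    cohort = generate_cohort(gen)
    if config.inject_violations:
        cohort = inject_exclusion_cases(
            cohort, config.inject_violations, _stream(config.seed, _STAGE_IDS["inject"])
        )
    write_cohort(cohort, outdir, seed=config.seed)
    echo = dataclasses.asdict(gen)
    echo["death_window"] = [d.isoformat() for d in gen.death_window]
    (outdir / "generator_config.json").write_text(json.dumps(echo, indent=2, default=str))
    _log_line(outdir, f"generate: n_patients={len(cohort.patients)} n_visits={len(cohort.visits)}")


def stage_build(config: RunConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir)
    retained, rep = apply_exclusions(cohort.patients, cohort.visits, config.exposure_window)
    attach = attach_physician(retained, cohort.visits)
    unattached = attach["attachment_type"] == "unattached"
    rep.add("unattached", int(unattached.sum()))
    keep = attach.loc[~unattached, "patient_id"]
    retained = retained[retained["patient_id"].isin(keep)].reset_index(drop=True)
    _write_csv(retained, outdir / "analysis_patients.csv", config.seed)
    _write_csv(attach[~unattached], outdir / "attachments.csv", config.seed)
    (outdir / "exclusion_report.json").write_text(rep.to_json())
    _log_line(outdir, "build-cohort:\n" + rep.pretty())


def stage_score(config: RunConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir)
    patients = pd.read_csv(
        outdir / "analysis_patients.csv", comment="#", parse_dates=["death_date"]
    )
    attach = pd.read_csv(outdir / "attachments.csv", comment="#")
    att_map = dict(zip(attach["patient_id"], attach["physician_id"]))
    tab = build_analysis_table(
        patients, cohort.visits, cohort.outcomes, config.exposure_window, attachment=att_map
    )
    _write_csv(tab, outdir / "analysis_table.csv", config.seed)

    scores = tab[
        ["patient_id", "fp_rvi", "quintile", "sp_rvi", "sp_quintile", "fp_visits", "sp_visits"]
    ]
    _write_csv(scores, outdir / f"rvi_scores_{config.exposure_window.label}.csv", config.seed)
    measures = utilization_measures(patients, cohort.visits, config.exposure_window, att_map)
    corr = correlation_matrix(measures.drop(columns=["patient_id"]))
    _write_csv(corr.reset_index(names="measure"), outdir / "correlations.csv", config.seed)
    _log_line(outdir, f"score: n_scored={len(tab)} median_fp_rvi={tab['fp_rvi'].median():.4f}")


def stage_fit(config: RunConfig, outdir: Path) -> None:
    tab = pd.read_csv(outdir / "analysis_table.csv", comment="#")
    effects = []
    fits = {}
    for spec in OUTCOME_SPECS:
        res = fit_outcome_model(tab, spec)
        effects.append(res.effects())
        fits[spec.label] = {"aic": res.aic, "n": res.nobs, "alpha": res.alpha}
    _write_csv(pd.concat(effects, ignore_index=True), outdir / "effects.csv", config.seed)
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2))
    _log_line(outdir, f"fit: {len(effects)} outcome models")


def stage_sensitivity(config: RunConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir)
    patients = pd.read_csv(
        outdir / "analysis_patients.csv", comment="#", parse_dates=["death_date"]
    )
    attach = pd.read_csv(outdir / "attachments.csv", comment="#")
    att_map = dict(zip(attach["patient_id"], attach["physician_id"]))

    visits = cohort.visits[cohort.visits["patient_id"].isin(patients["patient_id"])]
    if config.sensitivity_windows:
        windows = [config.exposure_window, *config.sensitivity_windows]
        summary, wide = window_sensitivity(visits, patients, windows, attachment=att_map)
        _write_csv(summary, outdir / "window_sensitivity.csv", config.seed)
        for w in windows:
            sc = wide[["patient_id", w.label]].rename(columns={w.label: "rvi"})
            _write_csv(sc, outdir / f"rvi_scores_window_{w.label}.csv", config.seed)

    tab = pd.read_csv(outdir / "analysis_table.csv", comment="#")
    comparison = {}
    for spec in OUTCOME_SPECS:
        sens = dataclasses.replace(spec, include_specialist_rvi=True, label=spec.label + "_sens")
        comparison[spec.label] = compare_models(spec, sens, tab).to_dict()
    (outdir / "model_comparison.json").write_text(json.dumps(comparison, indent=2))
    _log_line(outdir, "sensitivity: window summaries and specialist-adjusted models written")


_STAGES = (
    ("generate", stage_generate),
    ("build", stage_build),
    ("score", stage_score),
    ("fit", stage_fit),
    ("sensitivity", stage_sensitivity),
)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write ``manifest.json``; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    for name, fn in _STAGES:
        try:
            fn(config, outdir)
        except Exception as exc:
            raise PipelineStageError(name, str(exc)) from exc
    manifest = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }
    (outdir / "manifest.json").write_text(json.dumps({"seed": config.seed, "artifacts": manifest}, indent=2))
    return outdir


def _fmt_med(series) -> str:
    return (
        f"{series.median():.3g} ({series.quantile(0.25):.3g}, {series.quantile(0.75):.3g})"
    )


def report(run_dir) -> str:
    """Human-readable run summary; every number comes from a run artifact."""
    run_dir = Path(run_dir)
    needed = [
        "analysis_patients.csv", "analysis_table.csv", "exclusion_report.json", "effects.csv",
    ]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise InputError(f"incomplete run; missing artifacts: {missing}")
    tab = pd.read_csv(run_dir / "analysis_table.csv", comment="#")
    rep = json.loads((run_dir / "exclusion_report.json").read_text())
    effects = pd.read_csv(run_dir / "effects.csv", comment="#")

    out = ["=== Attrition flowchart ==="]
    out.append(f"Initial cohort: n = {rep['initial_n']}")
    for s in rep["steps"]:
        out.append(f"  removed {s['n_removed']:>6}  ({s['rule']}); remaining {s['n_remaining']}")
    out.append(f"Analysis cohort: n = {rep['final_n']}")

    out.append("\n=== Cohort profile (median (P25, P75) / %) ===")
    out.append(f"Age at 2 years before death: {_fmt_med(tab['age'])}")
    out.append(f"Male: {100 * tab['male'].mean():.1f}%")
    out.append(f"Rural: {100 * tab['rural'].mean():.1f}%")
    out.append(f"Homecare: {100 * tab['homecare'].mean():.1f}%")
    out.append(f"Cancer: {100 * tab['cancer'].mean():.1f}%")
    out.append(f"ADG count: {_fmt_med(tab['adg_count'])}")

    out.append("\n=== Utilization and regularity ===")
    out.append(f"FP visits in window: {_fmt_med(tab['fp_visits'])}")
    out.append(f"Specialist visits in window: {_fmt_med(tab['sp_visits'])}")
    out.append(f"FP RVI: {_fmt_med(tab['fp_rvi'])}")
    out.append(f"Specialist RVI: {_fmt_med(tab['sp_rvi'].dropna())}")

    out.append("\n=== Last-30-day outcomes ===")
    out.append(f"Hospitalizations: {_fmt_med(tab['n_hospitalizations_30d'])}")
    out.append(f"ED visits: {_fmt_med(tab['n_ed_visits_30d'])}")
    out.append(f"Acute care death: {100 * tab['acute_care_death'].mean():.1f}%")

    out.append("\n=== Adjusted effects (vs Q1, ratio scale) ===")
    show = effects[effects["term"].str.startswith(("rvi_", "homecare", "cancer", "adg"))]
    out.append(f"{'outcome':<22}{'term':<12}{'est':>7}{'lo95':>8}{'hi95':>8}")
    for _, r in show.iterrows():
        out.append(
            f"{r['outcome']:<22}{r['term']:<12}{r['estimate']:>7.3f}{r['lower95']:>8.3f}{r['upper95']:>8.3f}"
        )

    ws_path = run_dir / "window_sensitivity.csv"
    if ws_path.exists():
        ws = pd.read_csv(ws_path, comment="#")
        if len(ws):
            out.append("\n=== Window sensitivity (median (P25, P75) RVI) ===")
            for _, r in ws.iterrows():
                out.append(
                    f"window {r['window']:>9}: {r['median_rvi']:.4f} "
                    f"({r['p25_rvi']:.4f}, {r['p75_rvi']:.4f}), n={int(r['n_eligible'])}"
                )
    mc_path = run_dir / "model_comparison.json"
    if mc_path.exists():
        mc = json.loads(mc_path.read_text())
        out.append("\n=== Specialist-RVI sensitivity models (AIC) ===")
        for k, v in mc.items():
            out.append(
                f"{k:<22} base {v['aic_base']:.1f}  +specialist {v['aic_sensitivity']:.1f}  "
                f"delta {v['delta']:+.2f}"
            )
    return "\n".join(out)
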