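"""End-to-end orchestration: simulate -> RMR -> RAM -> personality ->
dominance -> models -> report.

A single :class:`RunConfig` (YAML or dict) drives the whole chain.  One
master seed fans out into an independent substream per stage, so results
are bit-reproducible and changing one stage's options (e.g. Monte Carlo
iterations) never perturbs another stage's draws.  Each stage writes CSV
outputs under the run directory; a manifest of input checksums makes
re-running a completed stage a no-op unless its inputs changed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import dominance as dom
from . import models as mdl
from . import ram as ram_mod
from . import repeatability as rpt
from . import respirometry as resp
from . import synthetic as syn

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "ValidationReport"]

log = logging.getLogger("metabehave")

#: stage seed-stream indices (fixed so streams are stable across versions)
STAGE_STREAMS = {"simulate": 0, "ram": 1, "personality": 2, "models": 3}

DEVIATIONS_NOTE = (
    "Model stand-ins: the count model uses maximum-likelihood negative-"
    "binomial regression (log link, profiled dispersion) in place of a "
    "negative-binomial GLMM with a chick random intercept, and the latency "
    "models use a right-censored Weibull accelerated-failure-time fit with "
    "a shared per-chick gamma frailty in place of a mixed-effects Cox "
    "model. For the chick-level metabolic predictor the error counts are "
    "pooled to per-chick totals, since a chick term would absorb the "
    "predictor and per-trial rows are correlated within chicks."
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Validated run settings; unknown keys are rejected."""

    seed: int = 0
    outdir: Union[str, Path] = "metabehave_run"
    simulate: dict = field(default_factory=dict)
    ram: dict = field(default_factory=dict)
    personality: dict = field(default_factory=dict)
    dominance: dict = field(default_factory=dict)
    report_format: str = "csv"

    _ALLOWED_SIM = {
        "enabled",
        "n_chicks",
        "n_ram_trials",
        "n_arms",
        "rmr_sessions_per_chick",
        "flow_rate_ml_min",
        "chamber_volume_ml",
        "ambient_o2_frac",
        "ambient_co2_frac",
        "baseline_drift_frac_per_min",
        "noise_sd_frac",
        "latency_cap_s",
        "sample_period_s",
        "icc_boldness",
        "icc_neophobia",
        "block_shift",
        "ability_sd",
        "rmr_effect",
        "n_dominance_trials",
        "encounters_per_dyad_mean",
    }
    _ALLOWED_RAM = {"iterations", "mode", "start_rule", "visit_cap"}
    _ALLOWED_PERSONALITY = {"n_bootstrap", "log_transform"}
    _ALLOWED_DOMINANCE = {"corrected"}

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.report_format not in ("csv", "markdown"):
            raise PipelineError(f"unknown report_format {self.report_format!r}")
        for label, section, allowed in (
            ("simulate", self.simulate, self._ALLOWED_SIM),
            ("ram", self.ram, self._ALLOWED_RAM),
            ("personality", self.personality, self._ALLOWED_PERSONALITY),
            ("dominance", self.dominance, self._ALLOWED_DOMINANCE),
        ):
            unknown = set(section) - allowed
            if unknown:
                raise PipelineError(
                    f"unknown keys in '{label}' config: {sorted(unknown)}"
                )

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        allowed = {"seed", "outdir", "simulate", "ram", "personality",
                   "dominance", "report_format"}
        unknown = set(payload) - allowed
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def sim_config(self) -> syn.SimConfig:
        kwargs = {
            k: v
            for k, v in self.simulate.items()
            if k in {f.name for f in syn.SimConfig.__dataclass_fields__.values()}
        }
        return syn.SimConfig(seed=self.seed, **kwargs)

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, STAGE_STREAMS[stage]])
        )


# ---------------------------------------------------------------------------
# manifest-based re-entrancy


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.state = (
            json.loads(self.path.read_text()) if self.path.exists() else {}
        )

    def fresh(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        """True when the stage's outputs exist and inputs are unchanged."""
        entry = self.state.get(stage)
        if entry is None:
            return False
        if not all(Path(p).exists() for p in entry["outputs"]):
            return False
        current = {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()}
        return current == entry["inputs"] and [str(p) for p in outputs] == entry[
            "outputs"
        ]

    def record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.state[stage] = {
            "inputs": {str(p): _checksum(Path(p)) for p in inputs},
            "outputs": [str(p) for p in outputs],
        }
        self.path.write_text(json.dumps(self.state, indent=2))


def _stage(name: str):
    """Log stage timing and re-raise failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = _time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, _time.perf_counter() - t0)
            return out

        return inner

    return wrap


# ---------------------------------------------------------------------------
# stages


@_stage("simulate")
def stage_simulate(config: RunConfig) -> dict:
    data_dir = config.outdir / "data"
    sim = config.sim_config()
    extra = {
        k: v
        for k, v in config.simulate.items()
        if k
        in {
            "icc_boldness",
            "icc_neophobia",
            "block_shift",
            "ability_sd",
            "rmr_effect",
            "n_dominance_trials",
            "encounters_per_dyad_mean",
        }
    }
    dataset = syn.generate_dataset(sim, **extra)
    return syn.write_dataset_csvs(dataset, data_dir)


@_stage("rmr")
def stage_rmr(config: RunConfig, paths: dict) -> Path:
    out = config.outdir / "rmr_table.csv"
    manifest = _Manifest(config.outdir)
    inputs = [Path(paths["sessions"]), Path(paths["masses"])]
    if manifest.fresh("rmr", inputs, [out]):
        log.info("stage rmr: up to date, skipping")
        return out
    sessions = resp.read_sessions_csv(paths["sessions"])
    masses = pd.read_csv(paths["masses"])
    rows = []
    for s in sessions:
        day = int(s.session_id.rsplit("_d", 1)[-1]) if "_d" in s.session_id else None
        sel = masses[masses["chick_id"] == s.chick_id]
        if day is not None and (sel["date_index"] == day).any():
            mass = float(sel[sel["date_index"] == day]["mass_g"].iloc[0])
        elif not sel.empty:
            mass = float(sel["mass_g"].mean())
        else:
            raise PipelineError(f"no body mass for chick {s.chick_id}")
        est = resp.estimate_rmr(s, body_mass_g=mass)
        rows.append(
            {
                "session_id": s.session_id,
                "chick_id": s.chick_id,
                "date_index": day,
                "vo2_ml_min": est.vo2_ml_min,
                "vco2_ml_min": est.vco2_ml_min,
                "mass_g": mass,
                "vo2_mass_corrected": est.vo2_mass_corrected,
                "window_start_s": est.window[0],
                "quality_flag": est.quality_flag,
            }
        )
    pd.DataFrame(rows).to_csv(out, index=False)
    manifest.record("rmr", inputs, [out])
    return out


def _load_trials(path) -> list[ram_mod.RAMTrial]:
    frame = pd.read_csv(path)
    trials = []
    n_arms = int(frame["arm"].max()) + 1 if len(frame) else 8
    n_arms = max(n_arms, 8) if n_arms <= 8 else n_arms
    for (chick, tnum), part in frame.groupby(["chick_id", "trial"], sort=True):
        part = part.sort_values("visit_index")
        trials.append(
            ram_mod.RAMTrial(
                chick_id=str(chick),
                trial_number=int(tnum),
                visits=part["arm"].to_numpy(int),
                n_arms=n_arms,
            )
        )
    return trials


@_stage("ram")
def stage_ram(config: RunConfig, paths: dict) -> dict:
    errors_out = config.outdir / "ram_errors.csv"
    nulls_out = config.outdir / "ram_nulls.csv"
    manifest = _Manifest(config.outdir)
    inputs = [Path(paths["ram_trials"])]
    if manifest.fresh("ram", inputs, [errors_out, nulls_out]):
        log.info("stage ram: up to date, skipping")
        return {"errors": errors_out, "nulls": nulls_out}
    trials = _load_trials(paths["ram_trials"])
    iterations = int(config.ram.get("iterations", 10_000))
    mode = config.ram.get("mode", "absolute")
    start_rule = config.ram.get("start_rule", "uniform")
    visit_cap = config.ram.get("visit_cap")
    rng = config.stage_rng("ram")

    errors = pd.DataFrame(
        {
            "chick_id": [t.chick_id for t in trials],
            "trial": [t.trial_number for t in trials],
            "errors": [ram_mod.count_errors(t) for t in trials],
            "completed": [t.completed for t in trials],
        }
    )
    errors.to_csv(errors_out, index=False)

    n_arms = trials[0].n_arms
    random_null = ram_mod.simulate_random_null(
        n_arms=n_arms, iterations=iterations, seed=rng, visit_cap=visit_cap
    )
    tm = ram_mod.estimate_transition_matrix(trials, mode=mode)
    stereo_null = ram_mod.simulate_stereotypic_null(
        tm,
        iterations=iterations,
        seed=rng,
        start_rule=start_rule,
        visit_cap=visit_cap,
    )
    obs = errors["errors"].to_numpy(float)
    rows = []
    for null in (random_null, stereo_null):
        test = ram_mod.compare_to_null(obs, null)
        rows.append(
            {
                "model": null.model,
                "iterations": null.iterations,
                "mean": null.mean,
                "sem": null.sem,
                "observed_mean": test.observed_mean,
                "t": test.t,
                "df": test.df,
                "p_one_sided": test.p,
                "seed": config.seed,
            }
        )
    pd.DataFrame(rows).to_csv(nulls_out, index=False)
    manifest.record("ram", inputs, [errors_out, nulls_out])
    return {"errors": errors_out, "nulls": nulls_out}


@_stage("personality")
def stage_personality(config: RunConfig, paths: dict) -> dict:
    rep_out = config.outdir / "repeatability.csv"
    corr_out = config.outdir / "trait_correlation.csv"
    manifest = _Manifest(config.outdir)
    inputs = [Path(paths["latencies"])]
    if manifest.fresh("personality", inputs, [rep_out, corr_out]):
        log.info("stage personality: up to date, skipping")
        return {"repeatability": rep_out, "correlation": corr_out}
    frame = pd.read_csv(paths["latencies"]).rename(columns={"trial": "trial_index"})
    n_bootstrap = int(config.personality.get("n_bootstrap", 10_000))
    log_transform = bool(config.personality.get("log_transform", True))
    rng = config.stage_rng("personality")
    rows = []
    for trait, part in frame.groupby("trait", sort=True):
        for grouping in ("chick", "block"):
            est = rpt.repeatability(
                part,
                grouping=grouping,
                n_bootstrap=n_bootstrap,
                seed=rng,
                log_transform=log_transform,
            )
            rows.append(
                {
                    "trait": trait,
                    "grouping": grouping,
                    "R": est.R,
                    "se": est.se_R,
                    "ci_low": est.ci95[0],
                    "ci_high": est.ci95[1],
                    "lrt_p": est.lrt_p,
                    "n_bootstrap": est.n_bootstrap,
                    "seed": config.seed,
                }
            )
    pd.DataFrame(rows).to_csv(rep_out, index=False)

    traits = sorted(frame["trait"].unique())
    corr_rows = []
    if len(traits) == 2:
        a = frame[frame["trait"] == traits[0]]
        b = frame[frame["trait"] == traits[1]]
        for drop in (False, True):
            c = rpt.trait_correlation(a, b, drop_censored=drop)
            corr_rows.append(
                {
                    "trait_a": traits[0],
                    "trait_b": traits[1],
                    "drop_censored": drop,
                    "r": c.r,
                    "t": c.t,
                    "p": c.p,
                    "n": c.n,
                }
            )
    pd.DataFrame(corr_rows).to_csv(corr_out, index=False)
    manifest.record("personality", inputs, [rep_out, corr_out])
    return {"repeatability": rep_out, "correlation": corr_out}


@_stage("dominance")
def stage_dominance(config: RunConfig, paths: dict) -> Path:
    out = config.outdir / "davids_scores.csv"
    manifest = _Manifest(config.outdir)
    inputs = [Path(paths["interactions"])]
    if manifest.fresh("dominance", inputs, [out]):
        log.info("stage dominance: up to date, skipping")
        return out
    trials = dom.read_interactions_csv(paths["interactions"])
    pooled = dom.pool_trials(trials)
    corrected = bool(config.dominance.get("corrected", False))
    result = dom.score_interactions(pooled, corrected=corrected)
    frame = result.to_frame()
    frame["total_interactions"] = pooled.total_interactions
    frame.to_csv(out, index=False)
    manifest.record("dominance", inputs, [out])
    return out


@_stage("models")
def stage_models(config: RunConfig, paths: dict, derived: dict) -> Path:
    out = config.outdir / "model_comparisons.csv"
    rmr_table = pd.read_csv(derived["rmr"])
    errors = pd.read_csv(derived["errors"])
    latencies = pd.read_csv(paths["latencies"]).rename(
        columns={"trial": "trial_index"}
    )
    ds_table = pd.read_csv(derived["davids_scores"])

    # chick-level scaled mean mass-corrected VO2
    mean_mc = rmr_table.groupby("chick_id")["vo2_mass_corrected"].mean()
    scaled = mdl.scale(mean_mc.to_numpy())
    rmr_z = pd.Series(scaled.values, index=mean_mc.index)

    comparisons = []

    # VO2 time trends (raw and mass-corrected), random chick intercept
    for col, label in (
        ("vo2_ml_min", "vo2_time"),
        ("vo2_mass_corrected", "vo2_mass_corrected_time"),
    ):
        y = mdl.scale(rmr_table[col].to_numpy()).values
        null = mdl.fit_lmm_time_trend(
            y, None, rmr_table["chick_id"], name="null_model", response_label=label
        )
        cand = mdl.fit_lmm_time_trend(
            y,
            rmr_table["date_index"].to_numpy(float),
            rmr_table["chick_id"],
            name="time",
            response_label=label,
        )
        comparisons.append((label, mdl.compare_models([null, cand])))

    # RAM errors ~ trial number (within-chick predictor; chick dummies kept)
    chick_dummies = pd.get_dummies(errors["chick_id"], drop_first=True, dtype=float)
    base = pd.concat(
        [pd.Series(1.0, index=errors.index, name="intercept"), chick_dummies], axis=1
    )
    with_time = base.assign(trial=errors["trial"].astype(float))
    null = mdl.fit_nb_regression(
        errors["errors"], base, name="null_model", response_label="errors_time"
    )
    cand = mdl.fit_nb_regression(
        errors["errors"], with_time, name="trial", response_label="errors_time"
    )
    comparisons.append(("errors_time", mdl.compare_models([null, cand])))

    # RAM errors ~ RMR.  The predictor is constant within chick, so trials
    # are pooled to per-chick totals; per-trial rows would let the
    # within-chick correlation masquerade as evidence for the predictor.
    per_chick = (
        errors[errors["chick_id"].isin(rmr_z.index)]
        .groupby("chick_id")["errors"]
        .sum()
    )
    z = per_chick.index.map(rmr_z).to_numpy(float)
    null = mdl.fit_nb_regression(
        per_chick.to_numpy(), name="null_model", response_label="errors_rmr"
    )
    cand = mdl.fit_nb_regression(
        per_chick.to_numpy(), z, name="rmr", response_label="errors_rmr"
    )
    comparisons.append(("errors_rmr", mdl.compare_models([null, cand])))

    # boldness / neophobia latency ~ RMR: Weibull AFT with right-censoring
    # and a shared gamma frailty per chick (repeated assays correlate)
    for trait, part in latencies.groupby("trait", sort=True):
        part = part[part["chick_id"].isin(rmr_z.index)]
        z = part["chick_id"].map(rmr_z).to_numpy(float)
        label = f"{trait}_rmr"
        null = mdl.fit_censored_latency_model(
            part,
            frailty_group=part["chick_id"],
            name="null_model",
            response_label=label,
        )
        cand = mdl.fit_censored_latency_model(
            part,
            predictor=z,
            frailty_group=part["chick_id"],
            name="rmr",
            response_label=label,
        )
        comparisons.append((label, mdl.compare_models([null, cand])))

    # David's score ~ RMR (chick-level linear model)
    ds = ds_table[ds_table["chick_id"].isin(rmr_z.index)]
    z = ds["chick_id"].map(rmr_z).to_numpy(float)
    null = mdl.fit_linear_model(ds["DS"], name="null_model", response_label="ds_rmr")
    cand = mdl.fit_linear_model(ds["DS"], z, name="rmr", response_label="ds_rmr")
    comparisons.append(("ds_rmr", mdl.compare_models([null, cand])))

    frames = []
    for label, comp in comparisons:
        frame = comp.to_frame()
        frame.insert(0, "response", label)
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    table["deviations"] = DEVIATIONS_NOTE
    table.to_csv(out, index=False)
    return out


@_stage("report")
def stage_report(config: RunConfig, derived: dict) -> Path:
    fmt = config.report_format
    out = config.outdir / ("report.md" if fmt == "markdown" else "report.csv")
    tables = {
        name: pd.read_csv(derived[name])
        for name in ("rmr", "nulls", "repeatability", "davids_scores", "comparisons")
    }
    summary_rows = [
        {
            "section": "rmr",
            "item": "mean_vo2_ml_min",
            "value": tables["rmr"]["vo2_ml_min"].mean(),
        },
        {
            "section": "rmr",
            "item": "mean_vo2_mass_corrected",
            "value": tables["rmr"]["vo2_mass_corrected"].mean(),
        },
    ]
    for _, row in tables["nulls"].iterrows():
        summary_rows.append(
            {
                "section": "ram",
                "item": f"{row['model']}_null_mean_errors",
                "value": row["mean"],
            }
        )
        summary_rows.append(
            {
                "section": "ram",
                "item": f"{row['model']}_null_p_one_sided",
                "value": row["p_one_sided"],
            }
        )
    for _, row in tables["repeatability"].iterrows():
        summary_rows.append(
            {
                "section": "personality",
                "item": f"R_{row['trait']}_{row['grouping']}",
                "value": row["R"],
            }
        )
    selected = tables["comparisons"][tables["comparisons"]["selected"]]
    for _, row in selected.iterrows():
        summary_rows.append(
            {
                "section": "models",
                "item": f"selected_{row['response']}",
                "value": row["model"],
            }
        )
    summary = pd.DataFrame(summary_rows)
    summary["seed"] = config.seed
    if fmt == "csv":
        summary.to_csv(out, index=False)
    else:
        lines = ["# metabehave run report", "", f"Seed: {config.seed}", ""]
        for section, part in summary.groupby("section", sort=True):
            lines.append(f"## {section}")
            for _, row in part.iterrows():
                lines.append(f"- {row['item']}: {row['value']}")
            lines.append("")
        lines += ["## Deviations from the full mixed-model analysis", "",
                  DEVIATIONS_NOTE, ""]
        out.write_text("\n".join(lines))
    return out


# ---------------------------------------------------------------------------
# entry points


def run_pipeline(config: RunConfig, paths: Optional[dict] = None) -> dict:
    """Execute all stages in order; returns the map of output paths.

    ``paths`` may point at pre-existing input CSVs (schema as written by
    the simulate stage); otherwise the simulate stage must be enabled
    (the default) and generates them under ``outdir/data``.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    simulate_enabled = bool(config.simulate.get("enabled", True))
    if paths is None:
        if not simulate_enabled:
            raise PipelineError(
                "stage 'simulate' disabled and no input paths supplied"
            )
        paths = stage_simulate(config)
    else:
        missing = [k for k, p in paths.items() if not Path(p).exists()]
        if missing:
            raise PipelineError(f"missing input files: {missing}")

    report = validate_inputs(paths)
    if report.violations:
        raise PipelineError(
            f"input validation failed: {report.violations[:5]}"
        )

    derived: dict = {}
    derived["rmr"] = stage_rmr(config, paths)
    ram_paths = stage_ram(config, paths)
    derived["errors"] = ram_paths["errors"]
    derived["nulls"] = ram_paths["nulls"]
    pers = stage_personality(config, paths)
    derived["repeatability"] = pers["repeatability"]
    derived["correlation"] = pers["correlation"]
    derived["davids_scores"] = stage_dominance(config, paths)
    derived["comparisons"] = stage_models(config, paths, derived)
    derived["report"] = stage_report(config, derived)
    return {k: str(v) for k, v in {**paths, **derived}.items()}


# ---------------------------------------------------------------------------
# input validation


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(paths: dict, n_arms: int = 8) -> ValidationReport:
    """Schema, range and referential-integrity checks on the input CSVs.

    Report-only: violations are listed, nothing raises.
    """
    v: list[str] = []
    frames: dict[str, pd.DataFrame] = {}
    schemas = {
        "sessions": {"session_id", "chick_id", "time_s", "segment", "o2_frac",
                     "co2_frac", "flow_ml_min"},
        "ram_trials": {"chick_id", "trial", "visit_index", "arm"},
        "latencies": {"chick_id", "trait", "block", "trial", "latency_s",
                      "censored"},
        "interactions": {"winner_id", "loser_id", "count"},
        "masses": {"chick_id", "date_index", "mass_g"},
    }
    for name, required in schemas.items():
        if name not in paths:
            continue
        path = Path(paths[name])
        if not path.exists():
            v.append(f"{name}: file missing ({path})")
            continue
        frame = pd.read_csv(path)
        frames[name] = frame
        missing = required - set(frame.columns)
        if missing:
            v.append(f"{name}: missing columns {sorted(missing)}")

    if "ram_trials" in frames and "arm" in frames["ram_trials"]:
        arms = frames["ram_trials"]["arm"]
        bad = arms[(arms < 0) | (arms >= n_arms)]
        if len(bad):
            v.append(
                f"ram_trials: {len(bad)} arm indices outside [0, {n_arms})"
            )
    if "latencies" in frames and {"latency_s", "censored"} <= set(
        frames["latencies"].columns
    ):
        lat = frames["latencies"]
        bad = lat[lat["censored"].astype(bool) & (lat["latency_s"] != 600.0)]
        if len(bad):
            v.append(
                f"latencies: {len(bad)} censored records not at the 600 s cap"
            )
        if (lat["latency_s"] <= 0).any():
            v.append("latencies: non-positive latency values")
    if "sessions" in frames and {"o2_frac", "co2_frac"} <= set(
        frames["sessions"].columns
    ):
        gas = frames["sessions"][["o2_frac", "co2_frac"]]
        if ((gas <= 0) | (gas >= 1)).any().any():
            v.append("sessions: gas fractions outside (0, 1)")

    # referential integrity on chick ids
    id_sets = {}
    for name, frame in frames.items():
        cols = [c for c in ("chick_id", "winner_id", "loser_id") if c in frame]
        ids: set = set()
        for c in cols:
            ids |= set(frame[c].astype(str))
        if ids:
            id_sets[name] = ids
    if id_sets:
        universe = set.union(*id_sets.values())
        for name, ids in id_sets.items():
            extra = ids - set.intersection(*id_sets.values())
            if len(id_sets) > 1 and ids != universe and extra:
                v.append(
                    f"{name}: chick ids not shared by all tables: "
                    f"{sorted(extra)[:5]}"
                )
    return ValidationReport(v)
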