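"""Pipeline stages tying simulation, fitting and reporting together.

Each stage reads/writes diff-able text artifacts (tidy CSV plus JSON
sidecars) and records provenance (config hash, seed, package version,
worst-case convergence diagnostic).  Time is always minutes
post-ingestion with t = 0 at the end of ingestion; fasting baseline rows
carry a negative sentinel time and ``is_baseline = True``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bayes import (
    HierarchicalModelSpec,
    compute_dob,
    contrasts,
    fit_hierarchical,
)
from .exceptions import ConfigurationError, DataError
from .intake import fit_intake_table
from .synthetic import (
    GroundTruth,
    StudyDesign,
    default_ground_truth,
    simulate_design,
    simulate_intake,
    simulate_timeseries,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "cmd_simulate",
    "cmd_fit",
    "cmd_intake",
    "cmd_report",
]

log = logging.getLogger("gastrokin")

_DESIGN_KEYS = {f.name for f in dataclasses.fields(StudyDesign)}
_FIT_KEYS = {"measures", "chains", "warmup", "draws", "thin", "rhat_threshold"}
_TOP_KEYS = {"design", "truth_overrides", "fit", "intake", "raw_mode"}


@dataclasses.dataclass
class PipelineConfig:
    design: StudyDesign
    truth: GroundTruth
    fit_measures: tuple[str, ...] = ("fat", "secretion", "cck")
    chains: int = 2
    warmup: int = 1000
    draws: int = 1500
    thin: int = 2
    rhat_threshold: float = 1.05
    intake_noise_sd: float = 120.0
    raw_mode: bool = False
    raw_text: str = ""

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.raw_text.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, seed: int | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or defaults).

    Unknown keys raise :class:`ConfigurationError` naming the key.  The
    ``seed`` argument overrides the design seed.
    """
    data: dict = {}
    raw_text = ""
    if path is not None:
        raw_text = Path(path).read_text()
        data = yaml.safe_load(raw_text) or {}
    for key in data:
        if key not in _TOP_KEYS:
            raise ConfigurationError(f"unknown config key: {key!r}")

    design_kwargs = dict(data.get("design") or {})
    for key in design_kwargs:
        if key not in _DESIGN_KEYS:
            raise ConfigurationError(f"unknown design key: {key!r}")
    for tup in ("final_n", "mri_grid", "blood_grid", "arms"):
        if tup in design_kwargs:
            design_kwargs[tup] = tuple(design_kwargs[tup])
    if seed is not None:
        design_kwargs["seed"] = int(seed)
    design = StudyDesign(**design_kwargs)

    truth = default_ground_truth()
    overrides = data.get("truth_overrides") or {}
    measures = dict(truth.measures)
    for mname, over in overrides.items():
        if mname not in measures:
            raise ConfigurationError(f"unknown measure in truth_overrides: {mname!r}")
        allowed = {"noise_sd", "cv"}
        bad = set(over) - allowed
        if bad:
            raise ConfigurationError(
                f"unknown truth_overrides key for {mname!r}: {sorted(bad)}"
            )
        mt = measures[mname]
        kwargs = {}
        if "noise_sd" in over:
            kwargs["noise_sd"] = float(over["noise_sd"])
        if "cv" in over:
            kwargs["cv"] = {p: float(over["cv"]) for p in mt.cv}
        measures[mname] = dataclasses.replace(mt, **kwargs)
    truth = GroundTruth(measures)

    fit = data.get("fit") or {}
    for key in fit:
        if key not in _FIT_KEYS:
            raise ConfigurationError(f"unknown fit key: {key!r}")
    intake = data.get("intake") or {}
    if set(intake) - {"noise_sd"}:
        raise ConfigurationError("intake block only supports 'noise_sd'")

    return PipelineConfig(
        design=design,
        truth=truth,
        fit_measures=tuple(fit.get("measures", ("fat", "secretion", "cck"))),
        chains=int(fit.get("chains", 2)),
        warmup=int(fit.get("warmup", 1000)),
        draws=int(fit.get("draws", 1500)),
        thin=int(fit.get("thin", 2)),
        rhat_threshold=float(fit.get("rhat_threshold", 1.05)),
        intake_noise_sd=float(intake.get("noise_sd", 120.0)),
        raw_mode=bool(data.get("raw_mode", False)),
        raw_text=raw_text,
    )


def _provenance(cfg: PipelineConfig, stage: str, extra: dict | None = None) -> dict:
    from . import __version__

    info = {
        "stage": stage,
        "config_hash": cfg.config_hash,
        "seed": cfg.design.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        info.update(extra)
    return info


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _truth_json(hidden: dict) -> dict:
    out: dict = {"population": {}, "subjects": {}}
    for (arm, measure), params in hidden["population"].items():
        out["population"][f"{arm}|{measure}"] = dataclasses.asdict(params)
    for (sid, arm, measure), params in hidden["subjects"].items():
        out["subjects"][f"{sid}|{arm}|{measure}"] = dataclasses.asdict(params)
    return out


def cmd_simulate(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Generate the dataset files for one synthetic study.

    Writes ``timeseries.csv``, ``intake.csv``, ``truth.json`` and
    ``provenance.json`` under ``out_dir``; returns the file map.
    """
    out = Path(out_dir)
    if not out.parent.exists():
        raise ConfigurationError(f"output directory parent missing: {out.parent}")
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    assignments = simulate_design(cfg.design)
    records, hidden = simulate_timeseries(
        cfg.design, cfg.truth, assignments=assignments, raw_mode=cfg.raw_mode
    )
    intake = simulate_intake(
        cfg.design, noise_sd=cfg.intake_noise_sd, assignments=assignments
    )
    files = {
        "timeseries": out / "timeseries.csv",
        "intake": out / "intake.csv",
        "truth": out / "truth.json",
        "assignments": out / "assignments.csv",
        "provenance": out / "provenance.json",
    }
    records.to_csv(files["timeseries"], index=False, lineterminator="\n")
    intake.to_csv(files["intake"], index=False, lineterminator="\n")
    assignments.to_csv(files["assignments"], index=False, lineterminator="\n")
    _write_json(files["truth"], _truth_json(hidden))
    _write_json(
        files["provenance"],
        _provenance(
            cfg,
            "simulate",
            {"n_records": int(len(records)), "elapsed_s": round(time.time() - t0, 2)},
        ),
    )
    log.info(
        "simulate: %d records, %d intake rows (config %s, seed %d)",
        len(records),
        len(intake),
        cfg.config_hash,
        cfg.design.seed,
    )
    return files


_REQUIRED_TS_COLUMNS = ["subject_id", "arm", "measure", "time_min", "value"]


def _validate_timeseries(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_TS_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"time-series table lacks columns: {missing}")
    if records.empty:
        raise DataError("time-series table is empty")
    if "is_baseline" not in records.columns:
        records = records.copy()
        records["is_baseline"] = records["time_min"] < 0
    bad = ~np.isfinite(records["value"])
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DataError(f"non-finite value at row {i}")
    return records


def cmd_fit(
    cfg: PipelineConfig,
    dataset_dir: str | Path,
    out_dir: str | Path,
) -> dict:
    """Fit every configured measure and write summary/contrast tables.

    In raw mode blood and sensation measures are first converted to DOB.
    Writes ``summaries.csv``, ``contrasts.csv`` and ``fit_log.json`` with
    the worst-case rhat; returns ``{"files": ..., "converged": bool}``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(Path(dataset_dir) / "timeseries.csv")
    records = _validate_timeseries(records)

    summary_rows = []
    contrast_rows = []
    worst_rhat = 0.0
    t_start = time.time()
    timings = {}
    dob_skipped = 0
    for measure in cfg.fit_measures:
        if measure not in cfg.truth.measures:
            raise ConfigurationError(f"no model spec for measure {measure!r}")
        mt = cfg.truth.measures[measure]
        sub = records[records["measure"] == measure]
        if sub.empty:
            raise DataError(f"dataset contains no rows for measure {measure!r}")
        if cfg.raw_mode and mt.kind in ("blood", "sensation", "gallbladder"):
            sub, n_skip = compute_dob(sub)
            dob_skipped += n_skip
        t0 = time.time()
        spec = HierarchicalModelSpec(
            measure=measure,
            curve_family=mt.family,
            chains=cfg.chains,
            warmup=cfg.warmup,
            draws=cfg.draws,
            thin=cfg.thin,
            seed=cfg.design.seed,
            rhat_threshold=cfg.rhat_threshold,
        )
        fit = fit_hierarchical(sub, spec)
        timings[measure] = round(time.time() - t0, 2)
        worst_rhat = max(worst_rhat, fit.worst_rhat)
        for s in fit.summaries:
            summary_rows.append({"measure": measure, **s.__dict__})
        params = ("v0", "k", "t_const") if mt.family == "linexp" else (
            "aob", "t_max", "a_max"
        )
        for pname in params:
            for c in contrasts(fit, pname):
                contrast_rows.append({"measure": measure, **c.__dict__})
        log.info("fit %s: worst rhat %.3f (%.1fs)", measure, fit.worst_rhat, timings[measure])

    files = {
        "summaries": out / "summaries.csv",
        "contrasts": out / "contrasts.csv",
        "fit_log": out / "fit_log.json",
    }
    pd.DataFrame(summary_rows).to_csv(files["summaries"], index=False, lineterminator="\n")
    pd.DataFrame(contrast_rows).to_csv(files["contrasts"], index=False, lineterminator="\n")
    converged = worst_rhat <= cfg.rhat_threshold
    _write_json(
        files["fit_log"],
        _provenance(
            cfg,
            "fit",
            {
                "worst_rhat": round(worst_rhat, 4),
                "converged": converged,
                "timings_s": timings,
                "elapsed_s": round(time.time() - t_start, 2),
                "dob_series_skipped": dob_skipped,
            },
        ),
    )
    return {"files": files, "converged": converged, "worst_rhat": worst_rhat}


def cmd_intake(cfg: PipelineConfig, dataset_dir: str | Path, out_dir: str | Path) -> Path:
    """Fit the intake linear model and write the coefficient table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    intake = pd.read_csv(Path(dataset_dir) / "intake.csv")
    table = fit_intake_table(intake)
    path = out / "intake_coefficients.csv"
    table.to_csv(path, index=False, lineterminator="\n")
    return path


def cmd_report(
    summaries_csv: str | Path,
    contrasts_csv: str | Path,
    out_path: str | Path,
    intake_csv: str | Path | None = None,
) -> Path:
    """Render a plain-text report of estimates and flagged differences.

    Mirrors the study's presentation: per measure and parameter, the
    arm-level medians with 95% HPDs, and only those pairwise differences
    whose HPD excludes zero; plus the intake coefficient table when given.
    """
    summaries = pd.read_csv(summaries_csv)
    contr = pd.read_csv(contrasts_csv)
    if not summaries.empty and not contr.empty:
        if set(contr["arm_a"]) - set(summaries["arm"]) or set(
            contr["arm_b"]
        ) - set(summaries["arm"]):
            raise DataError("contrast arms do not match the summary table arms")
    lines = ["Curve-parameter estimates (median, 95% HPD)", "=" * 46, ""]
    for (measure, parameter), grp in summaries.groupby(
        ["measure", "parameter"], sort=True
    ):
        lines.append(f"{measure} / {parameter}")
        for _, row in grp.iterrows():
            flag = "" if row.get("converged", True) else "  [non-converged]"
            lines.append(
                f"  {row['arm']:>8}: {row['median']:10.3f} "
                f"({row['hpd_low']:.3f}, {row['hpd_high']:.3f}){flag}"
            )
        sel = contr[
            (contr["measure"] == measure)
            & (contr["parameter"] == parameter)
            & contr["excludes_zero"]
        ]
        for _, row in sel.iterrows():
            lines.append(
                f"    diff {row['arm_b']} - {row['arm_a']}: "
                f"{row['median']:.3f} ({row['hpd_low']:.3f}, {row['hpd_high']:.3f})"
            )
        lines.append("")
    if intake_csv is not None:
        intake = pd.read_csv(intake_csv)
        lines += ["Buffet intake linear model (estimate, 95% CI)", "=" * 46, ""]
        lines.append(intake.to_string(index=False, float_format="%.1f"))
        lines.append("")
    text = "\n".join(lines)
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(text)
    return out
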