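"""Pipeline orchestration and file I/O: generate -> fit -> evaluate -> report.

On-disk layout under the run directory:

    records/S00.csv ...      per-subject trend records (units in headers)
    truth/S00.json ...       generating ground truth (synthetic cohorts)
    manifest.json            cohort spec and all seeds
    fits/S00_M3.json ...     fit results (parameters, J, delay profile)
    fits/S00_M3_pred.csv ... predicted trajectories next to the data
    report.json, report.csv  cohort comparison tables

CSV dialect: comma-separated, dot decimal, mandatory header with units
embedded in the column names (time_s, petco2_mmHg, vdot_lpm, ...).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import ParamDistribution, ProtocolSpec, SubjectData, generate_cohort
from .core import PhysioParams
from .evaluate import CohortComparison, compare_cohort
from .identify import FitFailureError, FitOptions, FitResult, fit_model
from .simulate import VentilationRecord

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["time_s", "petco2_mmHg", "vdot_lpm"]
SETTING_COLUMNS = {
    "rr_per_min": "rr_per_min",
    "tv_ml": "tv_ml",
    "ie_ratio": "ie_ratio",
    "ppeak_cmH2O": "ppeak_cmH2O",
}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "runs/demo"
    models: tuple = ("M1", "M2", "M3")
    n_subjects: int = 25
    master_seed: int = 0
    noise_sd: float = 0.5
    generator_method: str = "continuous"
    duration_min: float = 24.0
    tau_min_s: float = 5.0
    tau_max_s: float = 60.0
    n_starts: int = 8
    fit_seed: int = 0
    ts_s: float = 5.0
    input_dir: Optional[str] = None
    create_dirs: bool = True

    def __post_init__(self) -> None:
        bad = set(self.models) - {"M1", "M2", "M3"}
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.tau_min_s <= self.tau_max_s):
            raise ValueError("need 0 < tau_min_s <= tau_max_s")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as f:
            d = json.load(f)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)

    def fit_options(self) -> FitOptions:
        lo = max(1, int(round(self.tau_min_s / self.ts_s)))
        hi = max(lo, int(round(self.tau_max_s / self.ts_s)))
        return FitOptions(
            tau_grid=tuple(range(lo, hi + 1)),
            n_starts=self.n_starts,
            seed=self.fit_seed,
        )


def write_record(record: VentilationRecord, path: Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": record.t_s,
            "petco2_mmHg": record.petco2,
            "vdot_lpm": record.vdot,
        }
    )
    for col in SETTING_COLUMNS:
        if col in record.settings:
            df[col] = record.settings[col]
    df.to_csv(path, index=False)


def read_record(path: Path, ts_s: Optional[float] = None) -> VentilationRecord:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[RECORD_COLUMNS].isna().any().any():
        raise ValueError(f"{path}: non-numeric or missing values")
    t = df["time_s"].to_numpy(dtype=float)
    if ts_s is None:
        ts_s = float(np.median(np.diff(t)))
    settings = {
        col: df[col].to_numpy(dtype=float)
        for col in SETTING_COLUMNS
        if col in df.columns
    }
    return VentilationRecord(
        ts_s=ts_s,
        t_s=t,
        petco2=df["petco2_mmHg"].to_numpy(dtype=float),
        vdot=df["vdot_lpm"].to_numpy(dtype=float),
        settings=settings,
        subject_id=Path(path).stem,
    )


def _truth_json(sub: SubjectData) -> dict:
    return {
        "physio": sub.physio.to_json_dict(),
        "theta": sub.theta.to_json_dict(),
        "tau_true_s": sub.tau_true_s,
    }


def cmd_generate(config: RunConfig) -> list[Path]:
    """Generate the synthetic cohort and write records + truth + manifest.
    Idempotent for a given master seed."""
    out = Path(config.out_dir)
    rec_dir, truth_dir = out / "records", out / "truth"
    if not config.create_dirs and not out.exists():
        raise FileNotFoundError(f"output dir {out} does not exist (--no-create)")
    rec_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    protocol = ProtocolSpec(duration_min=config.duration_min, ts_s=config.ts_s)
    dist = ParamDistribution(tau_range_s=(config.tau_min_s, config.tau_max_s))
    cohort = generate_cohort(
        config.n_subjects,
        dist=dist,
        master_seed=config.master_seed,
        protocol=protocol,
        noise_sd=config.noise_sd,
        method=config.generator_method,
    )
    paths = []
    for sub in cohort:
        p = rec_dir / f"{sub.record.subject_id}.csv"
        write_record(sub.record, p)
        with open(truth_dir / f"{sub.record.subject_id}.json", "w") as f:
            json.dump(_truth_json(sub), f, indent=1)
        paths.append(p)
    manifest = {
        "n_subjects": config.n_subjects,
        "master_seed": config.master_seed,
        "noise_sd_mmHg": config.noise_sd,
        "generator_method": config.generator_method,
        "ts_s": config.ts_s,
        "duration_min": config.duration_min,
        "tau_range_s": [config.tau_min_s, config.tau_max_s],
        "records": [p.name for p in paths],
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    logger.info("wrote %d records to %s", len(paths), rec_dir)
    return paths


def cmd_fit(config: RunConfig) -> dict:
    """Fit every requested model to every record; returns
    {subject_id: {model_id: FitResult}}.  A malformed record is skipped
    with a logged error; others complete."""
    out = Path(config.out_dir)
    rec_dir = Path(config.input_dir) if config.input_dir else out / "records"
    fit_dir = out / "fits"
    fit_dir.mkdir(parents=True, exist_ok=True)
    opts = config.fit_options()

    fits: dict = {}
    failures = []
    for path in sorted(rec_dir.glob("*.csv")):
        try:
            record = read_record(path)
        except (ValueError, KeyError) as exc:
            logger.error("skipping %s: %s", path.name, exc)
            failures.append(path.name)
            continue
        sid = record.subject_id
        fits[sid] = {}
        for model_id in config.models:
            try:
                fr = fit_model(record, model_id, opts)
            except FitFailureError as exc:
                logger.error("fit failed for %s/%s: %s", sid, model_id, exc)
                failures.append(f"{sid}/{model_id}")
                continue
            fits[sid][model_id] = fr
            with open(fit_dir / f"{sid}_{model_id}.json", "w") as f:
                json.dump(fr.to_json_dict(), f, indent=1)
            pd.DataFrame(
                {
                    "time_s": record.t_s,
                    "petco2_mmHg": record.petco2,
                    "petco2_pred_mmHg": fr.predicted,
                    "vdot_lpm": record.vdot,
                }
            ).to_csv(fit_dir / f"{sid}_{model_id}_pred.csv", index=False)
            logger.info(
                "%s %s: J*=%.4g mmHg^2 tau*=%d", sid, model_id, fr.J_star, fr.tau_star
            )
    if failures:
        logger.warning("%d fit/parse failures: %s", len(failures), failures)
    return fits


def load_fits(config: RunConfig) -> tuple[dict, dict]:
    """Reload fit results and records from a run directory; predicted
    trajectories are read back from the sidecar CSVs."""
    out = Path(config.out_dir)
    rec_dir = Path(config.input_dir) if config.input_dir else out / "records"
    fit_dir = out / "fits"
    records = {p.stem: read_record(p) for p in sorted(rec_dir.glob("*.csv"))}
    fits: dict = {}
    for path in sorted(fit_dir.glob("*_M?.json")):
        sid, model_id = path.stem.rsplit("_", 1)
        with open(path) as f:
            d = json.load(f)
        pred_path = fit_dir / f"{sid}_{model_id}_pred.csv"
        predicted = pd.read_csv(pred_path)["petco2_pred_mmHg"].to_numpy()
        fits.setdefault(sid, {})[model_id] = FitResult.from_json_dict(d, predicted)
    return fits, records


def _recovery_table(fits: dict, truth_dir: Path, ts_s: float) -> list[dict]:
    rows = []
    for sid, per_model in sorted(fits.items()):
        tp = truth_dir / f"{sid}.json"
        if not tp.exists():
            continue
        with open(tp) as f:
            truth = json.load(f)
        true_physio = PhysioParams.from_json_dict(truth["physio"])
        for model_id, fr in per_model.items():
            if fr.physio_star is None:
                continue
            est = fr.physio_star
            row = {"subject_id": sid, "model_id": model_id}
            for attr, key in [
                ("VL", "VL_l"), ("VB", "VB_l"), ("Q", "Q_lpm"), ("VCO2", "VCO2_lpm_STPD"),
            ]:
                tv, ev = getattr(true_physio, attr), getattr(est, attr)
                row[f"{key}_true"] = tv
                row[f"{key}_est"] = ev
                row[f"{key}_rel_err"] = abs(ev - tv) / abs(tv)
            row["tau_true_s"] = truth["tau_true_s"]
            row["tau_est_s"] = fr.tau_star * ts_s
            rows.append(row)
    return rows


def cmd_report(
    config: RunConfig, fits: Optional[dict] = None, records: Optional[dict] = None
) -> CohortComparison:
    """Build the cohort comparison and write report.json / report.csv;
    adds a parameter-recovery table when ground truth is available."""
    if fits is None or records is None:
        fits, records = load_fits(config)
    if not fits:
        raise FileNotFoundError(f"no fit results under {config.out_dir}/fits")
    # restrict to subjects with the complete model set
    models = set(config.models)
    complete = {s: m for s, m in fits.items() if models <= set(m)}
    dropped = sorted(set(fits) - set(complete))
    if dropped:
        logger.warning("subjects without complete fits excluded: %s", dropped)
    if len(models) < 2:
        logger.info("single-model run: comparison tests omitted")
    comparison = compare_cohort(
        {s: {m: complete[s][m] for m in models} for s in complete}, records
    )

    out = Path(config.out_dir)
    report = comparison.to_json_dict()
    truth_dir = out / "truth"
    if truth_dir.exists():
        recovery = _recovery_table(complete, truth_dir, config.ts_s)
        if recovery:
            report["recovery"] = recovery
            pd.DataFrame(recovery).to_csv(out / "recovery.csv", index=False)
    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1)
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "model_id": r.model_id,
                "rmse_mmHg": r.rmse,
                "aic": r.aic,
                "n_samples": r.n_samples,
            }
            for r in comparison.reports
        ]
    ).to_csv(out / "report.csv", index=False)
    return comparison


def run_all(config: RunConfig) -> CohortComparison:
    """generate -> fit -> report from one master seed (deterministic)."""
    cmd_generate(config)
    fits = cmd_fit(config)
    _, records = load_fits(config)
    return cmd_report(config, fits=fits, records=records)
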