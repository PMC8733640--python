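"""End-to-end study orchestration: simulate -> extract -> statistics -> classify.

``run_study`` turns one :class:`PipelineConfig` into a reproducible study
report: a cohort table, a per-subject parameter table (DCR metrics,
stiffness slope, estimated modulus, recovery error), group-comparison and
ROC tables per contrast, a trained diagnosis network with its validation
accuracy and ROC, and the list of QC-excluded subjects.  One master seed
fans out to per-subject simulation seeds through the cohort generator, so
any single subject is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .airpuff import AirPuffConfig
from .extraction import (
    InsufficientWindowError,
    NoConcavityError,
    NotApplanatedError,
    extract_subject,
)
from .mlp import (
    DEFAULT_FEATURES,
    MLPConfig,
    accuracy,
    add_target_column,
    classify,
    predict,
    split_data,
    train,
)
from .shell import CorneaGeometry, elastic_modulus
from .stats import group_table, roc_curve, roc_table
from .synth import (
    DEFAULT_N_PER_GROUP,
    SimConfig,
    SubjectRecord,
    generate_cohort,
    simulate_examination,
)

log = logging.getLogger("cornea_emod")

#: DCR parameters reported in the group and ROC tables
DCR_COLUMNS = ("A1T", "A1V", "A2T", "A2V", "HCT", "PD", "DA")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_group: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    airpuff: AirPuffConfig = field(default_factory=AirPuffConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    mlp: MLPConfig = field(default_factory=MLPConfig)
    group_configs: Optional[dict] = None
    contrasts: Tuple[Tuple[str, str], ...] = (
        ("KC", "healthy"),
        ("FFKC", "healthy"),
        ("KC", "FFKC"),
    )
    roc_contrasts: Tuple[Tuple[str, str], ...] = (
        ("KC", "healthy"),
        ("FFKC", "healthy"),
    )


def process_subject(
    subject: SubjectRecord, config: PipelineConfig
) -> Optional[dict]:
    """Simulate and fully extract one subject; None on QC exclusion."""
    exam = simulate_examination(subject, config.airpuff, config.sim)
    try:
        trace, params, stiff = extract_subject(
            exam, config.airpuff, bIOP=subject.bIOP
        )
    except (NotApplanatedError, NoConcavityError, InsufficientWindowError) as e:
        log.warning("QC exclusion at extraction: %s", e)
        return None
    result = elastic_modulus(stiff.S_TSC, subject.geometry, config.airpuff.rp)
    row = subject.to_row()
    row.update(params.to_dict())
    row.update(
        {
            "S_TSC": stiff.S_TSC,
            "fit_r2": stiff.fit_r2,
            "E": result.E,
            "mu": result.mu,
            "c1": result.c1,
            "E_rel_error": (result.E - subject.E_true) / subject.E_true,
        }
    )
    return row


def run_study(config: PipelineConfig, out_dir: Optional[str] = None) -> dict:
    """Execute the full study.  Deterministic given ``config.seed``.

    Returns a report dict with the cohort table, subject-level results,
    group tables, ROC tables, classifier report and QC exclusions;
    optionally writes CSV/JSON/Markdown artifacts to ``out_dir``.
    """
    t0 = _time.perf_counter()
    subjects = generate_cohort(
        group_configs=config.group_configs,
        n_per_group=config.n_per_group,
        seed=config.seed,
    )
    log.info("cohort: %d subjects", len(subjects))

    rows: List[dict] = []
    excluded: List[str] = []
    for s in subjects:
        row = process_subject(s, config)
        if row is None:
            excluded.append(s.subject_id)
        else:
            rows.append(row)
    table = pd.DataFrame(rows)
    t_extract = _time.perf_counter()

    params_for_stats = [c for c in DCR_COLUMNS if c in table.columns]
    params_for_stats += ["SP-A1", "ARTh", "S_TSC", "E"]
    groups_tbl = group_table(table, params_for_stats)
    roc_tables = [
        roc_table(table, params_for_stats, case, control)
        for case, control in config.roc_contrasts
    ]
    roc_all = pd.concat(roc_tables, ignore_index=True)

    coded = add_target_column(table)
    train_df, valid_df = split_data(
        coded, config.mlp.train_fraction, seed=config.mlp.seed
    )
    model = train(train_df, config.mlp, feature_names=DEFAULT_FEATURES)
    valid_pred = predict(model, valid_df)
    valid_groups = classify(valid_pred)
    acc = accuracy(valid_groups, valid_df["group"].tolist())

    # ROC of the predicted value for FFKC vs healthy inside the validation set
    mask = valid_df["group"].isin(["FFKC", "healthy"]).to_numpy()
    pred_roc = None
    if mask.sum() >= 4 and len(set(valid_df["group"][mask])) == 2:
        labels = (valid_df["group"][mask] == "FFKC").to_numpy()
        pred_roc = roc_curve(valid_pred[mask], labels)

    recovery = table[
        ["subject_id", "group", "E_true", "E", "E_rel_error"]
    ].copy()

    report = {
        "config_seed": config.seed,
        "n_subjects": len(subjects),
        "n_processed": len(table),
        "excluded": excluded,
        "table": table,
        "group_table": groups_tbl,
        "roc_table": roc_all,
        "classifier": {
            "model": model,
            "validation_accuracy": acc,
            "validation_n": int(len(valid_df)),
            "training_report": model.training_report,
            "predicted_value_roc_ffkc": pred_roc,
        },
        "recovery_table": recovery,
        "timing_s": {
            "simulate_extract": t_extract - t0,
            "total": _time.perf_counter() - t0,
        },
    }
    if out_dir is not None:
        _write_report(report, out_dir)
    log.info(
        "study done: %d/%d processed, accuracy %.3f",
        len(table), len(subjects), acc,
    )
    return report


def _write_report(report: dict, out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["table"].to_csv(out / "subjects.csv", index=False)
    report["group_table"].to_csv(out / "group_comparison.csv", index=False)
    report["roc_table"].to_csv(out / "roc.csv", index=False)
    report["recovery_table"].to_csv(out / "recovery.csv", index=False)
    (out / "model.json").write_text(report["classifier"]["model"].to_json())
    summary = {
        "seed": report["config_seed"],
        "n_subjects": report["n_subjects"],
        "n_processed": report["n_processed"],
        "excluded": report["excluded"],
        "validation_accuracy": report["classifier"]["validation_accuracy"],
        "training_report": report["classifier"]["training_report"],
        "timing_s": report["timing_s"],
    }
    pr = report["classifier"]["predicted_value_roc_ffkc"]
    if pr is not None:
        summary["predicted_value_auc_ffkc"] = pr.auc
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    _write_markdown(report, out / "report.md")


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Study report", ""]
    lines.append(f"Seed {report['config_seed']}; "
                 f"{report['n_processed']}/{report['n_subjects']} subjects "
                 f"processed ({len(report['excluded'])} QC exclusions).")
    lines += ["", "## Group comparison", "",
              report["group_table"].to_markdown(index=False), "",
              "## ROC analysis", "",
              report["roc_table"].to_markdown(index=False), ""]
    acc = report["classifier"]["validation_accuracy"]
    lines.append(f"## Classifier\n\nValidation accuracy: {acc:.3f}")
    Path(path).write_text("\n".join(lines))


def recovery_experiment(
    E_grid: Sequence[float],
    noise_levels: Sequence[float],
    n_reps: int,
    seed: int = 0,
    geometry: Optional[CorneaGeometry] = None,
    airpuff: Optional[AirPuffConfig] = None,
    sim: Optional[SimConfig] = None,
) -> pd.DataFrame:
    """Bias and relative RMSE of the modulus estimate over a (E, noise) grid.

    For each cell, ``n_reps`` independent subjects with fixed geometry and
    true modulus E are simulated at elevation-noise sigma ``noise`` and run
    through the extraction and shell inversion.  Reported per cell: mean
    relative bias, relative RMSE and median absolute relative error.
    """
    if len(E_grid) == 0:
        raise ValueError("E grid must be non-empty")
    geometry = geometry or CorneaGeometry(R=7.75, t=0.5345)
    airpuff = airpuff or AirPuffConfig()
    base_sim = sim or SimConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for E_true in E_grid:
        for noise in noise_levels:
            sim_i = replace(base_sim, noise_sigma=float(noise))
            errors = []
            for _ in range(n_reps):
                subject = SubjectRecord(
                    subject_id=f"rec-{E_true:.3f}-{noise:.4f}",
                    group="healthy",
                    E_true=float(E_true),
                    geometry=geometry,
                    bIOP=15.0,
                    aux_features={},
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                exam = simulate_examination(subject, airpuff, sim_i)
                try:
                    _, _, stiff = extract_subject(exam, airpuff)
                except ValueError:
                    errors.append(np.nan)
                    continue
                E_hat = elastic_modulus(
                    stiff.S_TSC, geometry, airpuff.rp
                ).E
                errors.append((E_hat - E_true) / E_true)
            err = np.asarray(errors, dtype=float)
            ok = np.isfinite(err)
            rows.append(
                {
                    "E_true": E_true,
                    "noise_sigma": noise,
                    "n_reps": n_reps,
                    "n_ok": int(ok.sum()),
                    "bias_rel": float(np.mean(err[ok])) if ok.any() else np.nan,
                    "rmse_rel": float(np.sqrt(np.mean(err[ok] ** 2)))
                    if ok.any() else np.nan,
                    "median_abs_rel": float(np.median(np.abs(err[ok])))
                    if ok.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)
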