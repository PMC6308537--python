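"""End-to-end pipeline stages: batch extraction and the full experiment.

``run_extract`` turns a directory of signal files into a feature table.
``run_experiment`` runs the whole study on a synthetic cohort: simulate
-> extract -> per-subject calibration -> prediction on the test days ->
pooled and per-day evaluation of the MPF model, the 21 single-feature
models and the three PTT baselines, plus a model-comparison t-test.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import PulseBPError
from .evaluation import compare_models, evaluate
from .features import FEATURE_NAMES, record_features
from .models import PTT_VARIANTS, SubjectModels, fit_subject
from .record import read_record
from .synthetic import Cohort, CohortSpec, generate_cohort

__all__ = ["run_extract", "run_experiment", "extract_features_table"]

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "session_time", "n_beats", "ref_sbp", "ref_dbp")


def run_extract(
    signals_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Extract a feature table from a directory of signal/sidecar pairs.

    Expects ``<name>.csv`` signal files with matching ``<name>.json``
    sidecars.  Returns ``(table, rejected)`` where ``rejected`` lists
    ``(file, reason)`` pairs; unreadable or unusable files never abort
    the run.
    """
    config = config or PipelineConfig()
    signals_dir = Path(signals_dir)
    rows: list[dict] = []
    rejected: list[tuple[str, str]] = []
    files = sorted(signals_dir.glob("*.csv"))
    if not files:
        logger.warning("no signal files found in %s", signals_dir)
    for path in files:
        sidecar = path.with_suffix(".json")
        try:
            record = read_record(path, sidecar)
            fv = record_features(
                record,
                cutoff_hz=config.cutoff_hz,
                wavelet=config.wavelet,
                baseline_cutoff_hz=config.baseline_cutoff_hz,
                dicrotic_window=config.dicrotic_window,
                onset_frac=config.onset_frac,
            )
        except (PulseBPError, OSError) as exc:
            rejected.append((path.name, str(exc)))
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        row = {
            "subject_id": record.subject_id,
            "session_time": record.session_time,
            "n_beats": fv.n_accepted,
            **fv.values,
            "ref_sbp": record.ref_sbp,
            "ref_dbp": record.ref_dbp,
        }
        rows.append(row)
    return pd.DataFrame(rows), rejected


def extract_features_table(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature tables of a generated cohort (already extracted)."""
    return cohort.train, cohort.test


def _evaluate_block(
    sub_frames: list[tuple[pd.DataFrame, np.ndarray]], target: str
) -> dict:
    refs = np.concatenate([f[f"ref_{target}"].to_numpy(dtype=float) for f, _ in sub_frames])
    ests = np.concatenate([e for _, e in sub_frames])
    return evaluate(refs, ests, target=target).to_dict()


def run_experiment(
    spec: CohortSpec | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full calibration study on a synthetic cohort.

    Returns a report bundle (plain dict, JSON-serialisable):

    * ``models.MPF`` / ``models.<feature>`` / ``models.PTT_<variant>``:
      pooled evaluation per target;
    * ``per_day``: the same for each test day (calibration-interval
      robustness);
    * ``comparison``: Welch t-test of MPF vs the best PTT baseline
      errors per target;
    * ``errors``: raw per-row MPF errors for audit.
    """
    spec = spec or CohortSpec()
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    cohort = generate_cohort(spec, seed=seed)
    train, test = cohort.train, cohort.test

    # per-subject calibration, prediction on every test row
    preds: dict[str, dict[str, list]] = {}
    mpf_frames: dict[str, list] = {"sbp": [], "dbp": []}
    single_frames: dict[str, dict[str, list]] = {
        t: {n: [] for n in FEATURE_NAMES} for t in ("sbp", "dbp")
    }
    ptt_frames: dict[str, dict[str, list]] = {
        t: {v: [] for v in PTT_VARIANTS} for t in ("sbp", "dbp")
    }
    fitted: dict[str, SubjectModels] = {}
    for sid, sub in test.groupby("subject_id"):
        rows = train[train.subject_id == sid]
        if len(rows) < 2:
            logger.warning("subject %s lacks training rows; skipped", sid)
            continue
        models = fit_subject(rows, gamma=config.gamma, subject_id=str(sid))
        fitted[str(sid)] = models
        for target in ("sbp", "dbp"):
            mpf_frames[target].append((sub, models.mpf[target].predict(sub)))
            ens = models.mpf[target].predict_ensemble(sub)
            for j, name in enumerate(FEATURE_NAMES):
                single_frames[target][name].append((sub, ens[:, j]))
            if models.ptt is not None and sub["PTT"].notna().all():
                ptt = sub["PTT"].to_numpy(dtype=float)
                for variant in PTT_VARIANTS:
                    ptt_frames[target][variant].append(
                        (sub, models.ptt[target][variant].predict(ptt))
                    )

    report: dict = {"n_subjects": len(fitted), "models": {}, "per_day": {}}
    for target in ("sbp", "dbp"):
        report["models"].setdefault("MPF", {})[target] = _evaluate_block(
            mpf_frames[target], target
        )
        for name in FEATURE_NAMES:
            report["models"].setdefault(name, {})[target] = _evaluate_block(
                single_frames[target][name], target
            )
        for variant in PTT_VARIANTS:
            if ptt_frames[target][variant]:
                report["models"].setdefault(f"PTT_{variant}", {})[target] = (
                    _evaluate_block(ptt_frames[target][variant], target)
                )

    # per-day robustness (calibration-interval analysis)
    for day in sorted(test["day"].unique()):
        day_report = {}
        for target in ("sbp", "dbp"):
            frames = [
                (f[f.day == day], e[(f.day == day).to_numpy()])
                for f, e in mpf_frames[target]
                if (f.day == day).any()
            ]
            if frames:
                day_report[target] = _evaluate_block(frames, target)
        report["per_day"][int(day)] = day_report

    # model comparison: MPF vs best PTT baseline, per target
    report["comparison"] = {}
    for target in ("sbp", "dbp"):
        mpf_err = np.concatenate(
            [e - f[f"ref_{target}"].to_numpy(dtype=float) for f, e in mpf_frames[target]]
        )
        best_ptt, best_sd = None, np.inf
        for variant in PTT_VARIANTS:
            if not ptt_frames[target][variant]:
                continue
            err = np.concatenate(
                [
                    e - f[f"ref_{target}"].to_numpy(dtype=float)
                    for f, e in ptt_frames[target][variant]
                ]
            )
            if err.std(ddof=1) < best_sd:
                best_ptt, best_sd, best_err = variant, err.std(ddof=1), err
        if best_ptt is not None:
            t_stat, p = compare_models(
                np.abs(mpf_err), np.abs(best_err), equal_var=not config.welch
            )
            report["comparison"][target] = {
                "ptt_variant": best_ptt,
                "t_statistic": t_stat,
                "p_value": p,
            }
    return report
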