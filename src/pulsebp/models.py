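"""Per-subject blood-pressure calibration models.

The estimator of interest is the multiparameter-fusion (MPF) model:
each of the 21 waveform features calibrates its own univariate
least-squares model against reference BP; at prediction time the 21
single-feature estimates F_1..F_21 are fused as

    MPF = trimmed_mean(F, g) - std(F)

i.e. the g-trimmed mean (g = floor(gamma * N) dropped from each end of
the sorted estimates) minus the sample standard deviation of all N
untrimmed estimates.  The trimmed mean makes the fusion robust to
heavy-tailed single-model errors; the dispersion term penalises
disagreement among the models.

Three conventional pulse-transit-time baselines are provided for
comparison: BP ~ PTT, BP ~ 1/PTT, and BP ~ ln(1/PTT) + 1/PTT^2.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model selection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateFeatureError, ParameterError
from .features import FEATURE_NAMES

__all__ = [
    "fit_univariate",
    "mpf_predict",
    "MPFRegressor",
    "PTTRegressor",
    "PTT_VARIANTS",
    "SubjectModels",
    "fit_subject",
]

DEFAULT_GAMMA = 0.1


def fit_univariate(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares fit ``y = slope * x + intercept``.

    Raises
    ------
    ParameterError
        On length mismatch or fewer than 2 points.
    DegenerateFeatureError
        If ``x`` is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ParameterError("need at least 2 points for a univariate fit")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise DegenerateFeatureError("feature is constant; cannot fit")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    return slope, float(ym - slope * xm)


def mpf_predict(
    predictions: np.ndarray, gamma: float = DEFAULT_GAMMA, n_expected: int = 21
) -> float:
    """Fuse single-model BP estimates: trimmed mean minus dispersion.

    Sorts the ``N`` estimates, drops ``g = floor(gamma * N)`` from each
    end, averages the remainder, and subtracts the sample standard
    deviation (``ddof=1``) of all N untrimmed estimates.

    Raises
    ------
    ParameterError
        On non-finite input, wrong length, or gamma outside [0, 0.5).
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.ndim != 1 or preds.size != n_expected:
        raise ParameterError(f"expected {n_expected} predictions, got {preds.size}")
    if not np.all(np.isfinite(preds)):
        raise ParameterError("non-finite prediction in the ensemble")
    if not 0.0 <= gamma < 0.5:
        raise ParameterError(f"gamma must lie in [0, 0.5), got {gamma}")
    n = preds.size
    g = math.floor(gamma * n)
    if n - 2 * g < 1:
        raise ParameterError("trimming would remove every prediction")
    trimmed = np.sort(preds)[g : n - g]
    return float(trimmed.mean() - preds.std(ddof=1))


class MPFRegressor(RegressorMixin, BaseEstimator):
    """Multiparameter-fusion BP estimator over 21 univariate calibrations.

    Parameters
    ----------
    gamma : float, default 0.1
        Trimming fraction of the fusion; ``g = floor(gamma * N)``
        estimates are dropped from each end of the sorted ensemble.
    feature_names : sequence of str, optional
        Column names when ``X`` is a DataFrame; defaults to the
        package's 21-feature catalogue.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Slope of each univariate calibration.
    intercept_ : ndarray of shape (n_features,)
        Intercept of each univariate calibration.
    n_features_in_ : int
    """

    def __init__(self, gamma: float = DEFAULT_GAMMA, feature_names=None):
        self.gamma = gamma
        self.feature_names = feature_names

    def _resolve_X(self, X) -> np.ndarray:
        names = list(self.feature_names or FEATURE_NAMES)
        if isinstance(X, pd.DataFrame):
            missing = [n for n in names if n not in X.columns]
            if missing:
                raise ParameterError(f"missing feature column(s): {missing}")
            X = X[names].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(names):
                raise ParameterError(
                    f"X must have {len(names)} columns, got shape {X.shape}"
                )
        return X

    def fit(self, X, y):
        """Fit one univariate least-squares model per feature column."""
        Xv = self._resolve_X(X)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(Xv)):
            raise DegenerateFeatureError("training features contain NaN/inf")
        names = list(self.feature_names or FEATURE_NAMES)
        slopes, intercepts = [], []
        for j, name in enumerate(names):
            try:
                a, b = fit_univariate(Xv[:, j], y)
            except DegenerateFeatureError as exc:
                raise DegenerateFeatureError(f"feature '{name}': {exc}") from exc
            slopes.append(a)
            intercepts.append(b)
        self.coef_ = np.array(slopes)
        self.intercept_ = np.array(intercepts)
        self.n_features_in_ = Xv.shape[1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        return self

    def predict_ensemble(self, X) -> np.ndarray:
        """Per-feature univariate estimates, shape (n_samples, n_features)."""
        check_is_fitted(self, "coef_")
        Xv = self._resolve_X(X)
        return Xv * self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        ens = self.predict_ensemble(X)
        return np.array(
            [mpf_predict(row, self.gamma, n_expected=ens.shape[1]) for row in ens]
        )


#: design matrices of the three PTT baseline variants
PTT_VARIANTS = ("linear_PTT", "inverse_PTT", "log_inv_sq")


def _ptt_design(ptt: np.ndarray, variant: str) -> np.ndarray:
    ptt = np.asarray(ptt, dtype=float)
    if np.any(ptt <= 0):
        raise ParameterError("PTT values must be positive")
    if variant == "linear_PTT":
        return ptt[:, None]
    if variant == "inverse_PTT":
        return (1.0 / ptt)[:, None]
    if variant == "log_inv_sq":
        return np.column_stack([np.log(1.0 / ptt), 1.0 / ptt**2])
    raise ParameterError(f"unknown PTT model variant {variant!r}")


class PTTRegressor(RegressorMixin, BaseEstimator):
    """Pulse-transit-time baseline BP model.

    ``variant`` selects the regressor set: ``linear_PTT`` (BP ~ PTT),
    ``inverse_PTT`` (BP ~ 1/PTT) or ``log_inv_sq``
    (BP ~ ln(1/PTT) + 1/PTT^2, the two-regressor form).
    """

    def __init__(self, variant: str = "log_inv_sq"):
        self.variant = variant

    def fit(self, X, y):
        ptt = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        D = _ptt_design(ptt, self.variant)
        A = np.column_stack([D, np.ones(len(D))])
        if len(A) < A.shape[1]:
            raise ParameterError("not enough rows to fit the PTT model")
        coefs, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef_ = coefs[:-1]
        self.intercept_ = float(coefs[-1])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        ptt = np.asarray(X, dtype=float).reshape(-1)
        D = _ptt_design(ptt, self.variant)
        return D @ self.coef_ + self.intercept_


TARGETS = ("sbp", "dbp")


@dataclass
class SubjectModels:
    """Calibrated models for one subject: MPF per target, PTT baselines.

    ``ptt`` is None when the training rows carried no PTT (no ECG).
    """

    subject_id: str
    mpf: dict[str, MPFRegressor]
    ptt: dict[str, dict[str, PTTRegressor]] | None = None
    gamma: float = DEFAULT_GAMMA

    def to_dict(self) -> dict:
        doc = {"subject_id": self.subject_id, "gamma": self.gamma, "targets": {}}
        for target, model in self.mpf.items():
            doc["targets"][target] = {
                "features": {
                    name: {"slope": float(a), "intercept": float(b)}
                    for name, a, b in zip(
                        model.feature_names_in_, model.coef_, model.intercept_
                    )
                }
            }
            if self.ptt is not None:
                doc["targets"][target]["ptt"] = {
                    variant: {
                        "coef": [float(c) for c in m.coef_],
                        "intercept": m.intercept_,
                    }
                    for variant, m in self.ptt[target].items()
                }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SubjectModels":
        gamma = float(doc["gamma"])
        mpf: dict[str, MPFRegressor] = {}
        ptt: dict[str, dict[str, PTTRegressor]] = {}
        has_ptt = False
        for target, tdoc in doc["targets"].items():
            names = list(tdoc["features"])
            model = MPFRegressor(gamma=gamma, feature_names=names)
            model.coef_ = np.array(
                [tdoc["features"][n]["slope"] for n in names]
            )
            model.intercept_ = np.array(
                [tdoc["features"][n]["intercept"] for n in names]
            )
            model.n_features_in_ = len(names)
            model.feature_names_in_ = np.asarray(names, dtype=object)
            mpf[target] = model
            if "ptt" in tdoc:
                has_ptt = True
                ptt[target] = {}
                for variant, mdoc in tdoc["ptt"].items():
                    pm = PTTRegressor(variant=variant)
                    pm.coef_ = np.array(mdoc["coef"], dtype=float)
                    pm.intercept_ = float(mdoc["intercept"])
                    pm.n_features_in_ = 1
                    ptt[target] = {**ptt[target], variant: pm}
        return cls(
            subject_id=str(doc.get("subject_id", "")),
            mpf=mpf,
            ptt=ptt if has_ptt else None,
            gamma=gamma,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SubjectModels":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_subject(
    rows: pd.DataFrame, gamma: float = DEFAULT_GAMMA, subject_id: str = ""
) -> SubjectModels:
    """Calibrate one subject from training rows.

    ``rows`` must contain the 21 feature columns plus ``ref_sbp`` and
    ``ref_dbp``; a ``PTT`` column with finite values additionally fits
    the three PTT baselines.  All 21 features are required and must be
    non-constant.

    Raises
    ------
    ParameterError
        Fewer than 2 rows, or missing columns.
    DegenerateFeatureError
        Any constant feature (the error names it).
    """
    if len(rows) < 2:
        raise ParameterError("need at least 2 training rows")
    for col in ("ref_sbp", "ref_dbp"):
        if col not in rows.columns:
            raise ParameterError(f"training rows lack '{col}'")
    missing = [n for n in FEATURE_NAMES if n not in rows.columns]
    if missing:
        raise ParameterError(f"training rows lack feature column(s): {missing}")

    mpf: dict[str, MPFRegressor] = {}
    for target in TARGETS:
        y = rows[f"ref_{target}"].to_numpy(dtype=float)
        mpf[target] = MPFRegressor(gamma=gamma).fit(rows, y)

    ptt_models: dict[str, dict[str, PTTRegressor]] | None = None
    if "PTT" in rows.columns and rows["PTT"].notna().all():
        ptt = rows["PTT"].to_numpy(dtype=float)
        ptt_models = {}
        for target in TARGETS:
            y = rows[f"ref_{target}"].to_numpy(dtype=float)
            ptt_models[target] = {
                variant: PTTRegressor(variant=variant).fit(ptt, y)
                for variant in PTT_VARIANTS
            }
    return SubjectModels(subject_id=subject_id, mpf=mpf, ptt=ptt_models, gamma=gamma)
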