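"""Accuracy evaluation of BP estimators: error statistics, BHS grading,
AAMI verdict, correlation, Bland-Altman limits and model comparison.

Errors are ``estimate - reference`` in mmHg.  MD is their mean, SD their
sample standard deviation (``ddof=1``).  Cumulative percentages (CP)
count absolute errors within +/-5, +/-10 and +/-15 mmHg (closed
intervals); the British Hypertension Society (BHS) grade is the highest
grade whose three CP thresholds are all strictly exceeded, and the AAMI
verdict requires |MD| <= 5 and SD <= 8 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError

__all__ = [
    "md_sd",
    "cumulative_percentages",
    "bhs_grade",
    "aami_check",
    "pearson_cc",
    "bland_altman",
    "compare_models",
    "EvaluationReport",
    "evaluate",
    "BHS_THRESHOLDS",
]

#: BHS grade thresholds: CP5, CP10, CP15 must each be strictly exceeded
BHS_THRESHOLDS: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


def _errors(references, estimates) -> np.ndarray:
    x = np.asarray(references, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("references and estimates must be 1-D, equal length")
    return y - x


def md_sd(references, estimates) -> tuple[float, float]:
    """Mean difference and sample standard deviation of the errors."""
    e = _errors(references, estimates)
    if e.size < 2:
        raise ParameterError("need at least 2 pairs")
    return float(e.mean()), float(e.std(ddof=1))


def cumulative_percentages(errors) -> tuple[float, float, float]:
    """Percent of absolute errors within 5, 10 and 15 mmHg (inclusive)."""
    e = np.abs(np.asarray(errors, dtype=float))
    if e.size == 0:
        raise ParameterError("need at least 1 error")
    return tuple(float(100.0 * np.mean(e <= thr)) for thr in (5.0, 10.0, 15.0))


def bhs_grade(cp5: float, cp10: float, cp15: float) -> str:
    """BHS letter grade from a CP triple; 'D' when no grade is met."""
    for grade in ("A", "B", "C"):
        t5, t10, t15 = BHS_THRESHOLDS[grade]
        if cp5 > t5 and cp10 > t10 and cp15 > t15:
            return grade
    return "D"


def aami_check(md: float, sd: float) -> bool:
    """AAMI accuracy verdict: |MD| <= 5 mmHg and SD <= 8 mmHg."""
    return abs(md) <= 5.0 and sd <= 8.0


def pearson_cc(references, estimates) -> float:
    """Pearson product-moment correlation between reference and estimate."""
    x = np.asarray(references, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(references, estimates) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD)."""
    md, sd = md_sd(references, estimates)
    return md, md - 1.96 * sd, md + 1.96 * sd


def compare_models(
    errors_a, errors_b, equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t-test between two error samples (Welch by default).

    Returns ``(t_statistic, p_value)``.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each sample needs at least 2 errors")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if np.array_equal(a[:1], b[:1]) or a.mean() == b.mean():
            return 0.0, 1.0
        raise ParameterError("both samples degenerate with distinct means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Full accuracy report of one estimator on one BP target."""

    target: str
    n: int
    md: float
    sd: float
    cp5: float
    cp10: float
    cp15: float
    bhs: str
    aami_pass: bool
    pearson_r: float | None
    bland_altman: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "n": self.n,
            "md": self.md,
            "sd": self.sd,
            "cp5": self.cp5,
            "cp10": self.cp10,
            "cp15": self.cp15,
            "bhs_grade": self.bhs,
            "aami_pass": self.aami_pass,
            "pearson_r": self.pearson_r,
            "bland_altman": list(self.bland_altman),
        }


def evaluate(references, estimates, target: str = "sbp") -> EvaluationReport:
    """Assemble the full report for one estimator/target."""
    x = np.asarray(references, dtype=float)
    y = np.asarray(estimates, dtype=float)
    md, sd = md_sd(x, y)
    cps = cumulative_percentages(y - x)
    try:
        r = pearson_cc(x, y)
    except ParameterError:
        r = None
    return EvaluationReport(
        target=target,
        n=int(x.size),
        md=md,
        sd=sd,
        cp5=cps[0],
        cp10=cps[1],
        cp15=cps[2],
        bhs=bhs_grade(*cps),
        aami_pass=aami_check(md, sd),
        pearson_r=r,
        bland_altman=bland_altman(x, y),
    )
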