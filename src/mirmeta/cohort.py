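"""Two-group expression comparison from summaries or sample-level values.

Each cohort compares a case arm (tumor tissue) against a control arm
(adjacent non-tumor or healthy tissue) for a single transcript.  The module
works either from per-arm summary statistics (n, mean, SD — the form in
which published cohorts are tabulated) or from raw per-sample expression
vectors, and provides:

* Welch and pooled-variance two-sample t-tests from summaries,
* the linear / log2 fold-change screen (FC < 0.5 or > 2, p < 0.05),
* nonparametric ROC analysis with a DeLong-type covariance standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "StudySummary",
    "TTestResult",
    "RocResult",
    "FoldChangeResult",
    "summarize_samples",
    "welch_t",
    "pooled_t",
    "fold_change",
    "roc_auc",
    "read_summary_tsv",
    "write_summary_tsv",
    "read_samples_tsv",
]


class DegenerateInputError(ValueError):
    """Raised when an input is too small or too uniform for the statistic."""


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one arm of a cohort: sample count, mean, SD (n−1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateInputError(f"group needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class StudySummary:
    """One cohort's two-group summary — the meta-analysis input row."""

    study_id: str
    case: GroupSummary
    control: GroupSummary
    source: str = "synthetic"  # GEO | TCGA | qPCR | synthetic


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: Literal["welch", "pooled"]


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    orientation: Literal["case_low", "case_high"]


@dataclass(frozen=True)
class FoldChangeResult:
    fc: float
    passes: bool


def summarize_samples(values: Iterable[float]) -> GroupSummary:
    """Arithmetic mean and n−1 SD of a vector of expression measurements."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("need at least 2 values to summarize a group")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in sample vector")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()), sd=float(arr.std(ddof=1)))


def _check_not_degenerate(case: GroupSummary, control: GroupSummary) -> None:
    if case.sd == 0 and control.sd == 0 and case.mean == control.mean:
        raise DegenerateInputError("both SDs zero with equal means: t undefined")
    if case.sd == 0 and control.sd == 0:
        raise DegenerateInputError("both SDs zero: standard error is zero")


def welch_t(case: GroupSummary, control: GroupSummary) -> TTestResult:
    """Unequal-variance (Welch) two-sample t-test from arm summaries.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2), with Welch–Satterthwaite df and a
    two-sided p from the t distribution.
    """
    _check_not_degenerate(case, control)
    v1 = case.sd**2 / case.n
    v2 = control.sd**2 / control.n
    se = math.sqrt(v1 + v2)
    t = (case.mean - control.mean) / se
    df = (v1 + v2) ** 2 / (v1**2 / (case.n - 1) + v2**2 / (control.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p, method="welch")


def pooled_t(case: GroupSummary, control: GroupSummary) -> TTestResult:
    """Classic equal-variance (pooled) Student t-test, df = n1 + n2 − 2."""
    _check_not_degenerate(case, control)
    n1, n2 = case.n, control.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * case.sd**2 + (n2 - 1) * control.sd**2) / df
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (case.mean - control.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=t, df=df, p=p, method="pooled")


def fold_change(
    case: GroupSummary,
    control: GroupSummary,
    scale: Literal["linear", "log2"] = "linear",
    p: float | None = None,
) -> FoldChangeResult:
    """Case/control expression ratio and the differential-expression screen.

    On the linear scale fc = mean_case / mean_control; on log2 data
    fc = 2**(mean_case − mean_control).  The screen passes when the ratio is
    below 0.5 or above 2 (strict) *and* the accompanying two-group p-value is
    below 0.05.
    """
    if scale == "linear":
        if control.mean <= 0:
            raise ValueError("linear-scale control mean must be positive")
        if case.mean <= 0:
            raise ValueError("linear-scale case mean must be positive")
        fc = case.mean / control.mean
    elif scale == "log2":
        fc = 2.0 ** (case.mean - control.mean)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    extreme = fc < 0.5 or fc > 2.0
    passes = bool(extreme and p is not None and p < 0.05)
    return FoldChangeResult(fc=fc, passes=passes)


def _midrank_auc(case: np.ndarray, control: np.ndarray) -> float:
    """Mann–Whitney AUC P(case > control) with midrank tie handling."""
    ranks = stats.rankdata(np.concatenate([case, control]))
    n1, n2 = case.size, control.size
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def _delong_se(case: np.ndarray, control: np.ndarray, auc: float) -> float:
    """Covariance-based (DeLong) standard error of the Mann–Whitney AUC."""
    # placement values: for each case, fraction of controls it beats (ties ½)
    v10 = np.array([np.mean((c > control) + 0.5 * (c == control)) for c in case])
    v01 = np.array([np.mean((case > c) + 0.5 * (case == c)) for c in control])
    n1, n2 = case.size, control.size
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n2 > 1 else 0.0
    return float(math.sqrt(s10 / n1 + s01 / n2))


def roc_auc(case_values: Sequence[float], control_values: Sequence[float]) -> RocResult:
    """Diagnostic ROC area for one marker, oriented so AUC ≥ 0.5.

    The area equals the concordance probability of a random case/control
    pair.  Markers that go *down* in disease yield raw AUC < 0.5; the result
    is flipped and the direction recorded in ``orientation``.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise DegenerateInputError("ROC needs at least one value in each group")
    auc = _midrank_auc(case, control)
    if auc >= 0.5:
        orientation = "case_high"
    else:
        orientation = "case_low"
        case, control = control, case
        auc = 1.0 - auc
    se = _delong_se(case, control, auc)
    half = 1.959963984540054 * se
    return RocResult(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - half),
        ci_high=min(1.0, auc + half),
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# TSV interfaces

_SUMMARY_COLS = [
    "study_id",
    "n_case",
    "mean_case",
    "sd_case",
    "n_control",
    "mean_control",
    "sd_control",
    "source",
]


def read_summary_tsv(path) -> list[StudySummary]:
    """Read a per-study two-group summary table (one row per cohort)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_SUMMARY_COLS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"summary TSV missing columns: {sorted(missing)}")
    if df["study_id"].duplicated().any():
        dupes = df.loc[df["study_id"].duplicated(), "study_id"].tolist()
        raise ValueError(f"duplicate study ids: {dupes}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            StudySummary(
                study_id=str(row.study_id),
                case=GroupSummary(int(row.n_case), float(row.mean_case), float(row.sd_case)),
                control=GroupSummary(
                    int(row.n_control), float(row.mean_control), float(row.sd_control)
                ),
                source=str(getattr(row, "source", "synthetic")),
            )
        )
    return out


def write_summary_tsv(studies: Sequence[StudySummary], path) -> None:
    rows = [
        {
            "study_id": s.study_id,
            "n_case": s.case.n,
            "mean_case": s.case.mean,
            "sd_case": s.case.sd,
            "n_control": s.control.n,
            "mean_control": s.control.mean,
            "sd_control": s.control.sd,
            "source": s.source,
        }
        for s in studies
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLS).to_csv(path, sep="\t", index=False)


def read_samples_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read sample-level TSV (sample_id, group, value) → (case, control) arrays."""
    df = pd.read_csv(path, sep="\t")
    for col in ("group", "value"):
        if col not in df.columns:
            raise ValueError(f"sample TSV missing column {col!r}")
    bad = set(df["group"].unique()) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    case = df.loc[df["group"] == "case", "value"].to_numpy(float)
    control = df.loc[df["group"] == "control", "value"].to_numpy(float)
    return case, control
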