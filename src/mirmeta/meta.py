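"""Standardized-mean-difference meta-analysis across cohort summaries.

Effect sizes are Hedges' g (bias-corrected SMD) with the Hedges–Olkin
variance convention; pooling uses inverse-variance weights under a fixed-effect or a
DerSimonian–Laird random-effects model.  Heterogeneity is quantified with
Cochrane's Q and I², model choice follows the "p_Q < 0.05 or I² > 50% →
random effects" rule, and funnel-plot asymmetry is tested with Egger's
regression and Begg's rank correlation.

Conventions (recorded because they differ across software):

* g = J · (m1 − m2)/s_p with s_p the n−1-weighted pooled SD of the two arms
  and J = 1 − 3/(4(n1+n2−2) − 1);
* var(g) = J² · ((n1+n2)/(n1·n2) + d²/(2(n1+n2−2))) with d the uncorrected
  SMD — the Hedges–Olkin large-sample variance of the corrected estimator;
* DL tau² = max(0, (Q − df)/C), C = Σw − Σw²/Σw with fixed-effect weights;
* 95% CI uses the normal quantile 1.96, not a t quantile;
* Egger regresses the standardized effect g/se on precision 1/se (classic
  form), two-sided t with K−2 df on the intercept;
* Begg correlates variance-standardized deviations from the fixed-effect
  pooled value with the sampling variances, continuity-corrected normal
  approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DegenerateInputError, StudySummary

__all__ = [
    "EffectSize",
    "MetaResult",
    "BiasTestResult",
    "hedges_g",
    "pool_fixed",
    "pool_random",
    "select_model",
    "egger_test",
    "begg_test",
    "funnel_points",
    "leave_one_out",
    "forest_table",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class EffectSize:
    study_id: str
    g: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("effect-size variance must be positive")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class MetaResult:
    pooled: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: float
    df_Q: int
    p_Q: float
    I2: float
    tau2: float
    model: Literal["fixed", "random"]


@dataclass(frozen=True)
class BiasTestResult:
    method: Literal["egger", "begg"]
    statistic: float
    p: float


def hedges_g(study: StudySummary) -> EffectSize:
    """Hedges' g and its sampling variance for one two-arm cohort."""
    n1, n2 = study.case.n, study.control.n
    s1, s2 = study.case.sd, study.control.sd
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 <= 0:
        raise DegenerateInputError(f"{study.study_id}: pooled SD is zero")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = (study.case.mean - study.control.mean) / math.sqrt(sp2)
    g = j * d
    variance = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * df))
    return EffectSize(study_id=study.study_id, g=g, variance=variance)


def _heterogeneity(g: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float]:
    pooled = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - pooled) ** 2))
    df = len(g) - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, i2


def _build_result(
    pooled: float, se: float, q: float, df: int, p_q: float, i2: float,
    tau2: float, model: Literal["fixed", "random"],
) -> MetaResult:
    z = pooled / se
    return MetaResult(
        pooled=pooled,
        ci_low=pooled - _Z975 * se,
        ci_high=pooled + _Z975 * se,
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        Q=q,
        df_Q=df,
        p_Q=p_q,
        I2=i2,
        tau2=tau2,
        model=model,
    )


def pool_fixed(effects: Sequence[EffectSize]) -> MetaResult:
    """Inverse-variance fixed-effect pooled SMD with Q / I² heterogeneity."""
    if not effects:
        raise ValueError("cannot pool an empty panel")
    g = np.array([e.g for e in effects])
    w = np.array([1.0 / e.variance for e in effects])
    q, df, p_q, i2 = _heterogeneity(g, w)
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return _build_result(pooled, se, q, df, p_q, i2, 0.0, "fixed")


def pool_random(effects: Sequence[EffectSize]) -> MetaResult:
    """DerSimonian–Laird random-effects pooled SMD.

    tau² is the moment estimator max(0, (Q − df)/C); studies are re-weighted
    by 1/(variance + tau²).  A single study reduces to the fixed model.
    """
    if not effects:
        raise ValueError("cannot pool an empty panel")
    if len(effects) == 1:
        return pool_fixed(effects)
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    q, df, p_q, i2 = _heterogeneity(g, w)
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    return _build_result(pooled, se, q, df, p_q, i2, tau2, "random")


def select_model(effects: Sequence[EffectSize]) -> MetaResult:
    """Apply the heterogeneity rule: p_Q < 0.05 or I² > 50% → random effects."""
    if len(effects) < 2:
        raise ValueError("model selection needs at least 2 studies")
    fixed = pool_fixed(effects)
    if fixed.p_Q < 0.05 or fixed.I2 > 50.0:
        return pool_random(effects)
    return fixed


def egger_test(effects: Sequence[EffectSize]) -> BiasTestResult:
    """Egger's regression asymmetry test (intercept of g/se on 1/se)."""
    if len(effects) < 3:
        raise ValueError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in effects])
    y = np.array([e.g for e in effects]) / se
    x = 1.0 / se
    if np.ptp(x) == 0:
        raise DegenerateInputError("all standard errors equal: precision regressor is constant")
    res = stats.linregress(x, y)
    k = len(effects)
    t = res.intercept / res.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return BiasTestResult(method="egger", statistic=float(res.intercept), p=p)


def begg_test(effects: Sequence[EffectSize]) -> BiasTestResult:
    """Begg–Mazumdar rank-correlation asymmetry test.

    Kendall correlation between the variance-standardized deviations from
    the fixed-effect pooled estimate and the sampling variances, with the
    continuity-corrected normal approximation for the p-value.
    """
    if len(effects) < 3:
        raise ValueError("Begg's test needs at least 3 studies")
    g = np.array([e.g for e in effects])
    v = np.array([e.variance for e in effects])
    w = 1.0 / v
    pooled = float(np.sum(w * g) / np.sum(w))
    v_pooled = 1.0 / float(np.sum(w))
    t_star = (g - pooled) / np.sqrt(v - v_pooled)
    # Kendall S = concordant − discordant pairs (ties contribute 0)
    k = len(effects)
    s = 0
    for i in range(k - 1):
        s += int(np.sum(np.sign((t_star[i + 1 :] - t_star[i]) * (v[i + 1 :] - v[i]))))
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    sd_s = math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    z = max(0.0, abs(s) - 1.0) / sd_s
    p = float(2.0 * stats.norm.sf(z))
    return BiasTestResult(method="begg", statistic=float(tau), p=min(1.0, p))


def funnel_points(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Funnel-plot coordinate table (g vs se), sorted by se ascending.

    The ``pooled`` column repeats the fixed-effect reference line value so
    the table is self-contained for external plotting.
    """
    if not effects:
        raise ValueError("funnel table needs at least 1 effect")
    pooled = pool_fixed(effects).pooled
    df = pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "g": [e.g for e in effects],
            "se": [e.se for e in effects],
        }
    ).sort_values("se", kind="mergesort", ignore_index=True)
    df["pooled"] = pooled
    return df


def leave_one_out(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Sensitivity table: re-pool (model-selected) with each study removed."""
    if len(effects) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    rows = []
    for e in effects:
        rest = [x for x in effects if x.study_id != e.study_id]
        r = select_model(rest)
        rows.append(
            {
                "omitted": e.study_id,
                "pooled": r.pooled,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "I2": r.I2,
                "model": r.model,
            }
        )
    return pd.DataFrame(rows)


def forest_table(effects: Sequence[EffectSize], result: MetaResult) -> pd.DataFrame:
    """Per-study forest-plot table with the weights of the fitted model."""
    v = np.array([e.variance for e in effects])
    w = 1.0 / (v + result.tau2)
    w = 100.0 * w / w.sum()
    return pd.DataFrame(
        {
            "study_id": [e.study_id for e in effects],
            "g": [e.g for e in effects],
            "se": [e.se for e in effects],
            "ci_low": [e.g - _Z975 * e.se for e in effects],
            "ci_high": [e.g + _Z975 * e.se for e in effects],
            "weight_pct": w,
        }
    )
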