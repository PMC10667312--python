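"""Fitness estimators and the chromosome-wide deletion-association scan.

Implements the growth statistics used to phenotype SCRaMbLEd disomic
strains:

* growth recovery rate, (Si - Sr) / Sr x 100, from colony-size samples of a
  strain versus its unSCRaMbLEd disome parent;
* doubling time from an OD600 curve: log10-transform, ordinary least-squares
  slope over every 7-point sliding window, k = max slope, DT = log10(2) / k;
* retention-vs-recovery Pearson correlation and OLS fit with a pointwise 95%
  confidence band;
* a per-segment association scan comparing recovery between deletion and
  retention groups (Welch's t by default, optional permutation p), with
  Bonferroni family-wise control;
* aneuploid-chromosome stability: generations until a retaining fraction
  crosses a target, closed form and Monte Carlo.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .scramble_sim import GrowthCurve

__all__ = [
    "RecoveryRate",
    "DoublingTime",
    "RegressionResult",
    "growth_recovery_rate",
    "doubling_time",
    "retention_recovery_regression",
    "association_scan",
    "stability_generations",
    "simulate_stability",
]


@dataclass(frozen=True)
class RecoveryRate:
    """Growth recovery of a strain relative to the disome parent."""

    si_mm: float
    sr_mm: float
    value_pct: float
    n_i: int
    n_ref: int


@dataclass(frozen=True)
class DoublingTime:
    """Max sliding-window slope of log10(OD) and the implied doubling time."""

    k_per_min: float
    dt_min: float
    window_start_min: float


def growth_recovery_rate(
    colony_sizes_i: Sequence[float],
    colony_sizes_ref: Sequence[float],
    use_median: bool = False,
    min_n: int = 200,
) -> RecoveryRate:
    """Growth recovery rate (%) = (Si - Sr) / Sr x 100.

    Si and Sr are mean colony sizes (medians behind ``use_median``); a
    warning is issued below ``min_n`` colonies per sample.
    """
    xi = np.asarray(colony_sizes_i, dtype=float)
    xr = np.asarray(colony_sizes_ref, dtype=float)
    if xi.size == 0 or xr.size == 0:
        raise ValueError("colony-size samples must be nonempty")
    if xi.size < min_n or xr.size < min_n:
        warnings.warn(
            f"colony sample below {min_n} colonies (n_i={xi.size}, n_ref={xr.size})",
            stacklevel=2,
        )
    stat = np.median if use_median else np.mean
    si, sr = float(stat(xi)), float(stat(xr))
    if sr <= 0:
        raise ValueError("reference colony size must be positive")
    return RecoveryRate(si, sr, (si - sr) / sr * 100.0, xi.size, xr.size)


def doubling_time(curve: GrowthCurve, window: int = 7) -> DoublingTime:
    """Doubling time from the steepest 7-point window of log10(OD).

    The max-slope rule ignores lag and saturation phases by construction, so
    the estimate is exact on a pure exponential regardless of window
    position.
    """
    t, od = curve.times, curve.od
    if t.size < window:
        raise ValueError(f"need at least {window} readings, got {t.size}")
    y = np.log10(od)
    # closed-form OLS slope per sliding window via cumulative sums
    n = window
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    st = ct[n:] - ct[:-n]
    sy = cy[n:] - cy[:-n]
    sty = cty[n:] - cty[:-n]
    stt = ctt[n:] - ctt[:-n]
    slopes = (n * sty - st * sy) / (n * stt - st * st)
    best = int(np.argmax(slopes))
    k = float(slopes[best])
    if k <= 1e-10:  # guards exact-arithmetic noise on flat curves
        raise ValueError("no growth detected: maximal log10(OD) slope is nonpositive")
    return DoublingTime(k_per_min=k, dt_min=math.log10(2.0) / k, window_start_min=float(t[best]))


@dataclass(frozen=True)
class RegressionResult:
    """Pearson correlation plus OLS fit of recovery on retention."""

    r: float
    r_pvalue: float
    slope: float
    intercept: float
    x: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray


def retention_recovery_regression(strains: Sequence) -> RegressionResult:
    """Correlation/regression of growth recovery on chromosome retention.

    ``strains`` may be StrainRecord-like objects (with ``retained_fraction``
    and ``recovery_rate_pct``) or a pair of arrays ``(retained, recovery)``.
    The band is the pointwise 95% confidence interval of the fitted mean.
    """
    if isinstance(strains, tuple) and len(strains) == 2:
        x = np.asarray(strains[0], dtype=float)
        y = np.asarray(strains[1], dtype=float)
    else:
        x = np.array([s.retained_fraction for s in strains], dtype=float)
        y = np.array([s.recovery_rate_pct for s in strains], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 strains")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in retention or recovery")
    r, p = stats.pearsonr(x, y)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=0.05)
    order = np.argsort(x)
    return RegressionResult(
        r=float(r),
        r_pvalue=float(p),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        x=x[order],
        fitted=pred["mean"].to_numpy()[order],
        band_low=pred["mean_ci_lower"].to_numpy()[order],
        band_high=pred["mean_ci_upper"].to_numpy()[order],
    )


def association_scan(
    deletion_matrix: pd.DataFrame,
    recovery: pd.Series,
    method: str = "welch",
    n_perm: int = 0,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-segment association between deletion status and growth recovery.

    ``deletion_matrix`` is strains x segments (True = segment deleted);
    ``recovery`` is the per-strain recovery %.  Each segment with at least
    two strains in both groups gets a two-sided Welch t-test (optionally a
    seeded label-permutation p with ``n_perm`` shuffles); significance is
    Bonferroni-controlled at ``alpha`` over the tested segments.  Segments
    without contrast are returned untested with a reason.
    """
    if method not in ("welch", "permutation"):
        raise ValueError("method must be 'welch' or 'permutation'")
    idx = deletion_matrix.index
    rec = recovery.loc[idx].to_numpy(dtype=float)
    rows = []
    for seg in deletion_matrix.columns:
        mask = deletion_matrix[seg].to_numpy(dtype=bool)
        n_del, n_ret = int(mask.sum()), int((~mask).sum())
        row = {
            "segment": seg,
            "n_deleted": n_del,
            "n_retained": n_ret,
            "mean_deleted": float(rec[mask].mean()) if n_del else np.nan,
            "mean_retained": float(rec[~mask].mean()) if n_ret else np.nan,
            "stat": np.nan,
            "p": np.nan,
            "p_perm": np.nan,
            "tested": False,
            "reason": "",
        }
        if n_del == 0 or n_ret == 0:
            row["reason"] = "no contrast"
        elif n_del < 2 or n_ret < 2:
            row["reason"] = "insufficient group size"
        else:
            t, p = stats.ttest_ind(rec[mask], rec[~mask], equal_var=False)
            row.update(stat=float(t), p=float(p), tested=True)
            if n_perm > 0:
                if rng is None:
                    rng = np.random.default_rng()
                t_obs = abs(t)
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(rec)
                    tp, _ = stats.ttest_ind(perm[mask], perm[~mask], equal_var=False)
                    if abs(tp) >= t_obs:
                        hits += 1
                row["p_perm"] = (hits + 1) / (n_perm + 1)
        row["effect"] = row["mean_deleted"] - row["mean_retained"]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("segment")
    m = int(df["tested"].sum())
    if m == 0:
        raise ValueError("no testable segment: every segment lacks contrast")
    p_col = "p_perm" if (method == "permutation" and n_perm > 0) else "p"
    df["bonferroni_alpha"] = alpha / m
    df["significant"] = df["tested"] & (df[p_col] < alpha / m)
    return df


def stability_generations(p_loss_per_division: float, retained_fraction_target: float) -> float:
    """Generations until the chromosome-retaining fraction crosses a target.

    Under a constant per-division loss probability p, the retaining fraction
    after g generations is (1-p)^g, so g = ln(target) / ln(1-p).  Returns
    ``math.inf`` ("never") when p = 0.
    """
    p = p_loss_per_division
    tgt = retained_fraction_target
    if not (0 <= p < 1):
        raise ValueError("p_loss_per_division must be in [0, 1)")
    if not (0 < tgt < 1):
        raise ValueError("retained_fraction_target must be in (0, 1)")
    if p == 0:
        return math.inf
    return math.log(tgt) / math.log(1.0 - p)


def simulate_stability(
    p_loss_per_division: float,
    retained_fraction_target: float,
    n_lineages: int = 10_000,
    rng: np.random.Generator | None = None,
    max_generations: int = 100_000,
) -> float:
    """Monte Carlo companion to :func:`stability_generations`.

    Propagates ``n_lineages`` independent lineages with per-division loss and
    returns the first generation at which the retaining fraction drops below
    the target (``math.inf`` if never within ``max_generations``).
    """
    p = p_loss_per_division
    if not (0 <= p < 1):
        raise ValueError("p_loss_per_division must be in [0, 1)")
    if p == 0:
        return math.inf
    if rng is None:
        rng = np.random.default_rng()
    retaining = n_lineages
    for g in range(1, max_generations + 1):
        retaining -= rng.binomial(retaining, p)
        if retaining / n_lineages < retained_fraction_target:
            return float(g)
    return math.inf
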