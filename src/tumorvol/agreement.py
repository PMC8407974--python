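"""Method-comparison statistics: error indexes and agreement analysis.

Each formula method is compared against planimetry (the reference standard)
through four error indexes — volume difference VD (mL), percentage volume
difference PVD (%), and their absolute values AVD/APVD — plus Spearman rank
correlation, ICC(2,1) (two-way random effects, absolute agreement, single
measurement), Bland-Altman limits of agreement (mean difference +/- 1.96 SD),
the fraction of cases with APVD under clinically motivated thresholds, and the
Mann-Whitney U test for location differences between paired method outputs.

Quartiles use the linear-interpolation (type-7) percentile convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError
from .estimators import METHOD_FIELDS, METHOD_NAMES
from .records import records_to_frame

__all__ = [
    "DiffRecord",
    "AgreementReport",
    "volume_differences",
    "spearman_rs",
    "icc_2_1",
    "bland_altman",
    "diagnostic_accuracy",
    "mann_whitney_u",
    "evaluate_method",
    "subset_evaluate",
    "diameter_volume_analysis",
    "ellipsoidity_error_correlation",
]


@dataclass(frozen=True)
class DiffRecord:
    """Error indexes of one estimate against planimetry."""

    vd: float    # mL
    pvd: float   # %
    avd: float   # mL
    apvd: float  # %


@dataclass(frozen=True)
class Quartiles:
    p25: float
    median: float
    p75: float


@dataclass(frozen=True)
class AgreementReport:
    """Per-method agreement statistics against planimetry."""

    method: str
    n: int
    volume: Quartiles
    vd: Quartiles
    pvd: Quartiles
    avd: Quartiles
    apvd: Quartiles
    rs: float
    rs_ci: tuple[float, float]
    icc: float
    icc_ci: tuple[float, float]
    ba_mean: float
    ba_lower_loa: float
    ba_upper_loa: float
    n_outside_loa: int
    pct_outside_loa: float
    diag_accuracy: dict[float, float]
    subset_size: int | None = None
    subset_fraction: float | None = None

    def as_row(self) -> dict:
        row: dict = {"method": self.method, "n": self.n}
        for name in ("volume", "vd", "pvd", "avd", "apvd"):
            q: Quartiles = getattr(self, name)
            row[f"{name}_p25"] = q.p25
            row[f"{name}_median"] = q.median
            row[f"{name}_p75"] = q.p75
        row.update(
            rs=self.rs,
            rs_ci_low=self.rs_ci[0],
            rs_ci_high=self.rs_ci[1],
            icc=self.icc,
            icc_ci_low=self.icc_ci[0],
            icc_ci_high=self.icc_ci[1],
            ba_mean=self.ba_mean,
            ba_lower_loa=self.ba_lower_loa,
            ba_upper_loa=self.ba_upper_loa,
            n_outside_loa=self.n_outside_loa,
            pct_outside_loa=self.pct_outside_loa,
        )
        for t, v in self.diag_accuracy.items():
            row[f"diag_accuracy_{t:g}"] = v
        if self.subset_size is not None:
            row["subset_size"] = self.subset_size
            row["subset_fraction"] = self.subset_fraction
        return row


def volume_differences(v_est: float, v_plan: float) -> DiffRecord:
    """VD, PVD, AVD, APVD of a single estimate against planimetry."""
    if v_plan <= 0:
        raise StatisticsError(f"planimetric volume must be positive, got {v_plan}")
    vd = v_est - v_plan
    pvd = vd / v_plan * 100.0
    return DiffRecord(vd=vd, pvd=pvd, avd=abs(vd), apvd=abs(pvd))


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatisticsError("x and y must be 1D vectors of equal length")
    return x, y


def spearman_rs(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Spearman rank correlation with a Fisher-z 95% CI (SE = 1/sqrt(n-3)).

    Ties receive average ranks. Constant input has undefined rank variance and
    is rejected.
    """
    x, y = _check_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatisticsError("Spearman correlation undefined for a constant vector")
    rs = float(stats.spearmanr(x, y).statistic)
    n = len(x)
    if n < 4 or abs(rs) >= 1.0:
        return rs, rs, rs
    z = np.arctanh(rs)
    half = 1.959963984540054 / math.sqrt(n - 3)
    return rs, float(np.tanh(z - half)), float(np.tanh(z + half))


def _mean_squares(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n-subjects x 2-raters table."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_2_1(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Computed from the two-way ANOVA decomposition

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with the standard F-based 95% confidence bounds (Satterthwaite degrees of
    freedom for the mixed denominator).
    """
    x, y = _check_pair(x, y)
    if len(x) < 3:
        raise StatisticsError("ICC requires at least 3 cases")
    msr, msc, mse, n, k = _mean_squares(x, y)
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        raise StatisticsError("ICC undefined: no variance in the data")
    icc = (msr - mse) / denom
    # McGraw & Wong (1996) confidence bounds for ICC(A,1)
    alpha = 0.05
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a) or mse == 0:
        return float(icc), float(icc), float(icc)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), float(lower), float(upper)


def bland_altman(
    v_est: Sequence[float], v_plan: Sequence[float]
) -> tuple[float, float, float, int, float]:
    """Bland-Altman mean difference, 1.96-SD limits of agreement (sample SD),
    and the count / percentage of differences strictly outside the limits."""
    est, plan = _check_pair(v_est, v_plan)
    if len(est) < 2:
        raise StatisticsError("Bland-Altman needs at least 2 cases")
    d = est - plan
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.sum((d < lower) | (d > upper)))
    return mean, lower, upper, outside, 100.0 * outside / len(d)


def diagnostic_accuracy(
    apvd: Sequence[float], thresholds: Sequence[float] = (10.0, 20.0, 30.0)
) -> dict[float, float]:
    """Percentage of cases with APVD strictly below each threshold."""
    arr = np.asarray(apvd, dtype=float)
    if arr.size == 0:
        raise StatisticsError("diagnostic accuracy needs at least one case")
    if (arr < 0).any():
        raise StatisticsError("APVD values must be non-negative")
    return {float(t): 100.0 * float(np.mean(arr < t)) for t in thresholds}


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration of all C(nx+ny, nx) group assignments of the (tied)
    rank vector when nx + ny <= 16; otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatisticsError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    n = nx + ny
    if n <= 16:
        total = 0
        n_le = 0
        n_ge = 0
        offset = nx * (nx + 1) / 2
        for idx in combinations(range(n), nx):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if u <= u_obs + 1e-12:
                n_le += 1
            if u >= u_obs - 1e-12:
                n_ge += 1
        return min(1.0, 2.0 * min(n_le, n_ge) / total)
    mu = nx * ny / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    diff = u_obs - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2)
    return min(1.0, 2.0 * float(stats.norm.sf(abs(z))))


def _quartiles(values: np.ndarray) -> Quartiles:
    p25, med, p75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return Quartiles(float(p25), float(med), float(p75))


def evaluate_method(
    records,
    method: str,
    apvd_thresholds: Sequence[float] = (10.0, 20.0, 30.0),
) -> AgreementReport:
    """Full agreement analysis of one formula method against planimetry."""
    if method not in METHOD_FIELDS:
        raise StatisticsError(f"unknown method '{method}'; expected one of {METHOD_NAMES}")
    frame = records_to_frame(records)
    n = len(frame)
    if n < 4:
        raise StatisticsError(f"agreement analysis needs >= 4 cases, got {n}")
    v_est = frame[METHOD_FIELDS[method]].to_numpy(dtype=float)
    v_plan = frame["v_plan"].to_numpy(dtype=float)
    if (v_plan <= 0).any():
        raise StatisticsError("planimetric volumes must be positive")
    vd = v_est - v_plan
    pvd = vd / v_plan * 100.0
    rs, rs_lo, rs_hi = spearman_rs(v_est, v_plan)
    icc, icc_lo, icc_hi = icc_2_1(v_est, v_plan)
    ba_mean, ba_lo, ba_hi, n_out, pct_out = bland_altman(v_est, v_plan)
    diag = diagnostic_accuracy(np.abs(pvd), apvd_thresholds)
    return AgreementReport(
        method=method,
        n=n,
        volume=_quartiles(v_est),
        vd=_quartiles(vd),
        pvd=_quartiles(pvd),
        avd=_quartiles(np.abs(vd)),
        apvd=_quartiles(np.abs(pvd)),
        rs=rs,
        rs_ci=(rs_lo, rs_hi),
        icc=icc,
        icc_ci=(icc_lo, icc_hi),
        ba_mean=ba_mean,
        ba_lower_loa=ba_lo,
        ba_upper_loa=ba_hi,
        n_outside_loa=n_out,
        pct_outside_loa=pct_out,
        diag_accuracy=diag,
    )


def subset_evaluate(
    records,
    method: str,
    v_max: float,
    apvd_thresholds: Sequence[float] = (10.0, 20.0, 30.0),
) -> AgreementReport:
    """Agreement analysis restricted to cases with planimetric volume < v_max (mL)."""
    frame = records_to_frame(records)
    sub = frame[frame["v_plan"] < v_max]
    if len(sub) == 0:
        raise StatisticsError(f"no cases with planimetric volume < {v_max} mL")
    report = evaluate_method(sub, method, apvd_thresholds)
    return AgreementReport(
        **{
            **report.__dict__,
            "subset_size": len(sub),
            "subset_fraction": len(sub) / len(frame),
        }
    )


def diameter_volume_analysis(records) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Volume distribution per 1-cm maximum-diameter bin, plus the overall
    diameter-volume Spearman correlation.

    Bins are [0,1), [1,2), ... cm on the maximum tumor diameter; each bin row
    reports n, min/median/max planimetric volume and the volume range.
    """
    frame = records_to_frame(records)
    if len(frame) == 0:
        raise StatisticsError("empty cohort")
    diam = frame["max_diameter"].to_numpy(dtype=float)
    vol = frame["v_plan"].to_numpy(dtype=float)
    bins = np.floor(diam).astype(int)
    rows = []
    for b in sorted(set(bins)):
        v = vol[bins == b]
        rows.append(
            {
                "diameter_bin_cm": f"[{b},{b + 1})",
                "n": int(v.size),
                "v_plan_min": float(v.min()),
                "v_plan_median": float(np.median(v)),
                "v_plan_max": float(v.max()),
                "v_plan_range": float(v.max() - v.min()),
            }
        )
    rs = spearman_rs(diam, vol)
    return pd.DataFrame(rows), rs


def ellipsoidity_error_correlation(records, method: str) -> tuple[float, float, float]:
    """Spearman correlation between ellipsoidity and the method's APVD."""
    frame = records_to_frame(records)
    if len(frame) < 4:
        raise StatisticsError("needs >= 4 cases")
    ell = frame["ellipsoidity"].to_numpy(dtype=float)
    if np.isnan(ell).any():
        raise StatisticsError("ellipsoidity missing for some cases")
    v_est = frame[METHOD_FIELDS[method]].to_numpy(dtype=float)
    v_plan = frame["v_plan"].to_numpy(dtype=float)
    apvd = np.abs((v_est - v_plan) / v_plan * 100.0)
    return spearman_rs(ell, apvd)
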