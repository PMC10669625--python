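"""Non-compartmental analysis of breath washout curves.

Per subject: Cmax/Tmax over post-dose samples, a log-linear terminal fit from
Tmax onward (slope = elimination rate, intercept = C0 extrapolated to t = 0,
natural-log scale by default), and the linear-trapezoid AUC on a fixed
0-90 min window.  Group summaries mirror the usual kinetic-parameter table:
median [IQR] per group with Mann-Whitney p-values, slope/intercept restricted
to subjects whose terminal fit reaches R^2 > 0.8 (single-phase first-order
screening).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    IncompleteWindowError,
    InvalidInputError,
)
from .stats import mann_whitney_u

__all__ = [
    "WashoutCurve",
    "KineticParams",
    "compute_cmax_tmax",
    "fit_terminal_slope",
    "trapezoid_auc",
    "analyze_cohort",
    "summarize_kinetics",
    "R2_SCREEN",
]

#: terminal fits at or below this R^2 are excluded from slope/C0 group summaries
R2_SCREEN = 0.8


@dataclass(frozen=True)
class WashoutCurve:
    """One subject's timed breath amounts (ng per 400 mL sample)."""

    subject_id: str
    timepoints_min: tuple[float, ...]
    amounts_ng: tuple[float, ...]
    censored: tuple[bool, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, float)
        a = np.asarray(self.amounts_ng, float)
        if len(t) != len(a) or len(t) != len(self.censored):
            raise InvalidInputError(f"{self.subject_id}: ragged curve")
        if len(t) and np.any(np.diff(t) <= 0):
            raise InvalidInputError(f"{self.subject_id}: timepoints must increase")
        if np.any(a <= 0):
            raise InvalidInputError(f"{self.subject_id}: amounts must be > 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str) -> "WashoutCurve":
        sub = df[df["subject_id"] == subject_id].sort_values("timepoint_min")
        return cls(
            subject_id=subject_id,
            timepoints_min=tuple(float(x) for x in sub["timepoint_min"]),
            amounts_ng=tuple(float(x) for x in sub["limonene_ng"]),
            censored=tuple(bool(x) for x in sub["censored"]),
        )

    def post_dose(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(self.timepoints_min, float)
        a = np.asarray(self.amounts_ng, float)
        m = t > 0
        return t[m], a[m]


@dataclass(frozen=True)
class KineticParams:
    """Per-subject NCA output."""

    subject_id: str
    cmax_ng: float
    tmax_min: float
    c0_log: float          # terminal-fit intercept at t=0, natural-log scale
    slope_per_min: float   # negative for decaying curves
    r_squared: float
    auc_0_90: float        # ng*min per 400 mL; NaN when window incomplete
    n_fit_points: int

    @property
    def half_life_min(self) -> float:
        return math.log(2) / -self.slope_per_min if self.slope_per_min < 0 else math.inf


def compute_cmax_tmax(curve: WashoutCurve) -> tuple[float, float]:
    """Maximum post-dose amount and its time; ties go to the earliest time.

    The baseline (t = 0) sample never competes: it predates the dose.
    """
    t, a = curve.post_dose()
    if len(t) == 0:
        raise InsufficientDataError(f"{curve.subject_id}: no post-dose samples")
    i = int(np.argmax(a))  # argmax returns the first maximum; times ascend
    return float(a[i]), float(t[i])


def fit_terminal_slope(curve: WashoutCurve, *, log_base: float = math.e
                       ) -> tuple[float, float, float]:
    """OLS of log(amount) on time over all samples from Tmax (inclusive) on.

    Returns ``(slope_per_min, c0_log, r_squared)`` where ``c0_log`` is the
    fitted line evaluated at t = 0.  ``log_base`` defaults to natural log;
    pass 10 for a decadic fit (slope and intercept scale by 1/ln 10).
    """
    _, tmax = compute_cmax_tmax(curve)
    t, a = curve.post_dose()
    m = t >= tmax
    t, a = t[m], a[m]
    if len(t) < 3:
        raise InsufficientDataError(
            f"{curve.subject_id}: need >= 3 points from Tmax, have {len(t)}"
        )
    y = np.log(a) / math.log(log_base)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot <= 1e-300:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, float(intercept), float(r2)


def trapezoid_auc(curve: WashoutCurve, t_start: float = 0.0,
                  t_end: float = 90.0) -> float:
    """Linear-trapezoid AUC on [t_start, t_end] (ng*min per 400 mL).

    Endpoint values falling between two observations are linearly
    interpolated from their flanking samples; censored (LOQ-imputed) points
    participate at their imputed value.  Additive over sub-windows that meet
    at an observed timepoint.
    """
    if t_end <= t_start:
        raise InvalidInputError("t_end must exceed t_start")
    t = np.asarray(curve.timepoints_min, float)
    a = np.asarray(curve.amounts_ng, float)
    if len(t) == 0 or t[0] > t_start or t[-1] < t_end:
        raise IncompleteWindowError(
            f"{curve.subject_id}: observations do not span [{t_start}, {t_end}]"
        )
    inside = (t > t_start) & (t < t_end)
    knots = np.concatenate(([t_start], t[inside], [t_end]))
    values = np.interp(knots, t, a)
    return float(np.trapezoid(values, knots))


def analyze_cohort(washout: pd.DataFrame, *, t_start: float = 0.0,
                   t_end: float = 90.0) -> pd.DataFrame:
    """Run the per-subject NCA over a long washout table.

    Returns one row per subject (KineticParams columns plus group).  Subjects
    whose samples cannot cover the AUC window get ``auc_0_90 = NaN``; subjects
    with too few terminal points get NaN slope/intercept/R^2.
    """
    rows = []
    for sid, sub in washout.groupby("subject_id", sort=True):
        curve = WashoutCurve.from_frame(washout, sid)
        group = sub["group"].iloc[0]
        cmax, tmax = compute_cmax_tmax(curve)
        try:
            slope, c0, r2 = fit_terminal_slope(curve)
            t_pd, _ = curve.post_dose()
            n_fit = int(np.sum(t_pd >= tmax))
        except InsufficientDataError:
            slope = c0 = r2 = float("nan")
            n_fit = 0
        try:
            auc = trapezoid_auc(curve, t_start, t_end)
        except IncompleteWindowError:
            auc = float("nan")
        rows.append({
            "subject_id": sid, "group": group, "cmax_ng": cmax,
            "tmax_min": tmax, "c0_log": c0, "slope_per_min": slope,
            "r_squared": r2, "auc_0_90": auc, "n_fit_points": n_fit,
        })
    return pd.DataFrame(rows)


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.nanpercentile(x, [25, 50, 75])
    return f"{q2:.4g} [{q1:.4g}-{q3:.4g}]"


def summarize_kinetics(kinetics: pd.DataFrame,
                       *, r2_screen: float = R2_SCREEN) -> pd.DataFrame:
    """Kinetic-parameter table: per-group median [IQR] + Mann-Whitney p.

    Cmax and AUC use every subject; slope and C0 only subjects passing the
    R^2 screen.  A Tmax frequency block (count per sampled time) is appended.
    """
    groups = [g for g in ("control", "cirrhosis") if g in set(kinetics["group"])]
    if len(groups) < 2:
        raise InvalidInputError("need both control and cirrhosis groups")
    for g in groups:
        if (kinetics["group"] == g).sum() < 2:
            raise InvalidInputError(f"group '{g}' has fewer than 2 subjects")

    screened = kinetics[kinetics["r_squared"] > r2_screen]
    blocks = {
        "cmax_ng": kinetics, "c0_log": screened,
        "auc_0_90": kinetics, "slope_per_min": screened,
    }
    rows = []
    for param, df in blocks.items():
        by = {g: df.loc[df["group"] == g, param].dropna().to_numpy()
              for g in groups}
        if any(len(v) < 2 for v in by.values()):
            raise InvalidInputError(f"too few subjects for {param} summary")
        test = mann_whitney_u(by[groups[0]], by[groups[1]])
        rows.append({
            "parameter": param,
            groups[0]: _median_iqr(by[groups[0]]),
            groups[1]: _median_iqr(by[groups[1]]),
            "p_value": test.p_value,
        })
    for t in sorted(kinetics["tmax_min"].dropna().unique()):
        row = {"parameter": f"tmax_{int(t)}_min", "p_value": float("nan")}
        for g in groups:
            sub = kinetics[kinetics["group"] == g]
            n = int((sub["tmax_min"] == t).sum())
            row[g] = f"{n} ({100 * n / len(sub):.1f}%)"
        rows.append(row)
    return pd.DataFrame(rows)
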