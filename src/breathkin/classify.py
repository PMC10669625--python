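"""Per-timepoint diagnostic evaluation of breath levels.

For each sampling time (and for Cmax) the log-transformed breath amount is
scored with a univariable logistic model; performance is summarized as
AUROC / sensitivity / specificity averaged over repeated stratified 80/20
train-test splits (mean +/- sd), while predictive values and likelihood
ratios come from the whole-cohort confusion matrix at the full-fit Youden
threshold — the two conventions a clinical table typically mixes, reported
here side by side and labelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "ConfusionMatrix",
    "LogisticFit",
    "fit_logistic",
    "roc_curve",
    "roc_auroc",
    "youden_threshold",
    "confusion_metrics",
    "confusion_at_threshold",
    "evaluate_timepoints",
]


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise InvalidInputError("empty confusion matrix")


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Sens, spec, predictive values (%) and likelihood ratios.

    Zero denominators yield ``inf`` (positive numerator) or ``nan`` (0/0),
    both explicit in the output — callers can test with ``math.isfinite``.
    """
    def ratio(num, den):
        if den == 0:
            return math.inf if num > 0 else math.nan
        return num / den

    sens = ratio(cm.tp, cm.tp + cm.fn)
    spec = ratio(cm.tn, cm.tn + cm.fp)
    return {
        "sens": sens,
        "spec": spec,
        "ppv_pct": 100.0 * ratio(cm.tp, cm.tp + cm.fp),
        "npv_pct": 100.0 * ratio(cm.tn, cm.tn + cm.fn),
        "lr_pos": ratio(sens, 1.0 - spec) if not math.isnan(spec) else math.nan,
        "lr_neg": ratio(1.0 - sens, spec) if not math.isnan(sens) else math.nan,
    }


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionMatrix:
    """Counts for the rule `predict positive iff score >= threshold`."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pred = s >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))), fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))), tn=int(np.sum(~pred & (y == 0))),
    )


# ---------------------------------------------------------------------------
# logistic scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    coefficient: float
    converged: bool
    separated: bool
    n_iter: int

    def decision(self, x) -> np.ndarray:
        return self.intercept + self.coefficient * np.asarray(x, float)

    def predict_proba(self, x) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(x)))


GRAD_TOL = 1e-8
SEPARATION_RIDGE = 1e-4
_MAX_ITER = 100
_BETA_BLOWUP = 30.0


def _newton_logistic(x, y, ridge: float) -> tuple[np.ndarray, bool, int]:
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    pen = np.diag([0.0, ridge])  # intercept unpenalized
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - p) - pen @ beta
        if np.max(np.abs(grad)) < GRAD_TOL:
            return beta, True, it
        w = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(H, grad)
        # step halving keeps Newton on track for poorly scaled features
        for _ in range(30):
            cand = beta + step
            if np.all(np.isfinite(cand)) and np.max(np.abs(cand)) < 1e6:
                break
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_BLOWUP and ridge == 0.0:
            return beta, False, it  # likely separation; caller refits ridged
    return beta, False, _MAX_ITER


def fit_logistic(x: Sequence[float], y: Sequence[int]) -> LogisticFit:
    """Univariable logistic regression by Newton iterations.

    Maximum likelihood to gradient norm < 1e-8.  If the iterations diverge
    (complete or quasi-complete separation), the model is refitted with a
    small ridge (1e-4) on the coefficient and flagged ``separated``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, int)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length vectors")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("x must be finite")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")
    # complete separation makes the MLE diverge; detect it up front so the
    # flat-plateau "convergence" of float arithmetic cannot mask it
    x0max, x1min = x[y == 0].max(), x[y == 1].min()
    x1max, x0min = x[y == 1].max(), x[y == 0].min()
    fully_separated = (x1min > x0max) or (x1max < x0min)
    # centre x for numerical stability; un-centre the intercept afterwards
    mu = float(x.mean())
    beta, ok, it = _newton_logistic(x - mu, y, ridge=0.0)
    separated = fully_separated or not ok
    if separated:
        beta, ok, it = _newton_logistic(x - mu, y, ridge=SEPARATION_RIDGE)
        # the ridged likelihood still has an extreme but finite optimum
    return LogisticFit(
        intercept=float(beta[0] - beta[1] * mu),
        coefficient=float(beta[1]),
        converged=bool(ok),
        separated=bool(separated),
        n_iter=int(it),
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points for the rule `positive iff score >= threshold`.

    Candidate thresholds are midpoints between consecutive distinct scores,
    plus sentinels below/above every score — so with fully separated classes
    the gap midpoint is itself a candidate.  Returns a frame with columns
    threshold, sens, spec, fpr ordered from the strictest threshold down.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if s.shape != y.shape or s.ndim != 1:
        raise InvalidInputError("scores and labels must be equal-length vectors")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("both classes must be present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(uniq[-1] - uniq[0], 1.0)
    thresholds = np.concatenate(([uniq[-1] + span], mids[::-1], [uniq[0] - span]))
    rows = []
    for thr in thresholds:
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        rows.append((float(thr), tp / n1, 1.0 - fp / n0, fp / n0))
    return pd.DataFrame(rows, columns=["threshold", "sens", "spec", "fpr"])


def roc_auroc(scores, labels) -> float:
    """AUROC with ties at half credit: equals mid-rank U / (n1*n2).

    Computed from mid-ranks directly (exact, no trapezoid round-off); the
    threshold-sweep trapezoid gives the identical value by construction.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")
    from scipy.stats import rankdata
    r = rankdata(s)
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    u = float(np.sum(r[y == 1]) - n1 * (n1 + 1) / 2.0)
    return u / (n1 * n0)


def youden_threshold(roc: pd.DataFrame) -> tuple[float, float, float]:
    """Threshold maximizing J = sens + spec - 1; ties -> higher specificity.

    Returns (threshold, sens, spec) at the operating point.
    """
    if len(roc) == 0:
        raise InvalidInputError("empty ROC")
    j = roc["sens"] + roc["spec"] - 1.0
    best = j.max()
    cand = roc[np.isclose(j, best, rtol=0, atol=1e-12)]
    row = cand.sort_values(["spec", "threshold"], ascending=[False, False]).iloc[0]
    return float(row["threshold"]), float(row["sens"]), float(row["spec"])


# ---------------------------------------------------------------------------
# repeated-split evaluation
# ---------------------------------------------------------------------------

def _stratified_split(y: np.ndarray, test_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_frac * len(idx))))
        if n_test >= len(idx):
            raise InvalidInputError("class too small for stratified split")
        test_idx.append(rng.permutation(idx)[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        if len(idx) < k:
            raise InvalidInputError("class too small for k-fold split")
        for i, j in enumerate(idx):
            folds[i % k].append(int(j))
    return [np.sort(np.array(f)) for f in folds]


def _feature_table(washout: pd.DataFrame, kinetics: pd.DataFrame) -> pd.DataFrame:
    wide = washout.pivot_table(index="subject_id", columns="timepoint_min",
                               values="limonene_ng", aggfunc="first")
    wide.columns = [f"t{int(c)}" for c in wide.columns]
    feats = wide.join(kinetics.set_index("subject_id")[["cmax_ng", "group"]])
    feats = feats.rename(columns={"cmax_ng": "cmax"})
    return feats.reset_index()


def evaluate_timepoints(washout: pd.DataFrame, kinetics: pd.DataFrame, *,
                        scheme: str = "repeated-split", n_reps: int = 5,
                        test_frac: float = 0.2, seed: int = 0,
                        include_cmax: bool = True) -> pd.DataFrame:
    """Diagnostic performance of ln(breath amount) per timepoint (and Cmax).

    ``scheme`` is ``"repeated-split"`` (default: ``n_reps`` stratified
    ``test_frac`` hold-outs with test-set metric averaging) or ``"kfold"``
    (stratified ``n_reps``-fold cross-validation).  AUROC/sens/spec are
    reported as mean +/- sd over test sets; PPV/NPV/LR and the reported
    thresholds come from the whole-cohort fit at its Youden point.  All
    randomness derives from ``seed``.
    """
    if scheme not in ("repeated-split", "kfold"):
        raise InvalidInputError(f"unknown scheme '{scheme}'")
    feats = _feature_table(washout, kinetics)
    label_all = (feats["group"] == "cirrhosis").astype(int).to_numpy()
    if label_all.sum() < 5 or (1 - label_all).sum() < 5:
        raise InvalidInputError("need >= 5 subjects per class")

    feature_cols = [c for c in feats.columns if c.startswith("t") and c[1:].isdigit()]
    feature_cols.sort(key=lambda c: int(c[1:]))
    if include_cmax:
        feature_cols.append("cmax")

    master = np.random.SeedSequence(seed)
    rows = []
    for col, child in zip(feature_cols, master.spawn(len(feature_cols))):
        sub = feats[feats[col].notna()]
        x = np.log(sub[col].to_numpy(float))
        y = (sub["group"] == "cirrhosis").astype(int).to_numpy()
        if y.sum() < 5 or (1 - y).sum() < 5:
            raise InvalidInputError(f"feature {col}: class too small")
        rng = np.random.default_rng(child)
        if scheme == "repeated-split":
            splits = [_stratified_split(y, test_frac, rng) for _ in range(n_reps)]
        else:
            folds = _stratified_folds(y, n_reps, rng)
            allidx = np.arange(len(y))
            splits = [(np.setdiff1d(allidx, f), f) for f in folds]

        aurocs, senss, specs = [], [], []
        for train, test in splits:
            fit = fit_logistic(x[train], y[train])
            thr, _, _ = youden_threshold(roc_curve(fit.decision(x[train]), y[train]))
            s_test = fit.decision(x[test])
            aurocs.append(roc_auroc(s_test, y[test]))
            m = confusion_metrics(confusion_at_threshold(s_test, y[test], thr))
            senss.append(m["sens"])
            specs.append(m["spec"])

        full = fit_logistic(x, y)
        thr_full, sens_full, spec_full = youden_threshold(
            roc_curve(full.decision(x), y))
        cm = confusion_at_threshold(full.decision(x), y, thr_full)
        whole = confusion_metrics(cm)
        if full.coefficient != 0:
            thr_ln = (thr_full - full.intercept) / full.coefficient
            thr_ng = math.exp(thr_ln)
        else:
            thr_ln = thr_ng = math.nan

        rows.append({
            "feature": col, "n": int(len(y)),
            "auroc_mean": float(np.mean(aurocs)), "auroc_sd": float(np.std(aurocs, ddof=1)),
            "sens_mean": float(np.mean(senss)), "sens_sd": float(np.std(senss, ddof=1)),
            "spec_mean": float(np.mean(specs)), "spec_sd": float(np.std(specs, ddof=1)),
            "auroc_whole": roc_auroc(x, y),
            "sens_whole": whole["sens"], "spec_whole": whole["spec"],
            "ppv_pct": whole["ppv_pct"], "npv_pct": whole["npv_pct"],
            "lr_pos": whole["lr_pos"], "lr_neg": whole["lr_neg"],
            "threshold_score": float(thr_full),
            "threshold_ln_ng": float(thr_ln), "threshold_ng": float(thr_ng),
            "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
            "separated": bool(full.separated),
        })
    return pd.DataFrame(rows)
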