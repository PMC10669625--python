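"""Group-comparison and confounder machinery.

Mann-Whitney U with mid-ranks (exact enumeration p-value for small untied
samples, tie/continuity-corrected normal approximation otherwise) and a
random-intercept linear mixed model fitted by maximum likelihood with the
variance ratio profiled out, used for the longitudinal age-confounder check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InvalidInputError

__all__ = [
    "TestResult",
    "LMMResult",
    "mann_whitney_u",
    "random_intercept_lmm",
    "compare_auc_by_flag",
    "EXACT_SIZE_LIMIT",
]

#: largest n1+n2 for which the exact (enumeration) null distribution is used
EXACT_SIZE_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approx"
    n1: int
    n2: int


def mann_whitney_u(a: Sequence[float], b: Sequence[float],
                   *, exact_limit: int = EXACT_SIZE_LIMIT) -> TestResult:
    """Two-sided Mann-Whitney U test with mid-rank ties.

    The statistic is U for the first sample, so ``U(a,b) + U(b,a) = n1*n2``
    and ``U/(n1*n2)`` is the probability (with ties at half credit) that a
    random ``a`` value exceeds a random ``b`` value.  The exact permutation
    null is used when ``n1 + n2 <= exact_limit`` and there are no ties;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    use_exact = (a.size + b.size) <= exact_limit and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal-approx",
        n1=int(a.size), n2=int(b.size),
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model, profiled maximum likelihood
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LMMResult:
    """ML fit of y = X beta + b_subject + eps, b ~ N(0, var_b), eps ~ N(0, var_e)."""

    params: pd.DataFrame          # index: column names; coef, se, z, p
    var_random_intercept: float
    var_residual: float
    loglik: float
    n_obs: int
    n_groups: int
    psi: float                    # var_b / var_e at the optimum

    def fixed_effect(self, name: str) -> pd.Series:
        return self.params.loc[name]


def _profile_pieces(y, X, idx, counts, psi):
    """GLS quantities at variance ratio psi; V_i^{-1} = I - c_i J / n_i-free form."""
    c = psi / (1.0 + counts * psi)          # per group
    # group sums
    ncol = X.shape[1]
    gX = np.zeros((len(counts), ncol))
    gy = np.zeros(len(counts))
    np.add.at(gX, idx, X)
    np.add.at(gy, idx, y)
    XtX = X.T @ X - (gX * c[:, None]).T @ gX
    Xty = X.T @ y - gX.T @ (c * gy)
    yty = float(y @ y - np.sum(c * gy * gy))
    return XtX, Xty, yty


def _profile_loglik(y, X, idx, counts, log_psi):
    psi = math.exp(log_psi)
    XtX, Xty, yty = _profile_pieces(y, X, idx, counts, psi)
    beta = np.linalg.solve(XtX, Xty)
    n = len(y)
    rss = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / n
    logdet = float(np.sum(np.log1p(counts * psi)))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return ll, beta, sigma2, XtX


def _golden_max(fun, lo, hi, tol=1e-8):
    """Golden-section maximization on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def random_intercept_lmm(response: Sequence[float], design: pd.DataFrame,
                         subject_ids: Sequence) -> LMMResult:
    """Fit a random-intercept linear mixed model by profiled ML.

    ``design`` must contain an intercept column if one is wanted.  The
    variance ratio psi = var_b/var_e is profiled on the log scale by
    golden-section search (tolerance 1e-8), with beta and var_e in closed
    form at each psi; psi = 0 (plain OLS) is also considered.  Fixed-effect
    p-values are Wald z tests.
    """
    y = np.asarray(response, float)
    X = np.asarray(design, float)
    cols = list(design.columns)
    if y.ndim != 1 or X.shape[0] != len(y):
        raise InvalidInputError("response/design shape mismatch")
    codes, uniq = pd.factorize(np.asarray(subject_ids))
    if len(uniq) < 2 or len(y) < len(uniq) + 1:
        raise InvalidInputError("need >= 2 subjects with repeated observations")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # smallest |R_jj| of the QR factor points at the redundant column
        rdiag = np.abs(np.diag(np.linalg.qr(X)[1]))
        bad = cols[int(np.argmin(rdiag))]
        raise DegenerateDataError(f"design is singular; column '{bad}' is redundant")
    counts = np.bincount(codes).astype(float)

    def obj(log_psi):
        return _profile_loglik(y, X, codes, counts, log_psi)[0]

    log_psi = _golden_max(obj, -15.0, 8.0)
    ll, beta, sigma2, XtX = _profile_loglik(y, X, codes, counts, log_psi)
    # compare with the psi -> 0 boundary (ordinary least squares)
    ll0, beta0, sigma20, XtX0 = _profile_loglik(y, X, codes, counts, -60.0)
    psi = math.exp(log_psi)
    if ll0 >= ll:
        ll, beta, sigma2, XtX, psi = ll0, beta0, sigma20, XtX0, 0.0

    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    params = pd.DataFrame({"coef": beta, "se": se, "z": z, "p": p}, index=cols)
    return LMMResult(
        params=params,
        var_random_intercept=psi * sigma2,
        var_residual=sigma2,
        loglik=ll,
        n_obs=len(y),
        n_groups=len(uniq),
        psi=psi,
    )


def age_confounder_check(washout: pd.DataFrame, subjects: pd.DataFrame) -> LMMResult:
    """Longitudinal age check: ln(limonene) ~ group + age + timepoint, random
    intercept per subject.  Returns the full fit; the age row's Wald p is the
    quantity of interest."""
    df = washout.merge(subjects[["subject_id", "age", "group"]].rename(
        columns={"group": "grp"}), on="subject_id")
    df = df[df["timepoint_min"] > 0]
    design = pd.DataFrame({
        "intercept": 1.0,
        "cirrhosis": (df["grp"] == "cirrhosis").astype(float),
        "age": df["age"].astype(float),
    })
    tp_dummies = pd.get_dummies(df["timepoint_min"].astype(int),
                                prefix="t", drop_first=True).astype(float)
    design = pd.concat([design.reset_index(drop=True),
                        tp_dummies.reset_index(drop=True)], axis=1)
    return random_intercept_lmm(np.log(df["limonene_ng"].to_numpy()),
                                design, df["subject_id"].to_numpy())


def compare_auc_by_flag(kinetics: pd.DataFrame, subjects: pd.DataFrame,
                        flag: str) -> dict:
    """Mann-Whitney on AUC(0-90) within the cirrhosis group by a clinical flag.

    ``flag`` is one of the boolean subject columns (portal_htn,
    thrombocytopenia, splenomegaly).  Returns the test plus median [IQR]
    summaries for the flagged / unflagged subgroups.
    """
    if flag not in subjects.columns:
        raise InvalidInputError(f"unknown flag column '{flag}'")
    merged = kinetics.merge(subjects[["subject_id", flag]], on="subject_id")
    cirr = merged[(merged["group"] == "cirrhosis") & merged["auc_0_90"].notna()]
    pos = cirr.loc[cirr[flag].astype(bool), "auc_0_90"].to_numpy()
    neg = cirr.loc[~cirr[flag].astype(bool), "auc_0_90"].to_numpy()
    if len(pos) == 0 or len(neg) == 0:
        raise InvalidInputError(f"flag '{flag}' has a single level in cirrhosis")
    test = mann_whitney_u(pos, neg)

    def s(x):
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
        return {"n": int(len(x)), "median": float(q2), "iqr": [float(q1), float(q3)]}

    return {"flag": flag, "test": test, "with_flag": s(pos), "without_flag": s(neg)}
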