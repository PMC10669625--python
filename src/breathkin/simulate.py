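"""Synthetic breath-washout cohorts with a flow-limited first-pass structure.

The generator emulates a dynamic breath-test study: subjects ingest a fixed
oral dose of a high-hepatic-extraction volatile probe (limonene), and the
amount exhaled per standardized breath sample is followed over two hours.
Systemic availability of such a compound is governed by hepatic first pass:

    F_sys = F_abs * (shunt + (1 - shunt) * (1 - E)),   E = Cl_int / (Q + Cl_int)

(well-stirred liver; ``cl_int_rel`` below is Cl_int/Q).  Cirrhosis raises
F_sys through portosystemic shunting and reduced intrinsic clearance while
leaving the elimination rate essentially unchanged — so simulated groups
differ in level (Cmax, intercept, AUC) but not slope, which is exactly the
pattern the downstream analysis stages are built to detect.

Breath amount per sample follows a one-compartment oral-dose (Bateman) curve
scaled by a single dimensionless blood-to-breath constant; a dietary baseline
(itself subject to first pass) rides on top, values below the limit of
quantification are imputed at the limit, and multiplicative log-normal noise
models sampling + assay variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidInputError

__all__ = [
    "LogNormal",
    "Beta",
    "Fixed",
    "ScoreCoupling",
    "SimConfig",
    "bateman_amount",
    "systemic_availability",
    "apply_loq",
    "simulate_cohort",
]

#: relative tolerance below which |ka - ke| is treated as the ka == ke limit
KA_KE_REL_TOL = 1e-8


# ---------------------------------------------------------------------------
# distribution specs (kept tiny and explicit so configs serialize to YAML)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogNormal:
    """Log-normal specified by its median and the SD of the natural log."""

    median: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma_log < 0:
            raise InvalidParameterError(
                f"LogNormal requires median > 0 and sigma_log >= 0, "
                f"got {self.median}, {self.sigma_log}"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))


@dataclass(frozen=True)
class Beta:
    """Beta(a, b) scaled to [0, scale]; used for shunt fractions."""

    a: float
    b: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or not (0 < self.scale <= 1):
            raise InvalidParameterError(f"bad Beta spec: {self}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.scale * rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class Fixed:
    """Degenerate distribution (every subject gets the same value)."""

    value: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, float(self.value))


def _median_of(dist) -> float:
    if isinstance(dist, LogNormal):
        return dist.median
    if isinstance(dist, Fixed):
        return dist.value
    if isinstance(dist, Beta):
        # median of a scaled Beta; Wilson-Hilferty style approximation is
        # plenty here (used only to centre derived couplings)
        return dist.scale * (dist.a - 1 / 3) / (dist.a + dist.b - 2 / 3) if dist.a > 1 / 3 else dist.scale * dist.a / (dist.a + dist.b)
    raise InvalidParameterError(f"unknown distribution spec {dist!r}")


@dataclass(frozen=True)
class ScoreCoupling:
    """Linear link from ln(AUC) to a clinical score in the diseased group.

    score = intercept + slope * (ln AUC - centre) + N(0, noise_sd), clipped at
    ``floor``.  ``slope`` and ``noise_sd`` jointly set how strongly the score
    tracks bioavailability (hence its canonical loading downstream).
    """

    slope: float
    noise_sd: float
    intercept: float
    floor: float = 0.0


def _default_score_coupling() -> Mapping[str, ScoreCoupling]:
    # loadings should come out ordered MELD > FIB4 > APRI
    return {
        "meld": ScoreCoupling(slope=4.0, noise_sd=1.1, intercept=10.5, floor=6.0),
        "fib4": ScoreCoupling(slope=1.0, noise_sd=0.8, intercept=2.6, floor=0.2),
        "apri": ScoreCoupling(slope=0.15, noise_sd=0.22, intercept=0.65, floor=0.05),
    }


def _default_control_scores() -> Mapping[str, tuple[float, float, float]]:
    # (mean, sd, floor) for controls: independent of bioavailability by design,
    # so the block correlation is null in the control group
    return {
        "meld": (7.0, 1.0, 6.0),
        "fib4": (1.6, 0.8, 0.2),
        "apri": (0.25, 0.12, 0.05),
    }


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulated breath-test cohort.

    Defaults are calibrated to the study conditions the analysis stages
    expect: 29 subjects per group, a 100 mg (1e8 ng) oral dose, sampling at
    0/20/40/60/90/120 min, control median Cmax near 600 ng per 400 mL sample
    with a roughly four-fold elevation in cirrhosis, identical elimination-
    rate distributions across groups, and LOQ-censored baselines at 1.18 ng.
    """

    n_control: int = 29
    n_cirrhosis: int = 29
    dose_ng: float = 1e8  # 100 mg
    timepoints_min: tuple[int, ...] = (0, 20, 40, 60, 90, 120)
    ka_per_min: LogNormal = LogNormal(0.16, 0.35)
    ke_per_min: LogNormal = LogNormal(0.026, 0.15)
    f_abs: float = 1.0
    cl_int_rel: Mapping[str, object] = field(
        default_factory=lambda: {"control": LogNormal(19.0, 0.55),
                                 "cirrhosis": LogNormal(8.0, 0.50)}
    )
    shunt_fraction: Mapping[str, object] = field(
        default_factory=lambda: {"control": Fixed(0.0),
                                 "cirrhosis": Beta(2.0, 12.0)}
    )
    breath_scale: float = 2.0e-4
    baseline_ng: Mapping[str, object] = field(
        default_factory=lambda: {"control": LogNormal(2.0, 0.5),
                                 "cirrhosis": LogNormal(4.5, 0.5)}
    )
    loq_ng: float = 1.18
    noise_cv: float = 0.25
    score_coupling: Mapping[str, ScoreCoupling] = field(default_factory=_default_score_coupling)
    missing_rate: float = 0.02
    portal_htn_shunt_threshold: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_control < 2 or self.n_cirrhosis < 2:
            raise InvalidParameterError("group sizes must be >= 2")
        if self.dose_ng <= 0 or self.breath_scale <= 0:
            raise InvalidParameterError("dose_ng and breath_scale must be > 0")
        tps = tuple(self.timepoints_min)
        if len(tps) < 2 or tps[0] != 0 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise InvalidParameterError(
                "timepoints_min must be strictly increasing and start at 0"
            )
        if self.loq_ng <= 0:
            raise InvalidParameterError("loq_ng must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise InvalidParameterError("missing_rate must lie in [0, 1)")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        if not 0 <= self.f_abs <= 1:
            raise InvalidParameterError("f_abs must lie in [0, 1]")
        for name in ("cl_int_rel", "shunt_fraction", "baseline_ng"):
            spec = getattr(self, name)
            for grp in ("control", "cirrhosis"):
                if grp not in spec:
                    raise InvalidParameterError(f"{name} needs a '{grp}' entry")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# mechanistic primitives
# ---------------------------------------------------------------------------

def bateman_amount(t, dose: float, f_sys: float, ka: float, ke: float,
                   scale: float):
    """Breath amount (ng/sample) at time ``t`` after an oral dose.

    One-compartment first-order absorption/elimination (Bateman) solution,
    scaled by systemic availability and the blood-to-breath constant:

        A(t) = scale * f_sys * dose * ka/(ka-ke) * (exp(-ke t) - exp(-ka t))

    with the L'Hopital limit ``scale*f_sys*dose*ka*t*exp(-ka t)`` when
    |ka - ke| <= KA_KE_REL_TOL * max(ka, ke).  Vectorized over ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    if ka <= 0 or ke <= 0:
        raise InvalidParameterError("ka and ke must be > 0")
    if dose < 0 or scale < 0 or not 0 <= f_sys <= 1:
        raise InvalidParameterError("dose, scale >= 0 and f_sys in [0, 1] required")
    amp = scale * f_sys * dose
    if abs(ka - ke) <= KA_KE_REL_TOL * max(ka, ke):
        out = amp * ka * t * np.exp(-ka * t)
    else:
        out = amp * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    out = np.maximum(out, 0.0)  # guard tiny negative round-off
    return float(out) if out.ndim == 0 else out


def bateman_tpeak(ka: float, ke: float) -> float:
    """Continuous-time peak of the Bateman curve, ln(ka/ke)/(ka-ke)."""
    if ka <= 0 or ke <= 0:
        raise InvalidParameterError("ka and ke must be > 0")
    if abs(ka - ke) <= KA_KE_REL_TOL * max(ka, ke):
        return 1.0 / ka
    return math.log(ka / ke) / (ka - ke)


def bateman_auc(t_end: float, dose: float, f_sys: float, ka: float, ke: float,
                scale: float) -> float:
    """Exact integral of the Bateman curve on [0, t_end] (ng*min/sample)."""
    if t_end < 0:
        raise InvalidParameterError("t_end must be >= 0")
    if ka <= 0 or ke <= 0:
        raise InvalidParameterError("ka and ke must be > 0")
    amp = scale * f_sys * dose
    if abs(ka - ke) <= KA_KE_REL_TOL * max(ka, ke):
        # int ka t e^{-ka t} = (1 - (1+ka t)e^{-ka t})/ka
        return amp * (1.0 - (1.0 + ka * t_end) * math.exp(-ka * t_end)) / ka
    term = (1.0 - math.exp(-ke * t_end)) / ke - (1.0 - math.exp(-ka * t_end)) / ka
    return amp * ka / (ka - ke) * term


def systemic_availability(f_abs: float, cl_int_rel: float, shunt: float) -> float:
    """Fraction of an oral dose reaching systemic circulation.

    Well-stirred hepatic model: extraction E = cl_int_rel/(1+cl_int_rel) where
    ``cl_int_rel`` is intrinsic clearance relative to hepatic blood flow; a
    portosystemic ``shunt`` fraction bypasses the liver entirely.
    """
    if not 0 <= f_abs <= 1 or not 0 <= shunt <= 1:
        raise InvalidParameterError("f_abs and shunt must lie in [0, 1]")
    if cl_int_rel < 0:
        raise InvalidParameterError("cl_int_rel must be >= 0")
    extraction = cl_int_rel / (1.0 + cl_int_rel)
    return f_abs * (shunt + (1.0 - shunt) * (1.0 - extraction))


def apply_loq(value, loq: float):
    """Impute values below the limit of quantification at the limit.

    Returns ``(amount, censored)``; censored is True where imputation
    happened.  Vectorized over ``value``.
    """
    if loq <= 0:
        raise InvalidParameterError("loq must be > 0")
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("amounts must be >= 0")
    censored = arr < loq
    out = np.where(censored, loq, arr)
    if out.ndim == 0:
        return float(out), bool(censored)
    return out, censored


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_group_pk(cfg: SimConfig, group: str, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    ka = cfg.ka_per_min.sample(rng, n)
    ke = cfg.ke_per_min.sample(rng, n)
    cl = cfg.cl_int_rel[group].sample(rng, n)
    shunt = np.clip(cfg.shunt_fraction[group].sample(rng, n), 0.0, 1.0)
    f_sys = np.array([systemic_availability(cfg.f_abs, c, s)
                      for c, s in zip(cl, shunt)])
    b0 = cfg.baseline_ng[group].sample(rng, n)
    # baseline limonene is dietary and passes the same liver: couple it to the
    # subject's availability relative to the group-typical availability, so the
    # configured distribution stays the group marginal
    ref = systemic_availability(cfg.f_abs, _median_of(cfg.cl_int_rel[group]),
                                _median_of(cfg.shunt_fraction[group]))
    baseline = b0 * f_sys / ref
    return pd.DataFrame({
        "group": group, "ka": ka, "ke": ke, "cl_int_rel": cl,
        "shunt": shunt, "f_sys": f_sys, "baseline": baseline,
    })


def _clinical_metadata(cfg: SimConfig, pk: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Ages, labs, severity scores and portal-hypertension proxies.

    Marginals follow typical earlier-stage cirrhosis cohorts (controls
    younger, normal platelets; patients with moderately raised transaminases
    and a MELD median near 10).  In the cirrhosis group MELD/FIB4/APRI are
    linearly coupled to ln(noiseless AUC 0-90); control scores are drawn
    independently of kinetics so the block correlation is null there.
    """
    n = len(pk)
    is_cirr = (pk["group"] == "cirrhosis").to_numpy()
    out = pd.DataFrame(index=pk.index)

    age = np.where(is_cirr, 59 + 9 * rng.standard_normal(n),
                   46 + 12 * rng.standard_normal(n))
    out["age"] = np.clip(np.round(age), 18, 85).astype(int)
    out["sex"] = np.where(rng.random(n) < np.where(is_cirr, 0.69, 0.62), "f", "m")

    out["ast"] = np.round(np.where(is_cirr, 35.0, 21.0)
                          * np.exp(0.35 * rng.standard_normal(n)), 1)
    out["alt"] = np.round(np.where(is_cirr, 28.0, 18.0)
                          * np.exp(0.35 * rng.standard_normal(n)), 1)

    # platelets fall and the spleen grows with shunting (portal hypertension)
    shunt = pk["shunt"].to_numpy()
    ln_plt = np.where(is_cirr,
                      np.log(150.0) - 2.2 * (shunt - 0.14),
                      np.log(240.0)) + 0.25 * rng.standard_normal(n)
    out["platelets"] = np.round(np.exp(ln_plt), 1)
    spleen = np.where(is_cirr, 10.5 + 12.0 * shunt, 10.2) + 1.1 * rng.standard_normal(n)
    out["spleen_cm"] = np.round(spleen, 1)

    # flags: thrombocytopenia/splenomegaly are deterministic in the generated
    # covariates; the ultrasound portal-hypertension call tracks the shunt
    out["portal_htn"] = is_cirr & (shunt > cfg.portal_htn_shunt_threshold)
    out["thrombocytopenia"] = out["platelets"] < 150.0
    out["splenomegaly"] = out["spleen_cm"] > 12.0

    # severity scores
    ln_auc = np.log(pk["true_auc_0_90"].to_numpy())
    centre = float(np.median(ln_auc[is_cirr])) if is_cirr.any() else 0.0
    ctrl_marg = _default_control_scores()
    for name, cp in cfg.score_coupling.items():
        cirr_val = cp.intercept + cp.slope * (ln_auc - centre) \
            + cp.noise_sd * rng.standard_normal(n)
        mean, sd, _ = ctrl_marg.get(name, (cp.intercept, cp.noise_sd, cp.floor))
        ctrl_val = mean + sd * rng.standard_normal(n)
        out[name] = np.round(
            np.maximum(np.where(is_cirr, cirr_val, ctrl_val), cp.floor), 2)

    cp_class = np.where(is_cirr,
                        rng.choice(["A", "B", "unknown"], size=n, p=[0.78, 0.16, 0.06]),
                        "unknown")
    out["child_pugh"] = np.where(is_cirr, cp_class, "unknown")
    return out


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: per-subject metadata plus long washout table.

    Returns ``(subjects, washout)``.  ``subjects`` has one row per subject
    (id, group, demographics, labs, scores, flags plus the latent PK truth as
    ``true_*`` columns, handy for parameter-recovery tests).  ``washout`` is
    long format: subject_id, group, timepoint_min, limonene_ng, censored.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = []
    for group, n in (("control", config.n_control), ("cirrhosis", config.n_cirrhosis)):
        groups.append(_sample_group_pk(config, group, n, rng))
    pk = pd.concat(groups, ignore_index=True)
    pk["subject_id"] = [f"S{i:04d}" for i in range(1, len(pk) + 1)]

    # noiseless bioavailability proxy used to couple severity scores
    pk["true_auc_0_90"] = [
        bateman_auc(90.0, config.dose_ng, r.f_sys, r.ka, r.ke, config.breath_scale)
        + 90.0 * r.baseline
        for r in pk.itertuples()
    ]

    meta = _clinical_metadata(config, pk, rng)
    subjects = pd.concat([pk[["subject_id", "group"]], meta], axis=1)
    for col in ("ka", "ke", "cl_int_rel", "shunt", "f_sys", "baseline",
                "true_auc_0_90"):
        subjects[f"true_{col}" if not col.startswith("true_") else col] = pk[col]

    tps = np.asarray(config.timepoints_min, dtype=float)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv ** 2))
    rows = []
    for r in pk.itertuples():
        signal = bateman_amount(tps, config.dose_ng, r.f_sys, r.ka, r.ke,
                                config.breath_scale) + r.baseline
        signal[0] = r.baseline  # t=0: baseline only
        noise = np.exp(sigma * rng.standard_normal(len(tps)) - 0.5 * sigma ** 2)
        noise[0] = 1.0  # the baseline draw already carries its variability
        amount, censored = apply_loq(signal * noise, config.loq_ng)
        keep = rng.random(len(tps)) >= config.missing_rate
        for t, a, c, k in zip(tps, amount, censored, keep):
            if k:
                rows.append((r.subject_id, r.group, int(t), float(a), bool(c)))

    washout = pd.DataFrame(
        rows, columns=["subject_id", "group", "timepoint_min", "limonene_ng", "censored"]
    )
    return subjects, washout
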