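"""Joint-model likelihood: sub-model predictors, conditional and marginal
log-likelihood, quasi-Monte-Carlo integration and a Gauss-Hermite reference.

The model links four outcomes per subject i through a shared random-intercept
vector b_i = (b1, b2, b3):

* log ALT:        y_1(t) = x(t)'beta_1 + b1 + eps_1,   eps_1 ~ N(0, sigma_1^2)
* log bilirubin:  y_2(t) = x(t)'beta_2 + b2 + eps_2,   eps_2 ~ N(0, sigma_2^2)
* conmed count:   C_cm ~ Poisson(T * exp(x'beta_cm + b3))
* AE count:       C_ae ~ Poisson(T * exp(x'beta_ae + assoc))

with the association term either pure random-effects
(``m7``: alpha1*b1 + alpha2*b2 + alpha3*b3) or the mixed current-value form
(``m9``: alpha1*mu_1(t*) + alpha2*mu_2(t*) + alpha3*b3, where mu_k(t*) is the
expected current value of outcome k at the evaluation day t*, by default the
subject's end of follow-up).  T is the subject's follow-up in days, entering
both count sub-models as an exposure offset.

The marginal likelihood integrates b_i out of the product of conditional
densities.  Integration is by randomized quasi-Monte Carlo: a 3-dimensional
Halton sequence (bases 2, 3, 5; first 20 points dropped) with a per-subject
Cranley-Patterson shift keyed by (seed, canonical subject rank), mapped
through the Gaussian (or variance-standardized Student-t) quantile function.
Identical (seed, draws) give bit-identical log-likelihoods, and permuting
subject rows does not change the result.  A tensor-product Gauss-Hermite
integrator over the three dimensions serves as the small-problem reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, ndtri
from scipy.stats import qmc, t as student_t

from .design import (SplineSpec, COUNT_COLUMNS, build_count_design,
                     build_longitudinal_design, count_design_matrix,
                     longitudinal_columns, longitudinal_design_matrix)
from .trial_data import ANALYTES, TrialData, aggregate_counts

# exp() argument cap: keeps the Poisson mean finite during wild optimizer steps
_EXP_CAP = 500.0


@dataclass(frozen=True)
class RandomEffects:
    """A realized shared random-intercept triple."""

    b01: float  # log-ALT intercept
    b02: float  # log-bilirubin intercept
    b03: float  # log conmed-rate intercept

    def as_array(self) -> np.ndarray:
        a = np.array([self.b01, self.b02, self.b03], dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError("random effects must be finite")
        return a


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Distribution of the shared random intercepts (diagonal covariance)."""

    sds: tuple = (0.1, 0.1, 0.1)
    distribution: str = "gaussian"  # or "student_t"
    t_df: float = 5.0

    def __post_init__(self):
        if len(self.sds) != 3 or any(s < 0 for s in self.sds):
            raise ValueError("sds must be three non-negative values")
        if self.distribution not in ("gaussian", "student_t"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "student_t" and self.t_df <= 2:
            raise ValueError("student_t requires t_df > 2 (finite variance)")


@dataclass(frozen=True)
class AssociationSpec:
    """Which structure links the sub-models, and its coefficients.

    ``random_effects_m7`` loads all three random intercepts into the AE
    predictor; ``mixed_current_value_m9`` loads the expected current values of
    the two lab outcomes plus the conmed random intercept.
    """

    structure: str = "mixed_current_value_m9"
    alpha1: float = 0.0  # per unit log ALT (m9) or per unit b1 (m7)
    alpha2: float = 0.0  # per unit log bilirubin (m9) or per unit b2 (m7)
    alpha3: float = 0.0  # per unit b3 (conmed intercept) in both structures

    def __post_init__(self):
        if self.structure not in ("random_effects_m7", "mixed_current_value_m9"):
            raise ValueError(f"unknown association structure {self.structure!r}")


@dataclass
class JointModelParams:
    """Complete parameter set theta of the joint model."""

    beta_alt: np.ndarray
    beta_bili: np.ndarray
    sigma_eps_alt: float
    sigma_eps_bili: float
    beta_conmed: np.ndarray
    beta_ae: np.ndarray
    association: AssociationSpec = AssociationSpec()
    random_effects: RandomEffectsSpec = RandomEffectsSpec()
    spline: SplineSpec = SplineSpec()

    def __post_init__(self):
        self.beta_alt = np.asarray(self.beta_alt, dtype=float)
        self.beta_bili = np.asarray(self.beta_bili, dtype=float)
        self.beta_conmed = np.asarray(self.beta_conmed, dtype=float)
        self.beta_ae = np.asarray(self.beta_ae, dtype=float)
        p_long = len(longitudinal_columns(self.spline))
        if len(self.beta_alt) != p_long or len(self.beta_bili) != p_long:
            raise ValueError(
                f"longitudinal beta length must be {p_long} for this spline")
        if len(self.beta_conmed) != len(COUNT_COLUMNS) \
                or len(self.beta_ae) != len(COUNT_COLUMNS):
            raise ValueError(
                f"count beta length must be {len(COUNT_COLUMNS)}")
        if self.sigma_eps_alt <= 0 or self.sigma_eps_bili <= 0:
            raise ValueError("residual SDs must be strictly positive")


@dataclass(frozen=True)
class IntegrationSettings:
    """How the random effects are integrated out of the likelihood."""

    method: str = "halton_qmc"  # or "gauss_hermite"
    draws: int = 500            # QMC draws, or Gauss-Hermite nodes per dim
    seed: int = 0
    antithetic: bool = False

    def __post_init__(self):
        if self.method not in ("halton_qmc", "gauss_hermite"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if self.method == "gauss_hermite" and self.draws < 3:
            raise ValueError("Gauss-Hermite needs >= 3 nodes per dimension")


# ---------------------------------------------------------------------------
# single-subject API

def longitudinal_mean(params: JointModelParams, subject, day: float,
                      analyte: str, b: RandomEffects) -> float:
    """Expected log lab value mu_k(day) for one subject.

    This is the quantity the mixed current-value association loads into the
    AE sub-model.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}")
    x = build_longitudinal_design(subject, day, params.spline)
    if analyte == "alt":
        return float(x @ params.beta_alt + b.b01)
    return float(x @ params.beta_bili + b.b02)


def count_log_rate(params: JointModelParams, subject, b: RandomEffects,
                   outcome: str, day_eval: Optional[float] = None) -> float:
    """Conditional log event rate (per day of follow-up) for one subject."""
    if outcome not in ("ae", "conmed"):
        raise ValueError(f"unknown outcome {outcome!r}")
    x = build_count_design(subject)
    if outcome == "conmed":
        return float(x @ params.beta_conmed + b.b03)
    assoc = params.association
    if assoc.structure == "random_effects_m7":
        link = assoc.alpha1 * b.b01 + assoc.alpha2 * b.b02
    else:
        if day_eval is None:
            raise ValueError(
                "mixed_current_value_m9 needs day_eval for the AE sub-model")
        link = (assoc.alpha1 * longitudinal_mean(params, subject, day_eval,
                                                 "alt", b)
                + assoc.alpha2 * longitudinal_mean(params, subject, day_eval,
                                                   "bilirubin", b))
    return float(x @ params.beta_ae + link + assoc.alpha3 * b.b03)


@dataclass
class SubjectBlock:
    """One subject's data: lab records plus both event counts."""

    subject: object               # row with arm/age/trimester/followup fields
    labs: pd.DataFrame            # columns analyte, day, log_value (may be empty)
    ae_count: Optional[int] = None
    conmed_count: Optional[int] = None
    day_eval: Optional[float] = None


def subject_block(trial_data: TrialData, subject_id,
                  medication_filter: Optional[str] = None) -> SubjectBlock:
    """Assemble the per-subject block used by ``conditional_loglik``."""
    row = trial_data.subjects.set_index("subject_id").loc[subject_id]
    row = row.copy()
    row["subject_id"] = subject_id
    counts = aggregate_counts(trial_data, medication_filter)
    counts = counts[counts["subject_id"] == subject_id].set_index("outcome")
    labs = trial_data.labs[trial_data.labs["subject_id"] == subject_id]
    return SubjectBlock(subject=row, labs=labs,
                        ae_count=int(counts.loc["ae", "count"]),
                        conmed_count=int(counts.loc["conmed", "count"]),
                        day_eval=float(row["followup_days"]))


def _poisson_logpmf(count: float, log_mean: np.ndarray) -> np.ndarray:
    if count != int(count) or count < 0:
        raise ValueError(f"event count must be a non-negative integer, "
                         f"got {count}")
    log_mean = np.minimum(log_mean, _EXP_CAP)
    return count * log_mean - np.exp(log_mean) - gammaln(count + 1)


def conditional_loglik(params: JointModelParams, block: SubjectBlock,
                       b: RandomEffects) -> float:
    """Log density of one subject's data given its random effects.

    Gaussian log-densities of the log lab values plus Poisson log-pmfs of the
    two counts with mean T * exp(log-rate).  An empty block contributes 0;
    subjects without lab records contribute count terms only.
    """
    total = 0.0
    for _, rec in block.labs.iterrows():
        mu = longitudinal_mean(params, block.subject, rec["day"],
                               rec["analyte"], b)
        sd = (params.sigma_eps_alt if rec["analyte"] == "alt"
              else params.sigma_eps_bili)
        z = (rec["log_value"] - mu) / sd
        total += -0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * z * z
    for outcome, count in (("ae", block.ae_count),
                           ("conmed", block.conmed_count)):
        if count is None:
            continue
        T = float(block.subject.followup_days)
        eta = count_log_rate(params, block.subject, b, outcome,
                             day_eval=block.day_eval)
        total += float(_poisson_logpmf(count, np.log(T) + eta))
    return float(total)


# ---------------------------------------------------------------------------
# vectorized likelihood machinery

@dataclass
class PreparedData:
    """Design matrices and count arrays in canonical subject order."""

    n: int
    subject_ids: np.ndarray          # sorted
    T: np.ndarray                    # (n,) exposure days
    C_ae: np.ndarray                 # (n,)
    C_cm: np.ndarray                 # (n,)
    X_count: np.ndarray              # (n, p_count)
    lab_idx: dict                    # analyte -> (m,) subject index
    lab_X: dict                      # analyte -> (m, p_long)
    lab_y: dict                      # analyte -> (m,)
    X_cv: dict                       # analyte -> (n, p_long) at day_eval
    spline: SplineSpec
    n_lab_records: int
    include_counts: bool = True


def prepare_likelihood(trial_data: TrialData,
                       spline: SplineSpec = SplineSpec(),
                       day_eval: Union[str, float] = "followup",
                       medication_filter: Optional[str] = None,
                       include_counts: bool = True) -> PreparedData:
    """Precompute everything the likelihood needs, keyed by sorted subject id."""
    subs = trial_data.subjects.sort_values("subject_id").reset_index(drop=True)
    ids = subs["subject_id"].to_numpy()
    rank = {sid: i for i, sid in enumerate(ids)}
    counts = aggregate_counts(trial_data, medication_filter)
    counts = counts.pivot(index="subject_id", columns="outcome",
                          values="count").loc[ids]
    T = subs["followup_days"].to_numpy(dtype=float)
    X_count = count_design_matrix(subs)
    subs_ix = subs.set_index("subject_id")

    lab_idx, lab_X, lab_y = {}, {}, {}
    for analyte in ANALYTES:
        rec = trial_data.labs[trial_data.labs["analyte"] == analyte]
        lab_idx[analyte] = np.array([rank[s] for s in rec["subject_id"]],
                                    dtype=int)
        lab_X[analyte] = longitudinal_design_matrix(
            subs_ix, rec["subject_id"], rec["day"].to_numpy(), spline)
        lab_y[analyte] = rec["log_value"].to_numpy(dtype=float)

    eval_days = T if day_eval == "followup" \
        else np.full(len(ids), float(day_eval))
    X_cv = {a: longitudinal_design_matrix(subs_ix, ids, eval_days, spline)
            for a in ANALYTES}

    return PreparedData(n=len(ids), subject_ids=ids, T=T,
                        C_ae=counts["ae"].to_numpy(dtype=float),
                        C_cm=counts["conmed"].to_numpy(dtype=float),
                        X_count=X_count, lab_idx=lab_idx, lab_X=lab_X,
                        lab_y=lab_y, X_cv=X_cv, spline=spline,
                        n_lab_records=len(trial_data.labs),
                        include_counts=include_counts)


def standardized_draws(settings: IntegrationSettings, n_subjects: int,
                       re_spec: RandomEffectsSpec) -> np.ndarray:
    """Unit-variance QMC draws of the random effects, shape (n, draws, 3).

    Halton points (bases 2, 3, 5; first 20 dropped) with a per-subject
    Cranley-Patterson shift keyed by (seed, subject rank), pushed through the
    Gaussian or variance-standardized Student-t quantile function.  With
    ``antithetic`` the second half of the draws mirrors the first.
    """
    D = settings.draws
    n_base = (D + 1) // 2 if settings.antithetic else D
    base = qmc.Halton(d=3, scramble=False).random(20 + n_base)[20:]
    shifts = np.stack([np.random.default_rng([settings.seed, i]).random(3)
                       for i in range(n_subjects)])
    u = (base[None, :, :] + shifts[:, None, :]) % 1.0
    if settings.antithetic:
        u = np.concatenate([u, 1.0 - u], axis=1)[:, :D, :]
    u = np.clip(u, 1e-12, 1 - 1e-12)
    if re_spec.distribution == "gaussian":
        return ndtri(u)
    df = re_spec.t_df
    return student_t.ppf(u, df) * np.sqrt((df - 2.0) / df)


def _conditional_loglik_matrix(params: JointModelParams, data: PreparedData,
                               b: np.ndarray) -> np.ndarray:
    """Conditional log-likelihood for every (subject, draw), shape (n, D)."""
    n, D = b.shape[0], b.shape[1]
    total = np.zeros((n, D))

    for dim, analyte in enumerate(ANALYTES):
        beta = params.beta_alt if analyte == "alt" else params.beta_bili
        sd = params.sigma_eps_alt if analyte == "alt" \
            else params.sigma_eps_bili
        idx = data.lab_idx[analyte]
        r = data.lab_y[analyte] - data.lab_X[analyte] @ beta
        m_i = np.bincount(idx, minlength=n).astype(float)
        s1 = np.bincount(idx, weights=r, minlength=n)
        s2 = np.bincount(idx, weights=r * r, minlength=n)
        bi = b[:, :, dim]
        ss = s2[:, None] - 2.0 * bi * s1[:, None] + m_i[:, None] * bi ** 2
        total += (-0.5 * m_i[:, None] * np.log(2 * np.pi * sd ** 2)
                  - ss / (2.0 * sd ** 2))

    if not data.include_counts:
        return total

    logT = np.log(data.T)[:, None]
    eta_cm = (data.X_count @ params.beta_conmed)[:, None] + b[:, :, 2]
    total += _poisson_logpmf_vec(data.C_cm, logT + eta_cm)

    assoc = params.association
    if assoc.structure == "random_effects_m7":
        link = (assoc.alpha1 * b[:, :, 0] + assoc.alpha2 * b[:, :, 1])
    else:
        c1 = (data.X_cv["alt"] @ params.beta_alt)[:, None]
        c2 = (data.X_cv["bilirubin"] @ params.beta_bili)[:, None]
        link = (assoc.alpha1 * (c1 + b[:, :, 0])
                + assoc.alpha2 * (c2 + b[:, :, 1]))
    eta_ae = ((data.X_count @ params.beta_ae)[:, None] + link
              + assoc.alpha3 * b[:, :, 2])
    total += _poisson_logpmf_vec(data.C_ae, logT + eta_ae)
    return total


def _poisson_logpmf_vec(count: np.ndarray, log_mean: np.ndarray) -> np.ndarray:
    if np.any(count != np.round(count)) or np.any(count < 0):
        raise ValueError("event counts must be non-negative integers")
    c = count[:, None]
    log_mean = np.minimum(log_mean, _EXP_CAP)
    return c * log_mean - np.exp(log_mean) - gammaln(c + 1)


try:                                     # fast fused kernel (optional)
    from numba import njit as _njit
    _HAVE_NUMBA = True
except Exception:                        # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):                  # pragma: no cover
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _qmc_loglik_kernel(z, sds, a1, l1, q1, a2, l2, q2, off_cm, c_cm, lg_cm,
                       off_ae, c_ae, lg_ae, al1, al2, al3, with_counts):
    """Per-subject log of the draw-averaged conditional likelihood.

    The Gaussian lab contribution per subject is quadratic in the random
    intercept (a + l*b + q*b^2 with sufficient statistics folded into the
    coefficients), so the whole (subject, draw) sweep needs only two exp()
    calls per element for the count terms plus the final log-sum-exp.
    """
    n, D, _ = z.shape
    out = np.empty(n)
    tmp = np.empty(D)
    for i in range(n):
        mx = -np.inf
        for d in range(D):
            x1 = z[i, d, 0] * sds[0]
            x2 = z[i, d, 1] * sds[1]
            x3 = z[i, d, 2] * sds[2]
            v = (a1[i] + l1[i] * x1 + q1[i] * x1 * x1
                 + a2[i] + l2[i] * x2 + q2[i] * x2 * x2)
            if with_counts:
                lm = off_cm[i] + x3
                if lm > 500.0:
                    lm = 500.0
                v += c_cm[i] * lm - np.exp(lm) - lg_cm[i]
                lm = off_ae[i] + al1 * x1 + al2 * x2 + al3 * x3
                if lm > 500.0:
                    lm = 500.0
                v += c_ae[i] * lm - np.exp(lm) - lg_ae[i]
            tmp[d] = v
            if v > mx:
                mx = v
        s = 0.0
        for d in range(D):
            s += np.exp(tmp[d] - mx)
        out[i] = mx + np.log(s / D)
    return out


@_njit(cache=False)
def _qmc_moments_kernel(z, sds, a1, l1, q1, a2, l2, q2, off_cm, c_cm, lg_cm,
                        off_ae, c_ae, lg_ae, al1, al2, al3, with_counts):
    """Per-subject loglik plus importance-weighted posterior moments of b.

    Returns (out, mom) where mom columns are, in order:
    E[b1], E[b2], E[b3], E[b1^2], E[b2^2], E[b3^2],
    E[mu_cm], E[mu_ae], E[mu_ae*b1], E[mu_ae*b2], E[mu_ae*b3], E[mu_cm*b3]
    with mu = exp(capped log mean) and weights softmax over draws of the
    conditional log-likelihood.
    """
    n, D, _ = z.shape
    out = np.empty(n)
    mom = np.zeros((n, 12))
    tmp = np.empty(D)
    for i in range(n):
        mx = -np.inf
        for d in range(D):
            x1 = z[i, d, 0] * sds[0]
            x2 = z[i, d, 1] * sds[1]
            x3 = z[i, d, 2] * sds[2]
            v = (a1[i] + l1[i] * x1 + q1[i] * x1 * x1
                 + a2[i] + l2[i] * x2 + q2[i] * x2 * x2)
            if with_counts:
                lm = off_cm[i] + x3
                if lm > 500.0:
                    lm = 500.0
                v += c_cm[i] * lm - np.exp(lm) - lg_cm[i]
                lm = off_ae[i] + al1 * x1 + al2 * x2 + al3 * x3
                if lm > 500.0:
                    lm = 500.0
                v += c_ae[i] * lm - np.exp(lm) - lg_ae[i]
            tmp[d] = v
            if v > mx:
                mx = v
        s = 0.0
        for d in range(D):
            tmp[d] = np.exp(tmp[d] - mx)
            s += tmp[d]
        out[i] = mx + np.log(s / D)
        for d in range(D):
            w = tmp[d] / s
            x1 = z[i, d, 0] * sds[0]
            x2 = z[i, d, 1] * sds[1]
            x3 = z[i, d, 2] * sds[2]
            mom[i, 0] += w * x1
            mom[i, 1] += w * x2
            mom[i, 2] += w * x3
            mom[i, 3] += w * x1 * x1
            mom[i, 4] += w * x2 * x2
            mom[i, 5] += w * x3 * x3
            if with_counts:
                lm = off_cm[i] + x3
                if lm > 500.0:
                    lm = 500.0
                mu_cm = np.exp(lm)
                lm = off_ae[i] + al1 * x1 + al2 * x2 + al3 * x3
                if lm > 500.0:
                    lm = 500.0
                mu_ae = np.exp(lm)
                mom[i, 6] += w * mu_cm
                mom[i, 7] += w * mu_ae
                mom[i, 8] += w * mu_ae * x1
                mom[i, 9] += w * mu_ae * x2
                mom[i, 10] += w * mu_ae * x3
                mom[i, 11] += w * mu_cm * x3
    return out, mom


def _gaussian_coeffs(params: JointModelParams, data: PreparedData,
                     analyte: str) -> tuple:
    """Per-subject (a, l, q) with Gaussian lab loglik = a + l*b + q*b^2."""
    beta = params.beta_alt if analyte == "alt" else params.beta_bili
    sd = params.sigma_eps_alt if analyte == "alt" else params.sigma_eps_bili
    n = data.n
    idx = data.lab_idx[analyte]
    r = data.lab_y[analyte] - data.lab_X[analyte] @ beta
    m_i = np.bincount(idx, minlength=n).astype(float)
    s1 = np.bincount(idx, weights=r, minlength=n)
    s2 = np.bincount(idx, weights=r * r, minlength=n)
    inv2 = 1.0 / (2.0 * sd * sd)
    a = -0.5 * m_i * np.log(2 * np.pi * sd * sd) - s2 * inv2
    return a, 2.0 * s1 * inv2, -m_i * inv2


def _marginal_from_draws(params: JointModelParams, data: PreparedData,
                         z: np.ndarray) -> float:
    sds = np.asarray(params.random_effects.sds, dtype=float)
    if _HAVE_NUMBA:
        a1, l1, q1 = _gaussian_coeffs(params, data, "alt")
        a2, l2, q2 = _gaussian_coeffs(params, data, "bilirubin")
        assoc = params.association
        if data.include_counts:
            logT = np.log(data.T)
            off_cm = logT + data.X_count @ params.beta_conmed
            off_ae = logT + data.X_count @ params.beta_ae
            if assoc.structure == "mixed_current_value_m9":
                off_ae = off_ae + (assoc.alpha1 *
                                   (data.X_cv["alt"] @ params.beta_alt)
                                   + assoc.alpha2 *
                                   (data.X_cv["bilirubin"] @ params.beta_bili))
        else:
            off_cm = off_ae = np.zeros(data.n)
        per_subject = _qmc_loglik_kernel(
            z, sds, a1, l1, q1, a2, l2, q2,
            off_cm, data.C_cm, gammaln(data.C_cm + 1),
            off_ae, data.C_ae, gammaln(data.C_ae + 1),
            assoc.alpha1, assoc.alpha2, assoc.alpha3,
            data.include_counts)
        return float(np.sum(per_subject))
    b = z * sds[None, None, :]
    ll = _conditional_loglik_matrix(params, data, b)
    per_subject = logsumexp(ll, axis=1) - np.log(ll.shape[1])
    return float(np.sum(per_subject))


@dataclass
class JointScore:
    """Gradient of the marginal log-likelihood, block by block.

    SD blocks are derivatives with respect to the *log* SDs (the
    unconstrained optimization coordinates).
    """

    beta_alt: np.ndarray
    beta_bili: np.ndarray
    log_sigma_alt: float
    log_sigma_bili: float
    beta_conmed: np.ndarray
    beta_ae: np.ndarray
    alpha1: float
    alpha2: float
    alpha3: float
    log_sd: np.ndarray     # (3,)


def _weighted_moments(params: JointModelParams, data: PreparedData,
                      z: np.ndarray) -> tuple:
    """(per-subject loglik, 12 posterior moments) — numpy reference path."""
    sds = np.asarray(params.random_effects.sds, dtype=float)
    b = z * sds[None, None, :]
    ll = _conditional_loglik_matrix(params, data, b)
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    s = w.sum(axis=1, keepdims=True)
    out = (mx[:, 0] + np.log(s[:, 0] / ll.shape[1]))
    w = w / s
    mom = np.zeros((data.n, 12))
    mom[:, 0:3] = np.einsum("nd,ndk->nk", w, b)
    mom[:, 3:6] = np.einsum("nd,ndk->nk", w, b ** 2)
    if data.include_counts:
        logT = np.log(data.T)[:, None]
        lm_cm = np.minimum(
            logT + (data.X_count @ params.beta_conmed)[:, None] + b[:, :, 2],
            _EXP_CAP)
        assoc = params.association
        if assoc.structure == "random_effects_m7":
            link = assoc.alpha1 * b[:, :, 0] + assoc.alpha2 * b[:, :, 1]
        else:
            c1 = (data.X_cv["alt"] @ params.beta_alt)[:, None]
            c2 = (data.X_cv["bilirubin"] @ params.beta_bili)[:, None]
            link = (assoc.alpha1 * (c1 + b[:, :, 0])
                    + assoc.alpha2 * (c2 + b[:, :, 1]))
        lm_ae = np.minimum(
            logT + (data.X_count @ params.beta_ae)[:, None] + link
            + assoc.alpha3 * b[:, :, 2], _EXP_CAP)
        mu_cm, mu_ae = np.exp(lm_cm), np.exp(lm_ae)
        mom[:, 6] = (w * mu_cm).sum(axis=1)
        mom[:, 7] = (w * mu_ae).sum(axis=1)
        mom[:, 8] = (w * mu_ae * b[:, :, 0]).sum(axis=1)
        mom[:, 9] = (w * mu_ae * b[:, :, 1]).sum(axis=1)
        mom[:, 10] = (w * mu_ae * b[:, :, 2]).sum(axis=1)
        mom[:, 11] = (w * mu_cm * b[:, :, 2]).sum(axis=1)
    return out, mom


def marginal_loglik_and_score(params: JointModelParams, data: PreparedData,
                              z: np.ndarray) -> tuple:
    """Marginal log-likelihood and its analytic gradient.

    The score of a simulated likelihood is the importance-weighted average of
    the conditional score over the fixed draws; all pieces reduce to the 12
    per-subject posterior moments returned by the integration kernel.
    """
    sds = np.asarray(params.random_effects.sds, dtype=float)
    if _HAVE_NUMBA:
        a1, l1, q1 = _gaussian_coeffs(params, data, "alt")
        a2, l2, q2 = _gaussian_coeffs(params, data, "bilirubin")
        assoc = params.association
        if data.include_counts:
            logT = np.log(data.T)
            off_cm = logT + data.X_count @ params.beta_conmed
            off_ae = logT + data.X_count @ params.beta_ae
            if assoc.structure == "mixed_current_value_m9":
                off_ae = off_ae + (assoc.alpha1 *
                                   (data.X_cv["alt"] @ params.beta_alt)
                                   + assoc.alpha2 *
                                   (data.X_cv["bilirubin"] @ params.beta_bili))
        else:
            off_cm = off_ae = np.zeros(data.n)
        per_subject, mom = _qmc_moments_kernel(
            z, sds, a1, l1, q1, a2, l2, q2,
            off_cm, data.C_cm, gammaln(data.C_cm + 1),
            off_ae, data.C_ae, gammaln(data.C_ae + 1),
            assoc.alpha1, assoc.alpha2, assoc.alpha3, data.include_counts)
    else:
        per_subject, mom = _weighted_moments(params, data, z)
    ll = float(np.sum(per_subject))

    (Eb1, Eb2, Eb3, Eb1s, Eb2s, Eb3s,
     Ecm, Eae, Eaeb1, Eaeb2, Eaeb3, Ecmb3) = mom.T
    assoc = params.association
    m9 = assoc.structure == "mixed_current_value_m9"

    lab = {}
    for analyte, beta, sig, Eb, Ebs in (
            ("alt", params.beta_alt, params.sigma_eps_alt, Eb1, Eb1s),
            ("bilirubin", params.beta_bili, params.sigma_eps_bili, Eb2, Eb2s)):
        idx, X, y = data.lab_idx[analyte], data.lab_X[analyte], \
            data.lab_y[analyte]
        r = y - X @ beta
        m_i = np.bincount(idx, minlength=data.n).astype(float)
        s1 = np.bincount(idx, weights=r, minlength=data.n)
        s2 = np.bincount(idx, weights=r * r, minlength=data.n)
        g_beta = (X.T @ (r - Eb[idx])) / sig ** 2
        Ess = s2 - 2.0 * Eb * s1 + m_i * Ebs
        g_logsig = float(-m_i.sum() + Ess.sum() / sig ** 2)
        g_logsd_lab = float(((s1 * Eb - m_i * Ebs) / sig ** 2).sum())
        lab[analyte] = (g_beta, g_logsig, g_logsd_lab)

    if data.include_counts:
        res_cm = data.C_cm - Ecm
        res_ae = data.C_ae - Eae
        g_bcm = data.X_count.T @ res_cm
        g_bae = data.X_count.T @ res_ae
        A1 = float((data.C_ae * Eb1 - Eaeb1).sum())
        A2 = float((data.C_ae * Eb2 - Eaeb2).sum())
        A3 = float((data.C_ae * Eb3 - Eaeb3).sum())
        if m9:
            c1 = data.X_cv["alt"] @ params.beta_alt
            c2 = data.X_cv["bilirubin"] @ params.beta_bili
            g_al1 = float((c1 * res_ae).sum()) + A1
            g_al2 = float((c2 * res_ae).sum()) + A2
            g_beta_alt_extra = assoc.alpha1 * (data.X_cv["alt"].T @ res_ae)
            g_beta_bili_extra = assoc.alpha2 * (data.X_cv["bilirubin"].T
                                                @ res_ae)
        else:
            g_al1, g_al2 = A1, A2
            g_beta_alt_extra = g_beta_bili_extra = 0.0
        g_al3 = A3
        g_logsd3 = float((data.C_cm * Eb3 - Ecmb3).sum()) + assoc.alpha3 * A3
    else:
        p_cnt = len(params.beta_conmed)
        g_bcm = np.zeros(p_cnt)
        g_bae = np.zeros(p_cnt)
        g_al1 = g_al2 = g_al3 = 0.0
        A1 = A2 = 0.0
        g_beta_alt_extra = g_beta_bili_extra = 0.0
        g_logsd3 = 0.0

    score = JointScore(
        beta_alt=lab["alt"][0] + g_beta_alt_extra,
        beta_bili=lab["bilirubin"][0] + g_beta_bili_extra,
        log_sigma_alt=lab["alt"][1],
        log_sigma_bili=lab["bilirubin"][1],
        beta_conmed=g_bcm, beta_ae=g_bae,
        alpha1=g_al1, alpha2=g_al2, alpha3=g_al3,
        log_sd=np.array([lab["alt"][2] + assoc.alpha1 * A1,
                         lab["bilirubin"][2] + assoc.alpha2 * A2,
                         g_logsd3]))
    return ll, score


def marginal_loglik(params: JointModelParams,
                    trial_data: Union[TrialData, PreparedData],
                    settings: IntegrationSettings = IntegrationSettings()
                    ) -> float:
    """QMC marginal log-likelihood, sum over subjects of log E_b[exp(ll | b)].

    Draws come from the random-effects distribution itself, so the Monte
    Carlo weight is the plain average of the conditional likelihoods,
    computed by log-sum-exp.  An SD of exactly 0 collapses that dimension to
    a point mass at 0.  Bit-identical for identical (seed, draws).
    """
    if settings.method != "halton_qmc":
        raise ValueError("marginal_loglik integrates by halton_qmc; use "
                         "gh_reference_loglik for Gauss-Hermite")
    data = trial_data if isinstance(trial_data, PreparedData) \
        else prepare_likelihood(trial_data, params.spline)
    z = standardized_draws(settings, data.n, params.random_effects)
    return _marginal_from_draws(params, data, z)


def gh_reference_loglik(params: JointModelParams,
                        trial_data: Union[TrialData, PreparedData],
                        nodes_per_dim: int = 15) -> float:
    """Tensor-product Gauss-Hermite marginal log-likelihood (reference).

    Exact-in-the-limit deterministic integrator over the three Gaussian
    random-effect dimensions; intended for small datasets as the oracle the
    QMC integrator is checked against.  Gaussian random effects only.
    """
    if params.random_effects.distribution != "gaussian":
        raise ValueError("Gauss-Hermite reference supports gaussian random "
                         "effects only")
    if nodes_per_dim < 3:
        raise ValueError("need >= 3 nodes per dimension")
    data = trial_data if isinstance(trial_data, PreparedData) \
        else prepare_likelihood(trial_data, params.spline)
    x, w = np.polynomial.hermite.hermgauss(nodes_per_dim)
    grids = np.meshgrid(x, x, x, indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)   # (G^3, 3)
    logw = sum(np.log(w)[g.ravel()] for g in np.meshgrid(
        np.arange(nodes_per_dim), np.arange(nodes_per_dim),
        np.arange(nodes_per_dim), indexing="ij"))
    logw = logw - 1.5 * np.log(np.pi)
    sds = np.asarray(params.random_effects.sds, dtype=float)
    b = np.sqrt(2.0) * nodes[None, :, :] * sds[None, None, :]
    b = np.broadcast_to(b, (data.n, b.shape[1], 3))
    ll = _conditional_loglik_matrix(params, data, b)
    per_subject = logsumexp(ll + logw[None, :], axis=1)
    return float(np.sum(per_subject))
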