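"""Maximum-likelihood fitting: joint model, Poisson comparator, inference.

The joint model is fitted by maximizing the simulated (quasi-Monte-Carlo)
marginal log-likelihood with a quasi-Newton optimizer over an unconstrained
parameterization (all standard deviations log-transformed, no bounds on
regression or association coefficients).  The QMC draws are generated once
per fit and held fixed across iterations, so the objective is smooth and
deterministic and the same (data, config, seed) always reproduces the same
fit.  Standard errors come from the inverse negative central-finite-difference
Hessian of the marginal log-likelihood at the MLE, evaluated with the same
draws; SDs are reported back on the natural scale by the delta method.

The comparator is the conventional Poisson model for the AE count with a
log follow-up-time offset, fitted by iteratively reweighted least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.stats import chi2, norm

from .design import (COUNT_COLUMNS, COUNT_COLUMNS_M1, DEFAULT_KNOTS,
                     SplineSpec, count_design_matrix, longitudinal_columns,
                     longitudinal_design_matrix)
from .model import (AssociationSpec, IntegrationSettings, JointModelParams,
                    PreparedData, RandomEffectsSpec, _marginal_from_draws,
                    marginal_loglik_and_score, prepare_likelihood,
                    standardized_draws)
from .trial_data import ANALYTES, TrialData, aggregate_counts

_STRUCTURE_ALIASES = {"m7": "random_effects_m7", "m9": "mixed_current_value_m9",
                      "random_effects_m7": "random_effects_m7",
                      "mixed_current_value_m9": "mixed_current_value_m9"}


@dataclass
class ModelConfig:
    """What to fit: association structure, random-effects family, options.

    ``fixed`` maps natural-scale parameter names (e.g. ``alpha_alt``,
    ``sd_b_conmed``) to values held constant during optimization; an SD may
    be fixed at exactly 0 (point mass).
    """

    structure: str = "mixed_current_value_m9"
    random_effects: str = "gaussian"
    t_df: float = 5.0
    medication_filter: Optional[str] = None
    spline_knots: Sequence[float] = DEFAULT_KNOTS
    day_eval: Union[str, float] = "followup"
    fixed: dict = field(default_factory=dict)
    max_iter: int = 500

    def __post_init__(self):
        if self.structure not in _STRUCTURE_ALIASES:
            raise ValueError(f"unknown association structure "
                             f"{self.structure!r}; use m7 or m9")
        self.structure = _STRUCTURE_ALIASES[self.structure]


class ParamPacker:
    """Maps JointModelParams <-> the unconstrained free-parameter vector."""

    def __init__(self, spline: SplineSpec, config: ModelConfig):
        long_cols = longitudinal_columns(spline)
        self.spline = spline
        self.config = config
        self.names = ([f"alt:{c}" for c in long_cols]
                      + [f"bili:{c}" for c in long_cols]
                      + ["sigma_eps_alt", "sigma_eps_bili"]
                      + [f"conmed:{c}" for c in COUNT_COLUMNS]
                      + [f"ae:{c}" for c in COUNT_COLUMNS]
                      + ["alpha_alt", "alpha_bili", "alpha_conmed"]
                      + ["sd_b_alt", "sd_b_bili", "sd_b_conmed"])
        self.log_scale = {"sigma_eps_alt", "sigma_eps_bili",
                          "sd_b_alt", "sd_b_bili", "sd_b_conmed"}
        unknown = set(config.fixed) - set(self.names)
        if unknown:
            raise ValueError(f"unknown fixed parameter names {sorted(unknown)}")
        self.free_names = [n for n in self.names if n not in config.fixed]
        self.p_long = len(long_cols)

    def values_dict(self, params: JointModelParams) -> dict:
        d = {}
        long_cols = longitudinal_columns(self.spline)
        for c, v in zip(long_cols, params.beta_alt):
            d[f"alt:{c}"] = float(v)
        for c, v in zip(long_cols, params.beta_bili):
            d[f"bili:{c}"] = float(v)
        d["sigma_eps_alt"] = params.sigma_eps_alt
        d["sigma_eps_bili"] = params.sigma_eps_bili
        for c, v in zip(COUNT_COLUMNS, params.beta_conmed):
            d[f"conmed:{c}"] = float(v)
        for c, v in zip(COUNT_COLUMNS, params.beta_ae):
            d[f"ae:{c}"] = float(v)
        a = params.association
        d["alpha_alt"], d["alpha_bili"], d["alpha_conmed"] = \
            a.alpha1, a.alpha2, a.alpha3
        for name, v in zip(("sd_b_alt", "sd_b_bili", "sd_b_conmed"),
                           params.random_effects.sds):
            d[name] = float(v)
        return d

    def pack(self, params: JointModelParams) -> np.ndarray:
        d = self.values_dict(params)
        out = []
        for n in self.free_names:
            v = d[n]
            out.append(np.log(v) if n in self.log_scale else v)
        return np.array(out, dtype=float)

    def grad_vector(self, score) -> np.ndarray:
        """Flatten a JointScore into the free-parameter order."""
        long_cols = longitudinal_columns(self.spline)
        d = {}
        for c, v in zip(long_cols, score.beta_alt):
            d[f"alt:{c}"] = v
        for c, v in zip(long_cols, score.beta_bili):
            d[f"bili:{c}"] = v
        d["sigma_eps_alt"] = score.log_sigma_alt
        d["sigma_eps_bili"] = score.log_sigma_bili
        for c, v in zip(COUNT_COLUMNS, score.beta_conmed):
            d[f"conmed:{c}"] = v
        for c, v in zip(COUNT_COLUMNS, score.beta_ae):
            d[f"ae:{c}"] = v
        d["alpha_alt"], d["alpha_bili"], d["alpha_conmed"] = \
            score.alpha1, score.alpha2, score.alpha3
        d["sd_b_alt"], d["sd_b_bili"], d["sd_b_conmed"] = score.log_sd
        return np.array([d[n] for n in self.free_names], dtype=float)

    def unpack(self, x: np.ndarray) -> JointModelParams:
        d = dict(self.config.fixed)
        for n, v in zip(self.free_names, x):
            d[n] = float(np.exp(v)) if n in self.log_scale else float(v)
        long_cols = longitudinal_columns(self.spline)
        cfg = self.config
        return JointModelParams(
            beta_alt=np.array([d[f"alt:{c}"] for c in long_cols]),
            beta_bili=np.array([d[f"bili:{c}"] for c in long_cols]),
            sigma_eps_alt=d["sigma_eps_alt"],
            sigma_eps_bili=d["sigma_eps_bili"],
            beta_conmed=np.array([d[f"conmed:{c}"] for c in COUNT_COLUMNS]),
            beta_ae=np.array([d[f"ae:{c}"] for c in COUNT_COLUMNS]),
            association=AssociationSpec(structure=cfg.structure,
                                        alpha1=d["alpha_alt"],
                                        alpha2=d["alpha_bili"],
                                        alpha3=d["alpha_conmed"]),
            random_effects=RandomEffectsSpec(
                sds=(d["sd_b_alt"], d["sd_b_bili"], d["sd_b_conmed"]),
                distribution=cfg.random_effects, t_df=cfg.t_df),
            spline=self.spline)


# ---------------------------------------------------------------------------
# fit containers

@dataclass
class PoissonFit:
    """Conventional offset-Poisson fit for the AE count."""

    names: list
    estimates: dict
    se: dict
    vcov: pd.DataFrame
    loglik: float
    aic: float
    n_subjects: int
    converged: bool = True

    def ci(self, name: str, level: float = 0.95) -> tuple:
        z = norm.ppf(0.5 + level / 2)
        est, se = self.estimates[name], self.se[name]
        return (est - z * se, est + z * se)

    def p_value(self, name: str) -> float:
        z = self.estimates[name] / self.se[name]
        return float(2 * norm.sf(abs(z)))


@dataclass
class JointModelFit:
    """Joint-model MLE with covariance and fit record."""

    params: JointModelParams
    packer: ParamPacker
    estimates: dict                 # natural scale, all free parameters
    se: dict                        # natural scale (delta method for SDs)
    vcov: pd.DataFrame              # unconstrained parameterization
    loglik: float
    aic: float
    n_subjects: int
    settings: IntegrationSettings
    config: ModelConfig
    converged: bool
    iterations: int
    hessian_pd: bool = True

    @property
    def names(self) -> list:
        return list(self.packer.free_names)

    def ci(self, name: str, level: float = 0.95) -> tuple:
        z = norm.ppf(0.5 + level / 2)
        if name in self.packer.log_scale:
            log_est = np.log(self.estimates[name])
            log_se = float(np.sqrt(self.vcov.loc[name, name]))
            return (float(np.exp(log_est - z * log_se)),
                    float(np.exp(log_est + z * log_se)))
        est, se = self.estimates[name], self.se[name]
        return (est - z * se, est + z * se)

    def p_value(self, name: str) -> float:
        z = self.estimates[name] / self.se[name]
        return float(2 * norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "names": self.names,
            "estimates": self.estimates,
            "se": self.se,
            "vcov": self.vcov.to_numpy().tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_subjects": self.n_subjects,
            "settings": {"method": self.settings.method,
                         "draws": self.settings.draws,
                         "seed": self.settings.seed,
                         "antithetic": self.settings.antithetic},
            "config": {"structure": self.config.structure,
                       "random_effects": self.config.random_effects,
                       "t_df": self.config.t_df,
                       "medication_filter": self.config.medication_filter,
                       "spline_knots": list(self.config.spline_knots),
                       "day_eval": self.config.day_eval,
                       "fixed": self.config.fixed},
            "converged": self.converged,
            "iterations": self.iterations,
            "hessian_pd": self.hessian_pd,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_fit(path) -> JointModelFit:
    """Reload a serialized joint fit; linear predictors are reproduced exactly."""
    with open(path) as fh:
        doc = json.load(fh)
    cfg = ModelConfig(structure=doc["config"]["structure"],
                      random_effects=doc["config"]["random_effects"],
                      t_df=doc["config"]["t_df"],
                      medication_filter=doc["config"]["medication_filter"],
                      spline_knots=tuple(doc["config"]["spline_knots"]),
                      day_eval=doc["config"]["day_eval"],
                      fixed=doc["config"]["fixed"])
    packer = ParamPacker(SplineSpec(tuple(cfg.spline_knots)), cfg)
    x = np.array([np.log(doc["estimates"][n]) if n in packer.log_scale
                  else doc["estimates"][n] for n in packer.free_names])
    settings = IntegrationSettings(**doc["settings"])
    vcov = pd.DataFrame(np.array(doc["vcov"]), index=doc["names"],
                        columns=doc["names"])
    return JointModelFit(params=packer.unpack(x), packer=packer,
                         estimates=doc["estimates"], se=doc["se"], vcov=vcov,
                         loglik=doc["loglik"], aic=doc["aic"],
                         n_subjects=doc["n_subjects"], settings=settings,
                         config=cfg, converged=doc["converged"],
                         iterations=doc["iterations"],
                         hessian_pd=doc["hessian_pd"])


# ---------------------------------------------------------------------------
# conventional Poisson comparator

def fit_poisson_m1(trial_data: TrialData,
                   include_gravidity: bool = True,
                   intercept_only: bool = False) -> PoissonFit:
    """Offset-Poisson MLE for the AE count (IRLS).

    Covariates: treatment arm, maternal age, gravidity (optional) and
    trimester at enrolment, with log follow-up days as offset.
    ``intercept_only`` fits the crude-rate model, whose MLE is
    log(sum C / sum T) with SE 1/sqrt(sum C) in closed form.
    """
    counts = aggregate_counts(trial_data)
    ae = counts[counts["outcome"] == "ae"].set_index("subject_id")
    subs = trial_data.subjects
    y = ae.loc[subs["subject_id"], "count"].to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("all AE counts are zero: Poisson MLE lies on the "
                         "boundary; no rate model can be fitted")
    T = subs["followup_days"].to_numpy(dtype=float)
    if intercept_only:
        X = np.ones((len(subs), 1))
        names = ["const"]
    else:
        X = count_design_matrix(subs, include_gravidity=include_gravidity)
        names = list(COUNT_COLUMNS_M1 if include_gravidity
                     else COUNT_COLUMNS)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(T))
    try:
        res = model.fit(tol=1e-12)
    except Exception as exc:   # perfect separation and friends
        raise RuntimeError(f"Poisson IRLS did not converge: {exc}") from exc
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge "
                           "(possible separation)")
    vcov = pd.DataFrame(np.asarray(res.cov_params()), index=names,
                        columns=names)
    return PoissonFit(names=names,
                      estimates=dict(zip(names, map(float, res.params))),
                      se=dict(zip(names, map(float, res.bse))),
                      vcov=vcov, loglik=float(res.llf),
                      aic=aic(float(res.llf), len(names)),
                      n_subjects=len(subs))


# ---------------------------------------------------------------------------
# starting values

def _longitudinal_start(trial_data: TrialData, analyte: str,
                        spline: SplineSpec) -> tuple:
    """Random-intercept starting fit for one analyte: (beta, sd_b, sd_eps)."""
    rec = trial_data.labs[trial_data.labs["analyte"] == analyte]
    subs_ix = trial_data.subjects.set_index("subject_id")
    X = longitudinal_design_matrix(subs_ix, rec["subject_id"],
                                   rec["day"].to_numpy(), spline)
    y = rec["log_value"].to_numpy(dtype=float)
    groups = rec["subject_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        beta = np.asarray(res.fe_params, dtype=float)
        sd_b = float(np.sqrt(max(res.cov_re.iloc[0, 0], 1e-6)))
        sd_eps = float(np.sqrt(max(res.scale, 1e-6)))
    except Exception:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        means = pd.Series(r).groupby(groups).transform("mean").to_numpy()
        sd_b = float(max(np.std(np.unique(means)), 1e-2))
        sd_eps = float(max(np.std(r - means), 1e-2))
    return beta, sd_b, sd_eps


def initial_values(trial_data: TrialData,
                   model_config: Optional[ModelConfig] = None
                   ) -> JointModelParams:
    """Starting values from independent per-outcome fits.

    Longitudinal betas and variance components from per-analyte
    random-intercept fits; count betas from offset-Poisson fits; association
    coefficients start at 0 and the conmed random-intercept SD at 0.1.
    """
    cfg = model_config or ModelConfig()
    spline = SplineSpec(tuple(cfg.spline_knots))
    beta_alt, sd_b1, sd_e1 = _longitudinal_start(trial_data, "alt", spline)
    beta_bili, sd_b2, sd_e2 = _longitudinal_start(trial_data, "bilirubin",
                                                  spline)
    counts = aggregate_counts(trial_data, cfg.medication_filter)
    subs = trial_data.subjects
    T = subs["followup_days"].to_numpy(dtype=float)
    X = count_design_matrix(subs)
    betas = {}
    for outcome in ("conmed", "ae"):
        c = counts[counts["outcome"] == outcome].set_index("subject_id")
        y = c.loc[subs["subject_id"], "count"].to_numpy(dtype=float)
        if y.sum() == 0:
            b = np.zeros(X.shape[1])
            b[0] = -np.log(T.mean()) - 2.0   # weakly informed low rate
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = np.asarray(sm.GLM(y, X, family=sm.families.Poisson(),
                                      offset=np.log(T)).fit().params)
        betas[outcome] = b
    return JointModelParams(
        beta_alt=beta_alt, beta_bili=beta_bili,
        sigma_eps_alt=sd_e1, sigma_eps_bili=sd_e2,
        beta_conmed=betas["conmed"], beta_ae=betas["ae"],
        association=AssociationSpec(structure=cfg.structure),
        random_effects=RandomEffectsSpec(sds=(sd_b1, sd_b2, 0.1),
                                         distribution=cfg.random_effects,
                                         t_df=cfg.t_df),
        spline=spline)


# ---------------------------------------------------------------------------
# joint fit

def _finite_diff_hessian(f: Callable, x: np.ndarray,
                         rel_step: float = 1e-4) -> np.ndarray:
    """Central-finite-difference Hessian of scalar f at x."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                 - fm[i] - fm[j] + fmm) / (2.0 * h[i] * h[j])
    return H


@dataclass
class FitContext:
    """Everything needed to recompute the covariance at an MLE."""

    loglik: Callable           # unconstrained x -> marginal log-likelihood
    x_hat: np.ndarray
    names: list
    grad: Optional[Callable] = None   # analytic gradient, if available


def _finite_diff_hessian_from_grad(g: Callable, x: np.ndarray,
                                   rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic gradient (symmetrized)."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        H[:, i] = (g(x + e) - g(x - e)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def standard_errors(fit_context: FitContext) -> tuple:
    """(vcov DataFrame on the unconstrained scale, positive-definite flag).

    Inverse of the negative central-finite-difference Hessian evaluated with
    the same integration draws used for the fit.  A non-positive-definite
    Hessian falls back to the Moore-Penrose pseudo-inverse with a warning.
    """
    if fit_context.grad is not None:
        H = _finite_diff_hessian_from_grad(fit_context.grad,
                                           fit_context.x_hat)
    else:
        H = _finite_diff_hessian(fit_context.loglik, fit_context.x_hat)
    neg_H = -H
    pd_flag = bool(np.all(np.linalg.eigvalsh(neg_H) > 0))
    if pd_flag:
        V = np.linalg.inv(neg_H)
    else:
        warnings.warn("observed information is not positive definite; "
                      "using pseudo-inverse", UserWarning, stacklevel=2)
        V = np.linalg.pinv(neg_H)
    V = 0.5 * (V + V.T)
    names = fit_context.names
    return pd.DataFrame(V, index=names, columns=names), pd_flag


def fit_joint(trial_data: TrialData,
              model_config: Optional[ModelConfig] = None,
              settings: IntegrationSettings = IntegrationSettings(),
              start: Optional[JointModelParams] = None,
              compute_se: bool = True) -> JointModelFit:
    """Fit the joint model by simulated maximum likelihood.

    Quasi-Newton (L-BFGS) maximization over the unconstrained
    parameterization; the QMC draws are generated once and held fixed, so the
    objective is deterministic.  A fit hitting the iteration cap is returned
    with ``converged=False`` rather than raising.
    """
    cfg = model_config or ModelConfig()
    if len(trial_data.labs) == 0:
        raise ValueError(
            "trial has no laboratory measurements; the joint model needs the "
            "longitudinal sub-models — use count-only models "
            "(fit_poisson_m1) instead")
    spline = SplineSpec(tuple(cfg.spline_knots))
    data = prepare_likelihood(trial_data, spline, cfg.day_eval,
                              cfg.medication_filter)
    init = start if start is not None else initial_values(trial_data, cfg)
    packer = ParamPacker(spline, cfg)
    z = standardized_draws(settings, data.n, init.random_effects)

    def loglik_of(x: np.ndarray) -> float:
        return _marginal_from_draws(packer.unpack(x), data, z)

    def grad_of(x: np.ndarray) -> np.ndarray:
        _, score = marginal_loglik_and_score(packer.unpack(x), data, z)
        return packer.grad_vector(score)

    def negll_and_grad(x: np.ndarray):
        ll, score = marginal_loglik_and_score(packer.unpack(x), data, z)
        return -ll, -packer.grad_vector(score)

    x0 = packer.pack(init)
    if not np.isfinite(loglik_of(x0)):
        raise RuntimeError("marginal log-likelihood is non-finite at the "
                           "starting values")

    res = optimize.minimize(
        negll_and_grad, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "ftol": 1e-11, "gtol": 1e-6,
                 "maxcor": 100,
                 "maxfun": 20 * cfg.max_iter * max(1, len(x0))})
    if not np.isfinite(res.fun):
        raise RuntimeError("non-finite likelihood at the optimizer solution")
    converged = bool(res.success)
    x_hat = np.asarray(res.x, dtype=float)
    params_hat = packer.unpack(x_hat)
    ll = float(-res.fun)
    k = len(packer.free_names)

    names = packer.free_names
    if compute_se:
        vcov, pd_flag = standard_errors(
            FitContext(loglik_of, x_hat, names, grad=grad_of))
    else:
        vcov = pd.DataFrame(np.full((k, k), np.nan), index=names,
                            columns=names)
        pd_flag = True
    estimates, ses = {}, {}
    d = packer.values_dict(params_hat)
    for i, n in enumerate(names):
        estimates[n] = d[n]
        se_u = float(np.sqrt(max(vcov.iloc[i, i], 0.0)))
        # delta method back to the natural SD scale
        ses[n] = d[n] * se_u if n in packer.log_scale else se_u

    return JointModelFit(params=params_hat, packer=packer,
                         estimates=estimates, se=ses, vcov=vcov, loglik=ll,
                         aic=aic(ll, k), n_subjects=data.n,
                         settings=settings, config=cfg, converged=converged,
                         iterations=int(res.nit), hessian_pd=pd_flag)


# ---------------------------------------------------------------------------
# inference helpers

@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float


def wald_test(fit, coefficient_names: Sequence[str]) -> WaldResult:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    names = list(coefficient_names)
    missing = [n for n in names if n not in fit.estimates]
    if missing:
        raise KeyError(f"coefficients not in fit: {missing}")
    b = np.array([fit.estimates[n] for n in names])
    V = fit.vcov.loc[names, names].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular covariance block in Wald test") from exc
    if stat < 0:
        raise ValueError("negative Wald statistic: covariance block is not "
                         "positive definite")
    df = len(names)
    return WaldResult(statistic=stat, df=df,
                      p_value=float(chi2.sf(stat, df)))


def irr_transform(log_irr: float, ci_low: Optional[float] = None,
                  ci_high: Optional[float] = None):
    """Exponentiate a log incidence-rate ratio (and CI), to 4 decimals."""
    vals = [log_irr, ci_low, ci_high]
    if any(v is not None and not np.isfinite(v) for v in vals):
        raise ValueError("non-finite log IRR input")
    irr = round(float(np.exp(log_irr)), 4)
    if ci_low is None and ci_high is None:
        return irr
    ci = (None if ci_low is None else round(float(np.exp(ci_low)), 4),
          None if ci_high is None else round(float(np.exp(ci_high)), 4))
    return irr, ci


def aic(loglik: float, n_free_params: int) -> float:
    """Akaike information criterion; lower is better."""
    if n_free_params < 0:
        raise ValueError("negative parameter count")
    return -2.0 * loglik + 2.0 * n_free_params


def compare_fits(poisson_fit: PoissonFit,
                 joint_fit: JointModelFit) -> pd.DataFrame:
    """Side-by-side AE-sub-model coefficients of both fits.

    One row per AE coefficient: log IRR, SE, 95% CI and p for each model,
    plus the exponentiated IRR columns.  Requires the two AE covariate sets
    to match.
    """
    pois_names = poisson_fit.names
    joint_ae = [n for n in joint_fit.names if n.startswith("ae:")]
    stripped = [n.split(":", 1)[1] for n in joint_ae]
    if set(stripped) != set(pois_names):
        raise ValueError(
            f"mismatched AE covariate sets: poisson {sorted(pois_names)} vs "
            f"joint {sorted(stripped)}; refit with matching covariates")
    rows = []
    for pn in pois_names:
        jn = f"ae:{pn}"
        p_lo, p_hi = poisson_fit.ci(pn)
        j_lo, j_hi = joint_fit.ci(jn)
        rows.append({
            "coefficient": pn,
            "poisson_log_irr": poisson_fit.estimates[pn],
            "poisson_se": poisson_fit.se[pn],
            "poisson_ci_low": p_lo, "poisson_ci_high": p_hi,
            "poisson_p": poisson_fit.p_value(pn),
            "poisson_irr": irr_transform(poisson_fit.estimates[pn]),
            "joint_log_irr": joint_fit.estimates[jn],
            "joint_se": joint_fit.se[jn],
            "joint_ci_low": j_lo, "joint_ci_high": j_hi,
            "joint_p": joint_fit.p_value(jn),
            "joint_irr": irr_transform(joint_fit.estimates[jn]),
        })
    return pd.DataFrame(rows)
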