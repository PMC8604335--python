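"""Subject-level MAP estimation and Laplace model evidence.

Parameters are estimated in an unconstrained space — logit for rates
(a_self, a_other, theta), log for positive scales (beta0, beta_con),
identity for the unconstrained biases and tau — under independent Gaussian
priors in that space. The log-joint (log-likelihood + log-prior) is
maximized by multi-start quasi-Newton (L-BFGS-B), and the log model
evidence is approximated at the mode by Laplace's method:

    LME = log p(y, theta_MAP) + (d/2) log(2 pi) - (1/2) log |H|

with H the Hessian of the negative log-joint at the MAP.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from ._core import mabc_session_loglik, rw_loglik
from .model import (MABCParams, ModelSpec, PARAM_NAMES, get_spec,
                    session_arrays)
from .task import SessionLog

TRANSFORMS = {
    "a_self": "logit", "a_other": "logit", "theta": "logit",
    "beta0": "log", "beta_con": "log",
    "bias_pos": "identity", "bias_neg": "identity", "tau": "identity",
}
# optimizer box bounds per transform, wide enough to be inert under the priors
_BOUNDS = {"logit": (-16.0, 16.0), "log": (-10.0, 10.0),
           "identity": (-20.0, 20.0)}


def to_transformed(name: str, value: float) -> float:
    t = TRANSFORMS[name]
    if t == "logit":
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name}={value} outside (0,1)")
        return float(np.log(value / (1.0 - value)))
    if t == "log":
        if value <= 0.0:
            raise ValueError(f"{name}={value} must be positive")
        return float(np.log(value))
    return float(value)


def from_transformed(name: str, value: float) -> float:
    t = TRANSFORMS[name]
    if t == "logit":
        return float(expit(value))
    if t == "log":
        return float(np.exp(value))
    return float(value)


@dataclass(frozen=True)
class ParamPrior:
    transform: str
    mean: float = 0.0
    variance: float = 4.0

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class PriorSpec:
    """Transformed-space Gaussian priors, one per model parameter.

    The defaults are weakly informative: mean 0, variance 4 for every
    parameter in its estimation space (so e.g. learning rates center on 0.5
    in (0,1), scales on 1 on the positive axis).
    """

    priors: dict = field(default_factory=dict)

    @classmethod
    def default(cls, variance: float = 4.0) -> "PriorSpec":
        return cls({name: ParamPrior(TRANSFORMS[name], 0.0, variance)
                    for name in PARAM_NAMES})

    def __getitem__(self, name: str) -> ParamPrior:
        return self.priors[name]

    def with_overrides(self, **kw: ParamPrior) -> "PriorSpec":
        new = dict(self.priors)
        new.update(kw)
        return PriorSpec(new)

    def sample_natural(self, names: Sequence[str],
                       rng: np.random.Generator) -> dict[str, float]:
        """Draw parameter values from the priors, mapped to natural space."""
        return {n: from_transformed(
            n, rng.normal(self[n].mean, np.sqrt(self[n].variance)))
            for n in names}


def transform_params(params: MABCParams, free_names: Sequence[str]) -> np.ndarray:
    return np.array([to_transformed(n, getattr(params, n)) for n in free_names])


def untransform_params(x: np.ndarray, free_names: Sequence[str],
                       fixed: Optional[dict] = None) -> MABCParams:
    vals = dict(fixed or {})
    vals.update({n: from_transformed(n, v) for n, v in zip(free_names, x)})
    return MABCParams(**{n: vals.get(n, getattr(MABCParams(), n))
                         for n in PARAM_NAMES})


@dataclass
class FitResult:
    label: str
    free_names: tuple[str, ...]
    map_params_transformed: np.ndarray
    map_params_natural: MABCParams
    log_joint_at_map: float
    hessian: np.ndarray
    lme: float
    n_restarts_used: int
    converged: bool
    ridge_used: bool = False

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "free_names": list(self.free_names),
            "map_params_transformed": list(map(float, self.map_params_transformed)),
            "map_params_natural": dataclasses.asdict(self.map_params_natural),
            "log_joint_at_map": self.log_joint_at_map,
            "lme": self.lme,
            "n_restarts_used": self.n_restarts_used,
            "converged": self.converged,
            "ridge_used": self.ridge_used,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class EvidenceError(RuntimeError):
    """Raised when the Laplace evidence is undefined (singular curvature)."""


def finite_difference_hessian(fun: Callable[[np.ndarray], float],
                              x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central second differences of a scalar function."""
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def laplace_evidence(log_joint_at_map: float,
                     hessian: np.ndarray) -> tuple[float, bool]:
    """Laplace approximation to the log evidence; returns (lme, ridge_used).

    ``hessian`` is the curvature of the *negative* log-joint at the mode. A
    non-positive-definite Hessian gets an escalating diagonal ridge (warned
    and flagged) before the evidence is declared undefined.
    """
    H = np.asarray(hessian, dtype=float)
    if H.size == 0:
        return float(log_joint_at_map), False
    H = 0.5 * (H + H.T)
    d = H.shape[0]
    ridge_used = False
    scale = max(1.0, np.trace(np.abs(H)) / d)
    for ridge in (0.0, 1e-6, 1e-4, 1e-2):
        try:
            Hr = H + ridge * scale * np.eye(d)
            L = np.linalg.cholesky(Hr)
            if ridge > 0:
                ridge_used = True
                warnings.warn(
                    f"non-positive-definite Hessian; ridge {ridge:g} applied",
                    RuntimeWarning, stacklevel=2)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            return (float(log_joint_at_map) + 0.5 * d * np.log(2.0 * np.pi)
                    - 0.5 * logdet), ridge_used
        except np.linalg.LinAlgError:
            continue
    raise EvidenceError("Hessian singular even after ridge regularization")


def _map_optimize(neg_log_joint: Callable[[np.ndarray], float],
                  x0s: Sequence[np.ndarray],
                  bounds: Sequence[tuple[float, float]],
                  gtol: float = 1e-6):
    """Multi-start L-BFGS-B; returns (x, f, converged, n_restarts)."""
    best = None
    converged = False
    for x0 in x0s:
        res = optimize.minimize(neg_log_joint, np.asarray(x0, dtype=float),
                                method="L-BFGS-B", bounds=bounds,
                                options={"gtol": gtol, "ftol": 1e-12,
                                         "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    return best.x, float(best.fun), converged, len(x0s)


def map_laplace(neg_log_joint: Callable[[np.ndarray], float],
                x0s: Sequence[np.ndarray],
                bounds: Optional[Sequence[tuple[float, float]]] = None):
    """Generic MAP + Laplace driver for an arbitrary negative log-joint.

    Returns (x_map, log_joint_at_map, hessian, lme, converged, ridge_used).
    """
    d = len(x0s[0])
    bounds = bounds if bounds is not None else [(None, None)] * d
    x, f, converged, _ = _map_optimize(neg_log_joint, x0s, bounds)
    H = finite_difference_hessian(neg_log_joint, x)
    lme, ridge = laplace_evidence(-f, H)
    return x, -f, H, lme, converged, ridge


def map_fit(session: SessionLog, spec: ModelSpec | str,
            prior_spec: Optional[PriorSpec] = None,
            n_restarts: int = 10, seed: int = 0) -> FitResult:
    """MAP-estimate one model on one session, with Laplace evidence.

    Restart initial points are the transformed prior means plus seeded
    Gaussian jitter (the first start is the exact prior mean).
    """
    if isinstance(spec, str):
        spec = get_spec(spec)
    prior_spec = prior_spec or PriorSpec.default()
    free = spec.free_params
    fixed = spec.fixed_values
    d = len(free)
    arrs = session_arrays(session)
    args = (arrs["actions_self"], arrs["actions_other"], arrs["outcomes"],
            arrs["is_causality"], arrs["probe_resp"], arrs["task_start"])
    flags = (spec.use_other_likelihood, spec.report_form == "lcr",
             spec.mirror_update)

    def loglik_natural(params: MABCParams) -> float:
        return mabc_session_loglik(
            *args, params.a_self, params.a_other, params.bias_pos,
            params.bias_neg, params.beta0, params.tau, params.theta,
            params.beta_con, *flags)[0]

    if d == 0:
        params = untransform_params(np.empty(0), free, fixed)
        ll = loglik_natural(params)
        return FitResult(spec.label, free, np.empty(0), params, ll,
                         np.empty((0, 0)), ll, 0, True)

    means = np.array([prior_spec[n].mean for n in free])
    variances = np.array([prior_spec[n].variance for n in free])
    log_norm = -0.5 * np.sum(np.log(2.0 * np.pi * variances))

    def neg_log_joint(x: np.ndarray) -> float:
        params = untransform_params(x, free, fixed)
        ll = loglik_natural(params)
        lp = log_norm - 0.5 * np.sum((x - means) ** 2 / variances)
        val = -(ll + lp)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    x0s = [means] + [means + rng.normal(0.0, 1.0, size=d)
                     for _ in range(max(0, n_restarts - 1))]
    bounds = [_BOUNDS[TRANSFORMS[n]] for n in free]
    x, f, converged, used = _map_optimize(neg_log_joint, x0s, bounds)
    H = finite_difference_hessian(neg_log_joint, x)
    try:
        lme, ridge = laplace_evidence(-f, H)
    except EvidenceError:
        lme, ridge, converged = -np.inf, True, False
    return FitResult(spec.label, free, x, untransform_params(x, free, fixed),
                     -f, H, lme, used, converged, ridge)


def fit_population(sessions: Sequence[SessionLog],
                   specs: Sequence[ModelSpec | str],
                   prior_spec: Optional[PriorSpec] = None,
                   seed: int = 0, n_restarts: int = 10
                   ) -> tuple[pd.DataFrame, dict]:
    """Fit every model to every session; LME matrix subjects x models.

    Per-fit seeds derive deterministically from (seed, subject, model), so
    results do not depend on execution order.
    """
    specs = [get_spec(s) if isinstance(s, str) else s for s in specs]
    labels = [s.label for s in specs]
    lme = np.empty((len(sessions), len(specs)))
    fits: dict[tuple[int, str], FitResult] = {}
    for i, session in enumerate(sessions):
        for j, spec in enumerate(specs):
            sub_seed = int(np.random.SeedSequence(
                [seed, i, j]).generate_state(1)[0] % (2 ** 31))
            fr = map_fit(session, spec, prior_spec, n_restarts, sub_seed)
            lme[i, j] = fr.lme
            fits[(i, spec.label)] = fr
    frame = pd.DataFrame(lme, columns=labels,
                         index=[f"subject_{i}" for i in range(len(sessions))])
    return frame, fits


def fit_rw_mle(actions: np.ndarray, outcomes: np.ndarray,
               n_restarts: int = 5, seed: int = 0
               ) -> tuple[float, float, float]:
    """Maximum-likelihood fit of a two-parameter RW softmax model.

    Returns (learning_rate, inverse_temperature, loglik). Used to check
    that the simulated partner's behavior identifies its generating
    parameters.
    """
    a = np.asarray(actions, dtype=np.int64)
    o = np.asarray(outcomes, dtype=np.int64)

    def nll(x):
        lr = expit(x[0])
        beta = np.exp(x[1])
        val = -rw_loglik(a, o, lr, beta)
        return val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    x0s = [np.zeros(2)] + [rng.normal(0.0, 1.0, size=2)
                           for _ in range(max(0, n_restarts - 1))]
    x, f, _, _ = _map_optimize(nll, x0s, [(-16, 16), (-10, 10)])
    return float(expit(x[0])), float(np.exp(x[1])), -f
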