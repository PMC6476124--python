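"""Individualized dynamic prediction of graft-failure probability.

Given a fitted joint model and one subject's creatinine history up to a
landmark time s (with the subject event-free at s), the posterior class
probabilities at the landmark are

    pi_g(s)  propto  pi_g(x_c) * f(Y(<=s) | g) * S_g(s | x_s),

and the predicted probability of graft failure in (s, t] is the mixture
of class-conditional failure probabilities

    P(s, t) = sum_g pi_g(s) * [1 - S_g(t | x_s) / S_g(s | x_s)].

Confidence bands are Monte-Carlo: parameter vectors are drawn from the
asymptotic normal of the estimates in the unconstrained space, the curve
is recomputed per draw, and pointwise 2.5/50/97.5 percentiles are
reported (the median is the central curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Optional

import numpy as np

from .data import FitResult, JointModelParams, SubjectProfile
from .estimation import ParamPacker
from .latent import longitudinal_loglik_given_class, membership_probs
from .survival import survival_given_class


@dataclass
class RiskCurve:
    """Predicted failure-probability curve from a landmark time."""

    landmark: float
    grid: np.ndarray
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    point: np.ndarray  # plug-in curve at the point estimates
    n_draws: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        for name in ("median", "lower95", "upper95", "point"):
            a = getattr(self, name)
            if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(np.diff(self.median) < -1e-10):
            raise ValueError("median curve must be nondecreasing")
        if np.any(self.lower95 > self.median + 1e-10) or np.any(
            self.median > self.upper95 + 1e-10
        ):
            raise ValueError("band must bracket the median")


def posterior_class_at_landmark(
    params_or_fit,
    t: np.ndarray,
    y: np.ndarray,
    profile: SubjectProfile,
    s: float,
) -> np.ndarray:
    """Posterior class probabilities given data observed up to s.

    Conditions on the creatinine history at times <= s, on the baseline
    covariates, and on being event-free at s.  With no measurement
    before s, falls back to covariate-only membership with a warning.
    """
    p: JointModelParams = (
        params_or_fit.params if isinstance(params_or_fit, FitResult) else params_or_fit
    )
    G = p.n_classes
    if G == 1:
        return np.ones(1)
    t = np.asarray(t, float).ravel()
    y = np.asarray(y, float).ravel()
    keep = t <= s + 1e-12
    t, y = t[keep], y[keep]
    x_s = profile.hazard_covariates()
    logw = np.log(membership_probs(p.xi, profile.membership_covariates(), G))
    if t.size == 0:
        warnings.warn(
            f"subject {profile.subject_id}: no measurements at or before the "
            f"landmark {s}; using covariate-only class membership",
            stacklevel=2,
        )
    for g in range(G):
        if t.size:
            logw[g] += longitudinal_loglik_given_class(
                t, y, p.beta[g], p.B, p.sigma, p.link
            )
        surv = survival_given_class(s, p.zeta[g], p.delta, x_s) / max(
            float(survival_given_class(profile.entry_time, p.zeta[g], p.delta, x_s)),
            1e-300,
        )
        logw[g] += np.log(max(float(surv), 1e-300))
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _conditional_failure(
    p: JointModelParams, post: np.ndarray, x_s: np.ndarray, s: float, grid: np.ndarray
) -> np.ndarray:
    """P(s, t) = sum_g pi_g(s) [1 - S_g(t|x)/S_g(s|x)] over the grid."""
    out = np.zeros_like(np.asarray(grid, float))
    for g in range(p.n_classes):
        Ss = float(survival_given_class(s, p.zeta[g], p.delta, x_s))
        St = survival_given_class(grid, p.zeta[g], p.delta, x_s)
        out = out + post[g] * (1.0 - St / max(Ss, 1e-300))
    return np.clip(out, 0.0, 1.0)


def predict_failure_probability(
    fit: FitResult,
    profile: SubjectProfile,
    t: np.ndarray,
    y: np.ndarray,
    s: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Plug-in predicted failure-probability curve at the point estimates."""
    grid = np.asarray(grid, float)
    if np.any(grid < s):
        raise ValueError("prediction grid must satisfy t >= s")
    post = posterior_class_at_landmark(fit, t, y, profile, s)
    return _conditional_failure(fit.params, post, profile.hazard_covariates(), s, grid)


def risk_curve_with_ci(
    fit: FitResult,
    profile: SubjectProfile,
    t: np.ndarray,
    y: np.ndarray,
    s: float,
    grid: np.ndarray,
    n_draws: int = 500,
    seed: int = 0,
) -> RiskCurve:
    """Monte-Carlo 95% band for the predicted failure-probability curve.

    Draws parameter vectors from Normal(theta_hat, vcov) in the
    unconstrained space and recomputes the curve per draw; deterministic
    given ``seed``.  With no usable variance matrix the plug-in curve is
    returned with the band collapsed onto it (flagged via n_draws=0).
    """
    grid = np.asarray(grid, float)
    point = predict_failure_probability(fit, profile, t, y, s, grid)
    if fit.vcov is None:
        warnings.warn("fit has no variance matrix; confidence band unavailable")
        return RiskCurve(s, grid, point, point, point, point, 0, seed)
    packer = ParamPacker.for_params(fit.params)
    theta_hat = packer.pack(fit.params)
    vcov = 0.5 * (fit.vcov + fit.vcov.T)
    rng = np.random.default_rng(seed)
    # eigen decomposition tolerates the PSD-deficient case (vcov -> 0)
    w, V = np.linalg.eigh(vcov)
    root = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    x_s = profile.hazard_covariates()
    curves = np.empty((n_draws, grid.size))
    for d in range(n_draws):
        theta = theta_hat + root @ rng.standard_normal(theta_hat.size)
        try:
            p_d = packer.unpack(theta)
            post = posterior_class_at_landmark(p_d, t, y, profile, s)
            curves[d] = _conditional_failure(p_d, post, x_s, s, grid)
        except (ValueError, np.linalg.LinAlgError):
            curves[d] = point
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    med = np.maximum.accumulate(med)  # guard float noise; draws are monotone
    lo = np.minimum(lo, med)
    hi = np.maximum(hi, med)
    return RiskCurve(s, grid, med, lo, hi, point, n_draws, seed)


def repredict_after_event_update(
    fit: FitResult,
    profile: SubjectProfile,
    t: np.ndarray,
    y: np.ndarray,
    s: float,
    updates: dict,
    grid: np.ndarray | None = None,
    n_draws: int = 500,
    seed: int = 0,
) -> RiskCurve:
    """Recompute the risk curve after dnDSA and/or acute-rejection onset.

    ``updates`` may set ``dndsa``/``dndsa_time`` and ``acute_rejection``/
    ``ar_time``; the landmark moves to the latest onset time if it is
    beyond s, and the curve is recomputed conditional on being event-free
    at the new landmark with the updated hazard covariates.
    """
    new_profile = dc_replace(profile, **updates)
    s_new = s
    for key in ("dndsa_time", "ar_time"):
        v = getattr(new_profile, key)
        if v is not None:
            s_new = max(s_new, float(v))
    if grid is None:
        grid = np.linspace(s_new, 10.0, 50)
    else:
        grid = np.asarray(grid, float)
        grid = grid[grid >= s_new]
    return risk_curve_with_ci(
        fit, new_profile, t, y, s_new, grid, n_draws=n_draws, seed=seed
    )
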