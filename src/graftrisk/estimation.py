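"""Joint likelihood, maximum-likelihood estimation, and model criteria.

The joint latent class model combines three submodels: multinomial
logistic class membership, a class-specific mixed model for transformed
creatinine, and a class-specific Weibull proportional-hazards model for
graft failure.  The individual likelihood is the mixture

    L_i = sum_g pi_ig * f(Y_i | g) * L_surv(T_i, E_i | g),

maximized directly (no EM) over an unconstrained reparametrization by
quasi-Newton with central-difference numeric gradients.  Positivity
constraints (Weibull parameters, spline weights) are enforced by squaring
unconstrained parameters; the random-effect covariance is parametrized by
its Cholesky factor; the residual SD is fixed at 1 on the transformed
scale and the link intercept at 0 for identifiability.

Class labels are ordered post hoc by the fitted latent mean at 18 months
(ascending), so class 1 is always the best-kidney-function class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .data import Cohort, FitResult, JointModelParams, HAZARD_COVARIATES
from .latent import LOG2PI, membership_logprobs_matrix
from .links import LinkSpec, make_nodes, n_ispline_basis, transform
from .survival import event_loglik_matrix, weibull_cumhaz, weibull_loghaz

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Estimation settings.

    Defaults mirror desk-scale use: 10 starting points (the first from
    k-means moments, the rest alternative clusterings and perturbations),
    convergence on relative log-likelihood change 1e-8 / gradient 1e-4 /
    parameter change 1e-6, at most 600 quasi-Newton iterations per start.
    """

    n_starts: int = 10
    maxiter: int = 600
    lbfgs_memory: int = 30
    loglik_tol: float = 1e-8
    grad_tol: float = 1e-4
    param_tol: float = 1e-6
    seed: int = 0
    n_nodes: int = 5
    node_mode: str = "equidistant"
    compute_vcov: bool = True
    grad_step: float = 1e-5
    hess_step: float = 1e-4
    sigma: float = 1.0
    start_spread: float = 0.3


# ---------------------------------------------------------------------------
# prepared cohort arrays
# ---------------------------------------------------------------------------


class _Prepared:
    """Cohort unpacked into arrays, grouped by measurement count."""

    def __init__(self, cohort: Cohort):
        subs = cohort.subjects
        self.subject_ids = [s.subject_id for s in subs]
        self.n = len(subs)
        self.X_c = np.array([s.membership_covariates() for s in subs], float)
        self.X_s = np.array([s.hazard_covariates() for s in subs], float)
        self.times = np.array([s.event_time for s in subs], float)
        self.entries = np.array([s.entry_time for s in subs], float)
        self.events = np.array([s.event for s in subs], int)
        meas = cohort.measurements.sort_values(["subject_id", "t"])
        by_id = {
            str(sid): (g["t"].to_numpy(float), g["y"].to_numpy(float))
            for sid, g in meas.groupby("subject_id", sort=False)
        }
        per = [by_id[s.subject_id] for s in subs]
        buckets: dict[int, list[int]] = {}
        for i, (t, _) in enumerate(per):
            buckets.setdefault(len(t), []).append(i)
        # per measurement-count group: subject indices, times, values,
        # random-effect design Z=(1,t) and its Gram matrix Z'Z (theta-free)
        self.groups: list[tuple[np.ndarray, ...]] = []
        for k in sorted(buckets):
            idx = np.array(buckets[k], int)
            T = np.array([per[i][0] for i in idx])
            Y = np.array([per[i][1] for i in idx])
            Z = np.stack([np.ones_like(T), T], axis=-1)
            ZtZ = np.einsum("mki,mkj->mij", Z, Z)
            self.groups.append((idx, T, Y, Z, ZtZ))
        self.all_y = meas["y"].to_numpy(float)
        self.all_t = meas["t"].to_numpy(float)


# ---------------------------------------------------------------------------
# unconstrained parametrization
# ---------------------------------------------------------------------------


@dataclass
class ParamPacker:
    """Bijection between JointModelParams and the unconstrained vector.

    Layout: xi | beta | chol(B) | link | sqrt(zeta) | delta.  sigma and
    the link intercept are fixed, not packed.
    """

    G: int
    n_membership_cov: int
    link_family: str
    nodes: Optional[np.ndarray]
    y_range: tuple[float, float]
    sigma: float = 1.0

    @property
    def n_link(self) -> int:
        if self.link_family == "linear":
            return 1
        if self.link_family == "beta_cdf":
            return 3
        return n_ispline_basis(self.nodes)

    @property
    def n_params(self) -> int:
        G, K = self.G, self.n_membership_cov
        return (G - 1) * (1 + K) + 3 * G + 3 + self.n_link + 2 * G + 5

    def pack(self, p: JointModelParams) -> np.ndarray:
        G = self.G
        parts = [p.xi.ravel(), p.beta.ravel()]
        L = np.linalg.cholesky(p.B + 1e-12 * np.eye(2))
        parts.append(np.array([L[0, 0], L[1, 0], L[1, 1]]))
        eta = p.link.eta
        if self.link_family == "linear":
            parts.append(np.sqrt([eta[1]]))
        elif self.link_family == "beta_cdf":
            parts.append(np.sqrt(eta[1:4]))
        else:
            parts.append(np.sqrt(eta[1:]))
        parts.append(np.sqrt(p.zeta.ravel()))
        parts.append(p.delta.ravel())
        theta = np.concatenate(parts)
        assert theta.size == self.n_params
        return theta

    def unpack(self, theta: np.ndarray) -> JointModelParams:
        theta = np.asarray(theta, float).ravel()
        G, K = self.G, self.n_membership_cov
        pos = 0

        def take(k: int) -> np.ndarray:
            nonlocal pos
            out = theta[pos : pos + k]
            pos += k
            return out

        xi = take((G - 1) * (1 + K)).reshape(G - 1, 1 + K)
        beta = take(3 * G).reshape(G, 3)
        l11, l21, l22 = take(3)
        Lc = np.array([[l11, 0.0], [l21, l22]])
        B = Lc @ Lc.T
        u = take(self.n_link)
        if self.link_family == "linear":
            eta = np.array([0.0, max(u[0] ** 2, 1e-12)])
        elif self.link_family == "beta_cdf":
            eta = np.concatenate([[0.0], np.maximum(u**2, 1e-8)])
        else:
            eta = np.concatenate([[0.0], np.maximum(u**2, 1e-12)])
        link = LinkSpec(self.link_family, self.nodes, eta, self.y_range)
        zeta = np.maximum(take(2 * G).reshape(G, 2) ** 2, 1e-12)
        delta = take(5)
        return JointModelParams(
            n_classes=G,
            xi=xi,
            beta=beta,
            B=B,
            sigma=self.sigma,
            link=link,
            zeta=zeta,
            delta=delta,
        )

    @classmethod
    def for_params(cls, p: JointModelParams) -> "ParamPacker":
        return cls(
            G=p.n_classes,
            n_membership_cov=p.xi.shape[1] - 1 if p.n_classes > 1 else 1,
            link_family=p.link.family,
            nodes=p.link.nodes,
            y_range=p.link.y_range,
            sigma=p.sigma,
        )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _loglik_components(
    p: JointModelParams, prep: _Prepared
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log pi, longitudinal, survival) per subject and class."""
    G = p.n_classes
    ll_long = np.zeros((prep.n, G))
    sig2 = p.sigma**2
    Bm = p.B / sig2
    for idx, T, Y, Z, ZtZ in prep.groups:
        m, k = T.shape
        h, logjac = transform(Y, p.link)
        # V = sigma^2 I + Z B Z' handled via the rank-2 Woodbury identity:
        # all per-subject linear algebra reduces to 2x2 matrices
        M = np.eye(2) + ZtZ @ Bm  # (m, 2, 2); eigenvalues >= 1, always invertible
        detM = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        logdet = k * np.log(sig2) + np.log(detM)
        Minv = (
            np.stack(
                [
                    np.stack([M[:, 1, 1], -M[:, 0, 1]], axis=-1),
                    np.stack([-M[:, 1, 0], M[:, 0, 0]], axis=-1),
                ],
                axis=1,
            )
            / detM[:, None, None]
        )
        W = Bm[None] @ Minv  # B (I + Z'Z B)^{-1}, push-through identity
        jac = logjac.sum(axis=1)
        for g in range(G):
            b0, b1, b2 = p.beta[g]
            mu = b0 + b1 * T + b2 * T * T
            d = h - mu
            dtd = np.einsum("mk,mk->m", d, d)
            Ztd = np.einsum("mki,mk->mi", Z, d)
            quad = (dtd - np.einsum("mi,mij,mj->m", Ztd, W, Ztd)) / sig2
            ll_long[idx, g] = -0.5 * (k * LOG2PI + logdet + quad) + jac
    ll_surv = event_loglik_matrix(
        prep.times, prep.entries, prep.events, prep.X_s, p.zeta, p.delta
    )
    logpi = membership_logprobs_matrix(p.xi, prep.X_c, G)
    return logpi, ll_long, ll_surv


def _loglik_from_prepared(p: JointModelParams, prep: _Prepared) -> float:
    logpi, ll_long, ll_surv = _loglik_components(p, prep)
    per_subject = logsumexp(logpi + ll_long + ll_surv, axis=1)
    total = per_subject.sum()
    return float(total) if np.isfinite(total) else -np.inf


def joint_loglik(params: JointModelParams, cohort: Cohort) -> float:
    """Joint log-likelihood of the cohort under ``params``.

    Raises ValueError naming the first subject whose contribution is not
    finite (e.g. a measurement far outside the link support).
    """
    prep = _Prepared(cohort)
    logpi, ll_long, ll_surv = _loglik_components(params, prep)
    per_subject = logsumexp(logpi + ll_long + ll_surv, axis=1)
    bad = np.flatnonzero(~np.isfinite(per_subject))
    if bad.size:
        raise ValueError(
            f"non-finite likelihood contribution for subject "
            f"{prep.subject_ids[bad[0]]!r}"
        )
    return float(per_subject.sum())


# ---------------------------------------------------------------------------
# numeric derivatives
# ---------------------------------------------------------------------------


def numeric_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-5
) -> np.ndarray:
    """Central-difference gradient with relative steps."""
    x = np.asarray(x, float)
    g = np.empty_like(x)
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def numeric_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, rel_step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian (symmetric)."""
    x = np.asarray(x, float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------


def _initial_link(prep: _Prepared, family: str, config: FitConfig) -> LinkSpec:
    y = prep.all_y
    y_range = (float(y.min()), float(y.max()))
    # within-subject residual SD around per-subject linear trends; the
    # pooled residual would also absorb between-class and between-subject
    # variance and put the initial transformed scale far off
    sq, cnt = 0.0, 0
    for idx, T, Y, Z, ZtZ in prep.groups:
        tbar = T.mean(axis=1, keepdims=True)
        ybar = Y.mean(axis=1, keepdims=True)
        denom = np.maximum(((T - tbar) ** 2).sum(axis=1, keepdims=True), 1e-12)
        slope = (((T - tbar) * (Y - ybar)).sum(axis=1, keepdims=True)) / denom
        resid = Y - ybar - slope * (T - tbar)
        sq += float((resid**2).sum())
        cnt += resid.size
    resid_sd = max(np.sqrt(sq / max(cnt - 2 * prep.n, 1)), 1e-3)
    if family == "linear":
        return LinkSpec("linear", None, np.array([0.0, resid_sd]), y_range)
    if family == "beta_cdf":
        scale = (y_range[1] - y_range[0]) / resid_sd
        return LinkSpec("beta_cdf", None, np.array([0.0, scale, 2.0, 2.0]), y_range)
    mode = "equidistant" if family == "ispline_equidistant" else "quantile"
    nodes = make_nodes(y, config.n_nodes, mode)
    L = n_ispline_basis(nodes)
    total = (y_range[1] - y_range[0]) / resid_sd
    eta = np.concatenate([[0.0], np.full(L, total / L)])
    return LinkSpec(family, nodes, eta, y_range)


def _subject_features(prep: _Prepared, link: LinkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject OLS intercept and slope on the transformed scale."""
    feats = np.zeros((prep.n, 2))
    for idx, T, Y, Z, ZtZ in prep.groups:
        h, _ = transform(Y, link)
        tbar = T.mean(axis=1, keepdims=True)
        hbar = h.mean(axis=1, keepdims=True)
        denom = np.maximum(((T - tbar) ** 2).sum(axis=1), 1e-12)
        slope = ((T - tbar) * (h - hbar)).sum(axis=1) / denom
        feats[idx, 0] = (hbar.ravel() - slope * tbar.ravel())
        feats[idx, 1] = slope
    return feats[:, 0], feats[:, 1]


def _kmeans(X: np.ndarray, G: int, rng: np.random.Generator, n_iter: int = 60) -> np.ndarray:
    """Small seeded k-means (k-means++ init) returning cluster labels."""
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(G - 1):
        d2 = np.min(
            [((X - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        probs = d2 / max(d2.sum(), 1e-12)
        centers.append(X[rng.choice(n, p=probs)])
    C = np.array(centers)
    labels = np.zeros(n, int)
    for _ in range(n_iter):
        d = ((X[:, None, :] - C[None]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels) and _ > 0:
            break
        labels = new
        for g in range(G):
            if np.any(labels == g):
                C[g] = X[labels == g].mean(axis=0)
    return labels


def _initial_params(
    prep: _Prepared,
    G: int,
    link: LinkSpec,
    config: FitConfig,
    seed_offset: int = 0,
    slope_weight: float = 1.0,
    n_restarts: int = 8,
) -> JointModelParams:
    """Data-driven start: k-means on per-subject (intercept, slope)
    features, then class-wise trajectory/survival moment estimates.

    ``slope_weight`` rescales the slope feature so alternative starts
    emphasize either level or progression differences between classes.
    """
    h_all, _ = transform(prep.all_y, link)
    ints, slopes = _subject_features(prep, link)
    feats = np.column_stack([ints, slopes])
    feats_std = (feats - feats.mean(axis=0)) / np.maximum(feats.std(axis=0), 1e-12)
    feats_std[:, 1] *= slope_weight
    if G > 1:
        rng = np.random.default_rng(config.seed + 1 + seed_offset)
        best_labels, best_inertia = None, np.inf
        for _ in range(max(n_restarts, 1)):
            labels = _kmeans(feats_std, G, rng)
            C = np.array(
                [
                    feats_std[labels == g].mean(axis=0)
                    if np.any(labels == g)
                    else feats_std.mean(axis=0)
                    for g in range(G)
                ]
            )
            inertia = float(((feats_std - C[labels]) ** 2).sum())
            if inertia < best_inertia:
                best_labels, best_inertia = labels, inertia
        labels = best_labels
    else:
        labels = np.zeros(prep.n, int)
    # order provisional clusters by mean feature level at 18 months
    level = np.array(
        [
            feats[labels == g, 0].mean() + 1.5 * feats[labels == g, 1].mean()
            if np.any(labels == g)
            else np.inf
            for g in range(G)
        ]
    )
    relabel = np.argsort(np.argsort(level))
    labels = relabel[labels]

    beta = np.zeros((G, 3))
    zeta = np.zeros((G, 2))
    resid_int = np.zeros(prep.n)
    resid_slope = np.zeros(prep.n)
    for g in range(G):
        mask = labels == g
        if not mask.any():
            beta[g] = [h_all.mean(), 0.0, 0.0]
            zeta[g] = [0.05, 1.0]
            continue
        rows_X, rows_h = [], []
        for idx, T, Y, Z, ZtZ in prep.groups:
            sel = mask[idx]
            if not sel.any():
                continue
            h, _ = transform(Y[sel], link)
            t = T[sel].ravel()
            rows_X.append(np.column_stack([np.ones_like(t), t, t * t]))
            rows_h.append(h.ravel())
        Xg = np.vstack(rows_X)
        hg = np.concatenate(rows_h)
        beta[g], *_ = np.linalg.lstsq(Xg, hg, rcond=None)
        n_ev = max(int(prep.events[mask].sum()), 1)
        persontime = float(np.sum(prep.times[mask] - prep.entries[mask]))
        zeta[g] = [n_ev / max(persontime, 1e-6), 1.0]
        resid_int[mask] = ints[mask] - ints[mask].mean()
        resid_slope[mask] = slopes[mask] - slopes[mask].mean()
    B = np.diag(
        [
            max(0.8 * float(np.var(resid_int)), 1e-4),
            max(0.5 * float(np.var(resid_slope)), 1e-4),
        ]
    )
    props = np.maximum(np.bincount(labels, minlength=G) / prep.n, 1.0 / (4 * prep.n))
    xi = np.zeros((G - 1, 1 + prep.X_c.shape[1]))
    if G > 1:
        xi[:, 0] = np.log(props[:-1] / props[-1])
    return JointModelParams(
        n_classes=G,
        xi=xi,
        beta=beta,
        B=B,
        sigma=config.sigma,
        link=link,
        zeta=zeta,
        delta=np.zeros(5),
    )


def _relabel(p: JointModelParams) -> tuple[JointModelParams, np.ndarray]:
    """Order classes by latent mean at 18 months, ascending."""
    t18 = 1.5
    means = p.beta[:, 0] + p.beta[:, 1] * t18 + p.beta[:, 2] * t18**2
    perm = np.argsort(means, kind="stable")
    if np.array_equal(perm, np.arange(p.n_classes)):
        return p, perm
    full_xi = np.vstack([p.xi, np.zeros((1, p.xi.shape[1]))])
    new_full = full_xi[perm] - full_xi[perm[-1]]
    q = p.copy()
    q.beta = p.beta[perm]
    q.zeta = p.zeta[perm]
    q.xi = new_full[:-1]
    return q, perm


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(
    cohort: Cohort,
    G: int,
    link_family: str = "ispline_equidistant",
    config: FitConfig | None = None,
    init: JointModelParams | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the G-class joint model.

    Runs ``config.n_starts`` initializations (the first from data
    moments, the rest seeded perturbations) and returns the best
    converged solution, with the variance matrix from the inverted
    numeric observed information when ``config.compute_vcov``.
    """
    config = config or FitConfig()
    if not 1 <= G <= 5:
        raise ValueError("G must lie in 1..5")
    prep = _Prepared(cohort)
    link0 = init.link if init is not None else _initial_link(prep, link_family, config)
    base = init if init is not None else _initial_params(prep, G, link0, config)
    packer = ParamPacker(
        G=G,
        n_membership_cov=prep.X_c.shape[1],
        link_family=link_family,
        nodes=link0.nodes,
        y_range=link0.y_range,
        sigma=config.sigma,
    )

    def neg(theta: np.ndarray) -> float:
        try:
            val = _loglik_from_prepared(packer.unpack(theta), prep)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        return -val if np.isfinite(val) else 1e12

    def neg_grad(theta: np.ndarray) -> np.ndarray:
        return numeric_gradient(neg, theta, config.grad_step)

    rng = np.random.default_rng(config.seed)
    theta0 = packer.pack(base)
    best = None
    diagnostics = []
    for s in range(max(config.n_starts, 1)):
        if s == 0:
            start = theta0.copy()
        elif s % 2 == 1 and G > 1:
            # alternative class structure: fresh k-means with a different
            # emphasis on trajectory slope vs level
            sw = float(np.exp(rng.normal(0.0, 0.8)))
            alt = _initial_params(
                prep, G, link0, config, seed_offset=101 * s, slope_weight=sw,
                n_restarts=1,
            )
            start = packer.pack(alt)
            start = start + rng.normal(0.0, 0.02, start.size) * np.maximum(
                1.0, np.abs(start)
            )
        else:
            start = theta0 + rng.normal(
                0.0, config.start_spread, theta0.size
            ) * np.maximum(1.0, np.abs(theta0)) * 0.5
        try:
            res = optimize.minimize(
                neg,
                start,
                jac=neg_grad,
                method="L-BFGS-B",
                options={
                    "maxiter": config.maxiter,
                    "ftol": config.loglik_tol,
                    "gtol": config.grad_tol,
                    "maxcor": config.lbfgs_memory,
                },
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": s, "error": str(exc)})
            continue
        diagnostics.append(
            {
                "start": s,
                "loglik": -float(res.fun),
                "n_iter": int(res.nit),
                "status": int(res.status),
                "message": str(res.message),
            }
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"no start converged; diagnostics: {diagnostics}")

    params = packer.unpack(best.x)
    params, perm = _relabel(params)
    theta_hat = packer.pack(params)
    loglik = _loglik_from_prepared(params, prep)
    n_params = packer.n_params
    N = prep.n
    criteria = {
        "AIC": float(-2.0 * loglik + 2.0 * n_params),
        "BIC": float(-2.0 * loglik + n_params * np.log(N)),
    }

    vcov = None
    vcov_ok = False
    if config.compute_vcov:
        H = numeric_hessian(lambda th: -neg(th), theta_hat, config.hess_step)
        info = -H
        try:
            w = np.linalg.eigvalsh(0.5 * (info + info.T))
            if w.min() > 0:
                vcov = np.linalg.inv(0.5 * (info + info.T))
                vcov_ok = True
            else:
                vcov = np.linalg.pinv(0.5 * (info + info.T))
                logger.warning(
                    "observed information not positive definite "
                    "(min eigenvalue %.3g); vcov from pseudo-inverse", w.min()
                )
        except np.linalg.LinAlgError:
            vcov = None

    logpi, ll_long, ll_surv = _loglik_components(params, prep)
    joint = logpi + ll_long + ll_surv
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    modal = post.argmax(axis=1)

    grad = numeric_gradient(neg, theta_hat, config.grad_step)
    result = FitResult(
        params=params,
        loglik=loglik,
        vcov=vcov,
        n_params=n_params,
        criteria=criteria,
        posterior=post,
        modal_class=modal,
        convergence={
            "status": "converged" if best.success else "maxiter",
            "n_iter": int(best.nit),
            "grad_norm": float(np.abs(grad).max()),
            "starts_tried": len(diagnostics),
            "seed": config.seed,
            "vcov_ok": vcov_ok,
            "class_permutation": perm.tolist(),
        },
        meta={
            "n_subjects": N,
            "link_family": link_family,
            "membership_covariates": ["donor_age_ge60"],
            "hazard_covariates": list(HAZARD_COVARIATES),
            "subject_ids": prep.subject_ids,
        },
    )
    return result


@dataclass
class SelectionResult:
    table: pd.DataFrame
    chosen_G: int
    fits: dict[int, FitResult] = field(default_factory=dict)


def select_n_classes(
    cohort: Cohort,
    G_range: Iterable[int],
    link_family: str = "ispline_equidistant",
    config: FitConfig | None = None,
) -> SelectionResult:
    """Fit each candidate G and choose the minimal-BIC model."""
    rows = []
    fits: dict[int, FitResult] = {}
    for G in G_range:
        f = fit(cohort, G, link_family=link_family, config=config)
        fits[G] = f
        rows.append(
            {
                "G": G,
                "loglik": f.loglik,
                "n_params": f.n_params,
                "BIC": f.criteria["BIC"],
                "AIC": f.criteria["AIC"],
            }
        )
    table = pd.DataFrame(rows)
    chosen = int(table.loc[table["BIC"].idxmin(), "G"])
    return SelectionResult(table=table, chosen_G=chosen, fits=fits)


def discretized_aic(fit_result: FitResult, cohort: Cohort, n_bins: int = 30) -> float:
    """Discretized Akaike criterion for link-family comparison.

    Each continuous measurement's density contribution is replaced by the
    model-implied probability of its discretization bin (bin edges at
    empirical creatinine quantiles, outer bins open-ended), which makes
    the longitudinal likelihood comparable across link families.  Bin
    probabilities use the class-conditional marginal distribution of each
    measurement; empty bins are merged into their neighbours.
    """
    p = fit_result.params
    prep = _Prepared(cohort)
    G = p.n_classes
    edges = np.quantile(prep.all_y, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < n_bins + 1:
        logger.warning(
            "merged %d empty/duplicate bins", n_bins + 1 - edges.size
        )
    h_edges, _ = transform(edges, p.link)
    h_edges = np.concatenate([[-np.inf], h_edges[1:-1], [np.inf]])
    logpi = membership_logprobs_matrix(p.xi, prep.X_c, G)
    disc = np.zeros(prep.n)
    for idx, T, Y, Z, ZtZ in prep.groups:
        svar = np.einsum("mki,ij,mkj->mk", Z, p.B, Z) + p.sigma**2
        sd = np.sqrt(svar)
        bins = np.clip(np.searchsorted(edges, Y, side="right") - 1, 0, edges.size - 2)
        lo = h_edges[bins]
        hi = h_edges[bins + 1]
        ll_g = np.empty((T.shape[0], G))
        for g in range(G):
            b0, b1, b2 = p.beta[g]
            mu = b0 + b1 * T + b2 * T * T
            prob = stats.norm.cdf((hi - mu) / sd) - stats.norm.cdf((lo - mu) / sd)
            ll_g[:, g] = np.log(np.maximum(prob, 1e-300)).sum(axis=1)
        disc[idx] = logsumexp(logpi[idx] + ll_g, axis=1)
    return float(-2.0 * disc.sum() + 2.0 * fit_result.n_params)


def posterior_classification(
    fit_result: FitResult, cohort: Cohort
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Posterior class probabilities, modal classes, and the
    mean-posterior-probability-by-assigned-class discrimination table."""
    prep = _Prepared(cohort)
    logpi, ll_long, ll_surv = _loglik_components(fit_result.params, prep)
    joint = logpi + ll_long + ll_surv
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    modal = post.argmax(axis=1)
    rows = []
    for g in range(fit_result.params.n_classes):
        mask = modal == g
        rows.append(
            {
                "class": g + 1,
                "n_assigned": int(mask.sum()),
                "mean_posterior": float(post[mask, g].mean()) if mask.any() else np.nan,
            }
        )
    return post, modal, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------


def _univariate_weibull_wald(
    times: np.ndarray, entries: np.ndarray, events: np.ndarray, x: np.ndarray
) -> tuple[float, float, float]:
    """Wald test of one covariate in a Weibull PH model (coef, se, p)."""

    def neg(theta: np.ndarray) -> float:
        z1, z2 = theta[0] ** 2 + 1e-12, theta[1] ** 2 + 1e-12
        lp = theta[2] * x
        cum = (
            weibull_cumhaz(times, (z1, z2))
            - np.where(entries > 0, weibull_cumhaz(entries, (z1, z2)), 0.0)
        ) * np.exp(lp)
        ll = -cum
        ev = events.astype(bool)
        ll = ll + np.where(ev, weibull_loghaz(times, (z1, z2)) + lp, 0.0)
        val = ll.sum()
        return -val if np.isfinite(val) else 1e12

    rate = max(events.sum(), 1) / np.sum(times - entries)
    res = optimize.minimize(neg, np.array([np.sqrt(rate), 1.0, 0.0]), method="BFGS")
    H = numeric_hessian(lambda th: -neg(th), res.x)
    try:
        v = np.linalg.inv(-H)
        se = float(np.sqrt(max(v[2, 2], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    coef = float(res.x[2])
    p = 2.0 * stats.norm.sf(abs(coef) / se) if se and np.isfinite(se) and se > 0 else np.nan
    return coef, se, p


def screen_covariates(
    cohort: Cohort,
    candidates: dict[str, Sequence[float]] | None = None,
    p_threshold: float = 0.2,
) -> pd.DataFrame:
    """Univariate Weibull-PH Wald screening of candidate hazard covariates.

    Candidates passing ``p < p_threshold`` are flagged for the
    multivariate step.  The final model's covariate set
    (:data:`~graftrisk.data.HAZARD_COVARIATES`) remains available as a
    hard-wired preset independently of this screening.
    """
    prep = _Prepared(cohort)
    if candidates is None:
        candidates = {
            name: prep.X_s[:, i] for i, name in enumerate(HAZARD_COVARIATES[:4])
        }
        candidates["donor_age_ge60"] = prep.X_c[:, 0]
    rows = []
    for name, x in candidates.items():
        coef, se, p = _univariate_weibull_wald(
            prep.times, prep.entries, prep.events, np.asarray(x, float)
        )
        rows.append(
            {
                "covariate": name,
                "coef": coef,
                "se": se,
                "p_value": p,
                "selected": bool(p < p_threshold) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
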