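"""Class membership probabilities and class-specific trajectory densities.

The population is assumed to consist of G latent classes.  Membership
follows a multinomial logistic model on baseline covariates (donor age
>= 60 years by default, with the last class as reference).  Within class
g the transformed creatinine follows a linear mixed model quadratic in
time since transplantation, with a random intercept and slope shared
covariance B across classes and residual SD sigma on the transformed
scale.
"""

from __future__ import annotations

import numpy as np

from .links import LinkSpec, transform

LOG2PI = float(np.log(2.0 * np.pi))


def membership_probs(xi: np.ndarray, x_c: np.ndarray, G: int) -> np.ndarray:
    """Multinomial-logistic class probabilities for one subject.

    ``xi`` has G-1 rows (intercept + one coefficient per membership
    covariate); the last class is the reference with all coefficients 0.
    """
    if G == 1:
        return np.ones(1)
    xi = np.asarray(xi, float).reshape(G - 1, -1)
    x = np.concatenate([[1.0], np.asarray(x_c, float).ravel()])
    if xi.shape[1] != x.size:
        raise ValueError(
            f"xi has {xi.shape[1]} columns but design has {x.size} entries"
        )
    logits = np.concatenate([xi @ x, [0.0]])
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def membership_logprobs_matrix(
    xi: np.ndarray, X_c: np.ndarray, G: int
) -> np.ndarray:
    """Log class-membership probabilities for n subjects, shape (n, G)."""
    n = X_c.shape[0]
    if G == 1:
        return np.zeros((n, 1))
    xi = np.asarray(xi, float).reshape(G - 1, -1)
    design = np.column_stack([np.ones(n), X_c])
    logits = np.column_stack([design @ xi.T, np.zeros(n)])
    logits -= logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(logits).sum(axis=1, keepdims=True))
    return logits - lse


def trajectory_design(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect (1, t, t^2) and random-effect (1, t) design rows."""
    t = np.asarray(t, float)
    X = np.stack([np.ones_like(t), t, t * t], axis=-1)
    Z = np.stack([np.ones_like(t), t], axis=-1)
    return X, Z


def class_mean_trajectory(beta_g: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Latent-scale class mean mu_g(t) = b0 + b1 t + b2 t^2."""
    b0, b1, b2 = np.asarray(beta_g, float).ravel()
    t = np.asarray(t_grid, float)
    return b0 + b1 * t + b2 * t * t


def longitudinal_loglik_given_class(
    t: np.ndarray,
    y: np.ndarray,
    beta_g: np.ndarray,
    B: np.ndarray,
    sigma: float,
    link: LinkSpec,
    jitter: float = 1e-10,
) -> float:
    """Log-density of one subject's creatinine series given class g.

    The transformed series H(Y_i) is multivariate normal with mean
    ``X_i beta_g`` and covariance ``Z_i B Z_i' + sigma^2 I``; the sum of
    log-Jacobians of the link converts the density to the observed scale.
    Ridge ``jitter`` is added to the diagonal if the covariance is
    numerically singular.
    """
    t = np.asarray(t, float).ravel()
    y = np.asarray(y, float).ravel()
    if t.size == 0:
        raise ValueError("subject must have at least one measurement")
    h, logjac = transform(y, link)
    X, Z = trajectory_design(t)
    mu = X @ np.asarray(beta_g, float).ravel()
    V = Z @ np.asarray(B, float) @ Z.T + (sigma**2) * np.eye(t.size)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + jitter * np.eye(t.size))
    d = h - mu
    z = np.linalg.solve(L, d)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(
        -0.5 * (t.size * LOG2PI + logdet + z @ z) + logjac.sum()
    )
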