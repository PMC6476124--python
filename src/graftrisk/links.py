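"""Monotone link functions between observed creatinine and the latent scale.

The longitudinal submodel assumes that a monotone transformation
``H(y; eta)`` of serum creatinine follows a Gaussian linear mixed model.
Four families are available:

* ``linear``              -- affine map ``(y - a) / b``;
* ``beta_cdf``            -- rescaled regularized incomplete beta function of
                             the min-max normalized creatinine;
* ``ispline_equidistant`` -- quadratic I-splines with equidistant nodes;
* ``ispline_quantile``    -- quadratic I-splines with nodes at quantiles of
                             the creatinine distribution.

I-splines are running integrals of normalized M-splines, so positive basis
weights guarantee a monotone transformation.  During estimation positivity
is enforced by storing weights as squares of unconstrained parameters, and
the link intercept is fixed at 0 (the class intercepts of the latent
process carry the location; the residual SD fixed at 1 carries the scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special
from scipy.interpolate import BSpline

ISPLINE_DEGREE = 2  # quadratic
_MORDER = ISPLINE_DEGREE + 1

FAMILIES = ("linear", "beta_cdf", "ispline_equidistant", "ispline_quantile")


class DegenerateSupportError(ValueError):
    """All observed values identical; no transformation support."""


def make_nodes(values: Sequence[float], n_nodes: int, mode: str) -> np.ndarray:
    """Place spline nodes over the observed creatinine values.

    ``equidistant`` spaces ``n_nodes`` nodes evenly over [min, max];
    ``quantile`` places them at equally spaced quantiles (linear
    interpolation).  Boundary nodes always sit at the data min and max.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if v.size == 0 or v.min() == v.max():
        raise DegenerateSupportError("values have degenerate support")
    if mode == "equidistant":
        return np.linspace(v.min(), v.max(), n_nodes)
    if mode == "quantile":
        qs = np.linspace(0.0, 1.0, n_nodes)
        nodes = np.quantile(v, qs)
        nodes[0], nodes[-1] = v.min(), v.max()
        if np.any(np.diff(nodes) <= 0):
            raise DegenerateSupportError(
                "quantile nodes not strictly increasing; too many ties"
            )
        return nodes
    raise ValueError(f"unknown node mode {mode!r}")


def _mspline_knots(nodes: np.ndarray) -> np.ndarray:
    nodes = np.asarray(nodes, float)
    return np.concatenate(
        [np.repeat(nodes[0], _MORDER), nodes[1:-1], np.repeat(nodes[-1], _MORDER)]
    )


def n_ispline_basis(nodes: Sequence[float]) -> int:
    """Number of I-spline basis functions for the given node vector."""
    return len(nodes) - 2 + _MORDER


class _ISplineBasis:
    """Quadratic I-spline basis (and its M-spline derivative) on fixed nodes."""

    def __init__(self, nodes: Sequence[float]):
        self.nodes = np.asarray(nodes, float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        self.t = _mspline_knots(self.nodes)
        self.n_basis = n_ispline_basis(self.nodes)
        # normalization so each M-spline integrates to 1 over its support
        self._norm = np.array(
            [
                _MORDER / (self.t[l + _MORDER] - self.t[l])
                for l in range(self.n_basis)
            ]
        )
        eye = np.eye(self.n_basis)
        self._bsplines = [
            BSpline(self.t, eye[l], ISPLINE_DEGREE, extrapolate=False)
            for l in range(self.n_basis)
        ]
        self._antiderivs = [b.antiderivative() for b in self._bsplines]

    def _clamped(self, y) -> np.ndarray:
        return np.clip(np.asarray(y, float), self.nodes[0], self.nodes[-1])

    def ispline(self, y) -> np.ndarray:
        """I-spline basis values, shape (..., n_basis); each in [0, 1]."""
        yc = self._clamped(y)
        cols = [
            self._norm[l] * (self._antiderivs[l](yc) - self._antiderivs[l](self.nodes[0]))
            for l in range(self.n_basis)
        ]
        out = np.stack([np.nan_to_num(c, nan=0.0) for c in cols], axis=-1)
        # antiderivative of a clamped B-spline is flat past its support
        upper = yc[..., None] >= self.t[_MORDER : _MORDER + self.n_basis]
        full = self._norm * np.array(
            [
                self._antiderivs[l](self.t[l + _MORDER]) - self._antiderivs[l](self.nodes[0])
                for l in range(self.n_basis)
            ]
        )
        return np.where(upper, full, out)

    def mspline(self, y) -> np.ndarray:
        """M-spline basis values (derivative of the I-splines)."""
        yc = self._clamped(y)
        cols = [self._norm[l] * self._bsplines[l](yc) for l in range(self.n_basis)]
        return np.stack([np.nan_to_num(c, nan=0.0) for c in cols], axis=-1)


@dataclass
class LinkSpec:
    """Specification of one monotone transformation.

    eta layout by family:
      linear                -- (a, b): H(y) = (y - a) / b, b > 0
      beta_cdf              -- (intercept, scale, shape_a, shape_b)
      ispline_*             -- (intercept, w_1 .. w_L), all w_l > 0
    """

    family: str
    nodes: Optional[np.ndarray]
    eta: np.ndarray
    y_range: tuple[float, float]
    _basis: Optional[_ISplineBasis] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown link family {self.family!r}")
        self.eta = np.asarray(self.eta, float)
        if self.nodes is not None:
            self.nodes = np.asarray(self.nodes, float)
        if self.family.startswith("ispline"):
            if self.nodes is None:
                raise ValueError("spline families require nodes")
            L = n_ispline_basis(self.nodes)
            if self.eta.size != L + 1:
                raise ValueError(f"ispline eta needs 1 intercept + {L} weights")
            if np.any(self.eta[1:] <= 0):
                raise ValueError("I-spline weights must be > 0 (monotonicity)")
            self._basis = _ISplineBasis(self.nodes)
        elif self.family == "beta_cdf":
            if self.eta.size != 4:
                raise ValueError("beta_cdf eta is (intercept, scale, a, b)")
            if self.eta[1] <= 0 or self.eta[2] <= 0 or self.eta[3] <= 0:
                raise ValueError("beta_cdf scale and shape parameters must be > 0")
        elif self.family == "linear":
            if self.eta.size != 2:
                raise ValueError("linear eta is (a, b)")
            if self.eta[1] <= 0:
                raise ValueError("linear slope must be > 0")
        lo, hi = self.y_range
        if not hi > lo:
            raise ValueError("y_range must satisfy y_min < y_max")

    @property
    def basis(self) -> Optional[_ISplineBasis]:
        if self._basis is None and self.family.startswith("ispline"):
            self._basis = _ISplineBasis(self.nodes)
        return self._basis

    def transformed_range(self) -> tuple[float, float]:
        lo, hi = self.y_range
        h_lo, _ = transform(np.array([lo]), self)
        h_hi, _ = transform(np.array([hi]), self)
        return float(h_lo[0]), float(h_hi[0])


def linear_link(a: float, b: float, y_range: tuple[float, float]) -> LinkSpec:
    return LinkSpec("linear", None, np.array([a, b], float), y_range)


_BETA_EPS = 1e-6


def transform(y, link: LinkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``H`` to observed creatinine.

    Returns ``(h, log_jacobian)`` where ``log_jacobian = log dH/dy``.
    Values outside ``y_range`` are clamped to the boundary (the Jacobian is
    evaluated at the clamped point, where it stays positive for every
    family).
    """
    y = np.asarray(y, float)
    lo, hi = link.y_range
    if link.family == "linear":
        a, b = link.eta
        return (y - a) / b, np.full_like(y, -np.log(b))
    yc = np.clip(y, lo, hi)
    if link.family == "beta_cdf":
        c0, scale, sa, sb = link.eta
        u = (yc - lo) / (hi - lo)
        u = np.clip(u, _BETA_EPS, 1.0 - _BETA_EPS)
        h = c0 + scale * special.betainc(sa, sb, u)
        logpdf = (
            (sa - 1) * np.log(u)
            + (sb - 1) * np.log1p(-u)
            - special.betaln(sa, sb)
        )
        logjac = np.log(scale) + logpdf - np.log(hi - lo)
        return h, logjac
    basis = link.basis
    w = link.eta[1:]
    h = link.eta[0] + basis.ispline(yc) @ w
    dh = basis.mspline(yc) @ w
    return h, np.log(np.maximum(dh, 1e-300))


def inverse(h, link: LinkSpec) -> np.ndarray:
    """Map latent-scale values back to the creatinine scale.

    Values of ``h`` outside the achievable transformed range are clamped
    to the corresponding boundary of ``y_range``.
    """
    h = np.asarray(h, float)
    lo, hi = link.y_range
    if link.family == "linear":
        a, b = link.eta
        return a + b * h
    if link.family == "beta_cdf":
        c0, scale, sa, sb = link.eta
        u = np.clip((h - c0) / scale, _BETA_EPS, 1.0 - _BETA_EPS)
        return lo + (hi - lo) * special.betaincinv(sa, sb, u)
    h_lo, h_hi = link.transformed_range()
    hc = np.clip(h, h_lo, h_hi)
    flat = np.atleast_1d(hc).ravel()
    out = np.empty_like(flat)
    for i, target in enumerate(flat):
        if target <= h_lo:
            out[i] = lo
        elif target >= h_hi:
            out[i] = hi
        else:
            out[i] = optimize.brentq(
                lambda yy: float(transform(np.array([yy]), link)[0][0]) - target,
                lo,
                hi,
                xtol=1e-10,
            )
    return out.reshape(np.shape(hc)) if np.ndim(hc) else float(out[0])


def ispline_basis(y, nodes: Sequence[float], degree: int = 2) -> np.ndarray:
    """I-spline basis matrix at ``y`` (clamped to the node range)."""
    if degree != ISPLINE_DEGREE:
        raise NotImplementedError("only quadratic I-splines are provided")
    return _ISplineBasis(nodes).ispline(y)


def mspline_basis(y, nodes: Sequence[float], degree: int = 2) -> np.ndarray:
    """Normalized M-spline basis matrix (each column integrates to 1)."""
    if degree != ISPLINE_DEGREE:
        raise NotImplementedError("only quadratic M-splines are provided")
    return _ISplineBasis(nodes).mspline(y)
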