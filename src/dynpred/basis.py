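"""Time bases for marker trajectory models.

A basis maps measurement times to a fixed-effect or random-effect design row.
Summaries of a fitted trajectory need the basis value (level), its analytic
first derivative (slope) and its exact integral over a window (cumulative
level), so every basis implements all three.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TimeBasis", "PolynomialBasis", "NaturalSplineBasis"]


class TimeBasis:
    """Abstract basis of functions of time.

    Subclasses implement :meth:`design`, :meth:`deriv` and :meth:`integral`;
    all return one column per basis function (including the intercept).
    """

    n_terms: int

    def design(self, t: np.ndarray) -> np.ndarray:
        """Basis values at times ``t``; shape ``(len(t), n_terms)``."""
        raise NotImplementedError

    def deriv(self, t: np.ndarray) -> np.ndarray:
        """Analytic first derivative of each basis function at ``t``."""
        raise NotImplementedError

    def integral(self, a: float, b: float) -> np.ndarray:
        """Exact integral of each basis function over ``[a, b]``."""
        raise NotImplementedError


class PolynomialBasis(TimeBasis):
    """Monomial basis ``(1, s, s^2, ..., s^degree)`` in centered time
    ``s = t - center`` (centering at the landmark keeps high powers well
    conditioned and makes the landmark-time level/slope read directly off
    the low-order coefficients)."""

    def __init__(self, degree: int, center: float = 0.0):
        if degree < 0:
            raise ValueError("degree must be >= 0")
        self.degree = int(degree)
        self.center = float(center)
        self.n_terms = self.degree + 1

    def design(self, t):
        s = np.atleast_1d(np.asarray(t, dtype=float)) - self.center
        return np.vander(s, self.n_terms, increasing=True)

    def deriv(self, t):
        s = np.atleast_1d(np.asarray(t, dtype=float)) - self.center
        out = np.zeros((s.size, self.n_terms))
        for j in range(1, self.n_terms):
            out[:, j] = j * s ** (j - 1)
        return out

    def integral(self, a, b):
        powers = np.arange(1, self.n_terms + 1, dtype=float)
        sa, sb = a - self.center, b - self.center
        return (sb ** powers - sa ** powers) / powers

    def __repr__(self):
        return f"PolynomialBasis(degree={self.degree}, center={self.center})"


def _tp3(t, xi):
    """Truncated cubic (t - xi)^3_+."""
    return np.clip(t - xi, 0.0, None) ** 3


def _tp3_deriv(t, xi):
    return 3.0 * np.clip(t - xi, 0.0, None) ** 2


def _tp3_integral(a, b, xi):
    """Integral of (t - xi)^3_+ over [a, b] (a <= b assumed)."""
    lo, hi = max(a, xi), b
    if hi <= lo:
        return 0.0
    return ((hi - xi) ** 4 - (lo - xi) ** 4) / 4.0


class NaturalSplineBasis(TimeBasis):
    """Natural cubic spline basis, linear beyond the boundary knots.

    Uses the standard truncated-power parametrization: with knots
    ``xi_1 < ... < xi_K`` (boundary knots included), the basis is
    ``1, t, N_1(t), ..., N_{K-2}(t)`` where
    ``N_k(t) = d_k(t) - d_{K-1}(t)`` and
    ``d_k(t) = [(t - xi_k)^3_+ - (t - xi_K)^3_+] / (xi_K - xi_k)``.
    The natural (linear-tail) constraints are built into the parametrization,
    and derivative and integral are available in closed form.
    """

    def __init__(self, knots):
        knots = np.sort(np.asarray(knots, dtype=float))
        if knots.size < 3:
            raise ValueError("need at least 3 knots (2 boundary + 1 interior)")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be distinct")
        self.knots = knots
        self.n_terms = knots.size  # 1, t, and K-2 curvature terms

    @classmethod
    def from_quantiles(cls, times, n_interior: int):
        """Boundary knots at the data extremes, interior knots at quantiles."""
        times = np.unique(np.asarray(times, dtype=float))
        qs = np.linspace(0, 1, n_interior + 2)
        knots = np.quantile(times, qs)
        if np.unique(knots).size < knots.size:
            raise ValueError("duplicate knots from quantiles; reduce n_interior")
        return cls(knots)

    def _d(self, t, k):
        xi, K = self.knots, self.knots.size
        return (_tp3(t, xi[k]) - _tp3(t, xi[K - 1])) / (xi[K - 1] - xi[k])

    def _d_deriv(self, t, k):
        xi, K = self.knots, self.knots.size
        return (_tp3_deriv(t, xi[k]) - _tp3_deriv(t, xi[K - 1])) / (xi[K - 1] - xi[k])

    def _d_integral(self, a, b, k):
        xi, K = self.knots, self.knots.size
        return (_tp3_integral(a, b, xi[k]) - _tp3_integral(a, b, xi[K - 1])) / (
            xi[K - 1] - xi[k]
        )

    def design(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        K = self.knots.size
        cols = [np.ones_like(t), t]
        for k in range(K - 2):
            cols.append(self._d(t, k) - self._d(t, K - 2))
        return np.column_stack(cols)

    def deriv(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        K = self.knots.size
        cols = [np.zeros_like(t), np.ones_like(t)]
        for k in range(K - 2):
            cols.append(self._d_deriv(t, k) - self._d_deriv(t, K - 2))
        return np.column_stack(cols)

    def integral(self, a, b):
        K = self.knots.size
        out = [b - a, (b ** 2 - a ** 2) / 2.0]
        for k in range(K - 2):
            out.append(self._d_integral(a, b, k) - self._d_integral(a, b, K - 2))
        return np.asarray(out)

    def __repr__(self):
        return f"NaturalSplineBasis(knots={self.knots.tolist()})"
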