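"""Closed-form linear intensity normalization against a control template.

The normalized image is the affine map ``I_hat(x) = a * I(x) + b`` whose
parameters minimize the mean squared error against the template over the
non-specific region:

    xi(a, b) = (1/N_ns) * sum_i ( a*I(x_i) + b - T(x_i) )^2 .

Setting the partial derivatives to zero gives the normal equations, whose
closed-form solution is

    a = ( sum I*T - N_ns * m_T * m_I ) / ( sum I^2 - N_ns * m_I^2 ),
    b = m_T - a * m_I,

with ``m_I``, ``m_T`` the region means of the source and template.  At the
optimum the residual is orthogonal to the data and sums to zero
(orthogonality principle), and the minimum cost has the closed form

    xi_min = (1/N_ns) * ( sum T^2 - b * sum T - a * sum I*T ).

The fit uses only non-specific voxels but the map is applied to every
voxel, striatum included; all accumulations are double precision with
pairwise summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BinaryMask, Volume


@dataclass
class LinearNormResult:
    """Fitted scale/offset, minimum cost, and residual diagnostics.

    ``residual_dot_data`` is ``sum e*I`` and ``residual_sum`` is ``sum e``
    over the non-specific region; both vanish (to rounding) at the
    optimum by the orthogonality principle.
    """

    a: float
    b: float
    xi_min: float
    m_source: float
    m_template: float
    residual_dot_data: float
    residual_sum: float
    n_ns: int


def _region_arrays(
    source: Volume, template: Volume, nonspecific: BinaryMask
) -> tuple[np.ndarray, np.ndarray]:
    if not (source.shape == template.shape == nonspecific.shape):
        raise ValueError(
            f"grid mismatch: source {source.shape}, template {template.shape}, "
            f"mask {nonspecific.shape}"
        )
    sel = nonspecific.data
    return source.data[sel], template.data[sel]


def estimate_linear_params(
    source: Volume, template: Volume, nonspecific: BinaryMask
) -> LinearNormResult:
    """Closed-form least-squares fit of (a, b) over the non-specific region."""
    x, t = _region_arrays(source, template, nonspecific)
    n = x.size
    if n < 2:
        raise ValueError("non-specific region must contain at least 2 voxels")
    m_i = float(x.mean())
    m_t = float(t.mean())
    s_xx = float(np.dot(x, x))
    s_xt = float(np.dot(x, t))
    s_tt = float(np.dot(t, t))
    s_t = float(t.sum())
    denom = s_xx - n * m_i * m_i
    if denom <= 0 or float(x.var()) <= 1e-12 * (m_i * m_i + 1e-300):
        raise ValueError("degenerate source: zero variance in non-specific region")
    a = (s_xt - n * m_t * m_i) / denom
    b = m_t - a * m_i
    xi_min = (s_tt - b * s_t - a * s_xt) / n
    e = a * x + b - t
    return LinearNormResult(
        a=a,
        b=b,
        xi_min=xi_min,
        m_source=m_i,
        m_template=m_t,
        residual_dot_data=float(np.dot(e, x)),
        residual_sum=float(e.sum()),
        n_ns=n,
    )


def apply_linear(source: Volume, result: LinearNormResult) -> Volume:
    """Apply I_hat = a*I + b to every voxel (fit on NS, apply globally)."""
    return Volume(result.a * source.data + result.b, source.affine)


def minimum_mse(
    source: Volume,
    template: Volume,
    nonspecific: BinaryMask,
    result: LinearNormResult,
) -> float:
    """Evaluate the closed-form minimum cost at the fitted parameters.

    Contract: equals the directly evaluated residual mean square
    ``(1/N_ns) * sum e^2`` to 1e-10 relative.
    """
    x, t = _region_arrays(source, template, nonspecific)
    n = x.size
    return float((np.dot(t, t) - result.b * t.sum() - result.a * np.dot(x, t)) / n)


def mse_cost(
    source: Volume,
    template: Volume,
    nonspecific: BinaryMask,
    a: float,
    b: float,
) -> float:
    """Directly evaluated cost xi(a, b); the brute-force check route."""
    x, t = _region_arrays(source, template, nonspecific)
    e = a * x + b - t
    return float(np.dot(e, e) / x.size)


def normalize_mse(
    source: Volume, template: Volume, nonspecific: BinaryMask
) -> tuple[Volume, LinearNormResult]:
    """Fit and apply in one step; returns the normalized volume and the fit."""
    result = estimate_linear_params(source, template, nonspecific)
    return apply_linear(source, result), result
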