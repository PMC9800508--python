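"""Mie scattering amplitude functions for homogeneous spheres.

Implements the classical series solution for the scattering of a plane wave by
a sphere: the complex amplitude functions ``S1(theta)`` and ``S2(theta)`` for
the two polarization states, built from the scattering coefficients ``a_n``,
``b_n`` (Riccati–Bessel recurrences with a downward logarithmic-derivative
recursion) and the angular functions ``pi_n``, ``tau_n``.

The unpolarized scattered intensity at angle ``theta`` is proportional to
``(|S1|^2 + |S2|^2) / 2``.  The series is truncated at the standard order
``n_max = ceil(x + 4 x^{1/3} + 2)`` where ``x`` is the size parameter
(sphere circumference in medium wavelengths).
"""

from __future__ import annotations

import numpy as np

#: Refuse size parameters beyond this: the series length (and the upward
#: Riccati–Bessel recurrence error) grows with x and the package is meant for
#: micron-scale particles at visible wavelengths (x of order 10).
MAX_SIZE_PARAMETER = 500.0


def truncation_order(x: float) -> int:
    """Wiscombe-style series truncation order for size parameter ``x``."""
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_ab(m: complex, x: float, n_max: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Scattering coefficients ``a_n``, ``b_n`` for ``n = 1..n_max``.

    Parameters
    ----------
    m : complex
        Relative refractive index (particle index / medium index).  The
        imaginary part, if any, must be non-negative (absorbing medium
        convention).
    x : float
        Size parameter ``pi * d * n_medium / lambda_vacuum``.
    n_max : int, optional
        Series length; defaults to :func:`truncation_order`.

    Notes
    -----
    Uses the downward recurrence for the logarithmic derivative
    ``D_n(mx) = psi_n'(mx)/psi_n(mx)`` (stable for all ``n``), and upward
    recurrences for the Riccati–Bessel functions ``psi_n(x)``, ``chi_n(x)``.
    """
    if x <= 0:
        raise ValueError(f"size parameter must be positive, got {x}")
    if x > MAX_SIZE_PARAMETER:
        raise ValueError(
            f"size parameter {x:.1f} exceeds the supported cap {MAX_SIZE_PARAMETER}"
        )
    if m.imag < 0:
        raise ValueError("imaginary part of the relative refractive index must be >= 0")
    if n_max is None:
        n_max = truncation_order(x)
    mx = m * x

    # Logarithmic derivative D_n(mx), downward from well above the series end.
    n_start = int(max(n_max, abs(mx)) + 16)
    D = np.zeros(n_start + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        rn = n / mx
        D[n - 1] = rn - 1.0 / (D[n] + rn)

    n = np.arange(1, n_max + 1)
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x), upward.
    psi = np.empty(n_max + 1)
    chi = np.empty(n_max + 1)
    psi_m1, psi[0] = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi[0] = -np.sin(x), np.cos(x)
    for k in range(1, n_max + 1):
        fac = (2 * k - 1) / x
        psi[k] = fac * psi[k - 1] - (psi[k - 2] if k >= 2 else psi_m1)
        chi[k] = fac * chi[k - 1] - (chi[k - 2] if k >= 2 else chi_m1)
    xi = psi - 1j * chi

    Dn = D[1 : n_max + 1]
    da = Dn / m + n / x
    db = Dn * m + n / x
    a = (da * psi[1:] - psi[:-1]) / (da * xi[1:] - xi[:-1])
    b = (db * psi[1:] - psi[:-1]) / (db * xi[1:] - xi[:-1])
    return a, b


def amplitude_functions(
    m: complex, x: float, cos_theta: np.ndarray, n_max: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude functions ``S1``, ``S2`` at the given ``cos(theta)`` values.

    Returns two complex arrays shaped like ``cos_theta``.
    """
    a, b = mie_ab(m, x, n_max=n_max)
    mu = np.atleast_1d(np.asarray(cos_theta, dtype=float))
    if np.any(np.abs(mu) > 1 + 1e-12):
        raise ValueError("cos(theta) values must lie in [-1, 1]")
    mu = np.clip(mu, -1.0, 1.0)

    S1 = np.zeros(mu.shape, dtype=complex)
    S2 = np.zeros(mu.shape, dtype=complex)
    pi_prev = np.zeros_like(mu)  # pi_0
    pi_cur = np.ones_like(mu)  # pi_1
    for k in range(1, len(a) + 1):
        tau = k * mu * pi_cur - (k + 1) * pi_prev
        fac = (2 * k + 1) / (k * (k + 1))
        S1 += fac * (a[k - 1] * pi_cur + b[k - 1] * tau)
        S2 += fac * (a[k - 1] * tau + b[k - 1] * pi_cur)
        pi_next = ((2 * k + 1) * mu * pi_cur - (k + 1) * pi_prev) / k
        pi_prev, pi_cur = pi_cur, pi_next
    return S1, S2


def unpolarized_intensity(
    m: complex, x: float, angles_deg: np.ndarray, n_max: int | None = None
) -> np.ndarray:
    """Unpolarized angular intensity ``(|S1|^2 + |S2|^2)/2`` (not normalized)."""
    angles = np.asarray(angles_deg, dtype=float)
    if np.any(angles < 0) or np.any(angles > 180):
        raise ValueError("scattering angles must lie in [0, 180] degrees")
    S1, S2 = amplitude_functions(m, x, np.cos(np.radians(angles)), n_max=n_max)
    return 0.5 * (np.abs(S1) ** 2 + np.abs(S2) ** 2)
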