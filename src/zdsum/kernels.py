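"""Pairwise electrostatic kernels (pre-Coulomb-constant, 1/Å units).

Each cutoff scheme is a reconstructed pair potential u(r) applied inside a
cutoff sphere of radius r_c, plus a self-energy coefficient multiplying
Σ q_i². The zero-dipole (ZD) kernel completes the damped Coulomb kernel
erfc(αr)/r with a quadratic and a constant term,

    u_zd(r) = erfc(αr)/r + A r² + B,

with A and B fixed by the smooth-truncation conditions u(r_c) = 0 and
u'(r_c) = 0:

    A = [erfc(αr_c)/r_c³ + (2α/√π) e^(−α²r_c²)/r_c²] / 2
    B = −erfc(αr_c)/r_c − A r_c²

At α = 0 this reduces to 1/r + r²/(2r_c³) − 3/(2r_c). The self coefficient
B/2 − α/√π makes the scheme exact (at α=0) for any neutral, zero-dipole
charge set lying entirely inside the cutoff sphere; for a neutral set with
dipole moment D the residual error is exactly −k_C·A·|D|².

The zero-charge (Wolf) kernel keeps only the constant completion
(potential shift); the shifted-force kernel is the undamped force-shifted
Coulomb form whose value and derivative both vanish at r_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np
from scipy.special import erfc

from .units import SQRT_PI

__all__ = [
    "zd_coefficients",
    "zd_pair_potential",
    "zd_pair_force",
    "zd_self_coefficient",
    "wolf_pair_potential",
    "wolf_pair_force",
    "wolf_self_coefficient",
    "shifted_force_potential",
    "shifted_force_force",
    "shifted_force_self_coefficient",
    "get_kernel",
]


def zd_coefficients(alpha: float, r_c: float) -> Tuple[float, float]:
    """Completion coefficients (A, B) of the ZD kernel for given α, r_c."""
    if r_c <= 0:
        raise ValueError("r_c must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    erfc_rc = erfc(alpha * r_c)
    gauss = 2.0 * alpha / SQRT_PI * math.exp(-((alpha * r_c) ** 2))
    a = 0.5 * (erfc_rc / r_c**3 + gauss / r_c**2)
    b = -erfc_rc / r_c - a * r_c**2
    return float(a), float(b)


def _check_r(r: np.ndarray, r_c: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if np.any(r > r_c * (1 + 1e-12)):
        raise ValueError("r beyond the cutoff")
    return r


def zd_pair_potential(r, alpha: float, r_c: float):
    """ZD kernel u(r) = erfc(αr)/r + A r² + B for 0 < r <= r_c."""
    r = _check_r(r, r_c)
    a, b = zd_coefficients(alpha, r_c)
    return erfc(alpha * r) / r + a * r**2 + b


def zd_pair_force(r, alpha: float, r_c: float):
    """du/dr of the ZD kernel (continuous, zero at r_c)."""
    r = _check_r(r, r_c)
    a, _ = zd_coefficients(alpha, r_c)
    gauss = 2.0 * alpha / SQRT_PI * np.exp(-((alpha * r) ** 2))
    return -(erfc(alpha * r) / r**2 + gauss / r) + 2.0 * a * r


def zd_self_coefficient(alpha: float, r_c: float) -> float:
    """Self-energy coefficient: E_self = k_C · coeff · Σ q_i²."""
    _, b = zd_coefficients(alpha, r_c)
    return 0.5 * b - alpha / SQRT_PI


def wolf_pair_potential(r, alpha: float, r_c: float):
    """Zero-charge (Wolf) kernel: potential-shifted damped Coulomb."""
    r = _check_r(r, r_c)
    return erfc(alpha * r) / r - erfc(alpha * r_c) / r_c


def wolf_pair_force(r, alpha: float, r_c: float):
    r = _check_r(r, r_c)
    gauss = 2.0 * alpha / SQRT_PI * np.exp(-((alpha * r) ** 2))
    return -(erfc(alpha * r) / r**2 + gauss / r)


def wolf_self_coefficient(alpha: float, r_c: float) -> float:
    return -0.5 * erfc(alpha * r_c) / r_c - alpha / SQRT_PI


def shifted_force_potential(r, alpha: float, r_c: float):
    """Shifted-force kernel 1/r − 1/r_c + (r − r_c)/r_c² (α ignored)."""
    r = _check_r(r, r_c)
    return 1.0 / r - 1.0 / r_c + (r - r_c) / r_c**2


def shifted_force_force(r, alpha: float, r_c: float):
    r = _check_r(r, r_c)
    return -1.0 / r**2 + 1.0 / r_c**2


def shifted_force_self_coefficient(alpha: float, r_c: float) -> float:
    # Fennell–Gezelter convention at zero damping
    return -0.5 / r_c


@dataclass(frozen=True)
class Kernel:
    u: Callable
    du: Callable
    self_coefficient: Callable


_KERNELS = {
    "zd": Kernel(zd_pair_potential, zd_pair_force, zd_self_coefficient),
    "wolf": Kernel(wolf_pair_potential, wolf_pair_force, wolf_self_coefficient),
    "shifted_force": Kernel(
        shifted_force_potential, shifted_force_force, shifted_force_self_coefficient
    ),
}


def get_kernel(method: str) -> Kernel:
    try:
        return _KERNELS[method]
    except KeyError as exc:
        raise ValueError(f"no pairwise kernel for method {method!r}") from exc
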