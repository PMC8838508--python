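"""Simplified harmonic force field for the −N3 azide label.

The label is a linear triatomic: each N−N bond is a harmonic oscillator and
the N−N−N angle a harmonic bend about a linear equilibrium.  Energies follow
the CHARMM convention E = k (x − x₀)² *without* the ½ factor, so the
published constants are used verbatim and the Newtonian spring constant of a
bond is 2k.

Defaults: re = 1.14 Å, kb = 877.413 kcal/mol/Å², θe = 180°,
kθ = 46.706 kcal/mol/rad².  With nitrogen masses these place the asymmetric
stretch near 2100 cm⁻¹, the experimentally relevant azide reporter band.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .units import eigval_to_wavenumber

__all__ = [
    "LabelForceField",
    "NormalModeResult",
    "bond_energy",
    "angle_energy",
    "triatomic_energy_gradient",
    "normal_modes",
]

#: Average mass of nitrogen, amu.
NITROGEN_MASS = 14.007


@dataclass(frozen=True)
class LabelForceField:
    """Harmonic bond + angle constants for the azide label (CHARMM convention)."""

    re: float = 1.14          # Å
    kb: float = 877.413       # kcal/mol/Å²
    theta_e: float = math.pi  # rad
    ktheta: float = 46.706    # kcal/mol/rad²

    def __post_init__(self) -> None:
        for name in ("re", "kb", "theta_e", "ktheta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class NormalModeResult:
    """Eigenanalysis of the mass-weighted Hessian at a collinear geometry."""

    frequencies: np.ndarray      # cm⁻¹, ascending
    modes: np.ndarray            # columns: mass-weighted eigenvectors
    zero_mode_count: int
    eigenvalues: np.ndarray      # kcal/mol/Å²/amu, ascending


def bond_energy(r: float, ff: LabelForceField) -> tuple[float, float]:
    """Energy and dE/dr of one N−N bond, E = kb (r − re)².

    Returns (kcal/mol, kcal/mol/Å).  r must be positive.
    """
    if r <= 0:
        raise ValueError(f"bond length must be > 0 Å, got {r}")
    d = r - ff.re
    return ff.kb * d * d, 2.0 * ff.kb * d


def angle_energy(theta: float, ff: LabelForceField) -> tuple[float, float]:
    """Energy and dE/dθ of the N−N−N bend, E = kθ (θ − θe)².

    Valid for 0 < θ ≤ π (the equilibrium itself is linear).
    """
    if not 0.0 < theta <= math.pi + 1e-12:
        raise ValueError(f"angle must be in (0, π] rad, got {theta}")
    d = theta - ff.theta_e
    return ff.ktheta * d * d, 2.0 * ff.ktheta * d


def _angle_gradient_prefactor(theta: float, ff: LabelForceField) -> float:
    """g(θ) = (dE/dθ)/sin θ with the θ→π limit taken analytically.

    Cartesian angle gradients carry a 1/sin θ factor that is singular at the
    linear equilibrium; the product (θ − θe)/sin θ is regular there (→ −1
    for θe = π), so the force stays finite and smooth.
    """
    d = theta - ff.theta_e
    s = math.sin(theta)
    if s < 1e-8:
        # series: θ = π − δ, sin θ = δ − δ³/6 …, d = −δ  ⇒  d/s → −(1 + δ²/6)
        delta = math.pi - theta
        ratio = -(1.0 + delta * delta / 6.0)
    else:
        ratio = d / s
    return 2.0 * ff.ktheta * ratio


def triatomic_energy_gradient(
    positions: np.ndarray, ff: LabelForceField
) -> tuple[float, np.ndarray]:
    """Total label energy (kcal/mol) and Cartesian gradient (kcal/mol/Å).

    ``positions`` is (3, 3): atoms N1−N2−N3 with the angle at N2.
    """
    x = np.asarray(positions, dtype=float)
    if x.shape != (3, 3):
        raise ValueError(f"expected (3, 3) positions, got {x.shape}")
    grad = np.zeros((3, 3))
    energy = 0.0

    # bond terms
    for a, b in ((0, 1), (1, 2)):
        dvec = x[a] - x[b]
        r = float(np.linalg.norm(dvec))
        if r < 1e-12:
            raise ValueError(f"coincident atoms {a} and {b}: bond undefined")
        e, dEdr = bond_energy(r, ff)
        energy += e
        u = dvec / r
        grad[a] += dEdr * u
        grad[b] -= dEdr * u

    # angle term (vertex at atom 1): dE/dx = −g(θ) · d(cos θ)/dx
    v1 = x[0] - x[1]
    v2 = x[2] - x[1]
    r1 = float(np.linalg.norm(v1))
    r2 = float(np.linalg.norm(v2))
    if r1 < 1e-12 or r2 < 1e-12:
        raise ValueError("coincident atoms: angle undefined")
    cos_t = float(np.dot(v1, v2) / (r1 * r2))
    cos_t = max(-1.0, min(1.0, cos_t))
    theta = math.acos(cos_t)
    e_ang, _ = angle_energy(theta if theta > 0 else 1e-15, ff)
    energy += e_ang
    g = _angle_gradient_prefactor(theta, ff)
    # d(cos θ)/dx for the three atoms
    dcos_d0 = (v2 / (r1 * r2)) - cos_t * v1 / (r1 * r1)
    dcos_d2 = (v1 / (r1 * r2)) - cos_t * v2 / (r2 * r2)
    dcos_d1 = -(dcos_d0 + dcos_d2)
    grad[0] += -g * dcos_d0
    grad[1] += -g * dcos_d1
    grad[2] += -g * dcos_d2

    return energy, grad


def _collinear_axis(x: np.ndarray, tol: float = 1e-6) -> np.ndarray | None:
    """Unit chain axis if the 3 points are collinear, else None."""
    v1 = x[2] - x[0]
    n1 = np.linalg.norm(v1)
    if n1 < 1e-12:
        return None
    axis = v1 / n1
    off = (x[1] - x[0]) - np.dot(x[1] - x[0], axis) * axis
    if np.linalg.norm(off) > tol:
        return None
    return axis


def normal_modes(
    masses: np.ndarray,
    ff: LabelForceField,
    geometry: np.ndarray | None = None,
) -> NormalModeResult:
    """Normal modes of the label at a collinear geometry.

    The Hessian is built analytically: at a harmonic-bond equilibrium the
    bond block is 2kb êêᵀ along the chain axis, and the linear bend
    contributes 2kθ c cᵀ per transverse direction with
    c = (p/r₁₂, −(1/r₁₂ + 1/r₂₃) p, p/r₂₃) for transverse unit vector p.
    Eigenvalues of the mass-weighted Hessian are converted to cm⁻¹; a linear
    triatomic has exactly 5 zero modes (3 translations + 2 rotations).

    A geometry away from the collinear equilibrium at spacing re triggers a
    warning; the Hessian is still evaluated at the given spacings.
    """
    m = np.asarray(masses, dtype=float)
    if m.shape != (3,) or np.any(m <= 0):
        raise ValueError("masses must be 3 positive values")
    if geometry is None:
        geometry = np.array(
            [[-ff.re, 0.0, 0.0], [0.0, 0.0, 0.0], [ff.re, 0.0, 0.0]]
        )
    x = np.asarray(geometry, dtype=float)
    axis = _collinear_axis(x)
    if axis is None:
        raise ValueError("normal_modes requires a collinear 3-point geometry")
    r12 = float(np.linalg.norm(x[1] - x[0]))
    r23 = float(np.linalg.norm(x[2] - x[1]))
    if abs(r12 - ff.re) > 1e-6 * max(1.0, ff.re) or abs(r23 - ff.re) > 1e-6 * max(1.0, ff.re):
        warnings.warn(
            f"geometry spacings ({r12:.4f}, {r23:.4f}) Å differ from "
            f"re = {ff.re} Å; Hessian evaluated at the given geometry",
            stacklevel=2,
        )

    # orthonormal transverse directions
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, axis)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = trial - np.dot(trial, axis) * axis
    p /= np.linalg.norm(p)
    q = np.cross(axis, p)

    H = np.zeros((9, 9))
    kappa = 2.0 * ff.kb  # Newtonian spring constant under the k(x−x₀)² convention
    ee = kappa * np.outer(axis, axis)
    for a, b in ((0, 1), (1, 2)):
        sa, sb = 3 * a, 3 * b
        H[sa : sa + 3, sa : sa + 3] += ee
        H[sb : sb + 3, sb : sb + 3] += ee
        H[sa : sa + 3, sb : sb + 3] -= ee
        H[sb : sb + 3, sa : sa + 3] -= ee
    for t in (p, q):
        c = np.concatenate([t / r12, -(1.0 / r12 + 1.0 / r23) * t, t / r23])
        H += 2.0 * ff.ktheta * np.outer(c, c)

    inv_sqrt_m = np.repeat(1.0 / np.sqrt(m), 3)
    Hmw = H * np.outer(inv_sqrt_m, inv_sqrt_m)
    eigvals, eigvecs = np.linalg.eigh(Hmw)
    tol = 1e-8 * max(1.0, float(np.max(np.abs(eigvals))))
    zero_count = int(np.sum(np.abs(eigvals) < tol))
    freqs = np.array(
        [0.0 if abs(lam) < tol else eigval_to_wavenumber(lam) for lam in eigvals]
    )
    return NormalModeResult(
        frequencies=freqs,
        modes=eigvecs,
        zero_mode_count=zero_count,
        eigenvalues=eigvals,
    )
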