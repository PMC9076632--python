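"""Steady-state diffusion-dipole reflectance for a semi-infinite medium.

The fluence of a pencil beam on a semi-infinite homogeneous turbid medium
is approximated by the standard extrapolated-boundary dipole: an isotropic
source at depth z0 = 1/(mu_a + mu_s') and a negative image above the
extrapolated boundary at z = -(z0 + 2 zb), zb = 2 A D. The detected
reflectance combines the fluence and the flux at the surface, each weighted
by the Fresnel-transmission radiance moments of the index mismatch,

    R(rho) = C_phi * Phi(rho, 0) + C_j * j_z(rho, 0),

with C_phi = 1/2 int (1 - R_F(mu)) mu dmu and
C_j = 3/2 int (1 - R_F(mu)) mu^2 dmu (0.118 and 0.306 for n_rel = 1.4).
The internal-reflection parameter A is computed from the same Fresnel
moments. This hybrid form stays within a few percent of Monte Carlo
transport at the 1-2 mm probe separations, where the flux-only dipole
deviates by 10-20%.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from ..media import ReflectanceSample, TurbidMedium, ValidationError

__all__ = [
    "diffusion_reflectance",
    "diffusion_reflectance_profile",
    "diffusion_reflectance_ring",
    "boundary_mismatch_factor",
    "boundary_collection_moments",
]


def _fresnel_internal(mu: float, n_rel: float) -> float:
    """Unpolarised Fresnel reflectance for internal incidence cosine mu."""
    ci = mu
    st2 = (1.0 - ci * ci) * n_rel * n_rel
    if st2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - st2)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    return 0.5 * (rs * rs + rp * rp)


@lru_cache(maxsize=32)
def boundary_collection_moments(n_rel: float) -> tuple[float, float]:
    """(C_phi, C_j): fluence and flux collection weights at the boundary."""
    if n_rel < 1.0:
        raise ValidationError("n_rel must be >= 1")
    c_phi = 0.5 * quad(lambda mu: (1 - _fresnel_internal(mu, n_rel)) * mu, 0, 1)[0]
    c_j = 1.5 * quad(lambda mu: (1 - _fresnel_internal(mu, n_rel)) * mu**2, 0, 1)[0]
    return c_phi, c_j


@lru_cache(maxsize=32)
def boundary_mismatch_factor(n_rel: float) -> float:
    """Internal-reflection parameter A = (1 + R_eff) / (1 - R_eff).

    R_eff is built from the first and second Fresnel moments of the internal
    radiance (A ~ 2.95 for n_rel = 1.4, 1 for a matched boundary).
    """
    if n_rel < 1.0:
        raise ValidationError("n_rel must be >= 1")
    r1 = 2.0 * quad(lambda mu: _fresnel_internal(mu, n_rel) * mu, 0, 1)[0]
    r2 = 3.0 * quad(lambda mu: _fresnel_internal(mu, n_rel) * mu**2, 0, 1)[0]
    r_eff = (r1 + r2) / (2.0 - r1 + r2)
    return (1.0 + r_eff) / (1.0 - r_eff)


def diffusion_reflectance_profile(
    mu_a: np.ndarray | float,
    mu_s_prime: np.ndarray | float,
    rho: np.ndarray | float,
    n_rel: float = 1.4,
) -> np.ndarray | float:
    """Vectorized R(rho) in mm^-2; broadcasts over all arguments."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(mu_s_prime <= 0):
        raise ValidationError("mu_s_prime must be > 0")
    if np.any(mu_a < 0):
        raise ValidationError("mu_a must be >= 0")
    if np.any(rho <= 0):
        raise ValidationError("sds must be > 0")

    c_phi, c_j = boundary_collection_moments(n_rel)
    mu_t_prime = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_t_prime
    z0 = 1.0 / mu_t_prime
    diff_const = 1.0 / (3.0 * mu_t_prime)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t_prime)
    zb = 2.0 * boundary_mismatch_factor(n_rel) * diff_const
    z_img = z0 + 2.0 * zb

    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt(z_img**2 + rho**2)
    fluence = (
        albedo
        / (4.0 * np.pi * diff_const)
        * (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2)
    )
    flux = (
        albedo
        / (4.0 * np.pi)
        * (
            z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
            + z_img * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
        )
    )
    out = c_phi * fluence + c_j * flux
    if out.ndim == 0:
        return float(out)
    return out


def diffusion_reflectance(medium: TurbidMedium, sds: float) -> ReflectanceSample:
    """Closed-form diffuse reflectance at one source-detector separation."""
    if sds <= 0:
        raise ValidationError(f"sds must be > 0, got {sds}")
    value = diffusion_reflectance_profile(
        medium.mu_a, medium.mu_s_prime, sds, n_rel=medium.n_rel
    )
    return ReflectanceSample(sds=sds, reflectance=float(value), std_err=0.0)


def diffusion_reflectance_ring(
    medium: TurbidMedium, r_inner: float, r_outer: float
) -> float:
    """Area-averaged R over an annulus, for unbiased comparison with the
    Monte Carlo ring tallies: (2 pi / area) * int_{r_in}^{r_out} R(rho) rho drho."""
    if not 0 <= r_inner < r_outer:
        raise ValidationError("need 0 <= r_inner < r_outer")

    def integrand(rho: float) -> float:
        return (
            diffusion_reflectance_profile(
                medium.mu_a, medium.mu_s_prime, rho, n_rel=medium.n_rel
            )
            * rho
        )

    lo = max(r_inner, 1e-9)
    integral, _ = quad(integrand, lo, r_outer, limit=200)
    area = np.pi * (r_outer**2 - r_inner**2)
    return 2.0 * np.pi * integral / area
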