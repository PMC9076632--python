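"""Physiological features from absorption spectra.

Two feature sets drive the severity analysis:

* **Hemoglobin unmixing** over 500–600 nm: the recovered absorption spectrum
  is decomposed by non-negative least squares onto the oxy- and
  deoxyhemoglobin basis (Beer's law), giving concentrations ``c_o2hb``,
  ``c_hhb`` and their sum ``c_thb`` in uM.

* **Pure-water fitting residual (PWFR)** over 1230–1380 nm, the first water
  absorption overtone: a scale-only fit ``mu_a(lambda) ~ A * mu_a_water(lambda)``
  is performed and the score is ``100 * RSS / n_points``. A spectrum that is
  exactly proportional to pure water scores 0; disturbance of the band shape
  by water-protein binding (a compromised stratum-corneum barrier) raises it.

``compute_pwfr`` is unit-preserving. The study pipeline evaluates PWFR on
absorption expressed in cm^-1 (``extract_site_features``), the conventional
clinical scale for this score; the fitted scale A is unit-invariant, but the
residual — hence the score — grows with the square of the unit factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .chromophores import HEMOGLOBIN_WINDOW, WATER_WINDOW, ChromophoreBasis
from .spectra import OpticalPropertySpectrum

__all__ = [
    "HemoglobinResult",
    "PwfrResult",
    "SiteFeatures",
    "fit_hemoglobin",
    "compute_pwfr",
    "extract_site_features",
    "ABSORPTION_UNIT_SCALE",
]

#: mm^-1 -> cm^-1, the unit convention under which PWFR is reported
ABSORPTION_UNIT_SCALE = 10.0


@dataclass(frozen=True)
class HemoglobinResult:
    """Beer's-law unmixing result; concentrations in uM, fit_rss in mm^-2."""

    c_o2hb: float
    c_hhb: float
    fit_rss: float
    n_points: int

    @property
    def c_thb(self) -> float:
        return self.c_o2hb + self.c_hhb


@dataclass(frozen=True)
class PwfrResult:
    """Scale-only water fit: fitted scale A and pwfr = 100 * RSS / n."""

    scale: float
    pwfr: float
    n_points: int


@dataclass(frozen=True)
class SiteFeatures:
    """Per-site derived scalars used by the statistics layer."""

    c_o2hb: float
    c_hhb: float
    c_thb: float
    pwfr: float
    water_scale: float
    hb_fit_rss: float


def _window_arrays(
    optics: OpticalPropertySpectrum,
    basis: ChromophoreBasis,
    window: tuple[float, float],
    min_points: int,
):
    lo, hi = window
    wl, mu_a = optics.window(lo, hi)
    if len(wl) < min_points:
        raise ValueError(
            f"need >= {min_points} usable wavelengths in [{lo}, {hi}] nm, "
            f"got {len(wl)} (out-of-domain points are excluded)"
        )
    if wl.min() < basis.wavelengths[0] or wl.max() > basis.wavelengths[-1]:
        raise ValueError("basis does not cover the requested window")
    sub = basis.resample(wl)
    return wl, mu_a, sub


def fit_hemoglobin(
    optics: OpticalPropertySpectrum,
    basis: ChromophoreBasis,
    window: tuple[float, float] = HEMOGLOBIN_WINDOW,
) -> HemoglobinResult:
    """Unmix mu_a(lambda) onto the two hemoglobin bases by NNLS.

    Solves ``mu_a ~ c_o2hb * eps_o2hb + c_hhb * eps_hhb`` over the window
    with non-negativity on both concentrations (they are physical amounts).
    No offset or further chromophore is included.
    """
    wl, mu_a, sub = _window_arrays(optics, basis, window, min_points=3)
    design = np.column_stack([sub.eps_o2hb, sub.eps_hhb])
    coef, rnorm = nnls(design, mu_a)
    return HemoglobinResult(
        c_o2hb=float(coef[0]),
        c_hhb=float(coef[1]),
        fit_rss=float(rnorm**2),
        n_points=len(wl),
    )


def compute_pwfr(
    optics: OpticalPropertySpectrum,
    basis: ChromophoreBasis,
    window: tuple[float, float] = WATER_WINDOW,
) -> PwfrResult:
    """Scale-only pure-water fit and its residual score.

    The closed-form least-squares scale is A = <w, m> / <w, w> (clipped at 0);
    pwfr = 100 * sum((m - A w)^2) / n. Unit-preserving: inputs are fitted on
    whatever absorption scale they carry.
    """
    wl, mu_a, sub = _window_arrays(optics, basis, window, min_points=1)
    water = sub.mu_a_water
    denom = float(np.dot(water, water))
    if denom == 0.0:
        raise ValueError("water basis is identically zero on the window")
    scale = max(float(np.dot(water, mu_a)) / denom, 0.0)
    resid = mu_a - scale * water
    pwfr = 100.0 * float(np.dot(resid, resid)) / len(wl)
    return PwfrResult(scale=scale, pwfr=pwfr, n_points=len(wl))


def extract_site_features(
    optics: OpticalPropertySpectrum, basis: ChromophoreBasis
) -> SiteFeatures:
    """Hemoglobin and PWFR features for one site.

    PWFR is computed on absorption in cm^-1 (both the recovered spectrum and
    the water basis are scaled by 10), the convention under which the score's
    clinical magnitudes are defined; unmixing stays in mm^-1 / uM.
    """
    hb = fit_hemoglobin(optics, basis)
    scaled = OpticalPropertySpectrum(
        wavelengths=optics.wavelengths,
        mu_a=optics.mu_a * ABSORPTION_UNIT_SCALE,
        mu_s_prime=optics.mu_s_prime,
        out_of_domain=optics.out_of_domain,
    )
    scaled_basis = ChromophoreBasis(
        wavelengths=basis.wavelengths,
        eps_o2hb=basis.eps_o2hb,
        eps_hhb=basis.eps_hhb,
        mu_a_water=basis.mu_a_water * ABSORPTION_UNIT_SCALE,
        provenance=basis.provenance,
    )
    pw = compute_pwfr(scaled, scaled_basis)
    return SiteFeatures(
        c_o2hb=hb.c_o2hb,
        c_hhb=hb.c_hhb,
        c_thb=hb.c_thb,
        pwfr=pw.pwfr,
        water_scale=pw.scale,
        hb_fit_rss=hb.fit_rss,
    )
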