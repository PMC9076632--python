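"""Domain containers for turbid-medium optics.

Units follow the tissue-optics convention used throughout the package:
lengths in mm, absorption and reduced scattering coefficients in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


class ValidationError(ValueError):
    """Raised when a physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class TurbidMedium:
    """Semi-infinite homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1 (>= 0).
    mu_s_prime : float
        Reduced scattering coefficient mu_s * (1 - g), mm^-1 (> 0).
    g : float
        Scattering anisotropy of the Henyey-Greenstein phase function,
        in (-1, 1). Default 0.9, the canonical soft-tissue value.
    n_rel : float
        Tissue/ambient refractive-index ratio (>= 1). Default 1.4.
    """

    mu_a: float
    mu_s_prime: float
    g: float = 0.9
    n_rel: float = 1.4

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValidationError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValidationError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not -1.0 < self.g < 1.0:
            raise ValidationError(f"g must be in (-1, 1), got {self.g}")
        if self.n_rel < 1.0:
            raise ValidationError(f"n_rel must be >= 1, got {self.n_rel}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g), mm^-1."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t_prime(self) -> float:
        """Transport attenuation mu_a + mu_s', mm^-1."""
        return self.mu_a + self.mu_s_prime


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo run configuration.

    detector_annuli are (inner, outer) radii in mm; defaults are 0.2 mm wide
    rings centred at the probe's 1 and 2 mm source-detector separations,
    matching a 400 um collection-fiber diameter.
    """

    n_photons: int = 100_000
    seed: int = 0
    detector_annuli: Tuple[Tuple[float, float], ...] = ((0.9, 1.1), (1.9, 2.1))
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValidationError("n_photons must be >= 1")
        if not 0 < self.roulette_survival < 1:
            raise ValidationError("roulette_survival must be in (0, 1)")
        annuli = tuple(tuple(map(float, a)) for a in self.detector_annuli)
        prev_outer = 0.0
        for inner, outer in sorted(annuli):
            if inner < 0 or outer <= inner:
                raise ValidationError(f"bad annulus ({inner}, {outer})")
            if inner < prev_outer:
                raise ValidationError("detector annuli overlap")
            prev_outer = outer
        object.__setattr__(self, "detector_annuli", annuli)


@dataclass(frozen=True)
class ReflectanceSample:
    """Diffuse reflectance detected at one source-detector separation.

    reflectance is per unit area (mm^-2); std_err is the Monte Carlo standard
    error of the estimate (0 for closed-form values).
    """

    sds: float
    reflectance: float
    std_err: float = 0.0

    def __post_init__(self) -> None:
        if self.sds <= 0:
            raise ValidationError(f"sds must be > 0, got {self.sds}")
        if self.reflectance < 0:
            raise ValidationError("reflectance must be >= 0")
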