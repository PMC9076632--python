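"""Spectral containers: measured reflectance and recovered optical properties."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ReflectanceSpectrum", "OpticalPropertySpectrum", "INVERSION_RANGE"]

#: wavelength range (nm) over which spectra may be inverted
INVERSION_RANGE = (500.0, 1380.0)


def _as_1d(name: str, arr) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return out


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Diffuse reflectance (mm^-2) vs wavelength at the two probe separations."""

    wavelengths: np.ndarray
    r_sds1: np.ndarray
    r_sds2: np.ndarray

    def __post_init__(self) -> None:
        wl = _as_1d("wavelengths", self.wavelengths)
        r1 = _as_1d("r_sds1", self.r_sds1)
        r2 = _as_1d("r_sds2", self.r_sds2)
        if not len(wl) == len(r1) == len(r2):
            raise ValueError("wavelengths, r_sds1, r_sds2 must have equal length")
        if len(wl) > 1 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "r_sds1", r1)
        object.__setattr__(self, "r_sds2", r2)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def value_at(self, wavelength: float, sds: int = 1) -> float:
        """Linearly interpolated reflectance at one wavelength."""
        r = self.r_sds1 if sds == 1 else self.r_sds2
        if not self.wavelengths[0] <= wavelength <= self.wavelengths[-1]:
            raise ValueError(f"{wavelength} nm outside spectrum range")
        return float(np.interp(wavelength, self.wavelengths, r))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "r_sds1": self.r_sds1,
                "r_sds2": self.r_sds2,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReflectanceSpectrum":
        df = pd.read_csv(path, comment="#")
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            r_sds1=df["r_sds1"].to_numpy(),
            r_sds2=df["r_sds2"].to_numpy(),
        )


@dataclass(frozen=True)
class OpticalPropertySpectrum:
    """Recovered absorption and reduced scattering, mm^-1, per wavelength.

    ``out_of_domain`` flags wavelengths whose reflectance pair fell outside
    the inverse model's training domain; their values are nearest-neighbour
    fallbacks and should be treated with suspicion downstream.
    """

    wavelengths: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    out_of_domain: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        wl = _as_1d("wavelengths", self.wavelengths)
        mu_a = _as_1d("mu_a", self.mu_a)
        mu_s = _as_1d("mu_s_prime", self.mu_s_prime)
        flags = (
            np.zeros(len(wl), dtype=bool)
            if self.out_of_domain is None
            else np.asarray(self.out_of_domain, dtype=bool)
        )
        if not len(wl) == len(mu_a) == len(mu_s) == len(flags):
            raise ValueError("all arrays must have equal length")
        ok = ~flags
        if np.any(mu_a[ok] < 0) or np.any(mu_s[ok] <= 0):
            raise ValueError("unflagged entries must have mu_a >= 0, mu_s' > 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_s_prime", mu_s)
        object.__setattr__(self, "out_of_domain", flags)

    def __len__(self) -> int:
        return len(self.wavelengths)

    def window(self, lo: float, hi: float, include_flagged: bool = False):
        """(wavelengths, mu_a) restricted to [lo, hi] nm."""
        m = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not include_flagged:
            m &= ~self.out_of_domain
        return self.wavelengths[m], self.mu_a[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "mu_a": self.mu_a,
                "mu_s_prime": self.mu_s_prime,
                "out_of_domain": self.out_of_domain,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OpticalPropertySpectrum":
        df = pd.read_csv(Path(path), comment="#")
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            mu_a=df["mu_a"].to_numpy(),
            mu_s_prime=df["mu_s_prime"].to_numpy(),
            out_of_domain=df["out_of_domain"].to_numpy(),
        )
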