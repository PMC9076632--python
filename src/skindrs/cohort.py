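"""Synthetic psoriasis cohort generator.

Emulates the measurement design of a paired lesion / adjacent-uninvolved
DRS study of psoriasis vulgaris: each subject contributes one lesion and
one uninvolved site with ground-truth physiology, a simulated two-distance
reflectance spectrum, Corneometer- and Mexameter-like instrument readings,
and 4-rater-averaged PASI subscores (erythema, thickness, desquamation).

Generative model
----------------
Per site, a latent severity scalar ``s ~ N(0, 1)`` couples the physiology
fields (hemoglobin up, hydration down, bound-water distortion up with
severity), each drawn as a clipped Gaussian around site-type-specific means.
Absorption is composed as

    mu_a(lambda) = c_o2hb eps_O2Hb + c_hhb eps_HHb
                 + w(h) mu_a_water + b d(lambda),

where ``w(h) = 0.55 + 0.25 h`` maps epidermal hydration to a dermal water
fraction, and ``d`` is a fixed smooth distortion of the first water
absorption overtone, orthogonalised against the water spectrum on the
1230-1380 nm analysis grid and normalised to unit rms there. Because of the
orthogonalisation, the scale-only water fit removes none of the distortion
and the noiseless PWFR (on the cm^-1 reporting scale) is exactly
``10^4 b^2`` — quadratic in the bound-water deviation amplitude ``b``.

Default parameters are calibrated so that large-cohort means of the
pipeline-computed PWFR, and of the simulated Mexameter and Corneometer
readings, approximate the clinical summary constants the generator is
meant to emulate (lesion PWFR ~ 7.4 vs uninvolved ~ 2.9; Mexameter ~ 442 vs
~ 323; Corneometer ~ 11 vs ~ 46). Those constants parameterise the
generator; the pipeline never claims to reproduce clinical results.

The Mexameter emulation is a two-wavelength log-ratio erythema index
(the vendor's internal formula is proprietary); the Corneometer emulation
is a saturating function of epidermal hydration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import yaml

from .chromophores import (
    MEXAMETER_WAVELENGTHS,
    WATER_WINDOW,
    ChromophoreBasis,
    default_analysis_grid,
    load_chromophore_basis,
    synthetic_water_absorption,
)
from .forward import diffusion_reflectance_profile
from .media import TurbidMedium
from .spectra import ReflectanceSpectrum

__all__ = [
    "SitePhysiology",
    "FieldSpec",
    "CohortConfig",
    "Cohort",
    "sample_physiology",
    "physiology_to_medium",
    "physiology_to_absorption",
    "simulate_drs_measurement",
    "simulate_mexameter",
    "simulate_corneometer",
    "simulate_pasi_scores",
    "generate_cohort",
    "water_band_distortion",
]

LESION = "lesion"
UNINVOLVED = "uninvolved"


# ---------------------------------------------------------------------------
# water-band distortion shape (fixed, orthogonal to water on the 2 nm grid)
# ---------------------------------------------------------------------------

def _distortion_constants() -> tuple[float, float]:
    """Orthogonalisation and normalisation constants on the canonical grid."""
    grid = np.arange(WATER_WINDOW[0], WATER_WINDOW[1] + 1, 2.0)
    water = synthetic_water_absorption(grid)
    g1 = np.exp(-(((grid - 1300.0) / 28.0) ** 2))
    g2 = np.exp(-(((grid - 1365.0) / 18.0) ** 2))
    c = float(np.dot(g1, water) / np.dot(g2, water))
    d_raw = g1 - c * g2
    norm = float(np.sqrt(np.mean(d_raw**2)))
    return c, norm


_DIST_C, _DIST_NORM = _distortion_constants()


def water_band_distortion(wavelengths) -> np.ndarray:
    """Fixed bound-water distortion shape d(lambda), unit rms on the grid.

    Zero outside the first-overtone window so the distortion never leaks
    into the hemoglobin band.
    """
    wl = np.asarray(wavelengths, dtype=float)
    g1 = np.exp(-(((wl - 1300.0) / 28.0) ** 2))
    g2 = np.exp(-(((wl - 1365.0) / 18.0) ** 2))
    d = (g1 - _DIST_C * g2) / _DIST_NORM
    in_band = (wl >= WATER_WINDOW[0]) & (wl <= WATER_WINDOW[1])
    return np.where(in_band, d, 0.0)


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SitePhysiology:
    """Ground-truth physiology of one measured skin site."""

    site_type: str
    c_o2hb: float  # uM
    c_hhb: float  # uM
    bound_water_deviation: float  # mm^-1 rms amplitude of the band distortion
    epidermal_hydration: float  # dimensionless in [0, 1]
    scatter_amplitude: float  # mu_s' at 500 nm, mm^-1
    scatter_power: float  # scattering power law exponent

    def __post_init__(self) -> None:
        if self.site_type not in (LESION, UNINVOLVED):
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if min(self.c_o2hb, self.c_hhb, self.bound_water_deviation) < 0:
            raise ValueError("concentrations and deviation must be >= 0")
        if not 0.0 <= self.epidermal_hydration <= 1.0:
            raise ValueError("hydration must be in [0, 1]")
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter_amplitude must be > 0")

    @property
    def c_thb(self) -> float:
        return self.c_o2hb + self.c_hhb

    @property
    def water_fraction(self) -> float:
        """Dermal water volume fraction scaling the water absorption term."""
        return 0.55 + 0.25 * self.epidermal_hydration


@dataclass(frozen=True)
class FieldSpec:
    """Clipped-Gaussian marginal with a severity-factor loading."""

    mean: float
    sd: float
    lo: float
    hi: float
    loading: float = 0.0  # correlation with the site's severity latent

    def draw(self, severity: float, rng: np.random.Generator) -> float:
        eps = rng.standard_normal()
        rho = self.loading
        val = self.mean + self.sd * (rho * severity + np.sqrt(1 - rho**2) * eps)
        return float(np.clip(val, self.lo, self.hi))


def _lesion_defaults() -> Dict[str, FieldSpec]:
    return {
        "c_o2hb": FieldSpec(35.0, 8.0, 10.0, 60.0, loading=0.6),
        "c_hhb": FieldSpec(25.0, 7.0, 5.0, 45.0, loading=0.35),
        "bound_water_deviation": FieldSpec(0.0266, 0.007, 0.0, 0.055, loading=0.5),
        "epidermal_hydration": FieldSpec(0.052, 0.03, 0.0, 1.0, loading=-0.5),
        "scatter_amplitude": FieldSpec(2.6, 0.35, 1.2, 4.0, loading=0.5),
        "scatter_power": FieldSpec(1.3, 0.15, 0.5, 2.5, loading=0.0),
    }


def _uninvolved_defaults() -> Dict[str, FieldSpec]:
    return {
        "c_o2hb": FieldSpec(25.0, 6.0, 8.0, 45.0, loading=0.3),
        "c_hhb": FieldSpec(10.0, 3.0, 2.0, 20.0, loading=0.3),
        "bound_water_deviation": FieldSpec(0.0162, 0.004, 0.0, 0.04, loading=0.3),
        "epidermal_hydration": FieldSpec(0.313, 0.16, 0.0, 1.0, loading=-0.3),
        "scatter_amplitude": FieldSpec(2.0, 0.25, 1.0, 3.5, loading=0.3),
        "scatter_power": FieldSpec(1.3, 0.15, 0.5, 2.5, loading=0.0),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the paired-site design at n = 15 subjects with 4 raters and
    1% multiplicative measurement noise on reflectance.
    """

    n_subjects: int = 15
    seed: int = 0
    n_raters: int = 4
    noise_sd_fraction: float = 0.01
    corneometer_noise_sd: float = 2.0
    rater_noise_sd: float = 0.35
    #: effective optical sampling distance (mm) of the emulated Mexameter
    #: probe; set so the default cohort's erythema-index means land on the
    #: clinical calibration constants
    mexameter_sds: float = 1.4
    lesion_params: Dict[str, FieldSpec] = field(default_factory=_lesion_defaults)
    uninvolved_params: Dict[str, FieldSpec] = field(
        default_factory=_uninvolved_defaults
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.noise_sd_fraction < 0 or self.corneometer_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    def params_for(self, site_type: str) -> Dict[str, FieldSpec]:
        return self.lesion_params if site_type == LESION else self.uninvolved_params

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in (
            "n_subjects",
            "seed",
            "n_raters",
            "noise_sd_fraction",
            "corneometer_noise_sd",
            "rater_noise_sd",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        for group, attr in (
            ("lesion_params", "lesion_params"),
            ("uninvolved_params", "uninvolved_params"),
        ):
            if group in raw:
                base = (
                    _lesion_defaults() if group == "lesion_params"
                    else _uninvolved_defaults()
                )
                for name, spec in raw[group].items():
                    base[name] = FieldSpec(**spec)
                kwargs[attr] = base
        return cls(**kwargs)


def sample_physiology(
    config: CohortConfig, site_type: str, rng: np.random.Generator
) -> SitePhysiology:
    """Draw one site's physiology (clipped-Gaussian, severity-coupled)."""
    severity = rng.standard_normal()
    params = config.params_for(site_type)
    values = {name: spec.draw(severity, rng) for name, spec in params.items()}
    return SitePhysiology(site_type=site_type, **values)


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------


def physiology_to_absorption(
    phys: SitePhysiology, basis: ChromophoreBasis
) -> np.ndarray:
    """Composed mu_a(lambda) in mm^-1 on the basis grid."""
    mu_a = (
        phys.c_o2hb * basis.eps_o2hb
        + phys.c_hhb * basis.eps_hhb
        + phys.water_fraction * basis.mu_a_water
        + phys.bound_water_deviation * water_band_distortion(basis.wavelengths)
    )
    return np.maximum(mu_a, 1e-4)  # guard against distortion undershoot


def physiology_to_medium(
    phys: SitePhysiology, basis: ChromophoreBasis, wavelength: float
) -> TurbidMedium:
    """Deterministic physiology -> optical properties at one wavelength."""
    wl = basis.wavelengths
    if not wl[0] <= wavelength <= wl[-1]:
        raise ValueError(f"{wavelength} nm outside basis coverage")
    sub = basis.resample(np.array([wavelength]))
    mu_a = float(physiology_to_absorption(phys, sub)[0])
    mu_s = phys.scatter_amplitude * (wavelength / 500.0) ** (-phys.scatter_power)
    return TurbidMedium(mu_a=mu_a, mu_s_prime=mu_s)


def simulate_drs_measurement(
    phys: SitePhysiology,
    basis: ChromophoreBasis,
    config: CohortConfig,
    rng: np.random.Generator,
    forward: str = "diffusion",
) -> ReflectanceSpectrum:
    """Forward-model the site's reflectance at SDS 1 and 2 mm with noise.

    Noise is multiplicative log-normal with the configured fractional SD,
    mean-corrected so the expected reflectance equals the noiseless value.
    """
    if forward != "diffusion":
        raise ValueError("only the diffusion forward is supported for cohorts")
    wl = basis.wavelengths
    if len(wl) == 0:
        return ReflectanceSpectrum(
            wavelengths=np.array([]), r_sds1=np.array([]), r_sds2=np.array([])
        )
    mu_a = physiology_to_absorption(phys, basis)
    mu_s = phys.scatter_amplitude * (wl / 500.0) ** (-phys.scatter_power)
    r1 = diffusion_reflectance_profile(mu_a, mu_s, 1.0)
    r2 = diffusion_reflectance_profile(mu_a, mu_s, 2.0)
    f = config.noise_sd_fraction
    if f > 0:
        sigma = np.sqrt(np.log1p(f**2))
        r1 = r1 * np.exp(sigma * rng.standard_normal(len(wl)) - 0.5 * sigma**2)
        r2 = r2 * np.exp(sigma * rng.standard_normal(len(wl)) - 0.5 * sigma**2)
    return ReflectanceSpectrum(wavelengths=wl, r_sds1=np.asarray(r1), r_sds2=np.asarray(r2))


# ---------------------------------------------------------------------------
# instrument emulations
# ---------------------------------------------------------------------------


def simulate_mexameter(spectrum_or_r568, r660: float | None = None) -> float:
    """Two-wavelength log-ratio erythema index (Mexameter emulation).

    index = clamp(500 * log10(R660 / R568), 0, 999). Stronger hemoglobin
    absorption at 568 nm depresses R568 and raises the index.
    Accepts either a ReflectanceSpectrum (SDS 1 mm channel is used) or the
    two reflectance values directly.
    """
    if isinstance(spectrum_or_r568, ReflectanceSpectrum):
        r568 = spectrum_or_r568.value_at(MEXAMETER_WAVELENGTHS[0], sds=1)
        r660 = spectrum_or_r568.value_at(MEXAMETER_WAVELENGTHS[1], sds=1)
    else:
        r568 = float(spectrum_or_r568)
        if r660 is None:
            raise ValueError("r660 required when passing raw reflectance")
    if r568 <= 0 or r660 <= 0:
        raise ValueError("reflectance at 568 and 660 nm must be > 0")
    return float(np.clip(500.0 * np.log10(r660 / r568), 0.0, 999.0))


def _mexameter_reflectance(
    phys: SitePhysiology, basis: ChromophoreBasis, config: CohortConfig
) -> Tuple[float, float]:
    """Reflectance at the Mexameter channels from the emulated probe.

    The vendor probe has its own (undocumented) geometry; it is emulated as
    a diffuse-reflectance measurement at an effective sampling distance
    ``config.mexameter_sds``.
    """
    sub = basis.resample(np.array(MEXAMETER_WAVELENGTHS))
    mu_a = physiology_to_absorption(phys, sub)
    mu_s = phys.scatter_amplitude * (sub.wavelengths / 500.0) ** (
        -phys.scatter_power
    )
    r = diffusion_reflectance_profile(mu_a, mu_s, config.mexameter_sds)
    return float(r[0]), float(r[1])


def simulate_corneometer(
    phys: SitePhysiology, rng: np.random.Generator, noise_sd: float = 2.0
) -> float:
    """Capacitance-style hydration reading, arbitrary units.

    reading = 120 h / (h + 0.5) + N(0, noise_sd), clamped at 0; strictly
    increasing in hydration before noise.
    """
    h = phys.epidermal_hydration
    reading = 120.0 * h / (h + 0.5)
    if noise_sd > 0:
        reading += noise_sd * rng.standard_normal()
    return float(max(reading, 0.0))


def _pasi_latents(phys: SitePhysiology) -> Tuple[float, float, float]:
    erythema = (0.75 * phys.c_hhb + 0.25 * phys.c_o2hb) / 10.0
    thickness = 1.8 * (phys.scatter_amplitude - 1.8) + 1.5 * (
        1.0 - phys.epidermal_hydration
    )
    desquamation = 85.0 * phys.bound_water_deviation
    return erythema, max(thickness, 0.0), desquamation


def simulate_pasi_scores(
    phys: SitePhysiology,
    n_raters: int,
    rng: np.random.Generator,
    rater_noise_sd: float = 0.35,
) -> Tuple[float, float, float]:
    """Rater-averaged (erythema, thickness, desquamation) scores in [0, 4].

    Latent severities are linear in the physiology fields — erythema weighted
    toward deoxyhemoglobin (raters keying on the dusky color of HHb),
    desquamation driven by the bound-water distortion, thickness by the
    scattering amplitude and dryness — then discretised to the 0-4 integer
    scale per rater after additive rater noise, and averaged.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    latents = _pasi_latents(phys)
    means = []
    for latent in latents:
        scores = np.rint(
            np.clip(latent + rater_noise_sd * rng.standard_normal(n_raters), 0, 4)
        )
        means.append(float(scores.mean()))
    return tuple(means)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

_TRUTH_COLS = [
    "c_o2hb",
    "c_hhb",
    "bound_water_deviation",
    "epidermal_hydration",
    "scatter_amplitude",
    "scatter_power",
]


@dataclass
class Cohort:
    """Paired-site synthetic cohort: table of readings + per-site spectra."""

    table: pd.DataFrame
    spectra: Dict[Tuple[int, str], ReflectanceSpectrum]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.table)

    def spectrum(self, subject: int, site_type: str) -> ReflectanceSpectrum:
        return self.spectra[(subject, site_type)]

    def to_dir(self, directory) -> None:
        directory = Path(directory)
        (directory / "spectra").mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "cohort.csv", index=False)
        for (subject, site), spec in self.spectra.items():
            spec.to_csv(directory / "spectra" / f"s{subject:03d}_{site}.csv")

    @classmethod
    def from_dir(cls, directory, config: CohortConfig | None = None) -> "Cohort":
        directory = Path(directory)
        table = pd.read_csv(directory / "cohort.csv")
        spectra = {}
        for _, row in table.iterrows():
            subject = int(row["subject"])
            site = row["site_type"]
            spectra[(subject, site)] = ReflectanceSpectrum.from_csv(
                directory / "spectra" / f"s{subject:03d}_{site}.csv"
            )
        return cls(table=table, spectra=spectra, config=config or CohortConfig())


def generate_cohort(
    config: CohortConfig, basis: ChromophoreBasis | None = None
) -> Cohort:
    """Generate a paired lesion/uninvolved cohort, seed-deterministic."""
    if basis is None:
        basis = load_chromophore_basis(wavelengths=default_analysis_grid())
    rng = np.random.default_rng(config.seed)
    rows = []
    spectra: Dict[Tuple[int, str], ReflectanceSpectrum] = {}
    for subject in range(config.n_subjects):
        for site_type in (LESION, UNINVOLVED):
            phys = sample_physiology(config, site_type, rng)
            spectrum = simulate_drs_measurement(phys, basis, config, rng)
            corneo = simulate_corneometer(
                phys, rng, noise_sd=config.corneometer_noise_sd
            )
            mex = simulate_mexameter(*_mexameter_reflectance(phys, basis, config))
            pasi = simulate_pasi_scores(
                phys, config.n_raters, rng, rater_noise_sd=config.rater_noise_sd
            )
            row = {
                "subject": subject,
                "site_type": site_type,
                "corneometer": corneo,
                "mexameter": mex,
                "pasi_erythema": pasi[0],
                "pasi_thickness": pasi[1],
                "pasi_desquamation": pasi[2],
            }
            row.update({f"true_{c}": getattr(phys, c) for c in _TRUTH_COLS})
            row["true_c_thb"] = phys.c_thb
            rows.append(row)
            spectra[(subject, site_type)] = spectrum
    columns = (
        ["subject", "site_type", "corneometer", "mexameter",
         "pasi_erythema", "pasi_thickness", "pasi_desquamation"]
        + [f"true_{c}" for c in _TRUTH_COLS]
        + ["true_c_thb"]
    )
    table = pd.DataFrame(rows, columns=columns)
    return Cohort(table=table, spectra=spectra, config=config)
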