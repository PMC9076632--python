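"""Reference chromophore spectra and the ChromophoreBasis container.

The bundled spectra are SYNTHETIC analytic approximations, not literature
tables: smooth shape-preserving interpolants through anchor points chosen to
reproduce the well-known qualitative features of the real spectra —
oxyhemoglobin's 542/577 nm double peak, deoxyhemoglobin's single 556 nm peak
and its ~10x stronger absorption at 660 nm, and the rise of the first water
absorption overtone across 1230–1380 nm. Magnitudes are of the right order
for skin work (hemoglobin in mm^-1 per uM including the ln(10) Beer's-law
factor; water in mm^-1), so that tens of uM of hemoglobin and ~60% water
yield realistic skin absorption. Every quantitative result in this package
is self-consistent with this basis; none is a literature value.

Hemoglobin extinction is identically zero above ~1150 nm: hemoglobin
absorption in the first water overtone band is negligible, and zeroing it
makes the synthetic cohort's water-band absorption an exactly scaled water
spectrum when the bound-water distortion vanishes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "ChromophoreBasis",
    "load_chromophore_basis",
    "synthetic_hemoglobin_extinction",
    "synthetic_water_absorption",
    "write_fixture_files",
    "default_analysis_grid",
    "HEMOGLOBIN_WINDOW",
    "WATER_WINDOW",
]

HEMOGLOBIN_WINDOW = (500.0, 600.0)
WATER_WINDOW = (1230.0, 1380.0)
MEXAMETER_WAVELENGTHS = (568.0, 660.0)

# Anchor tables: wavelength (nm) -> absorption per unit concentration
# (mm^-1 uM^-1, ln(10) folded in). Order-of-magnitude calibrated to the
# classic compiled hemoglobin spectra but NOT copied from them.
_O2HB_ANCHORS = (
    (450.0, 1.45e-2),
    (480.0, 6.2e-3),
    (500.0, 4.8e-3),
    (520.0, 7.0e-3),
    (530.0, 9.2e-3),
    (542.0, 1.23e-2),
    (550.0, 1.10e-2),
    (560.0, 7.5e-3),
    (569.0, 1.04e-2),
    (577.0, 1.29e-2),
    (586.0, 7.0e-3),
    (600.0, 7.4e-4),
    (620.0, 2.2e-4),
    (660.0, 7.4e-5),
    (700.0, 6.7e-5),
    (760.0, 1.35e-4),
    (800.0, 1.90e-4),
    (900.0, 2.76e-4),
    (1000.0, 2.5e-4),
    (1100.0, 2.1e-4),
)
_HHB_ANCHORS = (
    (450.0, 1.35e-2),
    (480.0, 6.0e-3),
    (500.0, 4.8e-3),
    (520.0, 7.3e-3),
    (530.0, 8.8e-3),
    (542.0, 1.05e-2),
    (550.0, 1.18e-2),
    (556.0, 1.23e-2),
    (569.0, 1.04e-2),
    (577.0, 8.5e-3),
    (586.0, 7.4e-3),
    (600.0, 3.4e-3),
    (620.0, 2.6e-3),
    (660.0, 1.6e-3),
    (700.0, 7.0e-4),
    (760.0, 3.9e-4),
    (800.0, 1.8e-4),
    (900.0, 2.0e-4),
    (1000.0, 1.4e-4),
    (1100.0, 9.0e-5),
)
# Pure-water absorption coefficient anchors, mm^-1.
_WATER_ANCHORS = (
    (450.0, 9.2e-6),
    (500.0, 2.5e-5),
    (550.0, 4.5e-5),
    (600.0, 2.2e-4),
    (650.0, 3.2e-4),
    (700.0, 6.0e-4),
    (750.0, 2.6e-3),
    (800.0, 2.0e-3),
    (850.0, 4.3e-3),
    (900.0, 6.8e-3),
    (970.0, 4.8e-2),
    (1000.0, 3.6e-2),
    (1050.0, 2.0e-2),
    (1100.0, 1.7e-2),
    (1150.0, 5.5e-2),
    (1190.0, 1.05e-1),
    (1230.0, 8.8e-2),
    (1250.0, 8.2e-2),
    (1270.0, 8.0e-2),
    (1300.0, 1.2e-1),
    (1330.0, 1.8e-1),
    (1350.0, 2.6e-1),
    (1380.0, 4.5e-1),
    (1400.0, 7.5e-1),
    (1430.0, 2.2),
    (1450.0, 2.9),
    (1500.0, 2.05),
    (1550.0, 1.1),
    (1600.0, 0.67),
)

_FIXTURE_RANGE = (450.0, 1600.0)
_HB_CUTOFF = (1100.0, 1150.0)  # hemoglobin tapers linearly to 0 here


def _anchor_interp(anchors, wavelengths: np.ndarray) -> np.ndarray:
    xs = np.array([a[0] for a in anchors])
    ys = np.array([a[1] for a in anchors])
    # shape-preserving interpolation of log-values keeps spectra positive
    interp = PchipInterpolator(xs, np.log(ys), extrapolate=False)
    out = np.exp(interp(np.clip(wavelengths, xs[0], xs[-1])))
    return out


def _hb_taper(wavelengths: np.ndarray) -> np.ndarray:
    lo, hi = _HB_CUTOFF
    t = np.clip((hi - wavelengths) / (hi - lo), 0.0, 1.0)
    return t


def synthetic_hemoglobin_extinction(wavelengths) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (eps_o2hb, eps_hhb) in mm^-1 uM^-1 on the given grid."""
    wl = np.asarray(wavelengths, dtype=float)
    taper = _hb_taper(wl)
    return (
        _anchor_interp(_O2HB_ANCHORS, wl) * taper,
        _anchor_interp(_HHB_ANCHORS, wl) * taper,
    )


def synthetic_water_absorption(wavelengths) -> np.ndarray:
    """Synthetic pure-water absorption coefficient, mm^-1."""
    return _anchor_interp(_WATER_ANCHORS, np.asarray(wavelengths, dtype=float))


def default_analysis_grid() -> np.ndarray:
    """Wavelength grid of the study: 2 nm steps over both analysis windows
    (51 + 76 points) plus the Mexameter's 660 nm channel."""
    hb = np.arange(HEMOGLOBIN_WINDOW[0], HEMOGLOBIN_WINDOW[1] + 1, 2.0)
    water = np.arange(WATER_WINDOW[0], WATER_WINDOW[1] + 1, 2.0)
    return np.unique(np.concatenate([hb, [660.0], water]))


@dataclass(frozen=True)
class ChromophoreBasis:
    """Reference spectra resampled onto a common, strictly increasing grid."""

    wavelengths: np.ndarray
    eps_o2hb: np.ndarray
    eps_hhb: np.ndarray
    mu_a_water: np.ndarray
    provenance: str = "synthetic anchor-point approximation"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or (len(wl) > 1 and np.any(np.diff(wl) <= 0)):
            raise ValueError("wavelengths must be strictly increasing")
        for name in ("eps_o2hb", "eps_hhb", "mu_a_water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths", wl)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def resample(self, wavelengths) -> "ChromophoreBasis":
        wl = np.asarray(wavelengths, dtype=float)
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if wl.min() < lo or wl.max() > hi:
            raise ValueError(
                f"requested range [{wl.min()}, {wl.max()}] nm outside basis "
                f"coverage [{lo}, {hi}] nm"
            )
        return ChromophoreBasis(
            wavelengths=wl,
            eps_o2hb=np.interp(wl, self.wavelengths, self.eps_o2hb),
            eps_hhb=np.interp(wl, self.wavelengths, self.eps_hhb),
            mu_a_water=np.interp(wl, self.wavelengths, self.mu_a_water),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "eps_o2hb": self.eps_o2hb,
                "eps_hhb": self.eps_hhb,
                "mu_a_water": self.mu_a_water,
            }
        )


_HB_HEADER = """\
# Synthetic hemoglobin absorption basis (NOT a literature table).
# Shape-preserving interpolant through anchor points with the qualitative
# features of the classic compiled spectra; magnitudes order-of-accurate.
# Columns: wavelength_nm, eps_o2hb, eps_hhb  [mm^-1 per uM, ln(10) included].
# Hemoglobin is tapered to exactly zero above 1150 nm.
"""
_WATER_HEADER = """\
# Synthetic pure-water absorption coefficient (NOT a literature table).
# Shape-preserving interpolant through anchor points reproducing the visible
# transparency window and the 1190/1450 nm bands.
# Columns: wavelength_nm, mu_a_water  [mm^-1].
"""


def _fixture_frames(step: float = 2.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    wl = np.arange(_FIXTURE_RANGE[0], _FIXTURE_RANGE[1] + 0.5 * step, step)
    eps_o2, eps_h = synthetic_hemoglobin_extinction(wl)
    hb = pd.DataFrame(
        {"wavelength_nm": wl, "eps_o2hb": eps_o2, "eps_hhb": eps_h}
    )
    water = pd.DataFrame(
        {"wavelength_nm": wl, "mu_a_water": synthetic_water_absorption(wl)}
    )
    return hb, water


def write_fixture_files(directory) -> tuple[Path, Path]:
    """Write the bundled basis CSVs (with provenance headers) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hb, water = _fixture_frames()
    hb_path = directory / "hemoglobin_extinction_synthetic.csv"
    water_path = directory / "water_absorption_synthetic.csv"
    with open(hb_path, "w") as fh:
        fh.write(_HB_HEADER)
        hb.to_csv(fh, index=False, float_format="%.17e")
    with open(water_path, "w") as fh:
        fh.write(_WATER_HEADER)
        water.to_csv(fh, index=False, float_format="%.17e")
    return hb_path, water_path


def _read_fixture_csv(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), comment="#")


def load_chromophore_basis(
    source: str = "synthetic-default", wavelengths=None
) -> ChromophoreBasis:
    """Load a chromophore basis and resample it onto an analysis grid.

    Parameters
    ----------
    source : str
        ``"synthetic-default"`` for the bundled synthetic fixtures, or a
        directory containing ``hemoglobin_extinction_synthetic.csv`` and
        ``water_absorption_synthetic.csv``.
    wavelengths : array-like, optional
        Target grid (nm); defaults to :func:`default_analysis_grid`.
        A grid outside the fixture coverage raises ``ValueError``.
    """
    if source == "synthetic-default":
        pkg = resources.files("skindrs.data")
        hb = _read_fixture_csv(
            (pkg / "hemoglobin_extinction_synthetic.csv").read_text()
        )
        water = _read_fixture_csv(
            (pkg / "water_absorption_synthetic.csv").read_text()
        )
    else:
        directory = Path(source)
        hb = _read_fixture_csv(
            (directory / "hemoglobin_extinction_synthetic.csv").read_text()
        )
        water = _read_fixture_csv(
            (directory / "water_absorption_synthetic.csv").read_text()
        )
    if not np.array_equal(hb["wavelength_nm"], water["wavelength_nm"]):
        raise ValueError("fixture wavelength grids differ")
    native = ChromophoreBasis(
        wavelengths=hb["wavelength_nm"].to_numpy(),
        eps_o2hb=hb["eps_o2hb"].to_numpy(),
        eps_hhb=hb["eps_hhb"].to_numpy(),
        mu_a_water=water["mu_a_water"].to_numpy(),
    )
    if wavelengths is None:
        wavelengths = default_analysis_grid()
    return native.resample(wavelengths)
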