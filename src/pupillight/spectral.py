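"""Alpha-opic photometry: from raw spectrometer samples to light metrics.

Converts spectral irradiance measured on an irregular wavelength grid into
the quantities the pupil analyses consume: photopic illuminance, the five
alpha-opic irradiances and their equivalent daylight illuminances (EDIs,
CIE S026 semantics), and the melanopic daylight efficacy ratio (mel-DER).

The melanopic EDI (mEDI) of a test spectrum is the illuminance of standard
daylight D65 that would produce the same melanopic irradiance as the test
spectrum; the other four classes generalise the same construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import (
    ACTION_SPECTRA,
    ALPHA_CLASSES,
    D65,
    D65_NORMALIZATION,
    GRID,
    KM_LM_PER_W,
    N_GRID,
    VLAMBDA,
)

__all__ = [
    "ALPHA_CLASSES",
    "ActionSpectrum",
    "InvalidSpectrumError",
    "PhotometricRecord",
    "SpectrumRaw",
    "SpectrumRegular",
    "action_spectrum",
    "alpha_edi",
    "alpha_irradiance",
    "band_irradiance",
    "d65_spectrum",
    "illuminance",
    "photometrics",
    "regrid_spectrum",
]


class InvalidSpectrumError(ValueError):
    """Raised when a spectral sample cannot be interpreted."""


@dataclass(frozen=True)
class SpectrumRaw:
    """One spectrometer sample on its native irregular wavelength grid.

    Wavelengths must be strictly increasing and lie within 350-800 nm.
    Negative irradiance values (instrument noise) are permitted on input;
    they are clamped to zero during regridding and counted.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    saturated: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise InvalidSpectrumError("wavelengths and values must be 1-D and equal length")
        if wl.size < 2:
            raise InvalidSpectrumError("need at least 2 spectral samples")
        if np.any(~np.isfinite(wl)) or np.any(~np.isfinite(vals)):
            raise InvalidSpectrumError("NaN/inf in spectral sample")
        if np.any(np.diff(wl) <= 0):
            raise InvalidSpectrumError("wavelengths must be strictly increasing")
        if wl[0] < 350.0 or wl[-1] > 800.0:
            raise InvalidSpectrumError("wavelengths must lie within [350, 800] nm")


@dataclass(frozen=True)
class SpectrumRegular:
    """Spectral irradiance on the canonical 380..780 nm 1 nm grid.

    ``values`` are bin-mean spectral irradiances (W m^-2 nm^-1): entry k
    represents the mean over the band centred on wavelength 380 + k nm
    (half-width bands at the two grid edges).  With that convention the
    trapezoid rule on the grid integrates band energy exactly.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (N_GRID,):
            raise InvalidSpectrumError(f"expected {N_GRID} values, got {vals.shape}")
        if np.any(~np.isfinite(vals)):
            raise InvalidSpectrumError("NaN/inf in regular spectrum")
        if np.any(vals < 0):
            raise InvalidSpectrumError("regular spectrum must be nonnegative")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return GRID

    def total_irradiance(self) -> float:
        """Total irradiance over 380-780 nm (W m^-2), trapezoid rule."""
        return float(np.trapezoid(self.values, GRID))

    def scaled(self, factor: float) -> "SpectrumRegular":
        return SpectrumRegular(self.values * factor)


@dataclass(frozen=True)
class ActionSpectrum:
    """A photoreceptor spectral sensitivity on the canonical grid.

    ``d65_normalization`` is the alpha-opic irradiance of D65 per lux of D65
    (W m^-2 lx^-1); dividing an alpha-opic irradiance by it yields the EDI.
    The photopic class carries no EDI normalisation (its lux-valued metric
    is the illuminance itself).
    """

    name: str
    weights: np.ndarray
    d65_normalization: float | None


@dataclass(frozen=True)
class PhotometricRecord:
    """All light metrics derived from one spectral sample."""

    illuminance_lx: float
    alpha_irradiance: dict[str, float] = field(default_factory=dict)
    alpha_edi_lx: dict[str, float] = field(default_factory=dict)
    mel_der: float | None = None  # None when illuminance == 0

    def to_row(self) -> dict[str, float]:
        """Flatten to the canonical CSV column naming."""
        row: dict[str, float] = {"illuminance_lx": self.illuminance_lx}
        for name in ALPHA_CLASSES:
            row[f"{name}_irradiance_w_m2"] = self.alpha_irradiance[name]
            row[f"{name}_edi_lx"] = self.alpha_edi_lx[name]
        row["mel_der"] = np.nan if self.mel_der is None else self.mel_der
        return row


def _cumulative_integral(wl: np.ndarray, vals: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear density (wl, vals) from wl[0] to each
    point in ``at`` (points must lie within [wl[0], wl[-1]])."""
    merged = np.union1d(wl, at)
    dens = np.interp(merged, wl, vals)
    cum = np.concatenate([[0.0], np.cumsum(np.diff(merged) * (dens[1:] + dens[:-1]) / 2.0)])
    idx = np.searchsorted(merged, at)
    return cum[idx]


def regrid_spectrum(raw: SpectrumRaw) -> SpectrumRegular:
    """Conservative (flux-preserving) rebinning onto the 380-780 nm 1 nm grid.

    The raw samples define a piecewise-linear spectral density.  Negative
    values are clamped to zero, data outside 380-780 nm are discarded, and
    each destination value is the exact mean of the density over its band
    (half-width bands at the edges).  Band energy is conserved to floating
    point precision for any band aligned with the destination bin edges,
    and the trapezoid integral over the full grid equals the integral of
    the clamped input over 380-780 nm exactly.
    """
    wl = raw.wavelengths_nm
    vals = np.clip(raw.values, 0.0, None)
    inside = (wl >= 380.0) & (wl <= 780.0)
    # keep one sample just outside each edge so the density at the edge is defined
    lo_pad = np.where(~inside & (wl < 380.0))[0]
    hi_pad = np.where(~inside & (wl > 780.0))[0]
    keep = inside.copy()
    if lo_pad.size:
        keep[lo_pad[-1]] = True
    if hi_pad.size:
        keep[hi_pad[0]] = True
    wl, vals = wl[keep], vals[keep]
    if np.count_nonzero((wl >= 380.0) & (wl <= 780.0)) < 2 and not (
        wl.size >= 2 and wl[0] <= 380.0 and wl[-1] >= 780.0
    ):
        raise InvalidSpectrumError("fewer than 2 samples inside [380, 780] nm")

    # clip the support of the density to [380, 780] and to the measured span
    lo = max(380.0, wl[0])
    hi = min(780.0, wl[-1])
    edges = np.concatenate([[380.0], GRID[:-1] + 0.5, [780.0]])  # 402 edges
    edges_c = np.clip(edges, lo, hi)
    cum = _cumulative_integral(wl, vals, edges_c)
    bin_energy = np.diff(cum)  # 401 bands
    widths = np.diff(edges)  # 0.5, 1, 1, ..., 1, 0.5
    return SpectrumRegular(bin_energy / widths)


def band_irradiance(spec: SpectrumRegular, lo_nm: float, hi_nm: float) -> float:
    """Irradiance in the band [lo_nm, hi_nm] (W m^-2), from the bin-mean
    representation (exact for band edges on the half-integer bin edges)."""
    if not 380.0 <= lo_nm < hi_nm <= 780.0:
        raise ValueError("band must satisfy 380 <= lo < hi <= 780")
    edges = np.concatenate([[380.0], GRID[:-1] + 0.5, [780.0]])
    widths = np.diff(edges)
    overlap = np.clip(np.minimum(edges[1:], hi_nm) - np.maximum(edges[:-1], lo_nm), 0.0, None)
    return float(np.sum(spec.values * overlap * (widths > 0)))


def action_spectrum(name: str) -> ActionSpectrum:
    """Return the embedded spectral sensitivity for one photoreceptor class.

    Valid names: s_cone, m_cone, l_cone, rhodopic, melanopic, photopic.
    """
    if name not in ACTION_SPECTRA:
        raise KeyError(
            f"unknown photoreceptor class {name!r}; valid: {sorted(ACTION_SPECTRA)}"
        )
    norm = D65_NORMALIZATION.get(name)
    return ActionSpectrum(name=name, weights=ACTION_SPECTRA[name].copy(), d65_normalization=norm)


def illuminance(spec: SpectrumRegular) -> float:
    """Photopic illuminance in lux: K_m * sum E(lambda) V(lambda) d(lambda)."""
    return KM_LM_PER_W * float(np.sum(spec.values * VLAMBDA))


def alpha_irradiance(spec: SpectrumRegular, name: str) -> float:
    """Alpha-opic irradiance (W m^-2) for one of the five receptor classes."""
    if name not in ALPHA_CLASSES:
        raise KeyError(f"unknown alpha-opic class {name!r}; valid: {ALPHA_CLASSES}")
    return float(np.sum(spec.values * ACTION_SPECTRA[name]))


def alpha_edi(spec: SpectrumRegular, name: str) -> float:
    """Alpha-opic equivalent daylight illuminance (lux); melanopic -> mEDI."""
    return alpha_irradiance(spec, name) / D65_NORMALIZATION[name]


def photometrics(spec: SpectrumRegular) -> PhotometricRecord:
    """Bundle illuminance, all alpha-opic irradiances/EDIs and mel-DER."""
    lux = illuminance(spec)
    irr = {name: alpha_irradiance(spec, name) for name in ALPHA_CLASSES}
    edi = {name: irr[name] / D65_NORMALIZATION[name] for name in ALPHA_CLASSES}
    mel_der = edi["melanopic"] / lux if lux > 0 else None
    return PhotometricRecord(
        illuminance_lx=lux, alpha_irradiance=irr, alpha_edi_lx=edi, mel_der=mel_der
    )


def d65_spectrum(target_illuminance_lx: float = 1.0) -> SpectrumRegular:
    """The embedded D65 daylight reference scaled to a given illuminance."""
    if target_illuminance_lx < 0:
        raise ValueError("illuminance must be nonnegative")
    base = SpectrumRegular(D65.copy())
    return base.scaled(target_illuminance_lx / illuminance(base))
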