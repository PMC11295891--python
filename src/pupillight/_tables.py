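"""Embedded photometric reference data on the canonical 380-780 nm grid.

Everything here is reconstructed from standard, publicly tabulated sources so
the package never downloads anything at run time:

* ``VLAMBDA`` -- the CIE 1924 photopic luminous efficiency function V(lambda),
  embedded at its standard 5 nm resolution and interpolated to 1 nm with a
  monotone piecewise cubic (PCHIP).
* ``D65`` -- the CIE standard daylight illuminant D65 relative spectral power
  distribution, embedded at 10 nm resolution and interpolated to 1 nm.
* the five alpha-opic action spectra (S-, M-, L-cone-opic, rhodopic,
  melanopic), built from the Govardovskii et al. (2000) A1 visual-pigment
  nomogram evaluated at each photoreceptor class's pigment peak, filtered by
  a standard-observer ocular-media (lens) density template plus, for the
  cones, a macular pigment template, converted from quantal to energy units
  and peak-normalised to 1.

The nomogram route is an approximation to the officially tabulated alpha-opic
sensitivities: peak positions and bandwidths agree, but EDI values computed
from arbitrary spectra can differ from official-calculator values at the
percent level.  All equivalent-daylight normalisations in this package are
computed against the embedded D65, so the defining identity
EDI(D65) == illuminance(D65) holds exactly for every class.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

#: canonical destination grid, 380..780 nm inclusive, 1 nm spacing
GRID = np.arange(380, 781, dtype=float)
N_GRID = GRID.size  # 401

# CIE 1924 V(lambda) at 5 nm steps, 380-780 nm (81 values).
_VL_5NM = np.array([
    0.000039, 0.000064, 0.000120, 0.000217, 0.000396,
    0.000640, 0.001210, 0.002180, 0.004000, 0.007300,
    0.011600, 0.016840, 0.023000, 0.029800, 0.038000,
    0.048000, 0.060000, 0.073900, 0.090980, 0.112600,
    0.139020, 0.169300, 0.208020, 0.258600, 0.323000,
    0.407300, 0.503000, 0.608200, 0.710000, 0.793200,
    0.862000, 0.914850, 0.954000, 0.980300, 0.994950,
    1.000000, 0.995000, 0.978600, 0.952000, 0.915400,
    0.870000, 0.816300, 0.757000, 0.694900, 0.631000,
    0.566800, 0.503000, 0.441200, 0.381000, 0.321000,
    0.265000, 0.217000, 0.175000, 0.138200, 0.107000,
    0.081600, 0.061000, 0.044580, 0.032000, 0.023200,
    0.017000, 0.011920, 0.008210, 0.005723, 0.004102,
    0.002929, 0.002091, 0.001484, 0.001047, 0.000740,
    0.000520, 0.000361, 0.000249, 0.000172, 0.000120,
    0.000085, 0.000060, 0.000042, 0.000030, 0.000021,
    0.000015,
])

# CIE standard illuminant D65, relative SPD at 10 nm steps, 380-780 nm.
_D65_10NM = np.array([
    49.98, 54.65, 82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81,
    114.86, 115.92, 108.81, 109.35, 107.80, 104.79, 107.69, 104.41,
    104.05, 100.00, 96.33, 95.79, 88.69, 90.01, 89.60, 87.70, 83.29,
    83.70, 80.03, 80.21, 82.28, 78.28, 69.72, 71.61, 74.35, 61.60,
    69.89, 75.09, 63.59, 46.42, 66.81, 63.38,
])

# Ocular-media (lens + other pre-retinal) optical density for the standard
# 32-year-old observer, 10 nm steps 380-780 nm (zero above 700 nm).
_LENS_DENSITY_10NM = np.array([
    2.6000, 2.1000, 1.7649, 1.4935, 1.2341, 0.9650, 0.7378, 0.5534,
    0.4320, 0.3400, 0.2700, 0.2230, 0.1850, 0.1500, 0.1230, 0.1000,
    0.0810, 0.0651, 0.0541, 0.0445, 0.0362, 0.0285, 0.0220, 0.0168,
    0.0125, 0.0090, 0.0060, 0.0040, 0.0025, 0.0015, 0.0008, 0.0003,
    0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
])


def _interp_to_grid(values: np.ndarray, step: int) -> np.ndarray:
    src = np.arange(380, 781, step, dtype=float)
    out = PchipInterpolator(src, values)(GRID)
    return np.clip(out, 0.0, None)


VLAMBDA = _interp_to_grid(_VL_5NM, 5)
D65 = _interp_to_grid(_D65_10NM, 10)
_LENS_DENSITY = np.clip(
    PchipInterpolator(np.arange(380, 781, 10.0), _LENS_DENSITY_10NM)(GRID),
    0.0, None,
)

# Macular pigment density template: Gaussian approximation peaking at 458 nm.
# Applied to the cone classes only (rods and ipRGCs are extrafoveal).
_MACULAR_DENSITY = 0.10 * np.exp(-0.5 * ((GRID - 458.0) / 30.0) ** 2)

#: pigment peak wavelengths (nm) for the five alpha-opic classes
PIGMENT_PEAKS_NM = {
    "s_cone": 420.0,
    "m_cone": 530.0,
    "l_cone": 558.0,
    "rhodopic": 498.0,
    "melanopic": 480.0,
}

ALPHA_CLASSES = ("s_cone", "m_cone", "l_cone", "rhodopic", "melanopic")


def _govardovskii_quantal(lambda_max: float, wl: np.ndarray) -> np.ndarray:
    """Govardovskii et al. (2000) A1 pigment absorbance template (quantal)."""
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha_band = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta_band = 0.26 * np.exp(-(((wl - lam_beta) / b_beta) ** 2))
    return alpha_band + beta_band


def _build_action_spectrum(name: str) -> np.ndarray:
    pigment = _govardovskii_quantal(PIGMENT_PEAKS_NM[name], GRID)
    density = _LENS_DENSITY.copy()
    if name in ("s_cone", "m_cone", "l_cone"):
        density = density + _MACULAR_DENSITY
    transmittance = 10.0 ** (-density)
    # quantal sensitivity -> energy sensitivity (photon energy ~ 1/lambda)
    energy = pigment * transmittance * GRID
    return energy / energy.max()


ACTION_SPECTRA: dict[str, np.ndarray] = {
    name: _build_action_spectrum(name) for name in ALPHA_CLASSES
}
ACTION_SPECTRA["photopic"] = VLAMBDA / VLAMBDA.max()

#: maximum luminous efficacy of radiation, lm/W (SI definition)
KM_LM_PER_W = 683.002

# Alpha-opic irradiance of D65 per lux of D65 illuminance (W m^-2 lx^-1),
# computed once from the embedded tables; these are the EDI denominators.
_d65_illuminance = KM_LM_PER_W * float(np.sum(D65 * VLAMBDA))
D65_NORMALIZATION: dict[str, float] = {
    name: float(np.sum(D65 * ACTION_SPECTRA[name])) / _d65_illuminance
    for name in ALPHA_CLASSES
}
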