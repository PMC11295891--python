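"""Synthetic cohorts and recording sessions for the pupil/light pipeline.

Emulates a wearable protocol: ~1 h of naturalistic "field" exposure sampled
every 10 s, a 10 min in-laboratory dark adaptation, and a laboratory light
programme of four colour phases (red/blue/green/white LED primaries) at three
illuminance levels each, interleaved with <0.2 lx dark gaps.  Spectra are
generated physically (Planckian daylight, Gaussian LED primaries, triphosphor
fluorescent combs) and every light metric downstream is computed from those
spectra, so illuminance and mEDI dissociate in the lab and correlate tightly
in the field, as in real recordings.

Pupil diameter follows an age-dependent model in one of two parameterisations
(see ``CALIBRATION``):

* ``loglinear`` -- D = b0(age) + b1(age) * log10(mEDI), with (b0, b1)
  interpolated linearly between a young (18 y) and an old (87 y) anchor;
* ``cluster`` -- D = b0_c + b1_c * age for the sample's light-level cluster
  (dark, 1-10, 10-100, 100-1000, >1000 lx mEDI).

Noise is heteroscedastic (wider in dim field light, narrow in darkness and
bright light), and quality fields emulate the observed missingness: a
configurable fraction of frames with detection confidence below 0.6,
occasional pupil misestimates outside 1-9 mm, and saturated spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import spectral as sp
from ._tables import GRID

__all__ = [
    "CALIBRATION",
    "GeneratorConfig",
    "IlluminantSpec",
    "Participant",
    "illuminant_spectrum",
    "sample_cohort",
    "simulate_dark",
    "simulate_field",
    "simulate_field_clusters",
    "simulate_lab",
    "simulate_loglinear_samples",
    "simulate_study",
    "true_pupil",
    "write_ground_truth",
]

#: Pupil-model calibration: the printed per-individual log-linear regressions
#: (young/old anchor cases) and the per-cluster age regressions (intercept at
#: age 0 in mm; slope in mm per year).  Cluster noise SDs are generator
#: choices: small in controlled darkness, largest in dim field light and
#: shrinking as light level rises.
CALIBRATION: dict = {
    "loglinear_anchors": {
        "young": {"age": 18.0, "b0_mm": 6.28, "b1_mm_per_log10lx": -0.998},
        "old": {"age": 87.0, "b0_mm": 3.83, "b1_mm_per_log10lx": -0.463},
    },
    "cluster_params": {
        "dark": {"b0_mm": 8.13, "b1_mm_per_year": -0.0408, "noise_sd_mm": 0.20},
        "1-10": {"b0_mm": 6.16, "b1_mm_per_year": -0.0374, "noise_sd_mm": 0.50},
        "10-100": {"b0_mm": 4.32, "b1_mm_per_year": -0.0198, "noise_sd_mm": 0.40},
        "100-1000": {"b0_mm": 3.55, "b1_mm_per_year": -0.0141, "noise_sd_mm": 0.30},
        ">1000": {"b0_mm": 2.57, "b1_mm_per_year": -0.0080, "noise_sd_mm": 0.20},
    },
    "cluster_medi_bounds_lx": {
        "1-10": (1.0, 10.0),
        "10-100": (10.0, 100.0),
        "100-1000": (100.0, 1000.0),
        ">1000": (1000.0, 10000.0),
    },
}

#: lab LED primary peak wavelengths (nm) and per-colour maximum illuminance (lx)
LAB_PRIMARIES = {"red": 630.0, "green": 527.0, "blue": 467.0}
LAB_MAX_LX = {"red": 480.0, "blue": 250.0, "green": 1000.0, "white": 1000.0}
LAB_LEVELS_LX = (10.0, 100.0, None)  # None -> colour maximum

SAMPLING_INTERVAL_S = 10.0


@dataclass(frozen=True)
class Participant:
    id: str
    age_years: float
    sex: str
    iris_colour: str
    habitual_caffeine_mg_kg: float
    acute_caffeine_mg_kg: float
    random_intercept_mm: float

    def __post_init__(self) -> None:
        if not 18.0 <= self.age_years <= 87.0:
            raise ValueError("age must lie in [18, 87] years")
        if min(self.habitual_caffeine_mg_kg, self.acute_caffeine_mg_kg) < 0:
            raise ValueError("caffeine doses must be nonnegative")


@dataclass
class GeneratorConfig:
    """Study conditions for the generator; defaults emulate the protocol."""

    mode: str = "loglinear"  # or "cluster"
    sigma_random_intercept_mm: float = 0.3
    #: field pupil noise SD, linear in log10 mEDI between the two taps
    noise_sd_at_log0_mm: float = 0.5
    noise_sd_at_log4_mm: float = 0.15
    noise_sd_floor_mm: float = 0.15
    #: fraction of frames with detection confidence below 0.6
    low_confidence_fraction: float = 0.4337
    saturation_probability: float = 0.0141
    misestimate_probability: float = 0.0016
    medi_floor_lx: float = 0.01
    field_illuminance_range_lx: tuple[float, float] = (0.5, 1.0e5)
    daylight_cct_range_k: tuple[float, float] = (5000.0, 7500.0)
    #: family mixture below the daylight threshold: led, fluorescent, daylight
    indoor_family_probs: tuple[float, float, float] = (0.4, 0.3, 0.3)
    daylight_threshold_lx: float = 1000.0
    sex_effect_mm: float = 0.0
    iris_effect_mm: dict = field(default_factory=lambda: {"blue": 0.0, "hazel/green": 0.0, "brown": 0.0})
    caffeine_effect_mm_per_mg_kg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("loglinear", "cluster"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        for frac in (self.low_confidence_fraction, self.saturation_probability,
                     self.misestimate_probability):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.sigma_random_intercept_mm, self.noise_sd_floor_mm,
               self.noise_sd_at_log0_mm, self.noise_sd_at_log4_mm) < 0:
            raise ValueError("noise SDs must be nonnegative")


@dataclass(frozen=True)
class IlluminantSpec:
    """Recipe for one physically generated illuminant spectrum."""

    family: str  # blackbody | led_rgbw | fluorescent | lab_primary
    target_illuminance_lx: float
    cct_k: float = 6500.0
    channel_weights: tuple = (1.0, 1.0, 1.0, 1.0)  # r, g, b, w for led_rgbw
    colour: str = "white"  # for lab_primary
    fwhm_nm: float = 25.0

    def __post_init__(self) -> None:
        if self.target_illuminance_lx < 0:
            raise ValueError("target illuminance must be nonnegative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# cohort


def sample_cohort(n: int, seed, config: GeneratorConfig | None = None) -> list[Participant]:
    """Draw a cohort: ages uniform on [18, 87], balanced sex, iris-colour
    frequencies matching the study sample (30/20/49% blue, hazel/green,
    brown), log-normal habitual caffeine and zero-inflated acute caffeine."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    config = config or GeneratorConfig()
    rng = _rng(seed)
    ages = rng.uniform(18.0, 87.0, n)
    sexes = np.array(["female", "male"])[(np.arange(n) % 2)]
    rng.shuffle(sexes)
    iris_p = np.array([0.30, 0.20, 0.49])
    iris = rng.choice(["blue", "hazel/green", "brown"], size=n, p=iris_p / iris_p.sum())
    habitual = rng.lognormal(mean=0.8, sigma=0.6, size=n)  # ~2-3 mg/kg/day typical
    acute = np.where(rng.uniform(size=n) < 0.5, rng.lognormal(0.0, 0.5, n), 0.0)
    intercepts = rng.normal(0.0, config.sigma_random_intercept_mm, n)
    return [
        Participant(
            id=f"P{i:03d}",
            age_years=float(ages[i]),
            sex=str(sexes[i]),
            iris_colour=str(iris[i]),
            habitual_caffeine_mg_kg=float(habitual[i]),
            acute_caffeine_mg_kg=float(acute[i]),
            random_intercept_mm=float(intercepts[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# spectra


def _gaussian(peak_nm: float, fwhm_nm: float) -> np.ndarray:
    sd = fwhm_nm / 2.3548200450309493
    return np.exp(-0.5 * ((GRID - peak_nm) / sd) ** 2)


def _blackbody(cct_k: float) -> np.ndarray:
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    lam = GRID * 1e-9
    shape = 1.0 / (lam**5 * np.expm1(h * c / (lam * kb * cct_k)))
    return shape / shape.max()


def _phosphor_white() -> np.ndarray:
    # blue pump + broad phosphor, typical white LED
    return 0.35 * _gaussian(450.0, 20.0) + _gaussian(560.0, 120.0)


def _fluorescent() -> np.ndarray:
    lines = [(405.0, 0.25), (436.0, 0.6), (487.0, 0.3), (546.0, 1.0), (577.0, 0.5), (611.0, 0.9)]
    out = np.zeros_like(GRID)
    for peak, w in lines:
        out += w * _gaussian(peak, 10.0)
    return out


def illuminant_spectrum(spec: IlluminantSpec) -> sp.SpectrumRegular:
    """Generate the spectrum for a recipe and rescale to its target illuminance."""
    if spec.family == "blackbody":
        shape = _blackbody(spec.cct_k)
    elif spec.family == "led_rgbw":
        r, g, b, w = spec.channel_weights
        shape = (
            r * _gaussian(630.0, spec.fwhm_nm)
            + g * _gaussian(527.0, spec.fwhm_nm)
            + b * _gaussian(467.0, spec.fwhm_nm)
            + w * _phosphor_white()
        )
    elif spec.family == "fluorescent":
        shape = _fluorescent()
    elif spec.family == "lab_primary":
        if spec.colour == "white":
            shape = _phosphor_white()
        else:
            shape = _gaussian(LAB_PRIMARIES[spec.colour], spec.fwhm_nm)
    else:
        raise ValueError(f"unknown illuminant family {spec.family!r}")
    base = sp.SpectrumRegular(shape)
    lux = sp.illuminance(base)
    if lux <= 0:
        raise ValueError("zero-energy spectrum cannot reach a positive illuminance")
    return base.scaled(spec.target_illuminance_lx / lux)


# ---------------------------------------------------------------------------
# pupil model


def _loglinear_coeffs(age: float) -> tuple[float, float]:
    young = CALIBRATION["loglinear_anchors"]["young"]
    old = CALIBRATION["loglinear_anchors"]["old"]
    t = (age - young["age"]) / (old["age"] - young["age"])
    b0 = young["b0_mm"] + t * (old["b0_mm"] - young["b0_mm"])
    b1 = young["b1_mm_per_log10lx"] + t * (old["b1_mm_per_log10lx"] - young["b1_mm_per_log10lx"])
    return b0, b1


def _cluster_of_medi(medi_lx: float, condition: str) -> str | None:
    if condition == "dark":
        return "dark"
    if condition != "field" or medi_lx < 1.0:
        return None
    if medi_lx < 10.0:
        return "1-10"
    if medi_lx < 100.0:
        return "10-100"
    if medi_lx < 1000.0:
        return "100-1000"
    return ">1000"


def true_pupil(
    p: Participant,
    medi_lx: float,
    mode: str = "loglinear",
    config: GeneratorConfig | None = None,
    condition: str = "field",
) -> float:
    """Noise-free model pupil diameter (mm), clipped to the physical 1-9 mm range."""
    if medi_lx < 0:
        raise ValueError("mEDI must be nonnegative")
    config = config or GeneratorConfig(mode=mode)
    if mode == "loglinear":
        b0, b1 = _loglinear_coeffs(p.age_years)
        d = b0 + b1 * np.log10(max(medi_lx, config.medi_floor_lx))
    elif mode == "cluster":
        cluster = _cluster_of_medi(medi_lx, condition)
        if cluster is None:
            # out-of-cluster field sample: fall back to the nearest bin
            cluster = "1-10" if medi_lx < 1.0 else ">1000"
        par = CALIBRATION["cluster_params"][cluster]
        d = par["b0_mm"] + par["b1_mm_per_year"] * p.age_years
    else:
        raise ValueError(f"unknown pupil-model mode {mode!r}")
    d += p.random_intercept_mm
    d += config.sex_effect_mm * (1.0 if p.sex == "male" else -1.0) / 2.0
    d += config.iris_effect_mm.get(p.iris_colour, 0.0)
    d += config.caffeine_effect_mm_per_mg_kg * p.acute_caffeine_mg_kg
    return float(np.clip(d, 1.0, 9.0))


def _field_noise_sd(log10_medi: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    slope = (config.noise_sd_at_log4_mm - config.noise_sd_at_log0_mm) / 4.0
    sd = config.noise_sd_at_log0_mm + slope * np.clip(log10_medi, 0.0, None)
    return np.clip(sd, config.noise_sd_floor_mm, config.noise_sd_at_log0_mm)


# ---------------------------------------------------------------------------
# observation assembly


def _quality_fields(n: int, config: GeneratorConfig, rng: np.random.Generator):
    bad = rng.uniform(size=n) < config.low_confidence_fraction
    confidence = np.where(bad, rng.uniform(0.0, 0.6, n), rng.uniform(0.6, 1.0, n))
    saturated = rng.uniform(size=n) < config.saturation_probability
    misest = rng.uniform(size=n) < config.misestimate_probability
    return confidence, saturated, misest


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["saturated"] = df["saturated"].astype(bool)
    return df


def _make_rows(
    participant: Participant,
    spectra_metrics: list[dict],
    pupils: np.ndarray,
    condition: str,
    t0_s: float,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[dict]:
    n = len(spectra_metrics)
    confidence, saturated, misest = _quality_fields(n, config, rng)
    # the physical pupil stays within 1-9 mm; only misestimates fall outside
    pupils = np.clip(pupils, 1.0, 9.0)
    if misest.any():
        bad_vals = np.where(rng.uniform(size=n) < 0.5, rng.uniform(0.2, 0.95, n), rng.uniform(9.05, 12.0, n))
        pupils[misest] = bad_vals[misest]
    rows = []
    for i, pm in enumerate(spectra_metrics):
        row = {
            "participant_id": participant.id,
            "timestamp_s": t0_s + i * SAMPLING_INTERVAL_S,
            "condition": condition,
            "pupil_mm": float(pupils[i]),
            "confidence": float(confidence[i]),
            "saturated": bool(saturated[i]),
            "age_years": participant.age_years,
            "sex": participant.sex,
            "iris_colour": participant.iris_colour,
            "habitual_caffeine_mg_kg": participant.habitual_caffeine_mg_kg,
            "acute_caffeine_mg_kg": participant.acute_caffeine_mg_kg,
        }
        row.update(pm)
        rows.append(row)
    return rows


def _field_sample_metrics(config: GeneratorConfig, rng: np.random.Generator) -> dict:
    lo, hi = config.field_illuminance_range_lx
    lux = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
    if lux >= config.daylight_threshold_lx:
        spec = IlluminantSpec("blackbody", lux, cct_k=rng.uniform(*config.daylight_cct_range_k))
    else:
        fam = rng.choice(["led_rgbw", "fluorescent", "blackbody"], p=config.indoor_family_probs)
        if fam == "blackbody":
            spec = IlluminantSpec("blackbody", lux, cct_k=rng.uniform(*config.daylight_cct_range_k))
        elif fam == "led_rgbw":
            w = rng.uniform(0.0, 1.0, 4)
            w[3] = rng.uniform(0.5, 2.0)  # white channel dominates room LEDs
            spec = IlluminantSpec("led_rgbw", lux, channel_weights=tuple(w))
        else:
            spec = IlluminantSpec("fluorescent", lux)
    return sp.photometrics(illuminant_spectrum(spec)).to_row()


def simulate_field(
    cohort: list[Participant],
    n_per_participant: int,
    config: GeneratorConfig | None = None,
    seed=0,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """Naturalistic field exposure: log-uniform illuminances rendered with a
    daylight/LED/fluorescent illuminant mixture, pupil from the configured
    age model with heteroscedastic noise, 10 s cadence."""
    if n_per_participant < 1:
        raise ValueError("n_per_participant must be >= 1")
    config = config or GeneratorConfig()
    rng = _rng(seed)
    rows: list[dict] = []
    for p in cohort:
        metrics = [_field_sample_metrics(config, rng) for _ in range(n_per_participant)]
        medi = np.array([m["melanopic_edi_lx"] for m in metrics])
        log_medi = np.log10(np.maximum(medi, config.medi_floor_lx))
        base = np.array([true_pupil(p, m, config.mode, config, "field") for m in medi])
        pupils = base + rng.normal(0.0, 1.0, len(medi)) * _field_noise_sd(log_medi, config)
        rows += _make_rows(p, metrics, pupils, "field", t0_s, config, rng)
    return _rows_to_frame(rows)


def simulate_field_clusters(
    cohort: list[Participant],
    n_per_cluster: int,
    config: GeneratorConfig | None = None,
    seed=0,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """Field observations stratified by mEDI cluster (cluster-mode cohorts):
    every participant receives ``n_per_cluster`` samples whose mEDI is drawn
    log-uniformly inside each of the four field bins."""
    config = config or GeneratorConfig(mode="cluster")
    rng = _rng(seed)
    rows: list[dict] = []
    for p in cohort:
        metrics = []
        for cluster, (lo, hi) in CALIBRATION["cluster_medi_bounds_lx"].items():
            par = CALIBRATION["cluster_params"][cluster]
            for _ in range(n_per_cluster):
                target_medi = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi))
                fam = "blackbody" if target_medi >= 1000.0 else rng.choice(
                    ["led_rgbw", "fluorescent", "blackbody"], p=config.indoor_family_probs
                )
                if fam == "led_rgbw":
                    w = rng.uniform(0.0, 1.0, 4)
                    w[3] = rng.uniform(0.5, 2.0)
                    spec = IlluminantSpec("led_rgbw", 100.0, channel_weights=tuple(w))
                elif fam == "fluorescent":
                    spec = IlluminantSpec("fluorescent", 100.0)
                else:
                    spec = IlluminantSpec("blackbody", 100.0, cct_k=rng.uniform(*config.daylight_cct_range_k))
                s = illuminant_spectrum(spec)
                s = s.scaled(target_medi / sp.alpha_edi(s, "melanopic"))
                m = sp.photometrics(s).to_row()
                m["_noise_sd"] = par["noise_sd_mm"]
                metrics.append(m)
        medi = np.array([m["melanopic_edi_lx"] for m in metrics])
        sds = np.array([m.pop("_noise_sd") for m in metrics])
        base = np.array([true_pupil(p, m, "cluster", config, "field") for m in medi])
        pupils = base + rng.normal(0.0, 1.0, len(medi)) * sds
        rows += _make_rows(p, metrics, pupils, "field", t0_s, config, rng)
    return _rows_to_frame(rows)


def simulate_dark(
    cohort: list[Participant],
    duration_s: float = 600.0,
    config: GeneratorConfig | None = None,
    seed=0,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """10 min dark adaptation: residual light below 0.2 lx, pupil from the
    dark-cluster age model with small noise."""
    config = config or GeneratorConfig()
    rng = _rng(seed)
    n = int(round(duration_s / SAMPLING_INTERVAL_S))
    dark_sd = CALIBRATION["cluster_params"]["dark"]["noise_sd_mm"]
    rows: list[dict] = []
    for p in cohort:
        metrics = []
        for _ in range(n):
            lux = rng.uniform(0.01, 0.15)
            metrics.append(sp.photometrics(illuminant_spectrum(IlluminantSpec("blackbody", lux, cct_k=2700.0))).to_row())
        base = true_pupil(p, 0.0, "cluster", config, "dark")
        pupils = base + rng.normal(0.0, dark_sd, n)
        rows += _make_rows(p, metrics, pupils, "dark", t0_s, config, rng)
    return _rows_to_frame(rows)


def lab_schedule() -> list[tuple[str, float | None, int]]:
    """The lab light programme as (colour-or-'dark', level lx, n samples) blocks
    for one phase ordering slot; callers interleave dark gaps.  Total duration
    across the four phases and five 20 s gaps is 13 min 40 s."""
    blocks = []
    for level in LAB_LEVELS_LX:
        blocks.append(("light", level, 6))  # 1 min per level at 10 s cadence
    return blocks


def simulate_lab(
    cohort: list[Participant],
    config: GeneratorConfig | None = None,
    seed=0,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """Laboratory light programme: four colour phases (seeded random order),
    each 3 min at 10/100/colour-max lx, separated by 20 s <0.2 lx dark gaps.
    Pupil follows the log-linear age model on the achieved mEDI, so
    illuminance and mEDI dissociate across colours."""
    config = config or GeneratorConfig()
    rng = _rng(seed)
    rows: list[dict] = []
    for p in cohort:
        order = list(rng.permutation(["red", "blue", "green", "white"]))
        metrics: list[dict] = []
        medi_list: list[float] = []

        def _dark_gap():
            for _ in range(2):  # 20 s
                lux = rng.uniform(0.01, 0.15)
                m = sp.photometrics(illuminant_spectrum(IlluminantSpec("blackbody", lux, cct_k=2700.0))).to_row()
                metrics.append(m)
                medi_list.append(m["melanopic_edi_lx"])

        _dark_gap()
        for colour in order:
            for level in LAB_LEVELS_LX:
                lux = LAB_MAX_LX[colour] if level is None else level
                s = illuminant_spectrum(IlluminantSpec("lab_primary", lux, colour=colour))
                m = sp.photometrics(s).to_row()
                for _ in range(6):  # 1 min per level
                    metrics.append(dict(m))
                    medi_list.append(m["melanopic_edi_lx"])
            _dark_gap()
        medi = np.array(medi_list)
        log_medi = np.log10(np.maximum(medi, config.medi_floor_lx))
        base = np.array([true_pupil(p, m, "loglinear", config, "lab") for m in medi])
        pupils = base + rng.normal(0.0, 1.0, len(medi)) * _field_noise_sd(log_medi, config)
        rows += _make_rows(p, metrics, pupils, "lab", t0_s, config, rng)
    return _rows_to_frame(rows)


def simulate_loglinear_samples(
    participant: Participant,
    n: int,
    seed,
    medi_range_lx: tuple[float, float] = (0.1, 1.0e4),
    noise_sd_mm: float = 0.3,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Single-participant field series with mEDI drawn log-uniformly and pupil
    from the log-linear model plus homoscedastic noise; used for
    per-individual dose-response recovery."""
    config = config or GeneratorConfig()
    rng = _rng(seed)
    medi = 10.0 ** rng.uniform(np.log10(medi_range_lx[0]), np.log10(medi_range_lx[1]), n)
    base = np.array([true_pupil(participant, m, "loglinear", config, "field") for m in medi])
    pupil = np.clip(base + rng.normal(0.0, noise_sd_mm, n), 1.0, 9.0)
    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "timestamp_s": np.arange(n) * SAMPLING_INTERVAL_S,
            "condition": "field",
            "pupil_mm": pupil,
            "confidence": 1.0,
            "saturated": False,
            "age_years": participant.age_years,
            "sex": participant.sex,
            "melanopic_edi_lx": medi,
        }
    )


def simulate_study(
    cohort: list[Participant],
    n_field_per_participant: int = 100,
    config: GeneratorConfig | None = None,
    seed=0,
) -> pd.DataFrame:
    """Full session per participant: dark adaptation, lab programme, a couple
    of unlabelled transition samples, then field exposure."""
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.Generator) else None)
    s_dark, s_lab, s_field, s_tr = [np.random.default_rng(c) for c in ss.spawn(4)]
    dark = simulate_dark(cohort, 600.0, config, s_dark, t0_s=0.0)
    lab = simulate_lab(cohort, config, s_lab, t0_s=700.0)
    field = simulate_field(cohort, n_field_per_participant, config, s_field, t0_s=1700.0)
    # brief transition between lab and field
    tr_rows = []
    for p in cohort:
        m = sp.photometrics(illuminant_spectrum(IlluminantSpec("fluorescent", 150.0))).to_row()
        tr_rows += _make_rows(p, [m, dict(m)], np.array([true_pupil(p, m["melanopic_edi_lx"], config.mode, config)] * 2),
                              "transition", 1660.0, config, s_tr)
    out = pd.concat([dark, lab, _rows_to_frame(tr_rows), field], ignore_index=True)
    return out.sort_values(["participant_id", "timestamp_s"], kind="stable").reset_index(drop=True)


def write_ground_truth(cohort: list[Participant], path) -> None:
    """Sidecar JSON with the true per-participant parameters, for recovery tests."""
    payload = {
        "calibration": CALIBRATION,
        "participants": [asdict(p) for p in cohort],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
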