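"""File formats, run configuration and the end-to-end pipeline.

The canonical on-disk format is a wide CSV with one row per 10 s
observation.  Mandatory columns:

    participant_id, timestamp_s, condition, pupil_mm, confidence, saturated

plus either raw spectral columns ``w380 ... w780`` (spectral irradiance,
W m^-2 nm^-1, one column per nanometre) or precomputed light-metric columns
(``illuminance_lx``, ``{class}_irradiance_w_m2``, ``{class}_edi_lx``,
``mel_der``).  Covariate columns (age_years, sex, iris_colour, caffeine
doses) ride along unchanged, as do any unknown columns.

``run_pipeline`` chains the stages -- metrics, quality control, scree-based
participant exclusion, the Bayes-factor batteries and the age analyses --
and serialises every result with a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import age as age_mod
from . import inference, qc, synth
from . import spectral as sp
from ._tables import GRID

__all__ = [
    "MANDATORY_COLUMNS",
    "PipelineError",
    "RunConfig",
    "attach_photometrics",
    "read_observations",
    "run_pipeline",
    "spectra_long_to_wide",
    "write_observations",
]

log = logging.getLogger("pupillight")

MANDATORY_COLUMNS = (
    "participant_id",
    "timestamp_s",
    "condition",
    "pupil_mm",
    "confidence",
    "saturated",
)
VALID_CONDITIONS = {"field", "dark", "lab", "transition"}
SPECTRAL_COLUMNS = tuple(f"w{int(w)}" for w in GRID)
METRIC_COLUMNS = tuple(
    ["illuminance_lx"]
    + [f"{c}_irradiance_w_m2" for c in sp.ALPHA_CLASSES]
    + [f"{c}_edi_lx" for c in sp.ALPHA_CLASSES]
    + ["mel_der"]
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# observation tables


def read_observations(path) -> pd.DataFrame:
    """Read and validate an observation CSV (wide form)."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {missing}")
    has_spectra = all(c in df.columns for c in SPECTRAL_COLUMNS)
    has_metrics = "illuminance_lx" in df.columns and "melanopic_edi_lx" in df.columns
    if not (has_spectra or has_metrics):
        raise ValueError(
            f"{path} carries neither spectral columns (w380..w780) nor light-metric columns"
        )
    bad = df.index[~df["condition"].isin(VALID_CONDITIONS)]
    if len(bad):
        raise ValueError(
            f"malformed rows in {path}: invalid condition at CSV row(s) "
            f"{[int(i) + 2 for i in bad[:5]]}"  # +2: header and 1-based
        )
    for col in ("timestamp_s", "pupil_mm", "confidence"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"malformed rows in {path}: non-numeric {col} at CSV row(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = vals
    df["saturated"] = df["saturated"].astype(bool)
    order = df.groupby("participant_id")["timestamp_s"].diff().dropna()
    if (order < 0).any():
        raise ValueError(f"{path}: timestamps must be nondecreasing per participant")
    return df


def write_observations(obs: pd.DataFrame, path) -> None:
    """Write an observation table; numeric values round-trip exactly."""
    obs.to_csv(path, index=False)


def spectra_long_to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Convert long-form spectra (sample_id, wavelength_nm, irradiance) to the
    canonical wide columns, regridding each sample onto the 1 nm grid."""
    rows = {}
    for sid, g in long_df.groupby("sample_id"):
        g = g.sort_values("wavelength_nm")
        raw = sp.SpectrumRaw(
            g["wavelength_nm"].to_numpy(dtype=float), g["irradiance"].to_numpy(dtype=float)
        )
        rows[sid] = sp.regrid_spectrum(raw).values
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(SPECTRAL_COLUMNS))
    out.index.name = "sample_id"
    return out.reset_index()


def attach_photometrics(obs: pd.DataFrame) -> pd.DataFrame:
    """Compute light metrics from the spectral columns where present."""
    if not all(c in obs.columns for c in SPECTRAL_COLUMNS):
        raise ValueError("no spectral columns (w380..w780) to compute metrics from")
    spectra = obs.loc[:, list(SPECTRAL_COLUMNS)].to_numpy(dtype=float)
    records = [sp.photometrics(sp.SpectrumRegular(row)).to_row() for row in spectra]
    metrics = pd.DataFrame(records, index=obs.index)
    out = obs.drop(columns=[c for c in METRIC_COLUMNS if c in obs.columns])
    return pd.concat([out, metrics], axis=1)


# ---------------------------------------------------------------------------
# configuration


class RunConfig(BaseModel):
    """Parameters of one pipeline run; defaults mirror the study protocol."""

    input_path: str | None = None  # None -> simulate
    out_dir: str = "results"
    seed: int = 0
    # generator
    n_participants: int = Field(default=83, ge=1)
    n_field_per_participant: int = Field(default=100, ge=1)
    generator_mode: str = "loglinear"
    low_confidence_fraction: float = Field(default=0.4337, ge=0.0, le=1.0)
    saturation_probability: float = Field(default=0.0141, ge=0.0, le=1.0)
    # QC
    conf_min: float = Field(default=0.6, ge=0.0, le=1.0)
    pupil_lo_mm: float = 1.0
    pupil_hi_mm: float = 9.0
    threshold_mode: str = "fixed"  # fixed | scree
    loss_threshold: float = Field(default=0.75, gt=0.0, lt=1.0)
    # analysis
    light_transform: str = "log10"
    medi_floor_lx: float = Field(default=0.01, gt=0.0)
    pairwise_predictors: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("simulate")
def _obtain_observations(config: RunConfig) -> pd.DataFrame:
    if config.input_path is not None:
        return read_observations(config.input_path)
    gen = synth.GeneratorConfig(
        mode=config.generator_mode,
        low_confidence_fraction=config.low_confidence_fraction,
        saturation_probability=config.saturation_probability,
    )
    cohort = synth.sample_cohort(config.n_participants, np.random.default_rng(config.seed), gen)
    return synth.simulate_study(cohort, config.n_field_per_participant, gen, config.seed + 1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all result files to ``out_dir``.

    Returns the results bundle as a dict (also serialised to JSON/CSV).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    log.info("run config hash %s (seed %d)", chash, config.seed)

    obs = _obtain_observations(config)

    @_stage("metrics")
    def _metrics(obs):
        if all(c in obs.columns for c in SPECTRAL_COLUMNS):
            return attach_photometrics(obs)
        if "melanopic_edi_lx" not in obs.columns:
            raise ValueError("observations carry neither spectra nor light metrics")
        return obs

    obs = _metrics(obs)

    @_stage("qc")
    def _qc(obs):
        retained, report = qc.apply_filters(
            obs, config.conf_min, config.pupil_lo_mm, config.pupil_hi_mm
        )
        losses = qc.loss_table(obs, retained)
        return retained, report, losses

    retained, report, losses = _qc(obs)

    @_stage("exclusion")
    def _exclude(retained, losses):
        if config.threshold_mode == "scree":
            threshold, curve = qc.scree_threshold(losses)
        else:
            threshold, curve = config.loss_threshold, {}
        keep = qc.exclude_participants(losses, threshold)
        if not keep:
            raise ValueError("no participants retained after data-loss exclusion")
        return retained[retained["participant_id"].isin(keep)].reset_index(drop=True), threshold, curve

    analysed, threshold, scree_curve = _exclude(retained, losses)

    @_stage("inference")
    def _infer(analysed):
        evid = inference.run_confirmatory(
            analysed, config.light_transform, floor_lx=config.medi_floor_lx
        )
        evid["transform_check"] = inference.transform_check(
            analysed, floor_lx=config.medi_floor_lx
        )
        evid.update(inference.run_exploratory(analysed, floor_lx=config.medi_floor_lx))
        matrix = inference.predictor_comparison(
            analysed, pairwise=config.pairwise_predictors, floor_lx=config.medi_floor_lx
        )
        return evid, matrix

    evidence, predictor_matrix = _infer(analysed)

    @_stage("clusters")
    def _clusters(analysed):
        summary = age_mod.summarize_clusters(analysed)
        regressions = {}
        for cluster in age_mod.CLUSTER_ORDER:
            one = summary[summary["light_cluster"] == cluster]
            if len(one) >= 3:
                regressions[cluster] = age_mod.age_regression(one)
        rng_reg = age_mod.pupil_range_regression(analysed)
        return summary, regressions, rng_reg

    cluster_summary, age_regressions, range_regression = _clusters(analysed)

    # serialise
    provenance = {"config_hash": chash, "seed": config.seed, "config": config.model_dump()}
    (out / "qc_report.json").write_text(
        json.dumps({**report.to_dict(), "loss_threshold": threshold, **provenance}, indent=2)
    )
    losses.to_csv(out / "loss_table.csv")
    if scree_curve:
        pd.DataFrame(
            {"threshold": list(scree_curve), "n_excluded": list(scree_curve.values())}
        ).to_csv(out / "scree_curve.csv", index=False)
    (out / "evidence.json").write_text(
        json.dumps(
            {name: ev.to_dict() for name, ev in evidence.items()} | provenance, indent=2
        )
    )
    predictor_matrix.to_csv(out / "predictor_matrix.csv")
    cluster_summary.to_csv(out / "cluster_summary.csv", index=False)
    (out / "age_regressions.json").write_text(
        json.dumps(
            {
                "clusters": {k: r.to_dict() for k, r in age_regressions.items()},
                "pupil_range": range_regression.to_dict(),
                **provenance,
            },
            indent=2,
        )
    )
    (out / "run.log").write_text(
        f"config_hash={chash}\nseed={config.seed}\n"
        f"n_obs_total={report.n_total}\nn_obs_retained={report.n_retained}\n"
        f"loss_threshold={threshold}\nn_participants_analysed={analysed['participant_id'].nunique()}\n"
    )

    return {
        "observations": obs,
        "retained": analysed,
        "qc_report": report,
        "loss_table": losses,
        "loss_threshold": threshold,
        "scree_curve": scree_curve,
        "evidence": evidence,
        "predictor_matrix": predictor_matrix,
        "cluster_summary": cluster_summary,
        "age_regressions": age_regressions,
        "range_regression": range_regression,
        "config_hash": chash,
    }
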