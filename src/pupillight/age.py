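"""Post-hoc age analyses: dose-response fits, light clusters, senile miosis.

Light-level clusters follow the study layout: the in-laboratory dark
adaptation forms its own cluster, and field observations fall into four
half-open mEDI bins [1, 10), [10, 100), [100, 1000), [1000, inf) lux.
Per-participant medians (with IQRs) in each cluster are regressed on age by
ordinary least squares; slopes are also reported per decade of age.  The
per-individual dose-response fit regresses pupil diameter on log10 mEDI,
and the Watson & Yellott (2012) unified formula is provided as a
luminance-based reference predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FIELD_CLUSTERS",
    "RegressionResult",
    "age_regression",
    "assign_cluster",
    "assign_clusters",
    "individual_loglinear_fit",
    "pupil_range_regression",
    "summarize_clusters",
    "watson_yellott_pupil",
]

#: half-open field mEDI bins (lx); "dark" is the dark-adaptation condition
FIELD_CLUSTERS: dict[str, tuple[float, float]] = {
    "1-10": (1.0, 10.0),
    "10-100": (10.0, 100.0),
    "100-1000": (100.0, 1000.0),
    ">1000": (1000.0, np.inf),
}
CLUSTER_ORDER = ("dark", "1-10", "10-100", "100-1000", ">1000")


@dataclass(frozen=True)
class RegressionResult:
    """Two-parameter OLS fit with t-based 95% confidence intervals."""

    slope: float
    intercept: float
    ci95_slope: tuple[float, float]
    ci95_intercept: tuple[float, float]
    n: int
    degenerate: bool = False  # zero residual variance: CIs collapse to a point

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs >= 3 points")
        if not (self.ci95_slope[0] <= self.slope <= self.ci95_slope[1]):
            raise ValueError("slope CI does not contain the estimate")

    @property
    def slope_per_decade(self) -> float:
        """Slope expressed per decade of age (x10 of the per-year slope)."""
        return 10.0 * self.slope

    @property
    def ci95_slope_per_decade(self) -> tuple[float, float]:
        return (10.0 * self.ci95_slope[0], 10.0 * self.ci95_slope[1])

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "ci95_slope": list(self.ci95_slope),
            "ci95_intercept": list(self.ci95_intercept),
            "n": self.n,
            "degenerate": self.degenerate,
        }


def _ols_ci(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    n = x.size
    if n < 3:
        raise ValueError("regression needs >= 3 points")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, dof)
    intercept, slope = float(beta[0]), float(beta[1])
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        ci95_slope=(slope - tcrit * se[1], slope + tcrit * se[1]),
        ci95_intercept=(intercept - tcrit * se[0], intercept + tcrit * se[0]),
        n=n,
        degenerate=bool(s2 <= 1e-24 * max(1.0, float(np.mean(y**2)))),
    )


# ---------------------------------------------------------------------------
# clusters


def assign_cluster(condition: str, medi_lx: float | None) -> str | None:
    """Cluster for one observation, or None (lab/transition, or dim field).

    Dark-adaptation samples map to "dark" regardless of the residual light;
    field samples below 1 lx mEDI are excluded from the cluster analysis.
    """
    if condition == "dark":
        return "dark"
    if condition != "field":
        return None
    if medi_lx is None or np.isnan(medi_lx):
        raise ValueError("field observation without an mEDI value")
    for name, (lo, hi) in FIELD_CLUSTERS.items():
        if lo <= medi_lx < hi:
            return name
    return None  # mEDI < 1 lx


def assign_clusters(obs: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`assign_cluster` over an observation table."""
    return pd.Series(
        [
            assign_cluster(c, m)
            for c, m in zip(obs["condition"], obs["melanopic_edi_lx"])
        ],
        index=obs.index,
        dtype=object,
    )


def summarize_clusters(obs: pd.DataFrame) -> pd.DataFrame:
    """Per participant x cluster: median pupil, IQR and observation count.

    Quartiles use linear interpolation (the type-7 convention).  Participants
    without observations in a cluster are simply absent from that cluster.
    """
    df = obs.copy()
    df["light_cluster"] = assign_clusters(df)
    df = df.dropna(subset=["light_cluster"])
    out = (
        df.groupby(["participant_id", "light_cluster"])["pupil_mm"]
        .agg(
            median_pupil_mm="median",
            iqr_mm=lambda s: float(np.percentile(s, 75) - np.percentile(s, 25)),
            n_obs="size",
        )
        .reset_index()
    )
    if "age_years" in df.columns:
        ages = df.groupby("participant_id")["age_years"].first()
        out["age_years"] = out["participant_id"].map(ages)
    return out


def age_regression(cluster_summary: pd.DataFrame, ages: pd.Series | None = None) -> RegressionResult:
    """OLS of per-participant median pupil size on age for one cluster.

    ``cluster_summary`` holds one row per participant (a single cluster's
    slice of :func:`summarize_clusters`); ages are taken from its
    ``age_years`` column unless supplied separately.
    """
    if cluster_summary["participant_id"].duplicated().any():
        raise ValueError("expected one row per participant; filter to a single cluster first")
    if ages is None:
        age = cluster_summary["age_years"].to_numpy(dtype=float)
    else:
        age = cluster_summary["participant_id"].map(ages).to_numpy(dtype=float)
    y = cluster_summary["median_pupil_mm"].to_numpy(dtype=float)
    return _ols_ci(age, y)


def individual_loglinear_fit(
    obs: pd.DataFrame, floor_lx: float = 0.01, min_obs: int = 10, min_span_decades: float = 2.0
) -> RegressionResult:
    """Per-individual dose-response: OLS of pupil on log10 mEDI.

    The intercept is the predicted diameter at 1 lx mEDI; the slope is mm per
    log10 unit.  Dark frames enter at the mEDI floor.  Requires enough
    observations spanning at least ``min_span_decades`` of light level.
    """
    if obs["participant_id"].nunique() > 1:
        raise ValueError("fit one participant at a time")
    x = np.log10(np.maximum(obs["melanopic_edi_lx"].to_numpy(dtype=float), floor_lx))
    y = obs["pupil_mm"].to_numpy(dtype=float)
    if x.size < min_obs:
        raise ValueError(f"need >= {min_obs} observations, got {x.size}")
    span = x.max() - x.min()
    if span < min_span_decades:
        raise ValueError(
            f"light levels span only {span:.2f} decades of mEDI "
            f"(>= {min_span_decades} required for a stable dose-response fit)"
        )
    return _ols_ci(x, y)


def pupil_range_regression(
    obs: pd.DataFrame, min_obs: int = 20, require_dark: bool = True
) -> RegressionResult:
    """OLS of per-participant pupil range (max - min, mm) on age.

    Participants qualify with at least ``min_obs`` valid observations
    including, by default, the dark-adaptation condition (without which the
    upper end of the range is censored).
    """
    rows = []
    for pid, g in obs.groupby("participant_id"):
        if len(g) < min_obs:
            continue
        if require_dark and not (g["condition"] == "dark").any():
            continue
        pupil = g["pupil_mm"].to_numpy(dtype=float)
        rows.append((pid, float(g["age_years"].iloc[0]), float(pupil.max() - pupil.min())))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} qualifying participants (>= 3 required)")
    arr = pd.DataFrame(rows, columns=["participant_id", "age_years", "range_mm"])
    return _ols_ci(arr["age_years"].to_numpy(), arr["range_mm"].to_numpy())


# ---------------------------------------------------------------------------
# reference predictor


def watson_yellott_pupil(
    luminance_cdm2: float,
    field_diameter_deg: float,
    age_years: float,
    n_eyes: int = 2,
) -> float:
    """Watson & Yellott (2012) unified formula for light-adapted pupil diameter.

    The Stanley-Davies base diameter is driven by the effective corneal flux
    density F = L * a * M(e) (luminance x field area in deg^2 x a monocular
    attenuation of 0.1), and an age correction shrinks the pupil of older
    observers in dim light:

        D_SD(F) = 7.75 - 5.75 * (F/846)^0.41 / ((F/846)^0.41 + 2)
        D = D_SD + (y - 28.58) * (0.02132 - 0.009562 * D_SD)

    Valid for ages ~20-83 years; monotonically nonincreasing in luminance.
    """
    if n_eyes not in (1, 2):
        raise ValueError("n_eyes must be 1 or 2")
    if luminance_cdm2 <= 0:
        raise ValueError("luminance must be positive")
    if field_diameter_deg <= 0:
        raise ValueError("field diameter must be positive")
    area_deg2 = np.pi * (field_diameter_deg / 2.0) ** 2
    monocular = 0.1 if n_eyes == 1 else 1.0
    flux = luminance_cdm2 * area_deg2 * monocular
    z = (flux / 846.0) ** 0.41
    d_sd = 7.75 - 5.75 * z / (z + 2.0)
    return float(d_sd + (age_years - 28.58) * (0.02132 - 0.009562 * d_sd))
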