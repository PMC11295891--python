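"""Data-quality cascade for synchronized pupil/light observations.

Observations travel as a pandas DataFrame with one row per 10 s sample (see
:mod:`pupillight.io` for the schema).  Three rules are applied, in a fixed
precedence order so each exclusion is counted exactly once:

1. low confidence -- pupil missing, confidence missing, or confidence below
   ``conf_min`` (missing pupil/confidence is treated as confidence 0);
2. out of range -- pupil diameter outside [pupil_lo, pupil_hi] (inclusive
   bounds retained);
3. saturated -- the paired spectroradiometer sample clipped.

Participant-level exclusion uses the per-participant fraction of lost
samples, with a scree-style search for the loss threshold beyond which
raising the cut-off stops removing participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "apply_filters",
    "exclude_participants",
    "loss_table",
    "scree_threshold",
]


@dataclass(frozen=True)
class QCReport:
    """Per-rule exclusion accounting for one filter pass."""

    n_total: int
    n_low_confidence: int
    n_out_of_range: int
    n_saturated: int
    n_retained: int
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        excluded = self.n_low_confidence + self.n_out_of_range + self.n_saturated
        if self.n_retained + excluded != self.n_total:
            raise ValueError("QC counts do not conserve the total")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_low_confidence": self.n_low_confidence,
            "n_out_of_range": self.n_out_of_range,
            "n_saturated": self.n_saturated,
            "n_retained": self.n_retained,
            "proportions": dict(self.proportions),
        }


def apply_filters(
    obs: pd.DataFrame,
    conf_min: float = 0.6,
    pupil_lo: float = 1.0,
    pupil_hi: float = 9.0,
    drop_saturated: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the quality cascade; return (retained rows, report).

    A row is retained iff the pupil value is present, confidence >= conf_min,
    pupil_lo <= pupil <= pupil_hi, and the spectral sample is not saturated
    (when ``drop_saturated``).  Exclusions are counted with precedence
    confidence -> range -> saturation.
    """
    if obs.empty:
        raise ValueError("cannot filter an empty observation table")
    pupil = obs["pupil_mm"].to_numpy(dtype=float)
    conf = obs["confidence"].to_numpy(dtype=float)
    saturated = obs["saturated"].to_numpy(dtype=bool)

    conf_eff = np.where(np.isnan(pupil) | np.isnan(conf), 0.0, conf)
    low_conf = conf_eff < conf_min
    out_of_range = ~low_conf & ((pupil < pupil_lo) | (pupil > pupil_hi))
    sat = ~low_conf & ~out_of_range & saturated if drop_saturated else np.zeros_like(low_conf)
    retained_mask = ~(low_conf | out_of_range | sat)

    n = len(obs)
    report = QCReport(
        n_total=n,
        n_low_confidence=int(low_conf.sum()),
        n_out_of_range=int(out_of_range.sum()),
        n_saturated=int(sat.sum()),
        n_retained=int(retained_mask.sum()),
        proportions={
            "low_confidence": low_conf.sum() / n,
            "out_of_range": out_of_range.sum() / n,
            "saturated": sat.sum() / n,
            "retained": retained_mask.sum() / n,
        },
    )
    return obs.loc[retained_mask].copy(), report


def loss_table(raw: pd.DataFrame, retained: pd.DataFrame) -> pd.DataFrame:
    """Per-participant data-loss accounting.

    Returns a DataFrame indexed by participant_id with columns
    ``n_total``, ``n_retained`` and ``loss_fraction``.
    """
    unknown = set(retained["participant_id"]) - set(raw["participant_id"])
    if unknown:
        raise ValueError(f"retained participants not present in raw data: {sorted(unknown)}")
    n_total = raw.groupby("participant_id").size()
    n_ret = retained.groupby("participant_id").size().reindex(n_total.index, fill_value=0)
    out = pd.DataFrame({"n_total": n_total, "n_retained": n_ret})
    out["loss_fraction"] = 1.0 - out["n_retained"] / out["n_total"]
    return out


def scree_threshold(
    losses: pd.DataFrame,
    start: float = 0.50,
    step: float = 0.05,
    stop: float = 0.95,
) -> tuple[float, dict[float, int]]:
    """Data-driven participant-exclusion threshold from the loss curve.

    For each candidate threshold t in {start, start+step, ..., stop} the
    number of participants whose loss fraction exceeds t is counted.  The
    adopted threshold is the smallest t > start at which stepping on to
    t + step removes the fewest additional participants from the excluded
    set -- the start of the flattest step of the scree curve.  Ties resolve
    to the smallest qualifying threshold.

    Returns (threshold, {candidate: excluded count}) so the curve can be
    plotted or serialized.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if losses.empty:
        raise ValueError("loss table is empty")
    n_steps = int(round((stop - start) / step))
    candidates = [round(start + i * step, 10) for i in range(n_steps + 1)]
    loss = losses["loss_fraction"].to_numpy(dtype=float)
    counts = {t: int((loss > t).sum()) for t in candidates}
    # drop from one candidate to the next; defined on candidates[0..n-2]
    drops = {
        candidates[i]: counts[candidates[i]] - counts[candidates[i + 1]]
        for i in range(len(candidates) - 1)
    }
    eligible = [t for t in candidates[1:-1] if t > start] or [candidates[1]]
    min_drop = min(drops[t] for t in eligible)
    threshold = next(t for t in eligible if drops[t] == min_drop)
    return threshold, counts


def exclude_participants(losses: pd.DataFrame, threshold: float) -> list:
    """Participant ids retained at a given loss threshold (strict >)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    keep = losses.index[losses["loss_fraction"] <= threshold]
    return list(keep)
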