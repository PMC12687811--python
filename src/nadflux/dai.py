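"""Disease activity index (DAI) for DSS colitis from daily clinical observations.

Six components, each scored 0–5: weight loss relative to day 0 (binned by the
rubric below), stool consistency, bleeding, posture, activity and fur state
(recorded as ordinal scores by the observer).  The DAI is their sum, 0–30.

Weight-loss rubric: 0 = no loss or gain; 1 = 1–5%; 2 = 6–10%; 3 = 11–19%;
4 = 20–25%; 5 = >25%.  The printed bins have integer edges, so fractional
percentages are rounded half-up to an integer first — this covers every
percentage with no gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DAIObservation", "DAIScore", "weight_points", "dai",
           "dai_timecourse", "ORDINAL_COMPONENTS"]

ORDINAL_COMPONENTS = ("stool", "bleeding", "posture", "activity", "fur")


@dataclass(frozen=True)
class DAIObservation:
    """One mouse-day of clinical observations.

    ``weight_pct_change`` is percent change versus day 0 (negative = loss);
    the five ordinal components are integer scores in [0, 5].
    """

    mouse_id: str
    day: int
    weight_pct_change: float
    stool: int
    bleeding: int
    posture: int
    activity: int
    fur: int

    def __post_init__(self) -> None:
        for name in ORDINAL_COMPONENTS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 5):
                raise ValueError(f"{name} must be an integer in [0, 5], got {v!r}")
        if not math.isfinite(self.weight_pct_change):
            raise ValueError("weight_pct_change must be finite")


@dataclass(frozen=True)
class DAIScore:
    mouse_id: str
    day: int
    weight_points: int
    total: int


def weight_points(pct_loss: float) -> int:
    """Rubric points for percent weight loss (gain or 0% scores 0)."""
    if not math.isfinite(pct_loss):
        raise ValueError("pct_loss must be finite")
    loss = math.floor(pct_loss + 0.5)  # round half-up to the integer grid
    if loss <= 0:
        return 0
    if loss <= 5:
        return 1
    if loss <= 10:
        return 2
    if loss <= 19:
        return 3
    if loss <= 25:
        return 4
    return 5


def dai(obs: DAIObservation) -> DAIScore:
    """Total DAI: weight points plus the five ordinal components (0–30)."""
    wp = weight_points(-obs.weight_pct_change)
    total = wp + sum(getattr(obs, name) for name in ORDINAL_COMPONENTS)
    return DAIScore(mouse_id=obs.mouse_id, day=obs.day, weight_points=wp,
                    total=total)


def dai_timecourse(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-day group mean ± SEM of the DAI.

    Input columns: ``mouse_id, day, group, weight_pct_change`` plus the five
    ordinal components.  Single-mouse days get a NaN SEM and a flag.
    """
    if observations.empty:
        return pd.DataFrame(columns=["group", "day", "mean_dai", "sem",
                                     "n_mice", "flagged"])
    scores = observations.copy()
    scores["dai"] = [
        dai(DAIObservation(
            mouse_id=str(r.mouse_id), day=int(r.day),
            weight_pct_change=float(r.weight_pct_change),
            stool=int(r.stool), bleeding=int(r.bleeding),
            posture=int(r.posture), activity=int(r.activity), fur=int(r.fur),
        )).total
        for r in scores.itertuples()
    ]
    out = (
        scores.groupby(["group", "day"])["dai"]
        .agg(mean_dai="mean",
             sem=lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v)))
             if len(v) > 1 else np.nan,
             n_mice="count")
        .reset_index()
    )
    out["flagged"] = out["n_mice"] < 2
    return out
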