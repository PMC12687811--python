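"""Fractional labeling, serum enrichment time courses, pool sizes and ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import PathwayMap, TracerSpec, monitored_isotopologues
from .correction import MIDVector

__all__ = [
    "SampleRecord",
    "fractional_labeling",
    "label_table",
    "enrichment_timecourse",
    "relative_pool",
    "kyn_trp_ratio",
]

TISSUES = ("serum", "liver", "spleen", "kidney", "duodenum", "jejunum",
           "ileum", "cecum", "proximal colon", "distal colon", "colon")
LUMEN = ("duodenum_lumen", "jejunum_lumen", "ileum_lumen", "cecum_lumen",
         "proximal colon_lumen", "distal colon_lumen", "colon_lumen")
PHASES = ("early_flare_up", "active_flare")


@dataclass(frozen=True)
class SampleRecord:
    """Identity of one measured sample."""

    sample_id: str
    compartment: str
    group: str           # {"control", "DSS"}
    phase: str           # {"early_flare_up", "active_flare"}
    timepoint_min: float
    tracer: str

    def __post_init__(self) -> None:
        if self.group not in ("control", "DSS"):
            raise ValueError(f"unknown group {self.group!r}")


def fractional_labeling(
    corrected: MIDVector,
    sample_id: str,
    expected_shifts: set[int] | None = None,
) -> pd.DataFrame:
    """Tidy per-shift fractions for one corrected MID.

    Emits one row per shift; rows whose shift is among ``expected_shifts``
    (the atlas-predicted labels for the tracer) are tagged ``expected=True``.
    Normalization failures arrive as ``flagged`` on the MIDVector and are
    propagated, never dropped.
    """
    if corrected.kind != "corrected":
        raise ValueError("fractional_labeling expects a corrected MID")
    expected = expected_shifts or set()
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "metabolite": corrected.metabolite,
            "shift": np.arange(corrected.values.size),
            "fraction": corrected.values,
            "expected": [k in expected and k > 0
                         for k in range(corrected.values.size)],
            "flagged": corrected.flagged,
        }
    )


def label_table(corrected: pd.DataFrame, pmap: PathwayMap,
                tracer: TracerSpec) -> pd.DataFrame:
    """Tag a corrected fractions table with the atlas-expected labels."""
    monitored = monitored_isotopologues(tracer, pmap)
    out = corrected.copy()
    out["expected"] = [
        shift > 0 and shift in monitored.get(met, [])
        for met, shift in zip(out["metabolite"], out["shift"])
    ]
    return out


def enrichment_timecourse(
    serum: pd.DataFrame,
    *,
    plateau_start: float = 900.0,
    steady_tol: float = 0.05,
) -> pd.DataFrame:
    """Per-(metabolite, shift) serum enrichment series with plateau estimate.

    The plateau is the mean fraction over timepoints at or beyond
    ``plateau_start`` (default 15 h — the infusion runs 20 h to reach steady
    state, and the last two sampling times are 15 h and 20 h).  A series is
    flagged steady when its last two points differ by less than ``steady_tol``
    (absolute).  Requires at least three timepoints.

    ``serum`` needs columns ``metabolite, shift, timepoint_min, fraction``
    (an ``animal`` column, if present, is averaged over per timepoint).
    """
    rows = []
    for (met, shift), grp in serum.groupby(["metabolite", "shift"]):
        series = (grp.groupby("timepoint_min")["fraction"].mean()
                  .sort_index())
        if series.size < 3:
            raise ValueError(
                f"insufficient series for {met} M+{shift}: "
                f"{series.size} timepoints (need >= 3)"
            )
        plateau_pts = series[series.index >= plateau_start]
        plateau = float(plateau_pts.mean()) if plateau_pts.size else np.nan
        steady = bool(abs(series.iloc[-1] - series.iloc[-2]) < steady_tol)
        rows.append((met, int(shift), plateau, steady,
                     series.index.to_numpy(), series.to_numpy()))
    return pd.DataFrame(
        rows, columns=["metabolite", "shift", "plateau", "steady",
                       "times", "fractions"],
    )


def relative_pool(
    peaks: pd.DataFrame,
    metabolite: str,
    metadata: pd.DataFrame,
    *,
    control_group: str = "control",
) -> pd.DataFrame:
    """Relative total-ion-count pool size per sample.

    Sums raw isotopologue intensities per sample and scales so the
    control-group mean equals 1 (the convention behind 'relative TIC'
    bar plots).  Without any control samples the raw sums are returned
    unscaled with a warning.
    """
    tic = (peaks[peaks["metabolite"] == metabolite]
           .groupby("sample_id", sort=False)["intensity"].sum()
           .rename("tic").reset_index())
    out = tic.merge(metadata, on="sample_id", how="left")
    ctrl = out.loc[out["group"] == control_group, "tic"]
    if ctrl.empty:
        warnings.warn(
            f"no {control_group!r} samples for {metabolite}; returning "
            "unscaled TIC", stacklevel=2,
        )
        out["relative_tic"] = out["tic"]
        out.attrs["normalized"] = False
        return out
    out["relative_tic"] = out["tic"] / ctrl.mean()
    out.attrs["normalized"] = True
    out.attrs["reference"] = f"mean({control_group})"
    return out


def kyn_trp_ratio(peaks: pd.DataFrame, *, kyn: str = "Kyn",
                  trp: str = "Trp") -> pd.DataFrame:
    """Circulating Kyn/Trp ratio per sample from TIC intensities.

    A rising ratio marks increased IDO/TDO-driven kynurenine-pathway
    activity.  Samples with zero Trp signal yield NaN and are flagged.
    """
    tic = (peaks[peaks["metabolite"].isin([kyn, trp])]
           .groupby(["sample_id", "metabolite"])["intensity"].sum()
           .unstack("metabolite"))
    for col in (kyn, trp):
        if col not in tic:
            raise ValueError(f"metabolite {col!r} absent from peak table")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(tic[trp] > 0, tic[kyn] / tic[trp], np.nan)
    return pd.DataFrame(
        {
            "sample_id": tic.index,
            "kyn_trp_ratio": ratio,
            "flagged": tic[trp].to_numpy() <= 0,
        }
    ).reset_index(drop=True)
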