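"""Precursor contributions: partitioning NAD+ pools between NAM salvage and Trp.

After a 20-h constant infusion the serum enrichment of each precursor has
plateaued, and a compartment's NAD+ isotopologue fraction divided by the serum
enrichment of the precursor estimates the percent of that NAD+ pool derived
from it:

* NAM contribution = 100 × NAD+(M+3) fraction / [serum NAM(M+3) + NAM(M+4)]
  — both the intact d4 infusate (M+4) and host-recycled NAM (M+3) salvage
  into M+3 NAD+, so the denominator sums both serum isotopologues;
* Trp contribution = 100 × NAD+(M+6) fraction / serum Trp(M+11) fraction.

The two arms come from separate animals (one tracer each), so NAM and Trp
percentages are never forced to sum to 100, and values above 100% (possible
when the serum denominator underestimates the precursor enrichment the tissue
actually sees) are reported, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import sem as _sem

__all__ = [
    "ContributionRecord",
    "nam_contribution",
    "trp_contribution",
    "contribution_table",
]


@dataclass(frozen=True)
class ContributionRecord:
    compartment: str
    precursor: str            # {"NAM", "Trp"}
    percent: float
    denominator_value: float
    animal: str
    group: str
    phase: str
    flagged: bool = False


def nam_contribution(nad_m3_fraction: float, serum_nam_m3: float,
                     serum_nam_m4: float) -> float:
    """Percent of an NAD+ pool derived from nicotinamide salvage.

    Denominator fractions must come from the same animal's serum plateau.
    A zero denominator yields NaN (caller flags the record).
    """
    denom = serum_nam_m3 + serum_nam_m4
    if denom <= 0:
        return float("nan")
    return 100.0 * nad_m3_fraction / denom


def trp_contribution(nad_m6_fraction: float, serum_trp_m11: float) -> float:
    """Percent of an NAD+ pool derived from tryptophan via the kynurenine path."""
    if serum_trp_m11 <= 0:
        return float("nan")
    return 100.0 * nad_m6_fraction / serum_trp_m11


#: per arm: (serum metabolite, serum shifts summed, tissue NAD+ shift)
_ARMS = {
    "NAM": ("NAM", (3, 4), 3),
    "Trp": ("Trp", (11,), 11_000),  # tissue shift filled from tracer map below
}


def contribution_table(
    labeled: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    plateau_start: float = 900.0,
    nam_tracer: str = "2H4-NAM",
    trp_tracer: str = "13C11-Trp",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal contribution records plus group summaries.

    Parameters
    ----------
    labeled : DataFrame
        Tidy fractions with columns ``sample_id, metabolite, shift, fraction``.
    metadata : DataFrame
        ``sample_id, animal, compartment, group, phase, timepoint_min, tracer``.
    plateau_start : float
        Serum denominators are per-animal means over timepoints >= this value
        (default 15 h; configurable, recorded in the outputs' attrs).

    Returns ``(records, summary)``: one row per (animal, compartment,
    precursor), and mean ± SEM with n per (compartment, precursor, group,
    phase).  A missing tracer arm produces a partial table with a warning;
    single-animal groups get a NaN SEM and a flag.
    """
    df = labeled.merge(metadata, on="sample_id", how="left")
    arms = {
        "NAM": (nam_tracer, "NAM", (3, 4), 3),
        "Trp": (trp_tracer, "Trp", (11,), 6),
    }
    records: list[ContributionRecord] = []
    for precursor, (tracer, serum_met, serum_shifts, nad_shift) in arms.items():
        arm = df[df["tracer"] == tracer]
        if arm.empty:
            warnings.warn(f"missing {precursor} tracer arm ({tracer}); "
                          "partial contribution table", stacklevel=2)
            continue
        for animal, adf in arm.groupby("animal"):
            serum = adf[(adf["compartment"] == "serum")
                        & (adf["metabolite"] == serum_met)
                        & (adf["shift"].isin(serum_shifts))
                        & (adf["timepoint_min"] >= plateau_start)]
            denom = float(serum.groupby("shift")["fraction"].mean().sum())
            group = adf["group"].iloc[0]
            phase = adf["phase"].iloc[0]
            tissues = adf[(adf["compartment"] != "serum")
                          & (adf["metabolite"] == "NAD+")
                          & (adf["shift"] == nad_shift)]
            for comp, cdf in tissues.groupby("compartment"):
                num = float(cdf["fraction"].mean())
                pct = (100.0 * num / denom) if denom > 0 else float("nan")
                records.append(ContributionRecord(
                    compartment=comp, precursor=precursor, percent=pct,
                    denominator_value=denom, animal=animal, group=group,
                    phase=phase, flagged=denom <= 0,
                ))

    rec_df = pd.DataFrame([r.__dict__ for r in records]) if records else \
        pd.DataFrame(columns=["compartment", "precursor", "percent",
                              "denominator_value", "animal", "group",
                              "phase", "flagged"])
    if rec_df.empty:
        summary = pd.DataFrame(columns=["compartment", "precursor", "group",
                                        "phase", "mean_percent", "sem",
                                        "n_animals", "flagged"])
    else:
        summary = (
            rec_df.groupby(["compartment", "precursor", "group", "phase"])
            ["percent"]
            .agg(mean_percent="mean",
                 sem=lambda v: float(_sem(v)) if len(v) > 1 else np.nan,
                 n_animals="count")
            .reset_index()
        )
        summary["flagged"] = summary["n_animals"] < 2
    rec_df.attrs["plateau_start_min"] = plateau_start
    summary.attrs["plateau_start_min"] = plateau_start
    return rec_df, summary
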