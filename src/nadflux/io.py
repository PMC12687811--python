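"""Peak-table IO, pipeline configuration, and the end-to-end pipeline runner."""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .atlas import PathwayMap, default_map, default_tracers
from .contribution import contribution_table
from .correction import correct_peak_table
from .labeling import label_table

__all__ = [
    "read_peak_table",
    "write_peak_table",
    "to_wide",
    "PipelineConfig",
    "run_pipeline",
    "PeakTableError",
]

log = logging.getLogger("nadflux")

REQUIRED_COLUMNS = ("sample_id", "metabolite", "isotopologue", "intensity")
_ISO_RE = re.compile(r"^M\+(\d+)$")


class PeakTableError(ValueError):
    """Malformed long-format peak table."""


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a long-format peak table.

    Expected UTF-8 CSV with header ``sample_id, metabolite, isotopologue,
    intensity``; isotopologue labels are ``M+k`` with integer k >= 0;
    intensities are >= 0; (sample, metabolite, isotopologue) is unique.
    Violations raise :class:`PeakTableError` naming the offending line
    (1-based, counting the header as line 1).
    """
    # keep_default_na: the metabolite id "NA" (nicotinic acid) must stay a string
    df = pd.read_csv(path, dtype={"sample_id": str, "metabolite": str,
                                  "isotopologue": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableError(f"{path}: missing columns {missing}")
    problems = []
    for idx, label in df["isotopologue"].items():
        if not _ISO_RE.match(str(label)):
            problems.append(f"line {idx + 2}: bad isotopologue label {label!r}")
    bad_int = pd.to_numeric(df["intensity"], errors="coerce")
    for idx in df.index[bad_int.isna() | (bad_int < 0)]:
        problems.append(
            f"line {idx + 2}: negative or non-numeric intensity "
            f"{df.at[idx, 'intensity']!r}"
        )
    dup = df.duplicated(subset=["sample_id", "metabolite", "isotopologue"],
                        keep="first")
    for idx in df.index[dup]:
        problems.append(
            f"line {idx + 2}: duplicate (sample, metabolite, isotopologue) "
            f"key {tuple(df.loc[idx, ['sample_id', 'metabolite', 'isotopologue']])}"
        )
    if problems:
        raise PeakTableError(f"{path}:\n" + "\n".join(problems))
    df["intensity"] = bad_int
    return df


def write_peak_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def to_wide(df: pd.DataFrame, value_col: str = "intensity") -> pd.DataFrame:
    """Wide MID matrix (samples × isotopologues) per metabolite, for inspection."""
    col = "isotopologue" if "isotopologue" in df.columns else "shift"
    return df.pivot_table(index=["sample_id", "metabolite"], columns=col,
                          values=value_col, aggfunc="first")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; unknown keys in config files are rejected."""

    tracer: str = "2H4-NAM"
    abundances: dict = field(
        default_factory=lambda: {"C": 0.0107, "H": 0.000115})
    resolution_mode: str = "high"
    plateau_start_min: float = 900.0
    normalization: str = "control_mean"
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, peaks: pd.DataFrame,
                 metadata: pd.DataFrame,
                 pmap: PathwayMap | None = None) -> dict:
    """Correct → label → contribute, in order.

    Every output table is stamped (``attrs``) with the config hash and seed.
    A failing stage aborts with the stage name in the exception.
    """
    pmap = pmap or default_map()
    tracer = default_tracers()[config.tracer]
    for col in ("sample_id", "animal", "compartment", "group", "phase",
                "timepoint_min", "tracer"):
        if col not in metadata.columns:
            raise ValueError(f"metadata: missing column {col!r}")

    bundle: dict = {"config": config}
    stages = [
        ("correct", lambda: correct_peak_table(
            peaks, pmap, tracer, abundances=config.abundances,
            resolution_mode=config.resolution_mode)),
        ("label", lambda: label_table(bundle["corrected"], pmap, tracer)),
        ("contribute", lambda: contribution_table(
            bundle["labeling"], metadata,
            plateau_start=config.plateau_start_min)),
    ]
    for name, step in stages:
        log.info("pipeline stage %s: start (config %s, seed %d)",
                 name, config.hash, config.seed)
        try:
            result = step()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "contribute":
            bundle["contributions"], bundle["contribution_summary"] = result
        else:
            key = "corrected" if name == "correct" else "labeling"
            bundle[key] = result
        log.info("pipeline stage %s: done", name)

    for key in ("corrected", "labeling", "contributions",
                "contribution_summary"):
        bundle[key].attrs["config_hash"] = config.hash
        bundle[key].attrs["seed"] = config.seed
    return bundle
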