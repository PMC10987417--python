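"""Readers, writers and configuration shared by all stages.

Interchange formats are plain UTF-8 CSV with headers:

* symptom CSV, long dialect — columns ``athlete_id, day_post_injury, symptom,
  severity`` (one row per symptom rating);
* symptom CSV, wide dialect — ``athlete_id, day_post_injury`` plus one column
  per canonical SCAT5 symptom;
* metadata CSV — ``athlete_id, sex, sport, mechanism, rtp_day`` (``rtp_day``
  blank when unknown).

Validation is strict: unknown symptom names, severities outside 0-6 and
duplicate (athlete, day, symptom) cells are errors that name the offending
rows.  Registry and run configuration load from YAML with unknown keys
rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import ConcussionEpisode
from .scat5 import (
    SCAT5_SYMPTOMS,
    ProfileRegistry,
    SymptomChecklist,
    ValidationError,
    registry_from_dict,
)
from .simulate import SimulationConfig

__all__ = [
    "read_symptom_csv",
    "write_symptom_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "assemble_episodes",
    "load_registry",
    "RunConfig",
    "load_run_config",
]

_LONG_COLUMNS = ["athlete_id", "day_post_injury", "symptom", "severity"]
_WIDE_KEY = ["athlete_id", "day_post_injury"]
_META_COLUMNS = ["athlete_id", "sex", "sport", "mechanism", "rtp_day"]


def _require(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return path


def read_symptom_csv(path, dialect: str = "wide") -> pd.DataFrame:
    """Read and validate a symptom CSV; returns the wide form.

    The result has columns ``athlete_id, day_post_injury`` plus the 22
    canonical symptoms, one row per evaluation.  Errors cite 1-based data row
    numbers of the source file.
    """
    path = _require(path)
    df = pd.read_csv(path)
    if dialect == "long":
        missing = set(_LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
        bad = ~df["symptom"].isin(SCAT5_SYMPTOMS)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:10]
            raise ValidationError(
                f"{path}: unknown symptom name(s) "
                f"{sorted(df.loc[bad, 'symptom'].unique())} at row(s) {rows}"
            )
        _check_severity(df["severity"], path, df.index)
        dup = df.duplicated(subset=["athlete_id", "day_post_injury", "symptom"])
        if dup.any():
            rows = (df.index[dup] + 2).tolist()[:10]
            raise ValidationError(f"{path}: duplicate (athlete, day, symptom) at row(s) {rows}")
        wide = (
            df.pivot(index=_WIDE_KEY, columns="symptom", values="severity")
            .reset_index()
        )
        wide.columns.name = None
        present = [s for s in SCAT5_SYMPTOMS if s in wide.columns]
        absent = [s for s in SCAT5_SYMPTOMS if s not in wide.columns]
        if absent or wide[present].isna().any().any():
            raise ValidationError(
                f"{path}: evaluations missing symptom rating(s); "
                f"absent symptoms: {absent or 'partial rows'}"
            )
        wide = wide[_WIDE_KEY + list(SCAT5_SYMPTOMS)]
    elif dialect == "wide":
        missing = set(_WIDE_KEY + list(SCAT5_SYMPTOMS)) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
        extra = set(df.columns) - set(_WIDE_KEY + list(SCAT5_SYMPTOMS))
        if extra:
            raise ValidationError(f"{path}: unknown column(s) {sorted(extra)}")
        for symptom in SCAT5_SYMPTOMS:
            _check_severity(df[symptom], path, df.index, symptom)
        dup = df.duplicated(subset=_WIDE_KEY)
        if dup.any():
            rows = (df.index[dup] + 2).tolist()[:10]
            raise ValidationError(f"{path}: duplicate (athlete, day) at row(s) {rows}")
        wide = df[_WIDE_KEY + list(SCAT5_SYMPTOMS)].copy()
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")
    wide["day_post_injury"] = wide["day_post_injury"].astype(int)
    wide[list(SCAT5_SYMPTOMS)] = wide[list(SCAT5_SYMPTOMS)].astype(int)
    return wide.sort_values(_WIDE_KEY).reset_index(drop=True)


def _check_severity(series: pd.Series, path, index, symptom: str | None = None) -> None:
    values = pd.to_numeric(series, errors="coerce")
    non_integer = values.isna() | (values != np.floor(values))
    out_of_range = ~non_integer & ((values < 0) | (values > 6))
    bad = non_integer | out_of_range
    if bad.any():
        rows = (index[bad] + 2).tolist()[:10]
        where = f" in column {symptom!r}" if symptom else ""
        raise ValidationError(
            f"{path}: severity must be an integer in [0, 6]{where}; "
            f"offending row(s) {rows}"
        )


def write_symptom_csv(episodes: Sequence[ConcussionEpisode], path, dialect: str = "wide") -> None:
    """Write episode trajectories as a symptom CSV (long or wide dialect)."""
    rows = []
    for e in episodes:
        for checklist in e.trajectory:
            row = {"athlete_id": e.athlete_id, "day_post_injury": checklist.day_post_injury}
            row.update(checklist.symptom_severities)
            rows.append(row)
    wide = pd.DataFrame(rows, columns=_WIDE_KEY + list(SCAT5_SYMPTOMS))
    if dialect == "wide":
        wide.to_csv(path, index=False)
    elif dialect == "long":
        long = wide.melt(
            id_vars=_WIDE_KEY, var_name="symptom", value_name="severity"
        ).sort_values(_LONG_COLUMNS[:3], kind="stable")
        long.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_metadata_csv(path) -> pd.DataFrame:
    path = _require(path)
    df = pd.read_csv(path)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    dup = df.duplicated(subset=["athlete_id"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise ValidationError(f"{path}: duplicate athlete_id at row(s) {rows}")
    return df


def write_metadata_csv(episodes: Sequence[ConcussionEpisode], path) -> None:
    rows = [
        {
            "athlete_id": e.athlete_id,
            "sex": e.sex,
            "sport": e.sport,
            "sport_group": e.sport_group,
            "mechanism": e.mechanism,
            "rtp_day": e.rtp_day,
        }
        for e in episodes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble_episodes(
    symptom_table: pd.DataFrame,
    metadata: pd.DataFrame,
    sport_mapping: Optional[dict] = None,
) -> list[ConcussionEpisode]:
    """Join the wide symptom table with metadata into episodes.

    Athletes present in one file but not the other are an error.  Sports are
    collapsed through ``sport_mapping`` when given (otherwise ``sport_group``
    from the metadata, falling back to the raw sport name).
    """
    from .cohort import collapse_sport

    sym_ids = set(symptom_table["athlete_id"])
    meta_ids = set(metadata["athlete_id"])
    only_sym = sorted(sym_ids - meta_ids)[:10]
    only_meta = sorted(meta_ids - sym_ids)[:10]
    if only_sym or only_meta:
        raise ValidationError(
            f"athlete_id mismatch between symptom and metadata files; "
            f"symptoms-only: {only_sym}, metadata-only: {only_meta}"
        )
    episodes = []
    grouped = symptom_table.groupby("athlete_id", sort=True)
    meta = metadata.set_index("athlete_id")
    for athlete_id, block in grouped:
        block = block.sort_values("day_post_injury")
        trajectory = [
            SymptomChecklist(
                symptom_severities={s: int(row[s]) for s in SCAT5_SYMPTOMS},
                day_post_injury=int(row["day_post_injury"]),
            )
            for _, row in block.iterrows()
        ]
        m = meta.loc[athlete_id]
        sport = str(m["sport"])
        if sport_mapping is not None:
            group = collapse_sport(sport, sport_mapping)
        else:
            group = str(m["sport_group"]) if "sport_group" in meta.columns and pd.notna(m.get("sport_group")) else sport
        rtp = m["rtp_day"]
        episodes.append(
            ConcussionEpisode(
                athlete_id=str(athlete_id),
                sex=str(m["sex"]),
                sport=sport,
                sport_group=group,
                mechanism=str(m["mechanism"]),
                trajectory=trajectory,
                rtp_day=None if pd.isna(rtp) else int(rtp),
            )
        )
    return episodes


def load_registry(path) -> ProfileRegistry:
    """Load a profile registry from YAML (see ``data/default_registry.yaml``)."""
    path = _require(path)
    payload = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: registry config must be a mapping")
    return registry_from_dict(payload)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    seed: int = 0
    registry_path: Optional[str] = None
    symptom_csv: Optional[str] = None
    symptom_dialect: str = "wide"
    metadata_csv: Optional[str] = None
    sport_mapping: Optional[dict] = None
    simulate: Optional[SimulationConfig] = None
    spline_df: int = 3
    recovery_family: str = "nb2"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        has_files = self.symptom_csv is not None and self.metadata_csv is not None
        if not has_files and self.simulate is None:
            raise ValidationError(
                "config must provide either data paths (symptom_csv + metadata_csv) "
                "or a simulate block"
            )
        if self.symptom_dialect not in ("long", "wide"):
            raise ValidationError(f"unknown symptom dialect {self.symptom_dialect!r}")
        if self.recovery_family not in ("nb2", "poisson"):
            raise ValidationError(f"unsupported recovery family {self.recovery_family!r}")
        if self.spline_df < 1:
            raise ValidationError("spline_df must be >= 1")


def load_run_config(path) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys at every level."""
    path = _require(path)
    payload = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: run config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    sim = payload.pop("simulate", None)
    if sim is not None:
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ValidationError(
                f"{path}: unknown simulate key(s) {sorted(sim_unknown)}"
            )
        sim = SimulationConfig(**sim)
        sim.validate()
    return RunConfig(simulate=sim, **payload)
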