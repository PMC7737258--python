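"""CSV/JSON readers and writers with explicit schema validation.

All angles are serialized in degrees.  CSVs are comma-separated UTF-8 with a
mandatory header row and "." decimals; numeric fields round-trip at full
float precision (17 significant digits).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .cohort import COHORT_COLUMNS
from .errors import SchemaError
from .geometry import CupOrientation, PelvisPose
from .projection import BeamConfig
from .sweep import SWEEP_COLUMNS, CorrectionModel, SweepTable

__all__ = [
    "SceneConfig",
    "read_scene_config",
    "write_sweep_csv",
    "read_sweep_csv",
    "write_cohort_csv",
    "read_cohort_csv",
    "read_ratings_csv",
    "write_model_json",
    "read_model_json",
]

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class SceneConfig:
    """Flat scene description: cup, pose and beam in one JSON object."""

    anteversion_deg: float = 15.0
    inclination_deg: float = 45.0
    radius_mm: float = 24.0
    side: str = "right"
    pelvic_tilt_deg: float = 60.0
    natural_tilt_deg: float = 60.0
    beam_to_long_axis_deg: float = 45.0

    def cup(self) -> CupOrientation:
        return CupOrientation(
            anteversion_deg=self.anteversion_deg,
            inclination_deg=self.inclination_deg,
            radius_mm=self.radius_mm,
            side=self.side,
        )

    def pose(self) -> PelvisPose:
        return PelvisPose(
            pelvic_tilt_deg=self.pelvic_tilt_deg,
            natural_tilt_deg=self.natural_tilt_deg,
        )

    def beam(self) -> BeamConfig:
        return BeamConfig(
            beam_to_long_axis_deg=self.beam_to_long_axis_deg, side=self.side
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_scene_config(path: str | Path) -> SceneConfig:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    known = set(SceneConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"{path}: unknown scene keys {sorted(unknown)}")
    return SceneConfig(**payload)


def _read_csv_checked(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty CSV, expected columns {list(columns)}") from exc
    missing = [c for c in columns if c not in df.columns]
    unknown = [c for c in df.columns if c not in columns]
    if missing or unknown:
        raise SchemaError(
            f"{path}: bad header (missing {missing}, unknown {unknown}); "
            f"expected exactly {list(columns)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{path}: CSV has a header but no rows")
    return df[list(columns)]


def write_sweep_csv(path: str | Path, table: SweepTable) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sweep_csv(path: str | Path, **metadata) -> SweepTable:
    df = _read_csv_checked(path, SWEEP_COLUMNS)
    return SweepTable(data=df, **metadata)


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, COHORT_COLUMNS)


def read_ratings_csv(path: str | Path):
    """Read a ratings CSV: a ``subject_id`` column plus one column per rater.

    Returns ``(matrix, rater_labels)`` with subjects in row order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty CSV") from exc
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'subject_id'")
    raters = [c for c in df.columns if c != "subject_id"]
    if len(raters) < 2:
        raise SchemaError(f"{path}: need at least 2 rater columns, got {raters}")
    values = df[raters].to_numpy(dtype=float)
    return values, tuple(raters)


def write_model_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model_json(path: str | Path) -> CorrectionModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return CorrectionModel(
            tilt_coefficient=float(payload["tilt_coefficient"]),
            va_coefficient=float(payload["va_coefficient"]),
            offset_deg=float(payload["offset_deg"]),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing model key {exc}") from exc
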